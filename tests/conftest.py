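import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ppi_pharmscreen as pp
from ppi_pharmscreen import synthetic as syn

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def interface():
    structure, hotspots = syn.make_toy_interface()
    return structure, hotspots


@pytest.fixture(scope="session")
def receptor_model(interface):
    """Receptor-side 5-point model: 2 anion, 2 aromatic, 1 essential hydrophobic."""
    structure, hotspots = interface
    model = pp.build_interface_model(structure, hotspots["receptor"], name="receptor_model")
    model.constraints = pp.either_or_constraints([("F1", "F2"), ("F3", "F4")], ["F5"])
    return model


@pytest.fixture(scope="session")
def cytokine_model(interface):
    structure, hotspots = interface
    model = pp.build_interface_model(structure, hotspots["cytokine"], name="cytokine_model")
    model.constraints = pp.either_or_constraints([("F1", "F2"), ("F3", "F4")], ["F5"])
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
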