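import numpy as np
import pytest
from hypothesis import settings

import afferentsim as af

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def base_model():
    """Bare ML core, no added channels: the onset-only reference."""
    return af.reference_model("base")


@pytest.fixture(scope="session")
def normal_model():
    """Added channels at the normal operating point (gNa=2.0, gK=2.5)."""
    return af.reference_model("normal")


@pytest.fixture(scope="session")
def neuropathic_model():
    """Added channels past the tipping point (gNa=2.5, gK=2.0)."""
    return af.reference_model("neuropathic")


@pytest.fixture(scope="session")
def neuropathic_diagram(neuropathic_model):
    """1-D bifurcation diagram of the neuropathic cell (computed once)."""
    from afferentsim.dynamics import scan_Istim

    return scan_Istim(neuropathic_model, n_samples=29)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
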