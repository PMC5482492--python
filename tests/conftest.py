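import numpy as np
import pytest
from hypothesis import settings

from mitobetaox.model import Model, default_initial_state
from mitobetaox.protocols import state_protocol
from mitobetaox.simulate import dose_response_scan, find_steady_state

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

PCOA_GRID_MM = np.linspace(0.0, 0.04, 21)


@pytest.fixture(scope="session")
def model():
    return Model()


@pytest.fixture(scope="session")
def y0():
    return default_initial_state()


class SteadyStateCache:
    """Compute each (PCoA, ADP, scales) steady state once per session,
    warm-starting from the nearest previously converged state."""

    def __init__(self, model: Model):
        self.model = model
        self._cache = {}

    def get(self, pcoa_mM: float, adp_mM: float, **scales):
        key = (round(pcoa_mM, 9), round(adp_mM, 9),
               tuple(sorted(scales.items())))
        if key not in self._cache:
            mdl = self.model
            if scales:
                mdl = Model(mdl.params.replace(**scales))
            warm = None
            for (p, a, sc), res in self._cache.items():
                if a == key[1] and sc == key[2] and res.converged:
                    warm = res.state
            proto = state_protocol(pcoa_mM=pcoa_mM, adp_mM=adp_mM)
            self._cache[key] = find_steady_state(mdl, proto, initial=warm)
        return self._cache[key]


@pytest.fixture(scope="session")
def steady(model):
    return SteadyStateCache(model)


@pytest.fixture(scope="session")
def state4_scan(model):
    """State-4 dose-response over the standard 21-point grid (control)."""
    from mitobetaox.protocols import STATE4_ADP
    return dose_response_scan(model, PCOA_GRID_MM, STATE4_ADP)


@pytest.fixture(scope="session")
def state3_scan(model):
    """State-3 dose-response over the standard 21-point grid (control)."""
    from mitobetaox.protocols import STATE3_ADP
    return dose_response_scan(model, PCOA_GRID_MM, STATE3_ADP)
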