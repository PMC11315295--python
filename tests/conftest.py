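import numpy as np
import pytest

from phagequant import GrowthCurve, SimulationConfig


def logistic(t, n0, k, r):
    """Closed-form logistic, kept independent of the package's evaluator."""
    t = np.asarray(t, dtype=float)
    return k / (1.0 + ((k - n0) / n0) * np.exp(-r * t))


@pytest.fixture
def control_curve():
    """Noiseless logistic control sampled every 5 min over 0-12 h."""
    t = np.arange(0, 12.0 + 1e-9, 1 / 12)
    return GrowthCurve("ctrl", t, logistic(t, 0.05, 1.0, 0.8), treatment="buffer")


@pytest.fixture
def default_config():
    return SimulationConfig(seed=1234)
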