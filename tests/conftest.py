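import numpy as np
import pytest

from fermsense.physiology import CultivationRecord, StrainParams


@pytest.fixture
def constant_our_record():
    """Constant OUR = alpha, unit grid: biomass gains 1 g/L per step."""
    t = np.arange(6.0)
    return CultivationRecord(
        experiment_id="const", times=t, our=np.full(6, 1.0),
        cpr=np.full(6, 1.0), broth_weight=np.full(6, 3.7),
        feed_glucose=np.zeros(6), x0=1.0, s0=10.0)


@pytest.fixture
def default_params():
    return StrainParams(alpha=1.0, beta=0.0, k_cX=0.0, X_cX=0.0)


def make_record(times, our, x0=1.0):
    times = np.asarray(times, dtype=float)
    our = np.asarray(our, dtype=float)
    n = times.size
    return CultivationRecord(
        experiment_id="synthetic", times=times, our=our,
        cpr=np.zeros(n), broth_weight=np.full(n, 3.7),
        feed_glucose=np.zeros(n), x0=x0, s0=10.0)
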