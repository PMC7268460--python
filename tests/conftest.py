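import numpy as np
import pytest

from selfpace import estimator as est
from selfpace import simulator as sim


def quiet_walker(**kw):
    """Walker with all stochastic inputs disabled (deterministic gait)."""
    defaults = dict(accel_noise_std=0.0, cop_noise_std=0.0,
                    step_time_jitter_std=0.0)
    defaults.update(kw)
    return sim.WalkerParams(**defaults)


@pytest.fixture(scope="session")
def noisefree_log():
    """30-s constant-speed open-loop trial, no noise, default oscillation."""
    return sim.synth_trial(quiet_walker(), "const_1.3", 30.0, seed=11)


@pytest.fixture(scope="session")
def noisefree_est(noisefree_log):
    series = noisefree_log.series()
    return est.run_offline(series, est.FilterParams(),
                           truth=noisefree_log.ticks)


@pytest.fixture(scope="session")
def closedloop_log():
    """60-s noise-free self-paced trial, walker prefers 1.3 m/s."""
    return sim.closed_loop(quiet_walker(v_pref=1.3), duration=60.0, seed=5)


@pytest.fixture(scope="session")
def standing_series():
    """Quiet standing: constant load split across belts, small noise."""
    rng = np.random.default_rng(7)
    n = 5000
    fs = 1000.0
    from selfpace.forceplate import ForcePlateSeries
    mass = 70.0
    bw = mass * 9.81
    fz_l = 0.5 * bw + rng.normal(0, 5.0, n)
    fz_r = 0.5 * bw + rng.normal(0, 5.0, n)
    zeros = np.zeros(n)
    return ForcePlateSeries(
        fs=fs, fz_l=fz_l, fy_l=zeros.copy(), copy_l=np.full(n, -0.05),
        fz_r=fz_r, fy_r=zeros.copy(), copy_r=np.full(n, 0.05),
        vtm=zeros.copy())
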