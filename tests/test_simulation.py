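import numpy as np
import pytest

from lsoadapt.dynamics import lso_rate, steady_q, steady_r
from lsoadapt.params import DEFAULTS
from lsoadapt.simulation import Stepper, integrate, readout
from lsoadapt.stimuli import (
    BinauralStimulus,
    Segment,
    adapter_test_protocol,
    staircase_protocol,
)

NO_AD = DEFAULTS.without_adaptation()


def constant_stimulus(e, c, steps=800, dt=0.001, label="test"):
    ipsi = np.full((steps, 5), e)
    contra = np.full((steps, 5), c)
    return BinauralStimulus(dt, ipsi, contra,
                            [Segment(0, steps, 0.0, 0.0, label)])


def test_rest_is_equilibrium():
    traj = integrate(constant_stimulus(0.0, 0.0, 100), DEFAULTS)
    assert np.all(traj.r == 0.0)
    assert np.all(traj.q == 0.0)
    assert np.all(traj.p == 0.0)


def test_convergence_to_closed_form():
    # uniform constant drives, adaptation off -> algebraic steady state
    e, c = 0.75, 0.25
    traj = integrate(constant_stimulus(e, c), NO_AD,
                     adaptation_enabled=False)
    q_star = steady_q(c, NO_AD)
    r_star = steady_r(e, q_star, NO_AD)
    assert np.allclose(traj.q[-1], q_star, atol=1e-4)
    assert np.allclose(traj.r[-1], r_star, atol=1e-4)


def test_bit_determinism():
    stim = adapter_test_protocol(20.0, 0.0, adapter_s=0.1, silence_s=0.05,
                                 test_s=0.1)
    t1 = integrate(stim, DEFAULTS)
    t2 = integrate(stim, DEFAULTS)
    assert np.array_equal(t1.r, t2.r)
    assert np.array_equal(t1.q, t2.q)
    assert np.array_equal(t1.p, t2.p)


def test_step_halving_stability():
    e, c = 0.75, 0.25
    end1 = integrate(constant_stimulus(e, c, 800, dt=0.001), NO_AD).r[-1]
    end2 = integrate(constant_stimulus(e, c, 1600, dt=0.0005), NO_AD).r[-1]
    assert np.max(np.abs(end1 - end2)) < 1e-3


def test_boundedness_under_extreme_inputs():
    for e, c in [(1.0, 0.0), (0.0, 1.0), (1.0, 1.0)]:
        traj = integrate(constant_stimulus(e, c), DEFAULTS)
        assert np.all(traj.r >= -0.75 - 1e-9)
        assert np.all(traj.r <= 1.0 + 1e-9)
        assert np.all(traj.q >= -1e-12)
        assert np.all(traj.p >= 0.0)


def test_rate_monotone_in_levels():
    # steady rate increases with ipsi drive and decreases with contra drive
    def rate(e, c):
        traj = integrate(constant_stimulus(e, c), DEFAULTS)
        return lso_rate(traj.r[-1, 2], DEFAULTS)

    assert rate(0.8, 0.3) > rate(0.5, 0.3)
    assert rate(0.5, 0.6) < rate(0.5, 0.3)


def test_zero_adaptation_equivalence():
    """adaptation_enabled=False equals lambda_e=lambda_i=delta_r=0 exactly."""
    stim = constant_stimulus(0.7, 0.4, 400)
    a = integrate(stim, DEFAULTS, adaptation_enabled=False)
    b = integrate(stim, NO_AD, adaptation_enabled=True)
    assert np.array_equal(a.r, b.r)
    assert np.array_equal(a.q, b.q)


def test_stepper_update_order_manual():
    # one Euler step from rest under full drive, checked by hand
    step = Stepper(NO_AD, dt=0.001, adaptation_enabled=False)
    r, q, p = step(np.zeros(5), np.zeros(5), np.zeros(5),
                   np.ones(5), np.ones(5))
    assert np.allclose(q, 0.001 / 0.025 * 1.0)  # beta_q * drive * dt/tau_q
    assert np.allclose(r, 0.001 / 0.025 * 1.0)  # (beta_r - 0) * exc * dt/tau_r
    assert np.allclose(p, 0.0)  # driven by previous r = 0


def test_divergence_detected():
    # an unstable step size must raise, not return garbage
    bad = DEFAULTS.with_overrides(tau_r=1e-5)
    with pytest.raises(FloatingPointError):
        integrate(constant_stimulus(1.0, 1.0, 200), bad)


def test_band_count_mismatch():
    stim = BinauralStimulus(0.001, np.zeros((10, 3)), np.zeros((10, 3)))
    with pytest.raises(ValueError):
        integrate(stim, DEFAULTS)


def test_readout_plateau_end_matches_steady():
    stim = staircase_protocol(n_plateaus=2, steps_per_plateau=800)
    traj = integrate(stim, NO_AD, adaptation_enabled=False)
    pairs = readout(traj, "plateau_end")
    assert len(pairs) == 2
    # ILD +40: e=1, c=0 -> r* = 0.5, rate = g_r(0.5)
    expected = lso_rate(np.array(steady_r(1.0, 0.0, NO_AD)), NO_AD)
    assert pairs[0][1] == pytest.approx(float(expected), abs=1e-4)


def test_readout_onset_delay():
    stim = adapter_test_protocol(0.0, 20.0, adapter_s=0.1, silence_s=0.05,
                                 test_s=0.3)
    traj = integrate(stim, DEFAULTS)
    pairs = readout(traj, "onset_delay", delay_s=0.1)
    assert len(pairs) == 1
    assert pairs[0][0] == "test"
    seg = stim.segment("test")
    idx = seg.start + 1000  # 100 ms wall at the 0.1 ms wall step
    assert pairs[0][1] == pytest.approx(
        float(lso_rate(traj.r[idx, 2], DEFAULTS)))


def test_readout_errors():
    stim = adapter_test_protocol(0.0, 20.0, adapter_s=0.1, silence_s=0.05,
                                 test_s=0.1)
    traj = integrate(stim, DEFAULTS)
    with pytest.raises(ValueError):
        readout(traj, "onset_delay", delay_s=0.5)
    with pytest.raises(IndexError):
        readout(traj, neuron_index=7)
    with pytest.raises(ValueError):
        readout(traj, policy="median")
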