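"""Explicit-Euler integration of the coupled r/q/p system over stimuli.

The model is fully deterministic: identical inputs and parameters produce
bit-identical trajectories.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParameters
from .kernels import KernelSet, _modulation
from .dynamics import lso_rate, mntb_rate
from .stimuli import BinauralStimulus, Segment, WALL_SECONDS_PER_MODEL_SECOND

__all__ = ["Trajectory", "integrate", "readout", "Stepper"]


class Stepper:
    """Pre-bound Euler update for states of shape (..., n).

    Update order within a step: q and p advance using the previous r; r then
    advances using kernels modulated by the just-computed p and the previous
    rectified q.  p is clamped non-negative.
    """

    def __init__(self, params: ModelParameters, kernels: KernelSet | None = None,
                 dt: float = 0.001, adaptation_enabled: bool = True):
        self.params = params
        self.kernels = kernels or KernelSet.from_params(params)
        self.dt = dt
        self.adaptation_enabled = adaptation_enabled
        self._ee_t = self.kernels.ee.T.copy()
        self._ei_t = self.kernels.ei.T.copy()
        self._ei_off_t = (self.kernels.ei + params.delta_r).T.copy()
        self._ie_t = self.kernels.ie.T.copy()

    def __call__(self, r, q, p, s_r, s_q):
        pr = self.params
        dt = self.dt
        gq = np.maximum(q, 0.0)
        q_new = q + (dt / pr.tau_q) * (
            -pr.alpha_q * q + pr.beta_q * (s_q @ self._ie_t)
        )
        drive = lso_rate(r, pr) if pr.gaba_rate_driven else r
        p_new = np.clip(
            p + (dt / pr.tau_p) * (-pr.alpha_p * p + (pr.beta_p - p) * drive),
            0.0, None,
        )
        if self.adaptation_enabled:
            exc = _modulation(pr.lambda_e, p_new) * (s_r @ self._ee_t)
            inh = _modulation(pr.lambda_i, p_new) * (gq @ self._ei_off_t)
        else:
            exc = s_r @ self._ee_t
            inh = gq @ self._ei_t
        r_new = r + (dt / pr.tau_r) * (
            -pr.alpha_r * r
            + (pr.beta_r - r) * exc
            - (pr.gamma_r + pr.kappa_r * r) * inh
        )
        return r_new, q_new, p_new

    def run_constant(self, r, q, p, s_r, s_q, n_steps: int):
        """Advance ``n_steps`` with constant (broadcastable) drives."""
        for _ in range(n_steps):
            r, q, p = self(r, q, p, s_r, s_q)
        return r, q, p


@dataclass
class Trajectory:
    """Recorded state time series plus the stimulus segment metadata."""

    dt: float
    r: np.ndarray  # (T, n)
    q: np.ndarray
    p: np.ndarray
    segments: list[Segment] = field(default_factory=list)
    params: ModelParameters | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.r.shape[0]) * self.dt

    @property
    def rate_r(self) -> np.ndarray:
        return lso_rate(self.r, self.params or ModelParameters())


def integrate(
    stimulus: BinauralStimulus,
    params: ModelParameters,
    adaptation_enabled: bool = True,
    initial_state=None,
    kernels: KernelSet | None = None,
) -> Trajectory:
    """Forward-Euler integration of a stimulus from rest (or a given state)."""
    n = params.n_neurons
    if stimulus.n_bands != n:
        raise ValueError(
            f"stimulus has {stimulus.n_bands} bands, model has {n}"
        )
    if initial_state is None:
        r = np.zeros(n); q = np.zeros(n); p = np.zeros(n)
    else:
        r, q, p = (np.array(x, dtype=float) for x in initial_state)
    step = Stepper(params, kernels, stimulus.dt, adaptation_enabled)
    T = stimulus.n_steps
    out_r = np.empty((T, n)); out_q = np.empty((T, n)); out_p = np.empty((T, n))
    r_bound = 10.0 * max(params.beta_r, params.gamma_r / max(params.kappa_r, 1e-12))
    si, sc = stimulus.s_ipsi, stimulus.s_contra
    for t in range(T):
        r, q, p = step(r, q, p, si[t], sc[t])
        out_r[t] = r; out_q[t] = q; out_p[t] = p
        if not np.all(np.abs(r) <= r_bound):
            raise FloatingPointError(f"integration diverged at step {t}")
    return Trajectory(stimulus.dt, out_r, out_q, out_p,
                      list(stimulus.segments), params)


def readout(
    trajectory: Trajectory,
    policy: str = "plateau_end",
    delay_s: float = 0.1,
    neuron_index: int | None = None,
) -> list[tuple[str, float]]:
    """Per-segment firing-rate readouts of a single neuron.

    ``plateau_end`` returns the rate at each measurement segment's final
    step; ``onset_delay`` returns the rate ``delay_s`` wall seconds after the
    onset of each segment labelled ``test``.  Segments without a nominal ILD
    (silence, preroll) are skipped.
    """
    params = trajectory.params or ModelParameters()
    n = trajectory.r.shape[1]
    if neuron_index is None:
        neuron_index = n // 2
    if not 0 <= neuron_index < n:
        raise IndexError(f"neuron_index {neuron_index} out of range")
    rates = lso_rate(trajectory.r[:, neuron_index], params)
    out: list[tuple[str, float]] = []
    if policy == "plateau_end":
        for seg in trajectory.segments:
            if seg.ild is None:
                continue
            out.append((seg.label, float(rates[seg.end - 1])))
    elif policy == "onset_delay":
        delay_steps = int(round(
            delay_s / WALL_SECONDS_PER_MODEL_SECOND / trajectory.dt))
        for seg in trajectory.segments:
            if seg.label != "test":
                continue
            idx = seg.start + delay_steps
            if idx >= seg.end:
                raise ValueError(
                    f"readout delay {delay_s} s exceeds segment {seg.label!r}"
                )
            out.append((seg.label, float(rates[idx])))
    else:
        raise ValueError(f"unknown readout policy {policy!r}")
    return out
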