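"""Drift terms, output nonlinearities and closed-form steady states.

State variables (one value per band):
  r  LSO membrane state, bounded in [-gamma_r/kappa_r, beta_r]
  q  MNTB membrane state, non-negative for non-negative inputs
  p  retrograde GABA receptor activation, clamped non-negative

The drifts are written for arrays of shape (..., n); leading axes are batch
dimensions.
"""
from __future__ import annotations

import numpy as np

from .params import ModelParameters
from .kernels import KernelSet, _modulation

__all__ = [
    "lso_rate",
    "mntb_rate",
    "lso_drift",
    "mntb_drift",
    "gaba_drift",
    "steady_r",
    "steady_q",
    "steady_p",
]


def lso_rate(r: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Logistic firing-rate readout g_r(r) in (0, 1)."""
    with np.errstate(over="ignore"):  # deep hyperpolarization saturates to 0
        return 1.0 / (1.0 + np.exp(-(np.asarray(r) - params.b) * params.a))


def mntb_rate(q: np.ndarray) -> np.ndarray:
    """Half-wave rectified MNTB rate g_q(q) = max(q, 0)."""
    return np.maximum(np.asarray(q), 0.0)


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise FloatingPointError("non-finite value in state or input")


def lso_drift(
    r: np.ndarray,
    q: np.ndarray,
    p: np.ndarray,
    s_r: np.ndarray,
    params: ModelParameters,
    kernels: KernelSet,
) -> np.ndarray:
    """dr/dt for the LSO band population.

    Excitation is the ipsi drive through the GABA-modulated excitatory
    kernel; inhibition is the rectified MNTB rate through the modulated,
    delta_r-offset inhibitory kernel.  Both modulation factors are clamped to
    [0, 1] so synapses can be silenced but never change sign.
    """
    _check_finite(r, q, p, s_r)
    exc = _modulation(params.lambda_e, p) * (np.asarray(s_r) @ kernels.ee.T)
    inh = _modulation(params.lambda_i, p) * (
        mntb_rate(q) @ (kernels.ei + params.delta_r).T
    )
    return (
        -params.alpha_r * r
        + (params.beta_r - r) * exc
        - (params.gamma_r + params.kappa_r * r) * inh
    ) / params.tau_r


def mntb_drift(
    q: np.ndarray, s_q: np.ndarray, params: ModelParameters, kernels: KernelSet
) -> np.ndarray:
    """dq/dt for the MNTB relay: linear low-pass of the contra drive."""
    _check_finite(q, s_q)
    return (
        -params.alpha_q * q + params.beta_q * (np.asarray(s_q) @ kernels.ie.T)
    ) / params.tau_q


def gaba_drift(p: np.ndarray, r: np.ndarray, params: ModelParameters) -> np.ndarray:
    """dp/dt for the GABA receptor activation, driven by LSO activity.

    By default the drive is the raw membrane state r (the printed form of the
    equation); with ``params.gaba_rate_driven`` it is the firing rate g_r(r).
    """
    _check_finite(p, r)
    drive = lso_rate(r, params) if params.gaba_rate_driven else r
    return (-params.alpha_p * p + (params.beta_p - p) * drive) / params.tau_p


# ---------------------------------------------------------------------------
# Closed-form steady states (integration oracles, adaptation disabled)

def steady_r(exc: float, inh: float, params: ModelParameters) -> float:
    """Steady LSO state for constant total excitation and inhibition."""
    return (params.beta_r * exc - params.gamma_r * inh) / (
        params.alpha_r + exc + params.kappa_r * inh
    )


def steady_q(drive: float, params: ModelParameters) -> float:
    """Steady MNTB state for a constant kernel-filtered contra drive."""
    return params.beta_q * drive / params.alpha_q


def steady_p(r: float, params: ModelParameters) -> float:
    """Steady GABA activation for constant positive LSO activity."""
    if r <= 0:
        return 0.0
    return params.beta_p * r / (params.alpha_p + r)
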