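"""Gaussian connection kernels and their GABA-modulated effective forms.

Each kernel row holds the input weights of one band; rows are normalized to
sum to 1 so that uniform inputs drive every band identically (this preserves
the closed-form steady states used as integrator oracles).  Band distance is
the integer index difference.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters

__all__ = [
    "gaussian_kernel",
    "KernelSet",
    "effective_excitatory_kernel",
    "effective_inhibitory_kernel",
]


def gaussian_kernel(n: int, sigma: float) -> np.ndarray:
    """Row-normalized Gaussian kernel over integer band distances."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.arange(n)[:, None] - np.arange(n)[None, :]
    w = np.exp(-(d.astype(float) ** 2) / (2.0 * sigma**2))
    return w / w.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class KernelSet:
    """The three static kernels of the circuit."""

    ee: np.ndarray  # ipsi excitation -> LSO
    ei: np.ndarray  # MNTB inhibition -> LSO
    ie: np.ndarray  # contra excitation -> MNTB

    @classmethod
    def from_params(cls, params: ModelParameters) -> "KernelSet":
        n = params.n_neurons
        return cls(
            ee=gaussian_kernel(n, params.sigma_ee),
            ei=gaussian_kernel(n, params.sigma_ei),
            ie=gaussian_kernel(n, params.sigma_ie),
        )


def _modulation(lam: float, p: np.ndarray) -> np.ndarray:
    """Synaptic efficacy factor clamp(1 - lam*p) in [0, 1], one per row."""
    return np.clip(1.0 - lam * np.asarray(p, dtype=float), 0.0, 1.0)


def effective_excitatory_kernel(
    kernel_ee: np.ndarray, lambda_e: float, p: np.ndarray
) -> np.ndarray:
    """Row-wise GABA modulation of the excitatory kernel."""
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != kernel_ee.shape[0]:
        raise ValueError(
            f"p has {p.shape[-1]} entries but kernel has {kernel_ee.shape[0]} rows"
        )
    return _modulation(lambda_e, p)[..., :, None] * kernel_ee


def effective_inhibitory_kernel(
    kernel_ei: np.ndarray, delta_r: float, lambda_i: float, p: np.ndarray
) -> np.ndarray:
    """Row-wise GABA modulation of the offset inhibitory kernel.

    ``delta_r`` is added to every entry before modulation, so an unmodulated
    row with unit sum acquires row sum ``1 + n*delta_r``.
    """
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != kernel_ei.shape[0]:
        raise ValueError(
            f"p has {p.shape[-1]} entries but kernel has {kernel_ei.shape[0]} rows"
        )
    return _modulation(lambda_i, p)[..., :, None] * (kernel_ei + delta_r)
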