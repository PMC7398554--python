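"""Model parameters for the LSO/MNTB rate model.

All rate constants are expressed per model second; the integrator uses an
explicit Euler step ``dt`` in model seconds.  One model second corresponds to
0.1 s of wall-clock time under the calibration used throughout (see
docs/methods.md), so the default step ``dt = 0.001`` represents 0.1 ms.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, replace, fields

import yaml

__all__ = ["ModelParameters", "DEFAULTS"]


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the coupled LSO (r), MNTB (q) and GABA (p) dynamics.

    Defaults are the published operating point of the model (its Table-1
    equivalent).  ``lambda_e``/``lambda_i`` are the retrograde-GABA
    effectiveness factors on the excitatory and inhibitory inputs; ``delta_r``
    is the constant offset added to every entry of the inhibitory kernel.
    """

    n_neurons: int = 5
    # logistic output nonlinearity g_r
    a: float = 20.0
    b: float = 0.2
    # LSO membrane (Eq for r)
    tau_r: float = 0.025
    alpha_r: float = 1.0
    beta_r: float = 1.0
    gamma_r: float = 3.0
    kappa_r: float = 4.0
    # GABA effectiveness and inhibitory offset
    lambda_i: float = 1.0
    lambda_e: float = 2.0
    sigma_ee: float = 0.5
    sigma_ei: float = 0.6
    delta_r: float = 0.16
    # MNTB relay (Eq for q)
    tau_q: float = 0.025
    alpha_q: float = 2.0
    beta_q: float = 1.0
    sigma_ie: float = 0.1
    # retrograde GABA receptor activation (Eq for p)
    tau_p: float = 2500.0
    alpha_p: float = 25.0
    beta_p: float = 125.0
    # whether Eq 4 is driven by the raw membrane state r (default) or by the
    # firing rate g_r(r); the raw-state form is the printed equation.
    gaba_rate_driven: bool = False

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        for name in ("tau_r", "tau_q", "tau_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sigma_ee", "sigma_ei", "sigma_ie"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("lambda_e", "lambda_i"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_overrides(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **kwargs)

    def without_adaptation(self) -> "ModelParameters":
        """Copy with the GABA pathway and inhibitory offset disabled."""
        return self.with_overrides(lambda_e=0.0, lambda_i=0.0, delta_r=0.0)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        """Write parameters as a flat YAML document (lossless round-trip)."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ModelParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path} does not contain a parameter mapping")
        return cls(**data)


DEFAULTS = ModelParameters()
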