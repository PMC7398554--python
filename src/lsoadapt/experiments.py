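"""End-to-end experiment runners.

All runners are deterministic and return plain data structures; the CLI
serializes them.  Batched integration over grid dimensions keeps runtimes in
the seconds-to-minutes range.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParameters, DEFAULTS
from .kernels import KernelSet
from .dynamics import lso_rate
from .stimuli import (
    DEFAULT_DT,
    FINE_DT,
    WALL_SECONDS_PER_MODEL_SECOND,
    ild_to_drives,
)
from .analysis import (
    ResponseCurve,
    coding_precision,
    precision_at,
    measure_shift,
    criterion_ild,
    lambda_sweep,
    adaptation_range,
    trading_value,
    AdaptationMeasurement,
    SweepResult,
)

__all__ = [
    "ild_grid",
    "default_response_curve",
    "run_exp1",
    "run_exp2",
    "run_exp3",
    "run_exp4",
    "run_fig5",
    "exp3_reference_curve",
    "uv_shape_metrics",
]

ILD_GRID = np.arange(-40.0, 41.0, 2.0)
ITD_GRID = np.arange(-800.0, 401.0, 50.0)

def _steps(wall_seconds: float, dt: float) -> int:
    """Euler steps covering a wall-clock duration at step ``dt``."""
    return int(round(wall_seconds / WALL_SECONDS_PER_MODEL_SECOND / dt))


#: wall durations (seconds) of the standard protocol pieces
PLATEAU_S = 0.040
READOUT_DELAY_S = 0.100
ADAPTER_S = 1.2
SILENCE_S = 0.5
RAMP_S = 0.010


def ild_grid() -> np.ndarray:
    return ILD_GRID.copy()


def _drive_arrays(grid=ILD_GRID, base_level: float = 20.0):
    e = np.array([ild_to_drives(x, base_level)[0] for x in grid])
    c = np.array([ild_to_drives(x, base_level)[1] for x in grid])
    return e, c


class _BatchEngine:
    """Euler stepping for states (..., n) with broadcastable per-batch
    lambda_e / lambda_i / gamma_r / kappa_r overrides.

    Drives are uniform across bands (scalars or arrays broadcastable to the
    batch shape, without the band axis).  Because every kernel row is
    normalized to 1, a uniform drive passes through the excitatory and MNTB
    kernels unchanged, so only the inhibitory kernel needs a matrix product.
    """

    def __init__(self, params: ModelParameters, dt: float = DEFAULT_DT,
                 lam_e=None, lam_i=None, gamma_r=None, kappa_r=None,
                 delta_r=None, adaptation: bool = True):
        self.p = params
        self.dt = dt
        self.kern = KernelSet.from_params(params)
        self.lam_e = params.lambda_e if lam_e is None else lam_e
        self.lam_i = params.lambda_i if lam_i is None else lam_i
        self.gamma_r = params.gamma_r if gamma_r is None else gamma_r
        self.kappa_r = params.kappa_r if kappa_r is None else kappa_r
        dr = params.delta_r if delta_r is None else delta_r
        self.adaptation = adaptation
        if not adaptation:
            dr = 0.0
        self._ei_off_t = (self.kern.ei + dr).T.copy()

    def zeros(self, *batch_shape):
        shape = batch_shape + (self.p.n_neurons,)
        return np.zeros(shape), np.zeros(shape), np.zeros(shape)

    def step(self, r, q, p, s_r, s_q):
        pr = self.p
        dt = self.dt
        gq = np.maximum(q, 0.0)
        q_new = q + (dt / pr.tau_q) * (-pr.alpha_q * q + pr.beta_q * s_q)
        drive = lso_rate(r, pr) if pr.gaba_rate_driven else r
        p_new = np.clip(
            p + (dt / pr.tau_p) * (-pr.alpha_p * p + (pr.beta_p - p) * drive),
            0.0, None)
        exc = s_r
        inh = gq @ self._ei_off_t
        if self.adaptation:
            exc = np.clip(1.0 - self.lam_e * p_new, 0.0, 1.0) * exc
            inh = np.clip(1.0 - self.lam_i * p_new, 0.0, 1.0) * inh
        r_new = r + (dt / pr.tau_r) * (
            -pr.alpha_r * r + (pr.beta_r - r) * exc
            - (self.gamma_r + self.kappa_r * r) * inh)
        return r_new, q_new, p_new

    def run_constant(self, r, q, p, e_drive, c_drive, steps: int):
        for _ in range(steps):
            r, q, p = self.step(r, q, p, e_drive, c_drive)
        return r, q, p

    def run_envelope(self, r, q, p, e_drive, c_drive, envelope):
        for w in envelope:
            r, q, p = self.step(r, q, p, w * e_drive, w * c_drive)
        return r, q, p


def _readout_rates(engine: _BatchEngine, r) -> np.ndarray:
    """Middle-band firing rate from an LSO state array."""
    return lso_rate(r[..., engine.p.n_neurons // 2], engine.p)


# ---------------------------------------------------------------------------
# Experiment 1: default response and gamma_r / kappa_r influence

def _staircase_curves(engine: _BatchEngine, batch_shape=()) -> np.ndarray:
    """Plateau-end rates over the descending staircase, carrying state."""
    r, q, p = engine.zeros(*batch_shape)
    e, c = _drive_arrays()
    steps = _steps(PLATEAU_S, engine.dt)
    rates = np.empty(batch_shape + (len(ILD_GRID),))
    for k in range(len(ILD_GRID) - 1, -1, -1):  # staircase runs +40 -> -40
        r, q, p = engine.run_constant(r, q, p, e[k], c[k], steps)
        rates[..., k] = _readout_rates(engine, r)
    return rates


def default_response_curve(params: ModelParameters = DEFAULTS,
                           dt: float = DEFAULT_DT) -> ResponseCurve:
    """Staircase response of the middle neuron with adaptation disabled."""
    engine = _BatchEngine(params, dt=dt, adaptation=False)
    return ResponseCurve(ILD_GRID, _staircase_curves(engine), "default")


def run_exp1(
    params: ModelParameters = DEFAULTS,
    gamma_values: np.ndarray | None = None,
    kappa_values: np.ndarray | None = None,
    dt: float = DEFAULT_DT,
) -> dict:
    """Response curves over gamma_r in [0, 3.5] and kappa_r in [0, 14].

    The GABA pathway is disabled throughout (the experiment characterizes
    the static response).
    """
    gammas = (np.linspace(0.0, 3.5, 8) if gamma_values is None
              else np.asarray(gamma_values, dtype=float))
    kappas = (np.linspace(0.0, 14.0, 8) if kappa_values is None
              else np.asarray(kappa_values, dtype=float))
    if np.any(gammas < 0) or np.any(gammas > 3.5):
        raise ValueError("gamma_r values must lie in [0, 3.5]")
    if np.any(kappas < 0) or np.any(kappas > 14.0):
        raise ValueError("kappa_r values must lie in [0, 14]")
    eng_g = _BatchEngine(params, dt=dt, adaptation=False,
                         gamma_r=gammas[:, None, None])
    g_rates = _staircase_curves(eng_g, (len(gammas), 1))[:, 0, :]
    eng_k = _BatchEngine(params, dt=dt, adaptation=False,
                         kappa_r=kappas[:, None, None])
    k_rates = _staircase_curves(eng_k, (len(kappas), 1))[:, 0, :]
    return {
        "default": default_response_curve(params, dt),
        "gamma_values": gammas,
        "gamma_curves": [
            ResponseCurve(ILD_GRID, g_rates[i], f"gamma_r={g:g}")
            for i, g in enumerate(gammas)
        ],
        "kappa_values": kappas,
        "kappa_curves": [
            ResponseCurve(ILD_GRID, k_rates[i], f"kappa_r={k:g}")
            for i, k in enumerate(kappas)
        ],
    }


# ---------------------------------------------------------------------------
# Adapter conditioning helpers (Experiments 2 and 3)

def _adapter_envelope(steps: int, ramp: int) -> np.ndarray:
    env = np.ones(steps)
    if ramp:
        env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
        env[-ramp:] = np.linspace(1.0, 0.0, ramp)
    return env


def _adapted_test_rates(engine: _BatchEngine, adapter_drives,
                        adapter_s: float = ADAPTER_S) -> np.ndarray:
    """Adapter + silence conditioning, then all 41 test tones in parallel.

    ``adapter_drives`` is an (e, c) pair of arrays broadcastable to the
    engine batch shape.  Returns middle-band rates 100 ms after test onset.
    """
    e_ad, c_ad = adapter_drives
    batch = np.broadcast_shapes(np.shape(e_ad), np.shape(c_ad))
    r, q, p = engine.zeros(*batch, 1)
    env = _adapter_envelope(_steps(adapter_s, engine.dt),
                            _steps(RAMP_S, engine.dt))
    r, q, p = engine.run_envelope(r, q, p, e_ad[..., None, None],
                                 c_ad[..., None, None], env)
    r, q, p = engine.run_constant(r, q, p, 0.0, 0.0,
                                  _steps(SILENCE_S, engine.dt))
    e, c = _drive_arrays()
    K = len(ILD_GRID)
    n = engine.p.n_neurons
    r = np.broadcast_to(r, batch + (K, n)).copy()
    q = np.broadcast_to(q, batch + (K, n)).copy()
    p = np.broadcast_to(p, batch + (K, n)).copy()
    r, q, p = engine.run_constant(r, q, p, e[:, None], c[:, None],
                                  _steps(READOUT_DELAY_S, engine.dt))
    return _readout_rates(engine, r)


def exp3_reference_curve(params: ModelParameters = DEFAULTS,
                         dt: float = DEFAULT_DT) -> ResponseCurve:
    """No-adapter test response, measured exactly like the adapted ones."""
    engine = _BatchEngine(params, dt=dt)
    e, c = _drive_arrays()
    r, q, p = engine.zeros(len(ILD_GRID))
    r, q, p = engine.run_constant(r, q, p, e[:, None], c[:, None],
                                  _steps(READOUT_DELAY_S, dt))
    return ResponseCurve(ILD_GRID, _readout_rates(engine, r), "no adapter")


# ---------------------------------------------------------------------------
# Experiment 2: lambda sweep

def run_exp2(
    params: ModelParameters = DEFAULTS,
    resolution: float = 0.05,
    adapter_ild: float = 40.0,
    adapter_s: float = ADAPTER_S,
    saturation_tolerance_db: float = 0.5,
    dt: float = DEFAULT_DT,
) -> dict:
    """Exhaustive (lambda_e, lambda_i) sweep with ridge fit and saturation.

    Each cell runs the adapter-conditioning protocol with its own lambda
    pair, measures the test response curve and records its peak coding
    precision.  The ridge is the per-lambda_e argmax over lambda_i.
    """
    lam = np.round(np.arange(0.0, 1.0 + 1e-9, resolution), 6)
    LE, LI = np.meshgrid(lam, lam, indexing="ij")
    engine = _BatchEngine(
        params, dt=dt, lam_e=LE.reshape(-1, 1, 1), lam_i=LI.reshape(-1, 1, 1))
    e_ad, c_ad = ild_to_drives(adapter_ild)
    rates = _adapted_test_rates(
        engine,
        (np.full(LE.size, e_ad), np.full(LE.size, c_ad)),
        adapter_s,
    )
    peak_map = np.empty(LE.size)
    for i in range(LE.size):
        peak_map[i] = coding_precision(
            ResponseCurve(ILD_GRID, rates[i])).peak_value
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sweep = lambda_sweep(lam, lam, peak_map.reshape(LE.shape))

    # response-curve shift along the fitted ridge line
    ridge_li = np.clip(sweep.fit_slope * lam + sweep.fit_intercept, 0.0, 1.0)
    engine2 = _BatchEngine(
        params, dt=dt, lam_e=lam[:, None, None], lam_i=ridge_li[:, None, None])
    rates2 = _adapted_test_rates(
        engine2,
        (np.full(len(lam), e_ad), np.full(len(lam), c_ad)),
        adapter_s,
    )
    reference = coding_precision(exp3_reference_curve(params, dt))
    shifts = np.array([
        coding_precision(ResponseCurve(ILD_GRID, rates2[i])).peak_ild
        - reference.peak_ild
        for i in range(len(lam))
    ])
    sat_lambda_e, max_shift, saturated = adaptation_range(
        lam[1:], shifts[1:], saturation_tolerance_db)
    return {
        "sweep": sweep,
        "ridge_lambda_i": ridge_li,
        "shifts_along_ridge": shifts,
        "saturation_lambda_e": sat_lambda_e,
        "max_shift_db": max_shift,
        "saturated": saturated,
    }


# ---------------------------------------------------------------------------
# Experiment 3: adapter-tone paradigm

def run_exp3(
    params: ModelParameters = DEFAULTS,
    adapter_grid: np.ndarray | None = None,
    dt: float = DEFAULT_DT,
) -> dict:
    """41 x 41 adapter/test matrix plus per-adapter shift measurements."""
    adapters = ILD_GRID if adapter_grid is None else np.asarray(adapter_grid)
    engine = _BatchEngine(params, dt=dt)
    e_ad, c_ad = _drive_arrays(adapters)
    matrix = _adapted_test_rates(engine, (e_ad, c_ad))  # (n_adapters, 41)
    reference = exp3_reference_curve(params, dt)
    ref_cp = coding_precision(reference)
    curves, measurements = [], []
    for i, ad in enumerate(adapters):
        curve = ResponseCurve(ILD_GRID, matrix[i], f"adapter={ad:g}")
        cp = coding_precision(curve)
        m = measure_shift(cp, ref_cp)
        # sensitivity gain at the adapter-side ILD where the adapted peak sits
        local_ref = precision_at(ref_cp, cp.peak_ild)
        local_gain = (100.0 * (cp.peak_value / local_ref - 1.0)
                      if local_ref > 0 else float("inf"))
        curves.append(curve)
        measurements.append(AdaptationMeasurement(
            m.shift_db, local_gain, reference="no adapter"))
    return {
        "adapter_grid": np.asarray(adapters, dtype=float),
        "matrix": matrix,
        "curves": curves,
        "reference": reference,
        "measurements": measurements,
        "peak_gains": [
            measure_shift(coding_precision(c), ref_cp).gain_percent
            for c in curves
        ],
    }


# ---------------------------------------------------------------------------
# Experiment 4: timing / time-intensity trading

def run_exp4(
    params: ModelParameters = DEFAULTS,
    itd_grid: np.ndarray | None = None,
    trading_rate_us_per_db: float = 10.0,
    duration_wall_us: float = 20000.0,
    step_wall_us: float = 10.0,
    dt: float = DEFAULT_DT,
) -> dict:
    """Onset-timing experiment on the (ILD, ITD) grid.

    Constant drives with per-channel onset shifts: the contralateral onset
    is delayed by -ITD, and each onset is advanced by the trading rate times
    its level.  The experiment runs on the dedicated fast time base in which
    one Euler step of size ``dt`` represents ``step_wall_us`` microseconds
    (the membrane time constant then sits in the few-hundred-microsecond
    range where sub-millisecond onset timing matters).  The transient
    response is summarized by the maximal firing rate over the trace
    (``peak`` readout); the final steady rate is kept as the ``steady``
    readout.  The unadapted reference is the steady zero-ITD, zero-trading
    slice, which coincides with the default response curve.
    """
    itds = ITD_GRID if itd_grid is None else np.asarray(itd_grid, dtype=float)
    step_us = step_wall_us
    levels_i = 20.0 + ILD_GRID / 2.0
    levels_c = 20.0 - ILD_GRID / 2.0
    on_i = -trading_rate_us_per_db * levels_i[None, :] * np.ones((len(itds), 1))
    on_c = -itds[:, None] - trading_rate_us_per_db * levels_c[None, :]
    origin = min(on_i.min(), on_c.min())
    on_i = np.rint((on_i - origin) / step_us).astype(int)[:, :, None]
    on_c = np.rint((on_c - origin) / step_us).astype(int)[:, :, None]
    n_on = int(round(duration_wall_us / step_us))
    T = int(max(on_i.max(), on_c.max())) + n_on

    engine = _BatchEngine(params, dt=dt, adaptation=False)
    e, c = _drive_arrays()
    E = np.broadcast_to(e[None, :, None],
                        (len(itds), len(ILD_GRID), params.n_neurons))
    C = np.broadcast_to(c[None, :, None], E.shape)
    r, q, p = engine.zeros(len(itds), len(ILD_GRID))
    peak = np.zeros((len(itds), len(ILD_GRID)))
    for t in range(T):
        r, q, p = engine.step(r, q, p,
                              np.where(t >= on_i, E, 0.0),
                              np.where(t >= on_c, C, 0.0))
        np.maximum(peak, _readout_rates(engine, r), out=peak)
    steady = _readout_rates(engine, r)

    curves = [ResponseCurve(ILD_GRID, peak[m], f"itd={itds[m]:g}us")
              for m in range(len(itds))]
    reference = default_response_curve(params)
    ref_cp = coding_precision(reference)
    ref_mid = criterion_ild(reference)
    precisions = [coding_precision(cv) for cv in curves]
    peak_ilds = np.array([cp.peak_ild for cp in precisions])
    mids = np.array([
        (criterion_ild(cv) if criterion_ild(cv) is not None else np.nan)
        for cv in curves
    ])

    span = (itds >= -600.0) & (itds <= 200.0)
    max_displacement = float(peak_ilds[span].max() - peak_ilds[span].min())
    i_shift = int(np.argmax(np.abs(peak_ilds - ref_cp.peak_ild)))
    gain_percent = 100.0 * (precisions[i_shift].peak_value
                            / ref_cp.peak_value - 1.0)
    m600 = int(np.argmin(np.abs(itds - (-600.0))))
    trading = trading_value(
        [itds[m600], 0.0], [curves[m600], reference])
    positive = itds > 0
    ipsi_shift = float(np.nanmax(mids[positive] - ref_mid)) \
        if positive.any() else float("nan")
    return {
        "itd_grid": itds,
        "surface_peak": peak,
        "surface_steady": steady,
        "curves": curves,
        "reference": reference,
        "max_peak_displacement_db": max_displacement,
        "max_shift_itd_us": float(itds[i_shift]),
        "sensitivity_gain_percent": float(gain_percent),
        "trading_value_us_per_db": float(trading),
        "ipsilateral_shift_db": ipsi_shift,
        "midpoints": mids,
        "peak_ilds": peak_ilds,
    }


def uv_shape_metrics(exp4_result: dict, ild: float = -20.0) -> dict:
    """Curvature asymmetry of the rate-vs-ITD section at a negative ILD.

    The section falls from a released response at contralateral-leading
    (negative) ITDs to the suppressed floor at positive ITDs.  The
    negative-ITD limb ends in a sharp elbow (V-like) while the positive-ITD
    limb is smooth (U-like); the metric compares the maximal absolute second
    difference on each side.
    """
    j = int(np.searchsorted(ILD_GRID, ild))
    itds = exp4_result["itd_grid"]
    section = exp4_result["surface_peak"][:, j]
    d2 = np.abs(np.diff(section, 2))
    inner = itds[1:-1]
    v = float(d2[inner < 0].max())
    u = float(d2[inner > 0].max())
    return {"ild": float(ILD_GRID[j]), "v_curvature": v, "u_curvature": u,
            "v_sharper_than_u": bool(v > u)}


# ---------------------------------------------------------------------------
# Fig 5 style comparison

def run_fig5(params: ModelParameters = DEFAULTS,
             exp3_result: dict | None = None,
             exp4_result: dict | None = None) -> dict:
    """GABA vs timing adaptation: maximal shifts, gains, combined range."""
    e3 = exp3_result if exp3_result is not None else run_exp3(params)
    e4 = exp4_result if exp4_result is not None else run_exp4(params)
    shifts = np.array([m.shift_db for m in e3["measurements"]])
    i_max = int(np.argmax(np.abs(shifts)))
    gaba_shift = float(shifts[i_max])
    gaba_gain = float(e3["measurements"][i_max].gain_percent)
    itd_shift = float(e4["max_peak_displacement_db"])
    itd_gain = float(e4["sensitivity_gain_percent"])
    return {
        "gaba_shift_db": gaba_shift,
        "gaba_gain_percent": gaba_gain,
        "itd_shift_db": itd_shift,
        "itd_gain_percent": itd_gain,
        "combined_range_db": abs(gaba_shift) + abs(itd_shift),
    }
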