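"""Response curves, coding precision, adaptation measurements, the
lambda-sweep ridge fit and the time-intensity trading value."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResponseCurve",
    "CodingPrecisionCurve",
    "SweepResult",
    "AdaptationMeasurement",
    "response_curve",
    "coding_precision",
    "measure_shift",
    "criterion_ild",
    "zero_response_ild",
    "lambda_sweep",
    "adaptation_range",
    "trading_value",
]


@dataclass
class ResponseCurve:
    """Firing rate of the readout neuron over an ascending ILD grid."""

    ild_grid: np.ndarray
    rates: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.ild_grid = np.asarray(self.ild_grid, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.ild_grid.shape != self.rates.shape:
            raise ValueError("grid and rates lengths differ")
        if len(self.ild_grid) < 3:
            raise ValueError("need at least 3 distinct ILDs")
        if np.any(np.diff(self.ild_grid) <= 0):
            raise ValueError("ild_grid must be strictly ascending")
        if np.any(self.rates < 0) or np.any(self.rates > 1):
            raise ValueError("rates must lie in [0, 1]")


def response_curve(readouts, label: str = "") -> ResponseCurve:
    """Build a validated curve from (ILD, rate) pairs."""
    pairs = sorted(readouts)
    ilds = np.array([x for x, _ in pairs], dtype=float)
    rates = np.array([y for _, y in pairs], dtype=float)
    dup = np.isclose(np.diff(ilds), 0.0)
    if np.any(dup):
        for i in np.flatnonzero(dup):
            if not np.isclose(rates[i], rates[i + 1]):
                raise ValueError(
                    f"duplicate ILD {ilds[i]:g} with differing rates"
                )
        keep = np.concatenate([[True], ~dup])
        ilds, rates = ilds[keep], rates[keep]
    return ResponseCurve(ilds, rates, label)


@dataclass
class CodingPrecisionCurve:
    """Central-difference derivative of a response curve (interior points).

    ``peak_ild`` carries a 3-point parabolic sub-grid refinement around the
    discrete argmax; ``peak_value`` is the discrete maximum.
    """

    ild_grid: np.ndarray
    precision: np.ndarray
    peak_ild: float
    peak_value: float
    label: str = ""


def coding_precision(curve: ResponseCurve) -> CodingPrecisionCurve:
    grid, rates = curve.ild_grid, curve.rates
    spacing = np.diff(grid)
    if np.ptp(spacing) > 1e-9:
        raise ValueError("coding precision requires a uniform ILD grid")
    h = spacing[0]
    prec = (rates[2:] - rates[:-2]) / (2.0 * h)
    interior = grid[1:-1]
    k = int(np.argmax(prec))
    peak_ild = float(interior[k])
    peak_value = float(prec[k])
    if 0 < k < len(prec) - 1:
        # parabola through the three points around the argmax
        a = (prec[k - 1] + prec[k + 1]) / 2.0 - prec[k]
        b = (prec[k + 1] - prec[k - 1]) / 2.0
        if a < 0:
            peak_ild = float(interior[k] - h * b / (2.0 * a))
    return CodingPrecisionCurve(interior, prec, peak_ild, peak_value,
                                curve.label)


def precision_at(cp: CodingPrecisionCurve, ild: float) -> float:
    """Linearly interpolated precision at an arbitrary ILD."""
    return float(np.interp(ild, cp.ild_grid, cp.precision))


@dataclass
class AdaptationMeasurement:
    shift_db: float
    gain_percent: float
    reference: str = ""


def measure_shift(
    test: CodingPrecisionCurve, reference: CodingPrecisionCurve
) -> AdaptationMeasurement:
    """Peak displacement and peak-ratio sensitivity gain vs a reference."""
    if (len(test.ild_grid) != len(reference.ild_grid)
            or np.any(test.ild_grid != reference.ild_grid)):
        raise ValueError("curves must share the same ILD grid")
    if reference.peak_value <= 0:
        raise ValueError("reference peak precision is zero; gain undefined")
    return AdaptationMeasurement(
        shift_db=test.peak_ild - reference.peak_ild,
        gain_percent=100.0 * (test.peak_value / reference.peak_value - 1.0),
        reference=reference.label,
    )


def zero_response_ild(curve: ResponseCurve, floor: float = 0.0,
                      margin: float = 0.002) -> float | None:
    """First grid ILD at which the rate exceeds the zero floor.

    ``floor`` is the resting output of the rate nonlinearity (g_r(0) for the
    default parameters); ``margin`` guards against numerical dust.  Returns
    None if the curve never leaves the floor.
    """
    above = curve.rates > floor + margin
    if not above.any():
        return None
    return float(curve.ild_grid[int(np.argmax(above))])


def criterion_ild(curve: ResponseCurve, criterion: float = 0.5) -> float | None:
    """ILD of the first upward crossing of ``criterion`` (linear interp)."""
    r = curve.rates
    above = r >= criterion
    for i in range(len(r) - 1):
        if not above[i] and above[i + 1]:
            x0, x1 = curve.ild_grid[i], curve.ild_grid[i + 1]
            y0, y1 = r[i], r[i + 1]
            return float(x0 + (criterion - y0) * (x1 - x0) / (y1 - y0))
    if above[0]:
        return float(curve.ild_grid[0])
    return None


@dataclass
class SweepResult:
    lambda_e_grid: np.ndarray
    lambda_i_grid: np.ndarray
    precision_map: np.ndarray  # rows: lambda_e, cols: lambda_i
    ridge_points: np.ndarray  # per-lambda_e argmax over lambda_i
    fit_slope: float
    fit_intercept: float
    field_label: str = "peak coding precision"

    @property
    def implied_ratio(self) -> float:
        """lambda_e : lambda_i effectiveness ratio implied by the ridge."""
        return 1.0 / self.fit_slope if self.fit_slope else float("nan")


def lambda_sweep(
    lambda_e_grid: np.ndarray,
    lambda_i_grid: np.ndarray,
    precision_map: np.ndarray,
) -> SweepResult:
    """Ridge extraction and least-squares line fit on a precision map.

    The ridge is the per-lambda_e argmax over lambda_i; ties resolve to the
    smallest lambda_i (with a warning for fully degenerate columns).
    """
    le = np.asarray(lambda_e_grid, dtype=float)
    li = np.asarray(lambda_i_grid, dtype=float)
    pm = np.asarray(precision_map, dtype=float)
    if pm.shape != (len(le), len(li)):
        raise ValueError("precision_map shape does not match grids")
    ridge = np.empty(len(le))
    for i in range(len(le)):
        col = pm[i]
        if np.ptp(col) == 0:
            warnings.warn(
                f"degenerate ridge column at lambda_e={le[i]:g}; "
                "tie resolved to smallest lambda_i"
            )
        ridge[i] = li[int(np.argmax(col))]
    m, b = np.polyfit(le, ridge, 1)
    return SweepResult(le, li, pm, ridge, float(m), float(b))


def adaptation_range(
    lambda_e_values: np.ndarray,
    shifts_db: np.ndarray,
    tolerance_db: float = 0.5,
) -> tuple[float, float, bool]:
    """Saturation point of the response shift along a monotone lambda path.

    Returns ``(saturating_lambda_e, max_shift_db, saturated)`` where the
    saturating value is the smallest lambda_e beyond which every subsequent
    change of the shift stays below ``tolerance_db``; ``saturated`` is False
    if that never happens within the grid (the boundary is reported).
    """
    le = np.asarray(lambda_e_values, dtype=float)
    sh = np.asarray(shifts_db, dtype=float)
    if len(le) != len(sh) or len(le) < 2:
        raise ValueError("need matching lambda/shift sequences of length >= 2")
    if np.any(np.diff(le) <= 0):
        raise ValueError("lambda sequence must be strictly increasing")
    diffs = np.abs(np.diff(sh))
    for i in range(len(diffs)):
        if np.all(diffs[i:] < tolerance_db):
            return float(le[i]), float(np.max(np.abs(sh))), True
    return float(le[-1]), float(np.max(np.abs(sh))), False


def trading_value(
    itd_grid_us: np.ndarray,
    curves: list[ResponseCurve],
    criterion: float = 0.5,
) -> float:
    """|dITD| / |d(criterion ILD)| between the extreme ITDs of the grid."""
    itds = np.asarray(itd_grid_us, dtype=float)
    if len(itds) < 2 or len(curves) != len(itds):
        raise ValueError("need >= 2 ITDs with one curve each")
    crossings = []
    for itd, curve in zip(itds, curves):
        x = criterion_ild(curve, criterion)
        if x is None:
            warnings.warn(f"criterion never crossed at ITD {itd:g} us; excluded")
            continue
        crossings.append((itd, x))
    if len(crossings) < 2:
        raise ValueError("fewer than two curves cross the criterion")
    (itd_lo, x_lo) = min(crossings)
    (itd_hi, x_hi) = max(crossings)
    d_ild = x_hi - x_lo
    if d_ild == 0:
        raise ValueError("zero criterion-point shift; trading value undefined")
    return abs(itd_hi - itd_lo) / abs(d_ild)
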