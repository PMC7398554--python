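import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lsoadapt.analysis import (
    CodingPrecisionCurve,
    ResponseCurve,
    adaptation_range,
    coding_precision,
    criterion_ild,
    lambda_sweep,
    measure_shift,
    precision_at,
    response_curve,
    trading_value,
    zero_response_ild,
)

GRID = np.arange(-40.0, 41.0, 2.0)


def logistic_curve(center, slope=0.1, label=""):
    return ResponseCurve(GRID, 1.0 / (1.0 + np.exp(-(GRID - center) * slope)),
                         label)


def test_response_curve_validation():
    with pytest.raises(ValueError):
        ResponseCurve([0, 1], [0.1, 0.2])  # too short
    with pytest.raises(ValueError):
        ResponseCurve([0, 1, 1], [0.1, 0.2, 0.3])  # not ascending
    with pytest.raises(ValueError):
        ResponseCurve([0, 1, 2], [0.1, 1.2, 0.3])  # rate out of [0, 1]


def test_response_curve_from_pairs():
    c = response_curve([(2.0, 0.3), (0.0, 0.1), (1.0, 0.2), (2.0, 0.3)])
    assert np.allclose(c.ild_grid, [0.0, 1.0, 2.0])
    with pytest.raises(ValueError):
        response_curve([(0.0, 0.1), (0.0, 0.5), (1.0, 0.2)])


def test_precision_constant_curve():
    cp = coding_precision(ResponseCurve(GRID, np.full_like(GRID, 0.3)))
    assert np.allclose(cp.precision, 0.0)


@settings(max_examples=30, deadline=None)
@given(st.floats(1e-4, 0.01), st.floats(0.0, 0.1))
def test_precision_linear_curve_exact(slope, offset):
    # central differences are exact on affine data
    rates = offset + slope * (GRID + 40.0)
    cp = coding_precision(ResponseCurve(GRID, np.clip(rates, 0.0, 1.0)))
    if rates.max() <= 1.0:
        assert np.allclose(cp.precision, slope)


def test_precision_logistic_second_order():
    # O(h^2) agreement with the analytic derivative on a logistic curve
    def analytic(x, c=0.0, s=0.1):
        f = 1.0 / (1.0 + np.exp(-(x - c) * s))
        return s * f * (1 - f)

    errs = []
    for h in (2.0, 1.0):
        grid = np.arange(-40.0, 40.0 + h / 2, h)
        rates = 1.0 / (1.0 + np.exp(-grid * 0.1))
        cp = coding_precision(ResponseCurve(grid, rates))
        errs.append(np.max(np.abs(cp.precision - analytic(grid[1:-1]))))
    assert errs[1] < errs[0] / 3.5  # roughly quartered when h halves


def test_precision_nonuniform_grid_rejected():
    grid = np.array([0.0, 1.0, 3.0, 4.0])
    with pytest.raises(ValueError):
        coding_precision(ResponseCurve(grid, np.full(4, 0.2)))


def test_parabolic_refinement_recovers_vertex():
    # a cubic response has a parabolic derivative; the central difference of
    # a cubic equals that parabola up to a constant shift, so the 3-point
    # refinement recovers the off-grid vertex exactly
    vertex, a, c = 7.3, 1e-5, 0.02
    rates = 0.5 + 0.5 * (c * GRID - a * (GRID - vertex) ** 3 / 3.0)
    assert rates.min() >= 0.0 and rates.max() <= 1.0
    cp = coding_precision(ResponseCurve(GRID, rates))
    assert cp.peak_ild == pytest.approx(vertex, abs=1e-6)


def test_precision_at_interpolates():
    cp = CodingPrecisionCurve(np.array([0.0, 1.0, 2.0]),
                              np.array([0.0, 0.2, 0.1]), 1.0, 0.2)
    assert precision_at(cp, 0.5) == pytest.approx(0.1)
    assert precision_at(cp, 1.5) == pytest.approx(0.15)


def test_measure_shift_arithmetic():
    grid = np.arange(-38.0, 39.0, 2.0)
    ref = CodingPrecisionCurve(grid, np.zeros_like(grid), 25.0, 0.02, "ref")
    test = CodingPrecisionCurve(grid, np.zeros_like(grid), 20.0, 0.04)
    m = measure_shift(test, ref)
    assert m.shift_db == pytest.approx(-5.0)
    assert m.gain_percent == pytest.approx(100.0)
    same = measure_shift(ref, ref)
    assert same.shift_db == 0.0 and same.gain_percent == 0.0


def test_measure_shift_errors():
    grid = np.arange(-38.0, 39.0, 2.0)
    ref = CodingPrecisionCurve(grid, np.zeros_like(grid), 25.0, 0.0)
    test = CodingPrecisionCurve(grid, np.zeros_like(grid), 20.0, 0.04)
    with pytest.raises(ValueError):
        measure_shift(test, ref)  # zero reference peak
    other = CodingPrecisionCurve(grid[:-1], np.zeros(len(grid) - 1), 0.0, 0.1)
    with pytest.raises(ValueError):
        measure_shift(other, test)


def test_criterion_ild_interpolation():
    c = logistic_curve(10.0)
    x = criterion_ild(c)
    assert x == pytest.approx(10.0, abs=1e-6)
    flat = ResponseCurve(GRID, np.full_like(GRID, 0.1))
    assert criterion_ild(flat) is None
    high = ResponseCurve(GRID, np.full_like(GRID, 0.9))
    assert criterion_ild(high) == GRID[0]


def test_zero_response_ild():
    rates = np.where(GRID >= 10.0, 0.5, 0.01)
    c = ResponseCurve(GRID, rates)
    assert zero_response_ild(c, floor=0.018) == 10.0
    assert zero_response_ild(ResponseCurve(GRID, np.full_like(GRID, 0.01)),
                             floor=0.018) is None


def test_lambda_sweep_synthetic_ridge():
    le = np.arange(0.0, 1.01, 0.05)
    li = np.arange(0.0, 1.01, 0.05)
    true_m, true_b = 0.8, -0.06
    pm = np.empty((len(le), len(li)))
    for i, e in enumerate(le):
        pm[i] = -np.abs(li - (true_m * e + true_b))
    res = lambda_sweep(le, li, pm)
    assert res.fit_slope == pytest.approx(true_m, abs=0.05)
    assert res.fit_intercept == pytest.approx(true_b, abs=0.05)
    assert res.implied_ratio == pytest.approx(1.0 / true_m, abs=0.1)


def test_lambda_sweep_tie_break_and_shape():
    le = li = np.array([0.0, 0.5, 1.0])
    flat = np.ones((3, 3))
    with pytest.warns(UserWarning):
        res = lambda_sweep(le, li, flat)
    assert np.allclose(res.ridge_points, 0.0)  # smallest lambda_i wins ties
    with pytest.raises(ValueError):
        lambda_sweep(le, li, np.ones((3, 4)))


def test_adaptation_range_saturation():
    le = np.arange(0.1, 1.01, 0.1)
    shifts = np.minimum(le * 10.0, 5.0)  # saturates at le = 0.5
    sat, max_shift, ok = adaptation_range(le, shifts, 0.5)
    assert ok
    assert sat == pytest.approx(0.5, abs=0.1 + 1e-9)
    assert max_shift == pytest.approx(5.0)
    sat2, _, ok2 = adaptation_range(le, le * 10.0, 0.5)
    assert not ok2 and sat2 == le[-1]
    with pytest.raises(ValueError):
        adaptation_range([0.1], [1.0])
    with pytest.raises(ValueError):
        adaptation_range([0.2, 0.1], [1.0, 2.0])


def test_trading_value_example():
    # 38 dB criterion shift over 600 us -> about 15.8 us/dB
    c0 = logistic_curve(20.0)
    c1 = logistic_curve(-18.0)
    v = trading_value([-600.0, 0.0], [c1, c0])
    assert v == pytest.approx(600.0 / 38.0, abs=1e-6)


def test_trading_value_ratio_invariance():
    # halving both the ITD span and the criterion shift leaves the ratio
    c0 = logistic_curve(20.0)
    v1 = trading_value([-600.0, 0.0], [logistic_curve(-18.0), c0])
    v2 = trading_value([-300.0, 0.0], [logistic_curve(1.0), c0])
    assert v1 == pytest.approx(600.0 / 38.0, abs=1e-6)
    assert v2 == pytest.approx(300.0 / 19.0, abs=1e-6)
    assert v1 == pytest.approx(v2, rel=1e-9)


def test_trading_value_errors():
    c0 = logistic_curve(20.0)
    with pytest.raises(ValueError):
        trading_value([-600.0, 0.0], [c0, c0])  # zero shift
    with pytest.raises(ValueError):
        trading_value([0.0], [c0])
    flat = ResponseCurve(GRID, np.full_like(GRID, 0.1))
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError):
            trading_value([-600.0, 0.0], [flat, c0])
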