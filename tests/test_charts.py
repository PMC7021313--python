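"""Chart recursions vs brute-force oracles, reduction identities, limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spcmix import initial_state, limits_at, make_chart, step
from spcmix.charts import ewma_ma_update, ewma_update, ma_ewma_update, ma_update


def run_statistic(kind, xs, lambda_=1.0, w=1, smoothing="ma"):
    chart = make_chart(kind, lambda_=lambda_, w=w, H=3.0, center=0.0, scale=1.0,
                      smoothing=smoothing)
    state = initial_state(chart)
    out = []
    for x in xs:
        state, stat, _, _ = step(chart, state, x)
        out.append(stat)
    return np.asarray(out)


# ---------------------------------------------------------------- oracles


def brute_windowed_mean(xs, w):
    """Mean of the last min(t, w) values, from the stored full history."""
    return np.array([np.mean(xs[max(0, t - w):t]) for t in range(1, len(xs) + 1)])


def closed_form_ewma(xs, lam, z0=0.0):
    """Z_t = lam * sum_j (1-lam)^j x_{t-j} + (1-lam)^t Z_0."""
    out = []
    for t in range(1, len(xs) + 1):
        weights = lam * (1 - lam) ** np.arange(t)
        out.append(float(weights @ xs[t - 1::-1] + (1 - lam) ** t * z0))
    return np.array(out)


@pytest.fixture
def xs(rng):
    return rng.normal(size=200)


def test_ma_matches_brute_force_windowed_mean(xs):
    got = run_statistic("ma", xs, w=5)
    np.testing.assert_allclose(got, brute_windowed_mean(xs, 5), atol=1e-12)


def test_ewma_matches_closed_form_geometric_sum(xs):
    got = run_statistic("ewma", xs, lambda_=0.25)
    np.testing.assert_allclose(got, closed_form_ewma(xs, 0.25), atol=1e-12)


def test_ewma_ma_matches_composition_of_oracles(xs):
    """EWMA-MA = closed-form EWMA applied to the brute-force windowed means."""
    got = run_statistic("ewma_ma", xs, lambda_=0.25, w=5)
    expected = closed_form_ewma(brute_windowed_mean(xs, 5), 0.25)
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_ma_ewma_matches_composition_of_oracles(xs):
    """MA-EWMA = brute-force windowed mean of the closed-form EWMA values."""
    got = run_statistic("ma_ewma", xs, lambda_=0.25, w=5)
    expected = brute_windowed_mean(closed_form_ewma(xs, 0.25), 5)
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_raw_smoothing_is_plain_ewma(xs):
    got = run_statistic("ewma_ma", xs, lambda_=0.25, w=5, smoothing="raw")
    np.testing.assert_allclose(got, closed_form_ewma(xs, 0.25), atol=1e-12)


# ----------------------------------------------------- reduction identities


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=1, max_size=60))
def test_reduction_identities(vals):
    """w=1 / lambda=1 degeneracies collapse every chart onto its parent."""
    xs = np.asarray(vals)
    raw = np.asarray(vals)
    np.testing.assert_allclose(run_statistic("ma", xs, w=1), raw, atol=1e-9)
    np.testing.assert_allclose(run_statistic("ewma", xs, lambda_=1.0), raw, atol=1e-9)
    ewma = run_statistic("ewma", xs, lambda_=0.3)
    np.testing.assert_allclose(run_statistic("ewma_ma", xs, lambda_=0.3, w=1), ewma, atol=1e-9)
    np.testing.assert_allclose(run_statistic("ma_ewma", xs, lambda_=0.3, w=1), ewma, atol=1e-9)
    np.testing.assert_allclose(
        run_statistic("ma_ewma", xs, lambda_=1.0, w=4), run_statistic("ma", xs, w=4), atol=1e-9
    )


def test_constant_input_is_fixed_point():
    xs = np.full(30, 7.5)
    chart = make_chart("ewma_ma", lambda_=0.25, w=5, H=3, center=7.5, scale=1.0)
    state = initial_state(chart)
    for x in xs:
        state, stat, _, sig = step(chart, state, x)
        assert stat == pytest.approx(7.5)
        assert not sig


# ------------------------------------------------------------------ limits


def test_ewma_ma_limit_half_width_table_value():
    """H=6.480, w=5, lam=0.25: half-width 6.480*sqrt((1/5)(0.25/1.75))."""
    chart = make_chart("ewma_ma", lambda_=0.25, w=5, H=6.480, center=0.0, scale=1.0)
    lim = limits_at(chart, 100)
    assert lim.ucl == pytest.approx(6.480 * math.sqrt(0.2 * 0.25 / 1.75), abs=1e-4)
    assert lim.ucl == pytest.approx(1.0953, abs=2e-4)
    assert lim.lcl == pytest.approx(-lim.ucl)


def test_ma_limit_half_width_and_warmup():
    chart = make_chart("ma", w=5, H=3.0, center=0.0, scale=1.0)
    assert limits_at(chart, 5).ucl == pytest.approx(3.0 / math.sqrt(5.0))
    assert limits_at(chart, 1).ucl == pytest.approx(3.0)
    widths = [limits_at(chart, t).ucl for t in range(1, 12)]
    assert all(a >= b - 1e-12 for a, b in zip(widths, widths[1:]))  # non-increasing
    assert widths[5] == widths[10]  # constant past the span


def test_ewma_lambda1_limits_reduce_to_shewhart():
    for mode in ("time_varying", "asymptotic"):
        chart = make_chart("ewma", lambda_=1.0, H=2.5, center=0.0, scale=2.0, limit_mode=mode)
        assert limits_at(chart, 1).ucl == pytest.approx(5.0)


def test_ewma_time_varying_limits_increase_to_asymptote():
    tv = make_chart("ewma", lambda_=0.25, H=3.0, limit_mode="time_varying")
    asym = make_chart("ewma", lambda_=0.25, H=3.0, limit_mode="asymptotic")
    widths = [limits_at(tv, t).ucl for t in range(1, 60)]
    assert all(a <= b + 1e-12 for a, b in zip(widths, widths[1:]))
    assert widths[-1] == pytest.approx(limits_at(asym, 59).ucl, rel=1e-6)


def test_limits_require_positive_time():
    chart = make_chart("shewhart", H=3.0)
    with pytest.raises(ValueError):
        limits_at(chart, 0)


# -------------------------------------------------------------------- step


def test_signal_is_strict_excursion():
    chart = make_chart("shewhart", H=3.0, center=0.0, scale=1.0)
    _, _, _, sig = step(chart, initial_state(chart), 3.0)  # exactly UCL
    assert not sig
    _, _, _, sig = step(chart, initial_state(chart), np.nextafter(3.0, 4.0))
    assert sig
    _, _, _, sig = step(chart, initial_state(chart), -3.5)
    assert sig


@pytest.mark.parametrize(
    "kwargs,err",
    [
        (dict(kind="ma", w=0), "positive integer"),
        (dict(kind="ewma", lambda_=0.0), "lambda_"),
        (dict(kind="ewma", lambda_=1.5), "lambda_"),
        (dict(kind="shewhart", H=-1.0), "H must be"),
        (dict(kind="shewhart", scale=0.0), "scale must be"),
        (dict(kind="cusum"), "unknown chart kind"),
        (dict(kind="ewma", limit_mode="exact"), "unknown limit_mode"),
    ],
)
def test_make_chart_validation(kwargs, err):
    with pytest.raises(ValueError, match=err):
        make_chart(**kwargs)


def test_update_functions_track_state_incrementally(rng):
    """The low-level *_update functions agree with step() dispatch."""
    xs = rng.normal(size=40)
    chart = make_chart("ewma_ma", lambda_=0.4, w=3, H=3)
    s1 = initial_state(chart)
    s2 = initial_state(chart)
    for x in xs:
        s1, stat1, _, _ = step(chart, s1, x)
        s2, stat2 = ewma_ma_update(s2, x, 0.4, 3)
        assert stat1 == pytest.approx(stat2, abs=1e-15)
    assert s1.t == len(xs)
    assert len(s1.buffer) == min(len(xs), 3)


def test_state_invariants_at_zero():
    chart = make_chart("ma_ewma", lambda_=0.2, w=4, H=3, center=5.0)
    state = initial_state(chart)
    assert state.t == 0
    assert state.z == 5.0
    assert state.buffer == []
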