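"""Smoother contracts: diffusion, exponential moving averages, convex envelope,
and divisive de-trending."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import calciumpeaks as cp
from calciumpeaks.smoothing import DIFFUSION_ALPHA
from oracles import (brute_force_lower_hull, diffusion_operator_power,
                     ema_direct, hull_edges_leave_no_point_below)

traces = hnp.arrays(np.float64, st.integers(3, 60),
                    elements=st.floats(-50, 50, allow_nan=False, width=32))


# ---------------------------------------------------------------- diffusion

def test_diffusion_zero_steps_is_identity(rng):
    x = rng.normal(size=30)
    np.testing.assert_array_equal(cp.smooth_diffusion(x, 0), x)


def test_diffusion_constant_is_fixed_point():
    x = np.full(25, 3.7)
    np.testing.assert_allclose(cp.smooth_diffusion(x, 100), x, rtol=1e-12)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(traces, st.integers(0, 200))
def test_diffusion_conserves_mass(x, steps):
    out = cp.smooth_diffusion(x, steps)
    assert out.sum() == pytest.approx(x.sum(), rel=1e-9, abs=1e-9)


def test_diffusion_impulse_matches_operator_power_and_gaussian_variance():
    T, steps = 201, 80
    x = np.zeros(T)
    x[T // 2] = 1.0
    out = cp.smooth_diffusion(x, steps)
    expected = diffusion_operator_power(T, steps) @ x
    np.testing.assert_allclose(out, expected, atol=1e-12)
    # the kernel is near-Gaussian with variance 2*alpha*steps frames^2
    grid = np.arange(T) - T // 2
    var = np.sum(grid ** 2 * out) / out.sum()
    assert abs(var - 2 * DIFFUSION_ALPHA * steps) < 0.1 * 2 * DIFFUSION_ALPHA * steps


def test_diffusion_rejects_negative_smoothness():
    with pytest.raises(cp.ParameterError):
        cp.smooth_diffusion(np.ones(5), -1)


# ---------------------------------------------------------------- EMAs

def test_ema1_constant_is_fixed_point():
    x = np.full(40, 2.5)
    np.testing.assert_allclose(cp.smooth_ema1(x, 40), x, rtol=1e-12)


def test_ema1_unit_smoothness_is_identity(rng):
    x = rng.normal(size=20)
    np.testing.assert_array_equal(cp.smooth_ema1(x, 1), x)
    np.testing.assert_array_equal(cp.smooth_ema1(x, 0), x)


def test_ema1_matches_direct_weighted_sum_on_step():
    x = np.r_[np.zeros(30), np.ones(30)]
    np.testing.assert_allclose(cp.smooth_ema1(x, 40), ema_direct(x, 40), atol=1e-10)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(traces, st.integers(1, 80))
def test_ema1_matches_direct_weighted_sum(x, k):
    np.testing.assert_allclose(cp.smooth_ema1(x, k), ema_direct(x, k),
                               atol=1e-8 * max(1, np.abs(x).max()))


def test_ema1_is_causal(rng):
    x = rng.normal(size=50)
    base = cp.smooth_ema1(x, 20)
    x2 = x.copy()
    x2[30] += 100.0
    pert = cp.smooth_ema1(x2, 20)
    np.testing.assert_array_equal(base[:30], pert[:30])
    assert not np.allclose(base[30:], pert[30:])


def test_ema2_constant_and_palindrome_symmetry(rng):
    np.testing.assert_allclose(cp.smooth_ema2(np.full(15, 7.0), 10), 7.0)
    half = rng.normal(size=20)
    pal = np.r_[half, half[::-1]]
    out = cp.smooth_ema2(pal, 12)
    np.testing.assert_allclose(out, out[::-1], atol=1e-12)


def test_ema2_is_mean_of_forward_and_backward(rng):
    x = rng.normal(size=60)
    forward = cp.smooth_ema1(x, 25)
    backward = cp.smooth_ema1(x[::-1], 25)[::-1]
    np.testing.assert_allclose(cp.smooth_ema2(x, 25), 0.5 * (forward + backward),
                               atol=1e-12)


@pytest.mark.parametrize("smoother", [
    lambda x: cp.smooth_diffusion(x, 40),
    lambda x: cp.smooth_ema1(x, 15),
    lambda x: cp.smooth_ema2(x, 15),
])
def test_value_translation_equivariance(smoother, rng):
    x = rng.normal(size=80)
    np.testing.assert_allclose(smoother(x + 5.0), smoother(x) + 5.0, atol=1e-9)


# ---------------------------------------------------------------- convex

def test_convex_envelope_of_affine_series_is_itself():
    t = np.arange(30, dtype=float)
    x = 2.0 + 0.5 * t
    np.testing.assert_allclose(cp.smooth_convex(x, t), x, atol=1e-12)


def test_convex_envelope_skips_interior_bump():
    x = np.ones(21)
    x[8:13] = [2, 4, 5, 4, 2]
    env = cp.smooth_convex(x)
    np.testing.assert_allclose(env, np.ones(21), atol=1e-12)


def test_convex_hull_matches_brute_force_on_random_series(rng):
    for _ in range(50):
        T = int(rng.integers(3, 51))
        t = np.sort(rng.uniform(0, 10, T))
        t += np.arange(T) * 1e-3  # ensure strictly increasing
        x = rng.normal(size=T)
        verts = cp.lower_hull_indices(t, x)
        expected = brute_force_lower_hull(t, x)
        np.testing.assert_array_equal(verts, expected)
        assert hull_edges_leave_no_point_below(t, x, verts)
        env = cp.smooth_convex(x, t)
        assert np.all(env <= x + 1e-9)
        np.testing.assert_allclose(env[verts], x[verts], atol=1e-12)
        # envelope is convex: second differences at interior vertices
        if len(verts) >= 3:
            slopes = np.diff(x[verts]) / np.diff(t[verts])
            assert np.all(np.diff(slopes) >= -1e-12)


def test_convex_requires_two_points():
    with pytest.raises(cp.ParameterError):
        cp.smooth_convex(np.array([1.0]))


# ---------------------------------------------------------------- detrend

def test_detrend_none_has_mean_exactly_one(rng):
    ts = cp.TraceSet(np.arange(100) * 0.6, ["a", "b"],
                     100 + 10 * rng.standard_normal((2, 100)))
    res = cp.detrend(ts, cp.SmoothingConfig("none"))
    np.testing.assert_allclose(res.detrended.mean(axis=1), 1.0, atol=1e-12)


def test_detrend_convex_bounces_off_one(rng):
    vals = 100 * np.exp(-0.001 * np.arange(200)) * (1 + 0.05 * rng.standard_normal(200))
    ts = cp.TraceSet(np.arange(200) * 0.6, ["a"], vals[None, :])
    res = cp.detrend(ts, cp.SmoothingConfig("convex"))
    assert np.all(res.detrended >= 1.0 - 1e-12)
    contacts = np.isclose(res.trend[0], ts.values[0])
    np.testing.assert_allclose(res.detrended[0][contacts], 1.0, atol=1e-12)
    assert contacts.sum() >= 2


def test_detrend_raises_on_nonpositive_trend_never_emits_inf():
    vals = np.array([[1.0, -5.0, 1.0, 1.0, 1.0]])  # negative dip pulls hull <= 0
    ts = cp.TraceSet(np.arange(5.0), ["bad"], vals)
    with pytest.raises(cp.DegenerateTrendError, match="bad"):
        cp.detrend(ts, cp.SmoothingConfig("convex"))
    neg = cp.TraceSet(np.arange(5.0), ["neg"], -np.ones((1, 5)))
    with pytest.raises(cp.DegenerateTrendError):
        cp.detrend(neg, cp.SmoothingConfig("none"))


def test_ema2_detrending_flattens_bleached_trace():
    t = np.arange(1000) * 0.6
    raw = 100 * np.exp(-np.log(1 / 0.7) * t / t[-1])  # 30% loss, no events
    ts = cp.TraceSet(t, ["a"], raw[None, :])
    res = cp.detrend(ts, cp.SmoothingConfig("ema2", 20))
    ripple = np.abs(res.detrended[0] - 1).max()
    untreated = np.abs(raw / raw.mean() - 1).max()
    assert ripple < untreated


def test_detrender_estimator_api(rng):
    X = 100 + rng.standard_normal((3, 50))
    est = cp.Detrender(method="ema2", trend_smoothness=10)
    out = est.fit(X).transform(X)
    assert out.shape == X.shape
    assert est.n_features_in_ == 50
    params = est.get_params()
    assert params["method"] == "ema2"
    est.set_params(method="none")
    np.testing.assert_allclose(est.transform(X).mean(axis=1), 1.0, atol=1e-12)
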