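import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocutremor import (
    GazeRecording,
    VelocitySeries,
    angle_between,
    compute_velocity,
    fixational_velocity,
    period_to_frequency,
    reversal_peak,
    reversal_probability,
    unit_velocity,
)
from ocutremor.kinematics import ReversalCurve


def make_rec(x, y, labels=None):
    n = len(x)
    labels = np.array(["FIX"] * n) if labels is None else np.asarray(labels)
    return GazeRecording(np.arange(n, dtype=float), x, y, labels, "T")


class TestComputeVelocity:
    def test_constant_position_gives_zero(self):
        v = compute_velocity(make_rec(np.full(50, 2.0), np.full(50, -1.0)))
        assert np.allclose(v.vx, 0) and np.allclose(v.vy, 0)

    def test_unit_slope_gives_unit_velocity(self):
        t = np.arange(50, dtype=float)
        v = compute_velocity(make_rec(t, np.zeros(50)))
        assert np.allclose(v.vx, 1.0)

    def test_sinusoid_matches_derivative_to_second_order(self):
        t = np.arange(2000, dtype=float)
        f = 0.05  # cycles per ms
        x = np.sin(2 * np.pi * f * t)
        v = compute_velocity(make_rec(x, np.zeros_like(x)))
        # forward difference of sin at t equals the derivative at t + tau/2
        expected = 2 * np.pi * f * np.cos(2 * np.pi * f * (t[:-1] + 0.5))
        assert np.max(np.abs(v.vx - expected)) < (2 * np.pi * f) ** 3 / 24 * 1.1

    def test_blink_adjacent_samples_invalid(self):
        labels = np.array(["FIX", "FIX", "BLINK", "FIX", "FIX"])
        x = np.array([0.0, 1.0, np.nan, 3.0, 4.0])
        v = compute_velocity(make_rec(x, np.zeros(5), labels))
        assert list(v.valid) == [True, False, False, True]

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            compute_velocity(make_rec(np.array([1.0]), np.array([1.0])))


class TestUnitVelocity:
    def test_three_four_five(self):
        v = VelocitySeries(
            np.arange(2.0), np.array([3.0, 3.0]), np.array([4.0, 4.0]),
            np.array([True, True]),
        )
        u = unit_velocity(v)
        assert np.allclose(u.vx, 0.6) and np.allclose(u.vy, 0.8)

    def test_zero_vector_invalid(self):
        v = VelocitySeries(
            np.arange(2.0), np.array([0.0, 1.0]), np.array([0.0, 0.0]),
            np.array([True, True]),
        )
        u = unit_velocity(v)
        assert not u.valid[0] and u.valid[1]

    def test_all_valid_norms_are_one(self, rng):
        n = 500
        v = VelocitySeries(
            np.arange(float(n)), rng.normal(size=n), rng.normal(size=n),
            np.ones(n, bool),
        )
        u = unit_velocity(v)
        assert np.allclose(np.hypot(u.vx[u.valid], u.vy[u.valid]), 1.0, atol=1e-9)


class TestFixationalVelocity:
    def test_all_fix_equals_raw(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        rec = make_rec(x, y)
        vf, vr = fixational_velocity(rec), compute_velocity(rec)
        assert np.allclose(vf.vx, vr.vx) and vf.valid.all()

    def test_all_sacc_empty_with_warning(self):
        rec = make_rec(np.arange(10.0), np.zeros(10), ["SACC"] * 10)
        with pytest.warns(UserWarning):
            v = fixational_velocity(rec)
        assert not v.valid.any()

    def test_valid_exactly_on_fix_fix_pairs(self):
        labels = ["FIX", "FIX", "SACC", "FIX", "FIX", "FIX", "SACC", "SACC", "FIX", "FIX"]
        rec = make_rec(np.arange(10.0), np.zeros(10), labels)
        v = fixational_velocity(rec)
        expected = [a == "FIX" and b == "FIX" for a, b in zip(labels[:-1], labels[1:])]
        assert list(v.valid) == expected


class TestAngleBetween:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((1, 0), (0, 1), np.pi / 2), ((1, 0), (-1, 0), np.pi), ((1, 1), (1, 0), np.pi / 4)],
    )
    def test_examples(self, a, b, expected):
        assert angle_between(a, b) == pytest.approx(expected)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            angle_between((0, 0), (1, 0))

    @settings(deadline=None)
    @given(
        vx=st.floats(-10, 10), vy=st.floats(-10, 10),
        wx=st.floats(-10, 10), wy=st.floats(-10, 10),
        c=st.floats(0.01, 100),
    )
    def test_symmetry_scale_invariance_and_extremes(self, vx, vy, wx, wy, c):
        v, w = (vx, vy), (wx, wy)
        if np.hypot(*v) < 1e-6 or np.hypot(*w) < 1e-6:
            return
        assert angle_between(v, w) == pytest.approx(angle_between(w, v))
        assert angle_between((c * vx, c * vy), w) == pytest.approx(angle_between(v, w), abs=1e-7)
        assert angle_between(v, v) == pytest.approx(0.0, abs=1e-6)
        assert angle_between(v, (-vx, -vy)) == pytest.approx(np.pi, abs=1e-6)


def rotating_velocity(freq_hz, n=5000, fs=1000.0):
    """Unit velocity whose direction rotates uniformly at freq_hz."""
    t = np.arange(n) / fs
    ang = 2 * np.pi * freq_hz * t
    return VelocitySeries(
        np.arange(float(n)), np.cos(ang), np.sin(ang), np.ones(n, bool), "unit"
    )


class TestReversalProbability:
    def test_constant_direction_never_reverses(self):
        v = VelocitySeries(
            np.arange(100.0), np.ones(100), np.full(100, 0.5), np.ones(100, bool)
        )
        for k in (2, 4, 8):
            assert np.allclose(reversal_probability(v, k, [1, 2, 3]).pr, 0.0)

    def test_isotropic_directions_give_one_over_k(self, rng):
        # angles between independent isotropic directions are uniform on
        # [0, pi]; A_k has measure 1/k
        n = 20000
        ang = rng.uniform(0, 2 * np.pi, size=n)
        v = VelocitySeries(np.arange(float(n)), np.cos(ang), np.sin(ang), np.ones(n, bool))
        for k in (2, 4, 8):
            pr = reversal_probability(v, k, [1]).pr[0]
            se = np.sqrt((1 / k) * (1 - 1 / k) / (n - 1))
            assert abs(pr - 1 / k) < 3 * se

    def test_rotating_direction_closed_form(self):
        # at 150 Hz the direction advances 0.3*pi per ms: within lags 1..6 the
        # wrapped angle lies in A_8 = [7pi/8, pi] only at 3 ms (0.9*pi)
        v = rotating_velocity(150.0)
        curve = reversal_probability(v, 8, [1, 2, 3, 4, 5, 6])
        assert np.allclose(curve.pr, [0, 0, 1, 0, 0, 0])

    def test_nonincreasing_in_k(self, tremor_fix_velocity):
        lags = list(range(1, 8))
        prev = None
        for k in (2, 4, 8):
            pr = reversal_probability(tremor_fix_velocity, k, lags).pr
            if prev is not None:
                assert np.all(pr <= prev + 1e-12)
            prev = pr

    def test_unit_variant_equals_raw(self, tremor_fix_velocity):
        raw = reversal_probability(tremor_fix_velocity, 4, [1, 3, 5]).pr
        u = unit_velocity(
            VelocitySeries(
                tremor_fix_velocity.t,
                tremor_fix_velocity.vx,
                tremor_fix_velocity.vy,
                tremor_fix_velocity.valid,
            )
        )
        assert np.allclose(reversal_probability(u, 4, [1, 3, 5]).pr, raw)

    def test_small_valid_set_marked_missing(self):
        v = VelocitySeries(
            np.arange(5.0), np.ones(5), np.zeros(5),
            np.array([True, True, False, False, False]),
        )
        curve = reversal_probability(v, 2, [1, 3], n_min=1)
        assert not np.isnan(curve.pr[0]) and np.isnan(curve.pr[1])

    def test_non_multiple_lag_rejected(self, tremor_fix_velocity):
        with pytest.raises(ValueError):
            reversal_probability(tremor_fix_velocity, 2, [1.5])


class TestReversalPeak:
    def test_argmax(self):
        c = ReversalCurve(2, np.array([1.0, 2, 3, 4]), np.array([0.1, 0.5, 0.9, 0.4]),
                          np.full(4, 100))
        assert reversal_peak(c) == (3.0, 0.9)

    def test_tie_goes_to_smallest_lag(self):
        c = ReversalCurve(2, np.array([1.0, 2, 3, 4]), np.array([0.1, 0.5, 0.9, 0.9]),
                          np.full(4, 100))
        assert reversal_peak(c)[0] == 3.0

    def test_all_missing_raises(self):
        c = ReversalCurve(2, np.array([1.0, 2]), np.array([np.nan, np.nan]), np.zeros(2, int))
        with pytest.raises(ValueError):
            reversal_peak(c)

    def test_synthetic_tremor_peak_near_half_period(self, tremor_fix_velocity):
        curve = reversal_probability(tremor_fix_velocity, 8, list(range(1, 11)))
        tau_max, _ = reversal_peak(curve)
        assert 2.5 <= tau_max <= 3.5  # half-period of 150 Hz is 3.33 ms


class TestPeriodToFrequency:
    @pytest.mark.parametrize(
        "bounds,expected",
        [
            ((6, 8), (125.0, 1000 / 6)),
            ((5, 7), (1000 / 7, 200.0)),
            ((10, 10), (100.0, 100.0)),
        ],
    )
    def test_examples(self, bounds, expected):
        lo, hi = period_to_frequency(bounds)
        assert lo == pytest.approx(expected[0]) and hi == pytest.approx(expected[1])

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            period_to_frequency((0, 5))
        with pytest.raises(ValueError):
            period_to_frequency((5, 3))
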