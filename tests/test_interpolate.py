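import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aainterp.interpolate import (
    InterpolationMethod,
    evaluate_spline,
    fit_cubic_spline,
    linear_interpolant,
    resample,
    target_grid,
)

from oracles import dense_spline_eval

ALL_METHODS = ["linear", "spline", "fmm", "natural", "periodic"]

# Reference values computed with R 4.3.3 stats::spline (an independent
# implementation of the same interpolants) on y = (0.3, 1.7, -0.9, 0.4,
# 2.2, 1.1) at x = (1.5, 2.25, 3.8, 5.5); the periodic row uses the
# endpoint-equal variant y_per = (0.3, 1.7, -0.9, 0.4, 2.2, 0.3).
_R_FIXTURE_Y = [0.3, 1.7, -0.9, 0.4, 2.2, 1.1]
_R_FIXTURE_Y_PER = [0.3, 1.7, -0.9, 0.4, 2.2, 0.3]
_R_FIXTURE_X = [1.5, 2.25, 3.8, 5.5]
_R_REFERENCE = {
    "fmm": [2.073623511905, 1.026548549107, -0.070680952381, 2.203980654762],
    "natural": [1.498086124402, 1.178110047847, -0.105328229665, 1.919677033493],
    "periodic": [1.054545454545, 1.298863636364, -0.159345454545, 1.157954545455],
}


class TestLinearInterpolant:
    def test_segment_midpoint(self):
        assert linear_interpolant([2, 4], 1.5) == 3.0

    def test_constant_data(self):
        assert linear_interpolant([5, 5, 5], 2.7) == 5.0

    def test_segment_formula(self):
        assert linear_interpolant([0, 10, 0], 1.25) == pytest.approx(2.5)

    def test_exact_at_integers(self):
        y = [3.0, -1.0, 7.0, 2.0]
        for i, v in enumerate(y, start=1):
            assert linear_interpolant(y, float(i)) == v

    @pytest.mark.parametrize("x", [0.99, 4.01, -1.0])
    def test_no_extrapolation(self, x):
        with pytest.raises(ValueError, match="outside"):
            linear_interpolant([1, 2, 3, 4], x)


class TestFitCubicSpline:
    def test_linear_data_has_zero_moments(self):
        y = 0.5 + 1.25 * np.arange(1, 8)
        m = fit_cubic_spline(y, "natural")
        assert m.second_derivatives == pytest.approx(np.zeros(7), abs=1e-12)

    def test_hand_solved_natural_three_points(self):
        # y = [0, 1, 0]: single interior equation (2/3) M_2 = -2 => M_2 = -3
        m = fit_cubic_spline([0, 1, 0], "natural")
        assert m.second_derivatives == pytest.approx([0, -3, 0])
        assert evaluate_spline(m, 1.5) == pytest.approx(0.6875)

    def test_periodic_derivative_continuity(self):
        m = fit_cubic_spline([1.0, 0.0, 1.0], "periodic")
        eps = 1e-6

        def deriv(x, h=eps):
            return (evaluate_spline(m, x + h) - evaluate_spline(m, x)) / h

        assert deriv(1.0) == pytest.approx(deriv(3.0 - eps), abs=1e-4)
        assert m.second_derivatives[0] == pytest.approx(m.second_derivatives[-1])

    def test_periodic_unequal_endpoints_rejected(self):
        with pytest.raises(ValueError, match="equal endpoint"):
            fit_cubic_spline([0.0, 1.0, 2.0], "periodic")

    def test_fmm_reproduces_global_cubic(self):
        # the fmm end condition recovers an exact cubic from its samples
        x = np.arange(1, 9, dtype=float)
        y = 0.3 * x**3 - 2 * x**2 + x - 4
        m = fit_cubic_spline(y, "fmm")
        xs = np.linspace(1, 8, 41)
        expect = 0.3 * xs**3 - 2 * xs**2 + xs - 4
        assert evaluate_spline(m, xs) == pytest.approx(expect, abs=1e-9)

    def test_fmm_small_length_fallbacks(self, caplog):
        m = fit_cubic_spline([0, 1, 0], "fmm")
        assert m.boundary == "natural"
        with pytest.raises(ValueError, match="linear"):
            fit_cubic_spline([0, 1], "fmm")

    def test_unknown_boundary(self):
        with pytest.raises(ValueError, match="natural, periodic, fmm"):
            fit_cubic_spline([0, 1, 0], "quadratic")

    @pytest.mark.parametrize("boundary", ["fmm", "natural", "periodic"])
    def test_against_r_stats_spline(self, boundary):
        y = _R_FIXTURE_Y_PER if boundary == "periodic" else _R_FIXTURE_Y
        m = fit_cubic_spline(y, boundary)
        got = evaluate_spline(m, np.array(_R_FIXTURE_X))
        assert got == pytest.approx(_R_REFERENCE[boundary], abs=1e-10)

    @pytest.mark.parametrize("boundary", ["natural", "periodic"])
    def test_against_scipy_cubicspline(self, boundary, rng):
        from scipy.interpolate import CubicSpline

        for _ in range(20):
            L = int(rng.integers(4, 15))
            y = rng.normal(size=L)
            if boundary == "periodic":
                y[-1] = y[0]
            m = fit_cubic_spline(y, boundary)
            ref = CubicSpline(np.arange(1, L + 1), y, bc_type=boundary)
            xs = np.linspace(1, L, 37)
            assert evaluate_spline(m, xs) == pytest.approx(ref(xs), abs=1e-9)

    @pytest.mark.parametrize("boundary", ["natural", "periodic", "fmm"])
    def test_against_dense_oracle(self, boundary, rng):
        for _ in range(30):
            L = int(rng.integers(4, 13))
            y = rng.normal(size=L)
            if boundary == "periodic":
                y[-1] = y[0]
            m = fit_cubic_spline(y, boundary)
            xs = np.linspace(1, L, 29)
            assert evaluate_spline(m, xs) == pytest.approx(
                dense_spline_eval(y, boundary, xs), abs=1e-9
            )


class TestEvaluateSpline:
    def test_knot_reproduction(self, rng):
        y = rng.normal(size=9)
        m = fit_cubic_spline(y, "natural")
        for i, v in enumerate(y, start=1):
            assert evaluate_spline(m, float(i)) == pytest.approx(v, abs=1e-12)

    def test_out_of_range(self):
        m = fit_cubic_spline([0, 1, 0], "natural")
        with pytest.raises(ValueError, match="outside"):
            evaluate_spline(m, 3.5)

    def test_linear_data_any_position(self):
        m = fit_cubic_spline([2.0, 3.5, 5.0, 6.5], "natural")
        assert evaluate_spline(m, 2.2) == pytest.approx(2.0 + 1.5 * 1.2)


class TestResample:
    def test_affine_refinement(self):
        out = resample([0, 1, 2, 3], 7, "linear")
        assert out.tolist() == pytest.approx([0, 0.5, 1, 1.5, 2, 2.5, 3])

    def test_target_grid_definition(self):
        xs = target_grid(38, 35)
        assert xs[0] == 1.0 and xs[-1] == 38.0
        assert np.diff(xs) == pytest.approx(np.full(34, 37 / 34))

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_identity_when_dims_equal_length(self, method, rng):
        y = rng.normal(size=12)
        if method == "periodic":
            y[-1] = y[0]
        out = resample(y, 12, method)
        assert out == pytest.approx(y, abs=1e-10)

    @pytest.mark.parametrize("method", ALL_METHODS)
    @pytest.mark.parametrize("dims", [2, 5, 35, 80])
    def test_endpoint_preservation(self, method, dims, rng):
        y = rng.normal(size=16)
        if method == "periodic":
            y[-1] = y[0]
        out = resample(y, dims, method)
        assert len(out) == dims
        assert out[0] == y[0] and out[-1] == y[-1]

    def test_unknown_method_lists_valid_names(self):
        with pytest.raises(ValueError, match="linear.*spline.*fmm.*natural.*periodic"):
            resample([0, 1, 2], 5, "cubic")

    @pytest.mark.parametrize("bad_dims", [0, 1, -3])
    def test_dims_below_two_rejected(self, bad_dims):
        with pytest.raises(ValueError):
            resample([0, 1, 2], bad_dims)

    def test_periodic_coercion_overwrites_last_value(self, caplog):
        out = resample([0.0, 1.0, 2.0], 3, "periodic", coerce_periodic=True)
        assert out[0] == 0.0 and out[-1] == 0.0

    def test_spline_is_alias_of_fmm(self, rng):
        y = rng.normal(size=10)
        assert resample(y, 23, "spline").tolist() == resample(y, 23, "fmm").tolist()

    def test_fmm_length_two_falls_back_to_linear(self):
        out = resample([0.0, 2.0], 5, "spline")
        assert out == pytest.approx([0, 0.5, 1, 1.5, 2])


finite_vectors = st.lists(
    st.floats(-100, 100, allow_nan=False, allow_infinity=False),
    min_size=2,
    max_size=40,
)


class TestResampleProperties:
    @settings(derandomize=True, max_examples=80)
    @given(y=finite_vectors, method=st.sampled_from(ALL_METHODS))
    def test_knot_reproduction_all_methods(self, y, method):
        """Resampling to the original length returns the input exactly."""
        y = np.asarray(y)
        if method == "periodic":
            y = np.append(y, y[0])
        out = resample(y, len(y), method)
        assert out == pytest.approx(y, abs=1e-10)

    @settings(derandomize=True, max_examples=80)
    @given(
        y=finite_vectors,
        dims=st.integers(2, 90),
        method=st.sampled_from(ALL_METHODS),
    )
    def test_endpoints_always_preserved(self, y, dims, method):
        y = np.asarray(y)
        if method == "periodic":
            y = np.append(y, y[0])
        out = resample(y, dims, method)
        assert out[0] == y[0] and out[-1] == y[-1]

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.floats(-10, 10),
        b=st.floats(-10, 10),
        L=st.integers(4, 30),
        dims=st.integers(2, 60),
        method=st.sampled_from(["linear", "spline", "fmm", "natural"]),
    )
    def test_affine_data_exactness(self, a, b, L, dims, method):
        """Straight-line data stays a straight line under every method
        (periodic is excluded: the only affine periodic data is constant)."""
        y = a + b * np.arange(1, L + 1)
        xs = target_grid(L, dims)
        out = resample(y, dims, method)
        assert out == pytest.approx(a + b * xs, abs=1e-8)

    @settings(derandomize=True, max_examples=40)
    @given(c=st.floats(-50, 50), L=st.integers(3, 20), dims=st.integers(2, 40))
    def test_constant_data_periodic(self, c, L, dims):
        out = resample(np.full(L, c), dims, "periodic")
        assert out == pytest.approx(np.full(dims, c), abs=1e-10)

    @settings(derandomize=True, max_examples=80)
    @given(y=finite_vectors, dims=st.integers(2, 90))
    def test_linear_method_bounded_by_input_range(self, y, dims):
        out = resample(y, dims, "linear")
        assert out.min() >= min(y) - 1e-12
        assert out.max() <= max(y) + 1e-12

    @settings(derandomize=True, max_examples=40)
    @given(
        y=st.lists(st.floats(-100, 100, allow_nan=False), min_size=4, max_size=20),
        dims=st.integers(2, 50),
        boundary=st.sampled_from(["natural", "fmm", "periodic"]),
    )
    def test_resample_is_grid_evaluation(self, y, dims, boundary):
        """resample == fit once, evaluate on the target grid (the two
        endpoint outputs are pinned to the knot values, which raw evaluation
        reproduces only up to round-off)."""
        y = np.asarray(y)
        if boundary == "periodic":
            y = np.append(y, y[0])
        m = fit_cubic_spline(y, boundary)
        direct = np.asarray(evaluate_spline(m, target_grid(len(y), dims)))
        out = resample(y, dims, boundary)
        assert out[1:-1].tolist() == direct[1:-1].tolist()
        assert out[0] == y[0] and out[-1] == y[-1]
        assert direct == pytest.approx(out, rel=1e-12, abs=1e-300)
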