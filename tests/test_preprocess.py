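import numpy as np
import pytest

from ftirfp import (
    Spectrum, SpectraSet, PreprocessConfig,
    baseline_correct, area_normalize, sg_second_derivative, select_region,
    preprocess_pipeline, simulate_cohort, default_profiles,
)


def brute_force_lower_hull(x, y):
    """Independent rubberband oracle: O(n^2) lower-envelope of all chords."""
    n = len(x)
    base = np.full(n, -np.inf)
    hull_pts = []
    for i in range(n):
        # a point is on the lower hull iff no chord between outer points dips below it
        on_hull = all(
            y[i] <= y[j] + (y[k] - y[j]) * (x[i] - x[j]) / (x[k] - x[j]) + 1e-12
            for j in range(n) for k in range(n) if x[j] < x[i] < x[k]
        )
        if on_hull:
            hull_pts.append(i)
    return np.interp(x, x[np.array(hull_pts)], y[np.array(hull_pts)])


class TestBaseline:
    def test_flat_spectrum_maps_to_zero(self):
        s = Spectrum(np.array([0.0, 1.0, 2.0]), np.array([1.0, 1.0, 1.0]))
        assert np.allclose(baseline_correct(s, "rubberband").absorbance, 0.0)

    def test_linear_removes_pure_slope(self):
        s = Spectrum(np.array([0.0, 1.0, 2.0]), np.array([0.0, 5.0, 10.0]))
        out = baseline_correct(s, "linear")
        assert np.allclose(out.absorbance, 0.0)

    def test_rubberband_preserves_isolated_peak(self):
        s = Spectrum(np.array([0.0, 1.0, 2.0]), np.array([0.0, 5.0, 0.0]))
        assert np.allclose(baseline_correct(s, "rubberband").absorbance, [0.0, 5.0, 0.0])

    def test_rubberband_matches_brute_force_hull(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 100, 40))
        y = rng.normal(size=40) + 0.05 * x
        expected = y - brute_force_lower_hull(x, y)
        out = baseline_correct(Spectrum(x, y), "rubberband")
        assert np.allclose(out.absorbance, expected, atol=1e-9)
        assert np.all(out.absorbance >= -1e-9)

    def test_rubberband_invariant_to_affine_offsets(self, gaussian_spectrum, uniform_grid):
        s = gaussian_spectrum([(2922, 8, 1.0), (1651, 18, 2.0)])
        tilted = s.with_absorbance(s.absorbance + 0.3 + 1e-4 * uniform_grid)
        a = baseline_correct(s, "rubberband").absorbance
        b = baseline_correct(tilted, "rubberband").absorbance
        assert np.allclose(a, b, atol=1e-9)

    def test_none_returns_input_unchanged(self):
        s = Spectrum(np.array([0.0, 1.0]), np.array([3.0, 4.0]))
        assert baseline_correct(s, "none") is s


class TestAreaNormalize:
    def test_constant_spectrum_closed_form(self):
        s = Spectrum(np.arange(0.0, 11.0), np.full(11, 5.0))
        out = area_normalize(s)
        # trapezoidal area of the constant input is 50 -> 5/50 = 0.1
        assert np.allclose(out.absorbance, 0.1)
        assert abs(np.trapezoid(np.abs(out.absorbance), out.wavenumbers) - 1.0) < 1e-9

    def test_idempotent(self):
        s = Spectrum(np.arange(0.0, 11.0), np.random.default_rng(0).uniform(0.1, 1, 11))
        once = area_normalize(s)
        twice = area_normalize(once)
        assert np.allclose(once.absorbance, twice.absorbance, atol=1e-12)

    def test_negative_constant_uses_absolute_area(self):
        s = Spectrum(np.arange(0.0, 11.0), np.full(11, -5.0))
        assert np.allclose(area_normalize(s).absorbance, -0.1)

    @pytest.mark.parametrize("scale", [0.1, 1.0, 10.0])
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(1)
        s = Spectrum(np.arange(0.0, 21.0), rng.normal(size=21))
        a = area_normalize(s).absorbance
        b = area_normalize(s.with_absorbance(scale * s.absorbance)).absorbance
        assert np.allclose(a, b, atol=1e-12)

    def test_zero_spectrum_rejected(self):
        s = Spectrum(np.arange(0.0, 5.0), np.zeros(5))
        with pytest.raises(ValueError, match="zero-area"):
            area_normalize(s)


class TestSgSecondDerivative:
    def test_exact_on_quadratic(self, uniform_grid):
        s = Spectrum(uniform_grid, uniform_grid**2)
        out = sg_second_derivative(s)
        assert out.wavenumbers[0] == uniform_grid[1]
        assert out.wavenumbers[-1] == uniform_grid[-2]
        assert np.allclose(out.absorbance, 2.0, atol=1e-8)

    @pytest.mark.parametrize("coeffs", [(0.0, 0.0), (7.0, 0.0), (7.0, 3.0)])
    def test_exact_zero_on_polynomials_below_order_two(self, uniform_grid, coeffs):
        c0, c1 = coeffs
        s = Spectrum(uniform_grid, c0 + c1 * uniform_grid)
        assert np.allclose(sg_second_derivative(s).absorbance, 0.0, atol=1e-10)

    def test_gaussian_center_matches_analytic_value(self, gaussian_spectrum):
        # analytic d2/dx2 of exp(-x^2/(2*64)) at the center is -1/64
        s = gaussian_spectrum([(2922, 8, 1.0)])
        out = sg_second_derivative(s)
        center = out.absorbance[np.argmin(np.abs(out.wavenumbers - 2922))]
        assert abs(center - (-1 / 64)) < 0.01 * (1 / 64)

    def test_linearity(self, uniform_grid):
        rng = np.random.default_rng(3)
        a = rng.normal(size=uniform_grid.size)
        b = rng.normal(size=uniform_grid.size)
        sa = sg_second_derivative(Spectrum(uniform_grid, a)).absorbance
        sb = sg_second_derivative(Spectrum(uniform_grid, b)).absorbance
        sab = sg_second_derivative(Spectrum(uniform_grid, 2.0 * a - 3.0 * b)).absorbance
        assert np.allclose(sab, 2.0 * sa - 3.0 * sb, atol=1e-10)

    def test_nonuniform_grid_rejected_with_guidance(self):
        s = Spectrum(np.array([0.0, 1.0, 2.0, 4.0, 5.0, 6.0, 7.0]), np.zeros(7))
        with pytest.raises(ValueError, match="resample_to_grid"):
            sg_second_derivative(s)


class TestSelectRegion:
    def test_closed_interval_point_count(self):
        grid = np.arange(600.0, 4001.0, 2.0)
        s = Spectrum(grid, np.zeros_like(grid))
        out = select_region(s, 2800, 3000)
        assert len(out) == 101

    def test_reversed_bounds_accepted(self):
        grid = np.arange(600.0, 4001.0, 2.0)
        s = Spectrum(grid, np.zeros_like(grid))
        assert len(select_region(s, 3000, 2800)) == 101

    def test_single_point_region(self):
        grid = np.arange(600.0, 4001.0, 2.0)
        s = Spectrum(grid, np.arange(grid.size, dtype=float))
        out = select_region(s, 1000, 1001)
        assert len(out) == 1
        assert out.wavenumbers[0] == 1000

    def test_empty_overlap_rejected(self):
        s = Spectrum(np.arange(600.0, 4001.0, 2.0), np.zeros(1701))
        with pytest.raises(ValueError, match="overlap"):
            select_region(s, 5000, 6000)


class TestPipeline:
    def test_all_none_config_with_region_is_a_cropped_copy(self, small_set):
        cfg = PreprocessConfig(baseline_method="none", normalization="none",
                               derivative_order=0, regions=((1000, 1050),))
        out = preprocess_pipeline(small_set, cfg, region=(1000, 1050))
        ref = select_region(small_set, 1000, 1050)
        assert np.array_equal(out.grid, ref.grid)
        assert np.array_equal(out.matrix, ref.matrix)

    def test_identical_rows_stay_identical(self, small_set):
        dup = SpectraSet(
            grid=small_set.grid,
            matrix=np.vstack([small_set.matrix[0], small_set.matrix[0]]),
            sample_ids=["x", "y"], labels=["a", "a"], replicates=[1, 2],
        )
        out = preprocess_pipeline(dup, PreprocessConfig(baseline_method="linear"))
        assert np.array_equal(out.matrix[0], out.matrix[1])

    def test_rows_are_unit_area_before_derivative(self):
        cfg_cohort = default_profiles("coriell", seed=5, n_samples_per_group=1)
        sset, _ = simulate_cohort(cfg_cohort)
        cfg = PreprocessConfig(derivative_order=0)
        out = preprocess_pipeline(sset, cfg)
        areas = np.trapezoid(np.abs(out.matrix), out.grid, axis=1)
        assert np.allclose(areas, 1.0, atol=1e-9)

    def test_provenance_records_config(self, small_set):
        cfg = PreprocessConfig(baseline_method="linear")
        out = preprocess_pipeline(small_set, cfg)
        assert out.provenance["preprocess"]["baseline_method"] == "linear"
        assert out.provenance["preprocess"]["sg_half_width"] == 1

    def test_region_crop_commutes_with_derivative_when_unnormalized(self, gaussian_spectrum):
        # crop-then-derive equals derive-then-crop once the SG edge trim is aligned
        s = gaussian_spectrum([(1100, 10, 1.0)])
        sset = SpectraSet(grid=s.wavenumbers, matrix=s.absorbance[None, :],
                          sample_ids=["s"], labels=["g"], replicates=[1])
        cfg = PreprocessConfig(baseline_method="none", normalization="none")
        whole = select_region(preprocess_pipeline(sset, cfg), 1050, 1150)
        cropped_first = preprocess_pipeline(select_region(sset, 1049, 1151), cfg)
        assert np.allclose(whole.matrix, cropped_first.matrix, atol=1e-12)

    def test_stage_error_names_the_sample(self):
        grid = np.arange(0.0, 10.0)
        sset = SpectraSet(grid=grid, matrix=np.vstack([np.ones(10), np.zeros(10)]),
                          sample_ids=["good", "bad"], labels=["g", "g"],
                          replicates=[1, 1])
        with pytest.raises(ValueError, match="bad"):
            preprocess_pipeline(sset, PreprocessConfig(baseline_method="none"))


def test_sg_window_must_exceed_polyorder():
    with pytest.raises(ValueError, match="window"):
        PreprocessConfig(sg_half_width=1, sg_polyorder=3)
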