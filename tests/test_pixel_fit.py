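"""Tests of discrete Fourier coefficient estimation and algebraic inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pshglab import (
    DegenerateGridError,
    InsufficientSamplingError,
    InvalidInputError,
    NoiseModel,
    PolarizationStack,
    TensorParams,
    coeffs_from_params,
    estimate_coefficients,
    fit_stack,
    intensity_profile,
    invert_coefficients,
    make_fibril_phantom,
    make_uniform_phantom,
    mode_value,
    ratio_maps,
    render_stack,
)
from pshglab.model import FourierCoeffs


class TestEstimateCoefficients:
    def test_constant_profile(self, grid18):
        c = estimate_coefficients(np.full(18, 3.7), grid18)
        assert c.a0 == pytest.approx(3.7)
        assert (c.a2, c.b2, c.a4, c.b4) == pytest.approx((0, 0, 0, 0), abs=1e-12)

    def test_pure_harmonic_orthogonality(self, grid18):
        c = estimate_coefficients(np.cos(2 * np.deg2rad(grid18)), grid18)
        assert c.a2 == pytest.approx(1.0, abs=1e-12)
        assert (c.a0, c.b2, c.a4, c.b4) == pytest.approx((0, 0, 0, 0), abs=1e-12)

    def test_matches_closed_form_on_model_profile(self, grid18, example_params):
        c_ref = coeffs_from_params(example_params)
        c = estimate_coefficients(intensity_profile(example_params, grid18), grid18)
        for name in ("a0", "a2", "b2", "a4", "b4"):
            assert getattr(c, name) == pytest.approx(getattr(c_ref, name), abs=1e-12)

    def test_band_limit_nine_equals_eighteen(self, example_params):
        g9 = np.arange(0.0, 180.0, 20.0)
        g18 = np.arange(0.0, 180.0, 10.0)
        c9 = estimate_coefficients(intensity_profile(example_params, g9), g9)
        c18 = estimate_coefficients(intensity_profile(example_params, g18), g18)
        for name in ("a0", "a2", "b2", "a4", "b4"):
            assert getattr(c9, name) == pytest.approx(getattr(c18, name), abs=1e-10)

    def test_irregular_grid_least_squares(self, example_params):
        rng = np.random.default_rng(0)
        phis = np.sort(rng.uniform(0, 180, 12))
        c = estimate_coefficients(intensity_profile(example_params, phis), phis)
        c_ref = coeffs_from_params(example_params)
        for name in ("a0", "a2", "b2", "a4", "b4"):
            assert getattr(c, name) == pytest.approx(getattr(c_ref, name), abs=1e-8)

    def test_too_few_angles(self):
        with pytest.raises(InsufficientSamplingError):
            estimate_coefficients([1, 2, 3, 4], [0, 45, 90, 135])

    def test_duplicate_angles_degenerate(self):
        with pytest.raises(DegenerateGridError):
            estimate_coefficients([1, 2, 3, 4, 5], [0, 0, 90, 120, 150])


class TestInvertCoefficients:
    def test_round_trip_example(self, example_params):
        res = invert_coefficients(coeffs_from_params(example_params))
        assert res.valid and not res.isotropic
        assert res.params.alpha == pytest.approx(30.0, abs=1e-10)
        assert res.params.A == pytest.approx(1.0, abs=1e-10)
        assert res.params.B == pytest.approx(1.1, abs=1e-10)
        assert res.params.C == pytest.approx(0.5, abs=1e-10)

    def test_isotropic_pixel_flagged(self):
        res = invert_coefficients(FourierCoeffs(a0=1, a2=0, b2=0, a4=0, b4=0))
        assert res.isotropic
        assert res.params.alpha == 0.0
        assert res.params.A == pytest.approx(1.0)
        assert res.params.B == pytest.approx(1.0)
        assert res.params.C == pytest.approx(0.0)

    def test_quadrant_resolved_by_signed_projection(self):
        truth = TensorParams(alpha=120.0, A=0.8, B=1.2, C=0.4)
        res = invert_coefficients(coeffs_from_params(truth))
        assert res.params.alpha == pytest.approx(120.0, abs=1e-10)
        assert res.params.A == pytest.approx(0.8, abs=1e-10)
        assert res.params.B == pytest.approx(1.2, abs=1e-10)
        assert res.params.C == pytest.approx(0.4, abs=1e-10)

    @settings(max_examples=300, deadline=None)
    @given(
        alpha=st.floats(0, 180, exclude_max=True),
        A=st.floats(0.05, 5),
        dB=st.floats(1e-3, 5),
        C=st.floats(0, 5),
    )
    def test_exact_round_trip_property(self, alpha, A, dB, C):
        """params -> 18-angle profile -> coefficients -> params is the identity
        whenever B > A > 0, C >= 0."""
        truth = TensorParams(alpha=alpha, A=A, B=A + dB, C=C)
        grid = np.arange(0.0, 180.0, 10.0)
        c = estimate_coefficients(intensity_profile(truth, grid), grid)
        res = invert_coefficients(c)
        assert res.valid
        scale = max(truth.B, 1.0)
        d_alpha = abs(res.params.alpha - truth.alpha)
        assert min(d_alpha, 180 - d_alpha) < 1e-6
        assert res.params.A == pytest.approx(truth.A, rel=1e-7, abs=1e-8 * scale)
        assert res.params.B == pytest.approx(truth.B, rel=1e-7, abs=1e-8 * scale)
        assert res.params.C == pytest.approx(truth.C, rel=1e-6, abs=1e-6 * scale)


class TestFitStack:
    def test_noise_free_phantom_recovers_truth(self, grid18, collagen_ratios):
        ph = make_fibril_phantom(
            size=(48, 48), n_fibrils=12, length_px=20, thickness_px=3,
            orientation_center=25.0, orientation_sd=15.0,
            tensor=collagen_ratios, seed=4,
        )
        stack = render_stack(ph, grid18)
        fit = fit_stack(stack, smooth_radius=0)
        fg = ph.foreground
        assert fit.valid_mask[fg].all()
        assert np.max(np.abs(fit.alpha_map[fg] - ph.truth_alpha[fg])) < 1e-8
        for est, truth in ((fit.A_map, ph.truth_A), (fit.B_map, ph.truth_B),
                           (fit.C_map, ph.truth_C)):
            assert np.max(np.abs(est[fg] - truth[fg])) < 1e-8
        assert np.nanmax(fit.residual_map[fg]) < 1e-12

    def test_all_zero_stack_has_no_valid_pixels(self, grid18):
        stack = PolarizationStack(data=np.zeros((8, 8, 18)), angles=grid18)
        fit = fit_stack(stack)
        assert not fit.valid_mask.any()

    def test_smoothing_is_identity_on_interior_of_constant_regions(self, grid18):
        ph = make_uniform_phantom((16, 16), TensorParams(40.0, 1.0, 1.2, 0.4))
        stack = render_stack(ph, grid18)
        f0 = fit_stack(stack, smooth_radius=0)
        f1 = fit_stack(stack, smooth_radius=1)
        interior = np.s_[2:-2, 2:-2]
        assert np.allclose(f0.alpha_map[interior], f1.alpha_map[interior])
        assert np.allclose(f0.B_map[interior], f1.B_map[interior])

    def test_mask_shape_mismatch_raises(self, grid18):
        stack = PolarizationStack(data=np.ones((8, 8, 18)), angles=grid18)
        with pytest.raises(InvalidInputError):
            fit_stack(stack, foreground=np.ones((4, 4), dtype=bool))

    def test_poisson_noise_mode_theta_near_truth(self, grid18, collagen_ratios):
        """Under shot noise at 1000 peak counts the histogram mode of the
        recovered pitch angle stays within half a degree of the truth."""
        ph = make_uniform_phantom((128, 128), collagen_ratios, alpha=40.0)
        stack = render_stack(ph, grid18, noise=NoiseModel(peak_count=1000, seed=7))
        fit = fit_stack(stack, smooth_radius=0)
        mol = ratio_maps(fit)
        mode_theta = mode_value(mol.theta_map, mol.theta_valid_mask, bin_width=0.25)
        assert abs(mode_theta - ph.geometry.theta_true) < 0.5


class TestStackValidation:
    def test_angle_page_mismatch(self):
        with pytest.raises(InvalidInputError):
            PolarizationStack(data=np.ones((4, 4, 18)), angles=np.arange(0, 170, 10.0))

    def test_negative_intensities_rejected(self, grid18):
        data = np.ones((4, 4, 18))
        data[0, 0, 0] = -1
        with pytest.raises(InvalidInputError):
            PolarizationStack(data=data, angles=grid18)

    def test_angles_must_increase_within_period(self):
        with pytest.raises(InvalidInputError):
            PolarizationStack(data=np.ones((4, 4, 5)), angles=[0.0, 50, 40, 120, 160])
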