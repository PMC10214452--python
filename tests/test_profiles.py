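"""Profile model, fitting and K_p,int estimation."""

import numpy as np
import pytest

from lineactant.profiles import (
    IntensityProfile,
    ProfileModel,
    fit_profile,
    kpint_from_fit,
    model_profile,
    normalize_profile,
)
from lineactant.synthetic import ProfileTruth, gen_profiles

X = np.linspace(-2.5, 2.5, 101)


class TestModelProfile:
    def test_zero_amplitude_is_pure_step(self):
        y = model_profile(X, 1.0, 0.4, 0.0, 0.2)
        assert y[0] == pytest.approx(1.0, abs=1e-9)
        assert y[-1] == pytest.approx(0.4, abs=1e-9)
        assert np.all(np.diff(y) <= 1e-12)

    def test_equal_baselines_symmetric_gaussian(self):
        y = model_profile(X, 1.0, 1.0, 0.5, 0.2)
        assert np.allclose(y, y[::-1])
        assert y.max() == pytest.approx(1.5)

    def test_value_at_center_on_symmetric_step(self):
        y0 = model_profile(np.array([0.3]), 1.0, 0.4, 0.8, 0.15, center=0.3)
        assert y0[0] == pytest.approx((1.0 + 0.4) / 2 + 0.8)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            model_profile(X, 1, 1, 1, 0.0)


class TestProfileValidation:
    def test_decreasing_positions_rejected(self):
        with pytest.raises(ValueError):
            IntensityProfile(X[::-1], np.ones_like(X))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            IntensityProfile(X, -np.ones_like(X))

    def test_too_few_samples_rejected(self):
        p = IntensityProfile(X[:5], np.ones(5))
        with pytest.raises(ValueError):
            ProfileModel(p)


class TestFitting:
    def test_noiseless_recovery_within_point1_percent(self):
        truth = dict(b_ld=1.0, b_lo=0.45, amplitude=0.9, width=0.22, center=0.12)
        y = model_profile(X, **truth)
        fit = fit_profile(IntensityProfile(X, y))
        assert fit.converged
        for name, val in truth.items():
            assert fit.params[name] == pytest.approx(val, rel=1e-3)

    def test_flat_profile_flags_degenerate_peak(self):
        fit = fit_profile(IntensityProfile(X, np.full_like(X, 2.0)))
        assert abs(fit.params["amplitude"]) < 1e-2
        assert fit.degenerate_peak

    def test_fit_is_deterministic(self):
        truth = ProfileTruth(kpint=5.0, noise_sigma=0.05, seed=3)
        prof = gen_profiles(truth)[0]
        f1 = fit_profile(prof)
        f2 = fit_profile(prof)
        assert f1.params == f2.params

    def test_residuals_unstructured_on_self_generated_data(self):
        truth = ProfileTruth(kpint=5.0, noise_sigma=0.05, seed=4)
        fit = fit_profile(gen_profiles(truth)[0])
        r = fit.residuals
        lag1 = np.corrcoef(r[:-1], r[1:])[0, 1]
        assert abs(lag1) < 0.35

    def test_summary_lists_parameters(self):
        y = model_profile(X, 1.0, 0.5, 0.8, 0.2)
        text = fit_profile(IntensityProfile(X, y)).summary()
        for name in ("b_ld", "b_lo", "amplitude", "width", "center"):
            assert name in text


class TestKpint:
    def test_no_peak_equal_baselines_gives_unity(self):
        params = {"b_ld": 1.0, "b_lo": 1.0, "amplitude": 0.0, "width": 0.2,
                  "center": 0.0}
        assert kpint_from_fit(params, xi_um=0.008) == 1.0

    def test_halving_xi_doubles_peak_contribution(self):
        params = {"b_ld": 1.0, "b_lo": 1.0, "amplitude": 0.5, "width": 0.2,
                  "center": 0.0}
        k1 = kpint_from_fit(params, xi_um=0.008)
        k2 = kpint_from_fit(params, xi_um=0.004)
        assert k2 - 1.0 == pytest.approx(2 * (k1 - 1.0))

    def test_scale_invariance(self):
        truth = ProfileTruth(kpint=5.0, noise_sigma=0.0)
        prof = gen_profiles(truth)[0]
        scaled = IntensityProfile(prof.x, prof.intensity * 10)
        k1 = fit_profile(prof).kpint(truth.xi_um)
        k2 = fit_profile(scaled).kpint(truth.xi_um)
        assert k1 == pytest.approx(k2, rel=1e-6)

    def test_round_trip_target_recovered(self):
        truth = ProfileTruth(kpint=5.0, noise_sigma=0.0)
        fit = fit_profile(gen_profiles(truth)[0])
        assert fit.kpint(truth.xi_um, truth.area_fractions) == pytest.approx(5.0, rel=1e-3)

    def test_bad_area_fractions_rejected(self):
        params = {"b_ld": 1.0, "b_lo": 1.0, "amplitude": 0.0, "width": 0.2,
                  "center": 0.0}
        with pytest.raises(ValueError):
            kpint_from_fit(params, 0.008, area_fractions=(0.7, 0.6))


class TestNormalization:
    def _profile(self):
        return gen_profiles(ProfileTruth(kpint=4.0, noise_sigma=0.0))[0]

    def test_reference_mean_is_one(self):
        norm = normalize_profile(self._profile(), "ld", width=0.2)
        mask = norm.x < -0.6
        assert np.mean(norm.intensity[mask]) == pytest.approx(1.0)

    def test_scale_invariant(self):
        p = self._profile()
        scaled = IntensityProfile(p.x, 10 * p.intensity)
        a = normalize_profile(p, "ld", width=0.2)
        b = normalize_profile(scaled, "ld", width=0.2)
        assert np.allclose(a.intensity, b.intensity)

    def test_already_normalized_unchanged(self):
        a = normalize_profile(self._profile(), "ld", width=0.2)
        b = normalize_profile(a, "ld", width=0.2)
        assert np.allclose(a.intensity, b.intensity, atol=1e-12)

    def test_empty_reference_region_rejected(self):
        p = self._profile()
        with pytest.raises(ValueError):
            normalize_profile(p, "ld", width=10.0)  # 3w exceeds the span
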