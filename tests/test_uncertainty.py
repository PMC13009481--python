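import json

import numpy as np
import pytest

from slabrestore.uncertainty import (
    EvidentialMaps, QualityCalibrator, fit_calibration, moments,
    predict_quality, slice_mean_epistemic,
)


def nig_sampling_oracle(gamma, v, alpha, beta, n, rng):
    """Draw (mu, sigma^2) from the NIG hierarchy and return empirical moments."""
    sigma2 = 1.0 / rng.gamma(alpha, 1.0 / beta, size=n)   # InvGamma(alpha, beta)
    mu = rng.normal(gamma, np.sqrt(sigma2 / v))
    return sigma2.mean(), mu.var(), sigma2.std() / np.sqrt(n)


class TestMoments:
    def test_closed_forms_at_reference_point(self):
        maps = EvidentialMaps(np.array([0.5]), np.array([1.0]),
                              np.array([2.0]), np.array([1.0]))
        pred, u = moments(maps)
        assert pred[0] == 0.5
        assert u.aleatoric[0] == pytest.approx(1.0)
        assert u.epistemic[0] == pytest.approx(1.0)

    def test_epistemic_vanishes_as_v_grows(self):
        maps = EvidentialMaps(np.zeros(1), np.array([1e9]), np.array([3.0]), np.array([1.5]))
        _, u = moments(maps)
        assert u.aleatoric[0] == pytest.approx(0.75)
        assert u.epistemic[0] == pytest.approx(0.0, abs=1e-8)

    def test_identity_epistemic_times_v_is_aleatoric(self, rng):
        v = rng.gamma(2, 1, size=(4, 4, 4)) + 0.1
        maps = EvidentialMaps(rng.normal(size=(4, 4, 4)), v,
                              1.1 + rng.gamma(2, 1, size=(4, 4, 4)),
                              rng.gamma(2, 1, size=(4, 4, 4)) + 0.1)
        _, u = moments(maps)
        assert np.allclose(u.epistemic * v, u.aleatoric, rtol=1e-14)

    def test_monte_carlo_oracle_small(self, rng):
        # light version of the sampling check (the full 1e6-draw version
        # runs in the acceptance suite)
        g, v, a, b = 0.0, 2.0, 3.0, 1.5
        _, u = moments(EvidentialMaps(*(np.array([x]) for x in (g, v, a, b))))
        ale_hat, epi_hat, se = nig_sampling_oracle(g, v, a, b, 10**5, rng)
        assert abs(u.aleatoric[0] - ale_hat) < 3 * se
        assert abs(u.epistemic[0] - epi_hat) < 3 * se

    def test_alpha_at_most_one_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            EvidentialMaps(np.zeros(1), np.ones(1), np.ones(1), np.ones(1))


class TestSliceMeans:
    def test_constant_map(self):
        from slabrestore.uncertainty import UncertaintyMaps
        u = UncertaintyMaps(np.full((4, 4, 6), 0.2), np.full((4, 4, 6), 0.2))
        assert np.allclose(slice_mean_epistemic(u, plane="sagittal"), 0.2)

    def test_hot_voxel_elevates_only_its_slice(self):
        from slabrestore.uncertainty import UncertaintyMaps
        epi = np.zeros((4, 4, 6))
        epi[1, 2, 3] = 1.0
        u = UncertaintyMaps(epi, epi)
        means = slice_mean_epistemic(u, plane="sagittal")
        assert means[3] > 0 and np.all(means[np.arange(6) != 3] == 0)

    def test_permutation_equivariance(self, rng):
        from slabrestore.uncertainty import UncertaintyMaps
        epi = rng.random((4, 4, 6))
        perm = rng.permutation(6)
        a = slice_mean_epistemic(UncertaintyMaps(epi, epi), plane="sagittal")
        b = slice_mean_epistemic(UncertaintyMaps(epi[:, :, perm], epi[:, :, perm]),
                                 plane="sagittal")
        assert np.allclose(a[perm], b)


class TestCalibration:
    def test_noiseless_linear_recovery(self):
        u = np.linspace(0.01, 0.2, 40)
        y = -2.0 * u + 1.0
        model = fit_calibration(u, y, kind="linear_ssim")
        assert model.coef_["a"] == pytest.approx(-2.0, abs=1e-8)
        assert model.coef_["b"] == pytest.approx(1.0, abs=1e-8)
        assert model.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_exponential_recovery(self):
        u = np.linspace(0.01, 0.3, 50)
        y = 12.0 * np.exp(-8.0 * u) + 25.0
        model = fit_calibration(u, y, kind="exp_psnr")
        assert model.coef_["c"] == pytest.approx(12.0, rel=1e-6)
        assert model.coef_["d"] == pytest.approx(-8.0, rel=1e-6)
        assert model.coef_["e"] == pytest.approx(25.0, rel=1e-6)

    def test_linear_interval_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        u = rng.uniform(0.02, 0.3, size=60)
        y = 0.98 - 1.5 * u + rng.normal(0, 0.01, size=60)
        model = fit_calibration(u, y, kind="linear_ssim")
        res = sm.OLS(y, sm.add_constant(u)).fit()
        grid = np.array([0.05, 0.15, 0.25])
        frame = res.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
        _, (lo, hi) = model.predict(grid, return_interval=True)
        assert np.allclose(lo, frame["obs_ci_lower"].to_numpy(), atol=1e-10)
        assert np.allclose(hi, frame["obs_ci_upper"].to_numpy(), atol=1e-10)

    def test_interval_narrowest_at_predictor_mean(self, rng):
        u = rng.uniform(0.0, 1.0, size=80)
        y = 1.0 - u + rng.normal(0, 0.05, size=80)
        model = fit_calibration(u, y, kind="linear_ssim")
        grid = np.array([u.mean() - 0.4, u.mean(), u.mean() + 0.4])
        _, (lo, hi) = model.predict(grid, return_interval=True)
        widths = hi - lo
        assert widths[1] < widths[0] and widths[1] < widths[2]

    def test_refit_on_own_predictions_is_identical(self, rng):
        u = rng.uniform(0.02, 0.3, size=40)
        y = 0.95 - 1.2 * u + rng.normal(0, 0.02, size=40)
        model = fit_calibration(u, y, kind="linear_ssim")
        refit = fit_calibration(u, model.predict(u), kind="linear_ssim")
        assert np.allclose(model.predict(u), refit.predict(u), atol=1e-10)

    def test_coverage_of_prediction_intervals(self, rng):
        u_fit = rng.uniform(0.02, 0.3, size=200)
        y_fit = 0.98 - 1.5 * u_fit + rng.normal(0, 0.02, size=200)
        model = fit_calibration(u_fit, y_fit, kind="linear_ssim")
        u_new = rng.uniform(0.02, 0.3, size=160)
        y_new = 0.98 - 1.5 * u_new + rng.normal(0, 0.02, size=160)
        point, (lo, hi) = model.predict(u_new, return_interval=True)
        coverage = np.mean((y_new >= lo) & (y_new <= hi))
        assert coverage >= 0.9

    def test_extrapolation_warns(self, rng):
        u = rng.uniform(0.1, 0.2, size=20)
        y = 1.0 - u
        model = fit_calibration(u, y, kind="linear_ssim")
        with pytest.warns(UserWarning, match="twice the fitted range"):
            model.predict(np.array([0.9]))

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_calibration(np.full(20, 0.1), np.linspace(0, 1, 20))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="10"):
            fit_calibration(np.linspace(0, 1, 5), np.linspace(0, 1, 5))

    def test_json_round_trip(self, rng):
        u = rng.uniform(0.02, 0.3, size=40)
        for kind, y in [("linear_ssim", 1.0 - u + rng.normal(0, 0.01, 40)),
                        ("exp_psnr", 10 * np.exp(-5 * u) + 24 + rng.normal(0, 0.1, 40))]:
            model = fit_calibration(u, y, kind=kind)
            clone = QualityCalibrator.from_json(model.to_json())
            grid = np.linspace(0.05, 0.25, 7)
            p0, (lo0, hi0) = predict_quality(model, grid)
            p1, (lo1, hi1) = predict_quality(clone, grid)
            assert np.allclose(p0, p1) and np.allclose(lo0, lo1) and np.allclose(hi0, hi1)
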