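import numpy as np
import pytest

from paleopop.ethnography import EthnographicRecord, pairwise_great_circle_km
from paleopop.predictors import MonthlyClimate, derive_predictors
from paleopop.qgam import (CVConfig, QuantileFit, crossing_rate,
                           deviance_explained, fit_ensemble, fit_qgam,
                           hblock_folds, pinball_loss, pspline_knots)
from paleopop.synth import (SyntheticWorldConfig, default_responses,
                            generate_ethnographic_table)

from conftest import lp_linear_quantile


class TestFitQgam:
    def test_constant_response_reproduced(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 60)
        for tau in (0.1, 0.5, 0.9):
            f = fit_qgam(x, np.full(60, 3.2), tau, lam=1.0)
            assert np.allclose(f(np.linspace(0, 10, 50)), 3.2, atol=1e-8)

    @pytest.mark.parametrize("tau", [0.1, 0.5, 0.9])
    def test_noiseless_linear_matches_lp_oracle(self, tau):
        rng = np.random.default_rng(1)
        x = rng.uniform(-3, 7, 200)
        y = 1.5 - 0.8 * x
        f = fit_qgam(x, y, tau, seed=0)
        a, b = lp_linear_quantile(x, y, tau)
        xs = np.linspace(x.min(), x.max(), 300)
        assert np.max(np.abs(f(xs) - (a + b * xs))) < 1e-3

    def test_lambda_to_infinity_is_linear_quantile_regression(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 400)
        y = 0.5 + 0.3 * x + rng.normal(0, 0.4, 400)
        f = fit_qgam(x, y, 0.5, lam=1e12)
        a, b = lp_linear_quantile(x, y, 0.5)
        xs = np.linspace(x.min(), x.max(), 200)
        assert np.max(np.abs(f(xs) - (a + b * xs))) < 1e-2

    def test_heteroscedastic_coverage(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.uniform(0, 10, n)
        y = np.sin(x / 3.0) + (0.2 + 0.1 * x) * rng.standard_normal(n)
        f = fit_qgam(x, y, 0.9, seed=0)
        cover = float(np.mean(y < f(x)))
        assert 0.88 <= cover <= 0.92

    def test_degenerate_predictor_refused(self):
        with pytest.raises(ValueError):
            fit_qgam(np.full(50, 2.0), np.arange(50.0), 0.5)

    def test_affine_equivariance_in_x(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 150)
        y = np.cos(3 * x) + rng.normal(0, 0.1, 150)
        f1 = fit_qgam(x, y, 0.5, lam=5.0)
        f2 = fit_qgam(100.0 * x + 7.0, y, 0.5, lam=5.0)
        xs = np.linspace(0, 1, 80)
        assert np.allclose(f1(xs), f2(100.0 * xs + 7.0), atol=1e-8)


class TestPredict:
    def test_out_of_domain_is_flagged_never_extrapolated(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 80)
        f = fit_qgam(x, 2.0 * x, 0.5, lam=0.01)
        vals, ok = f.predict([5.0, 11.0, -1.0])
        assert ok.tolist() == [True, False, False]
        # clamped value equals the boundary value, not a spline extension
        hi_val, _ = f.predict([x.max()])
        assert vals[1] == pytest.approx(hi_val[0])
        vals_nan, _ = f.predict([11.0], extrapolation="nan")
        assert np.isnan(vals_nan[0])

    def test_midpoint_is_finite_and_in_domain(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 10, 80)
        f = fit_qgam(x, np.sin(x), 0.5, lam=0.1)
        mid = 0.5 * (f.train_range[0] + f.train_range[1])
        vals, ok = f.predict([mid])
        assert np.isfinite(vals[0]) and ok[0]


class TestDevianceExplained:
    def _constant_fit(self, c, tau, xmin=0.0, xmax=1.0):
        knots = pspline_knots(xmin, xmax, 4)
        return QuantileFit(variable_id="x", tau=tau, knots=knots,
                           coefficients=np.full(4, c), lam=0.0,
                           train_range=(xmin, xmax), deviance_explained=0.0,
                           n_train=10)

    def test_intercept_only_scores_zero(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 200)
        x = rng.uniform(0, 1, 200)
        f = self._constant_fit(float(np.median(y)), 0.5)
        assert deviance_explained(f, x, y) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_fit_scores_one(self):
        x = np.linspace(0, 10, 60)
        f = fit_qgam(x, 1.0 + 0.2 * x, 0.5, seed=0)
        assert deviance_explained(f, x, 1.0 + 0.2 * x) == pytest.approx(1.0, abs=1e-6)

    def test_constant_y_convention_zero(self):
        x = np.linspace(0, 1, 10)
        f = self._constant_fit(5.0, 0.5)
        assert deviance_explained(f, x, np.full(10, 5.0)) == 0.0

    def test_ten_point_brute_force_oracle(self):
        """Best-constant median fit found by exhaustive search over a grid."""
        y = np.array([0.1, 0.5, 0.2, 0.9, 1.5, 0.3, 0.8, 1.1, 0.4, 0.7])
        x = np.linspace(0, 1, 10)
        grid = np.linspace(-1, 3, 40001)
        losses = [sum(abs(yi - c) * (0.5 if yi >= c else 0.5) for yi in y)
                  for c in grid]
        c_star = grid[int(np.argmin(losses))]
        f = self._constant_fit(float(c_star), 0.5)
        null = pinball_loss(y - np.quantile(y, 0.5), 0.5)
        resid = pinball_loss(y - c_star, 0.5)
        assert deviance_explained(f, x, y) == pytest.approx(
            1.0 - resid / null, abs=1e-8)


class TestHBlockFolds:
    def test_far_apart_points_drop_nothing(self):
        # antipodal-ish points, pairwise far beyond h
        lat = np.array([0.0, 0.0, 60.0, -60.0, 0.0, 30.0] * 10)
        lon = np.linspace(-180, 175, 60)
        coords = np.column_stack([lat, lon])
        d = pairwise_great_circle_km(lat, lon)
        h = 0.9 * d[d > 0].min()
        folds = hblock_folds(coords, n_folds=5, h_km=h, seed=0, min_train=10)
        for f in folds:
            assert f.n_dropped == 0

    def test_clustered_points_exhaust_retries(self):
        rng = np.random.default_rng(0)
        coords = np.column_stack([rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)])
        with pytest.raises(RuntimeError):
            hblock_folds(coords, n_folds=2, h_km=4500.0, seed=0)

    def test_buffered_contract_no_close_train_test_pairs(self):
        rng = np.random.default_rng(1)
        lat = rng.uniform(-60, 70, 200)
        lon = rng.uniform(-180, 180, 200)
        coords = np.column_stack([lat, lon])
        h = 1500.0
        folds = hblock_folds(coords, n_folds=20, h_km=h, seed=2)
        d = pairwise_great_circle_km(lat, lon)
        for f in folds:
            assert d[np.ix_(f.train, f.test)].min() >= h

    def test_literal_strategy_thins_training_pairwise(self):
        rng = np.random.default_rng(2)
        lat = rng.uniform(-60, 70, 300)
        lon = rng.uniform(-180, 180, 300)
        coords = np.column_stack([lat, lon])
        h = 1000.0
        folds = hblock_folds(coords, n_folds=3, h_km=h, strategy="literal", seed=0)
        d = pairwise_great_circle_km(lat, lon)
        for f in folds:
            sub = d[np.ix_(f.train, f.train)]
            off_diag = sub[~np.eye(len(f.train), dtype=bool)]
            assert off_diag.min() >= h

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        coords = np.column_stack([rng.uniform(-60, 60, 80),
                                  rng.uniform(-180, 180, 80)])
        a = hblock_folds(coords, n_folds=4, h_km=800, seed=9)
        b = hblock_folds(coords, n_folds=4, h_km=800, seed=9)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.train, fb.train)
            assert np.array_equal(fa.test, fb.test)


def _records_from_xy(x, y, lat, lon):
    """Minimal records whose ET predictor equals x and density 10^y."""
    recs = []
    for i in range(len(x)):
        # seasonless profile: ET == monthly temperature == x
        mc = MonthlyClimate(np.full(12, x[i]), np.full(12, 50.0), lat=float(lat[i]))
        recs.append(EthnographicRecord(
            id=f"p{i}", lat=float(lat[i]), lon=float(lon[i]),
            density=float(10.0 ** y[i]), subsistence_class="forager",
            years_at_location=0.5, aquatic_protein_pct=0.0, equestrian=False,
            monthly_climate=mc, predictors=derive_predictors(mc)))
    return recs


class TestEnsemble:
    CV = CVConfig(n_folds=10, h_km=500.0, seed=0)

    def _xy(self, seed, n=250, noise=0.25, slope=0.15):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 20, n)
        y = -0.5 + slope * x + noise * rng.standard_normal(n)
        lat = rng.uniform(-60, 70, n)
        lon = rng.uniform(-180, 180, n)
        return x, y, lat, lon

    def test_monotone_truth_recovered(self):
        x, y, lat, lon = self._xy(0)
        model = fit_ensemble(_records_from_xy(x, y, lat, lon), "ET", 0.5, self.CV)
        assert model.metrics["deviance_explained_mean"] > 0.2
        xs = np.linspace(x.min() + 1, x.max() - 1, 30)
        mean_curve = np.log10(model.predict_mean_density(xs))
        assert np.all(np.diff(mean_curve) > -0.02)  # monotone over the interior

    def test_pure_noise_has_no_skill(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 20, 250)
        y = rng.normal(0, 0.4, 250)
        lat = rng.uniform(-60, 70, 250)
        lon = rng.uniform(-180, 180, 250)
        model = fit_ensemble(_records_from_xy(x, y, lat, lon), "ET", 0.5, self.CV)
        assert -0.05 <= model.metrics["deviance_explained_mean"] <= 0.05

    def test_same_seed_identical_metrics(self):
        x, y, lat, lon = self._xy(2)
        recs = _records_from_xy(x, y, lat, lon)
        m1 = fit_ensemble(recs, "ET", 0.5, self.CV)
        m2 = fit_ensemble(recs, "ET", 0.5, self.CV)
        assert m1.metrics == m2.metrics

    def test_metrics_report_both_correlation_conventions(self):
        x, y, lat, lon = self._xy(3)
        m = fit_ensemble(_records_from_xy(x, y, lat, lon), "ET", 0.5, self.CV)
        for key in ("r2_test_mean", "r2_train_mean", "deviance_explained_lo",
                    "deviance_explained_hi"):
            assert np.isfinite(m.metrics[key])


class TestQuantileProperties:
    def test_generator_coverage_and_crossing(self, world_config, responses):
        """τ-curves fitted on generator data: calibrated and rarely crossing."""
        cfg = SyntheticWorldConfig(seed=11, n_societies=2000,
                                   exclude_fracs=(0, 0, 0, 0))
        et = [r for r in responses if r.variable_id == "ET"]
        records = generate_ethnographic_table(cfg, et)
        x = np.array([r.predictors.ET for r in records])
        y = np.array([r.log10_density for r in records])
        fits = {}
        for tau in (0.1, 0.5, 0.9):
            f = fit_qgam(x, y, tau, seed=0)
            fits[tau] = f
            cover = float(np.mean(y < f(x)))
            assert abs(cover - tau) <= 0.02
        xs = np.linspace(x.min(), x.max(), 500)
        assert crossing_rate(fits, xs) < 0.02
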