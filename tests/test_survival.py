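"""Tests for the Weibull proportional-hazards healing model."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import eswtcea as e
from eswtcea.survival import COEF_NAMES

from conftest import make_fit


def _recovery_config(seed, n=5000, shape=1.3, hr_high=2.0):
    """Data with a known shape and high-dose effect, no competing events."""
    return dataclasses.replace(
        e.TrialConfig(),
        n_patients=n, seed=seed, weibull_shape=shape,
        baseline_log_scale=-6.0, followup_days=365,
        log_hazard_ratios={"high_dose": math.log(hr_high)},
        daily_event_probs={"amputation": 0.0, "death": 0.0},
    )


class TestFit:
    def test_parameter_recovery(self):
        ds = e.generate_trial(_recovery_config(seed=21))
        fit = e.fit_weibull_ph(ds)
        assert fit.shape == pytest.approx(1.3, abs=0.1)
        assert fit.coeffs["high_dose"] == pytest.approx(math.log(2.0),
                                                        abs=0.1)

    def test_exponential_rate_closed_form(self):
        # intercept-only exponential MLE is events / total exposure
        cfg = _recovery_config(seed=22, shape=1.0, hr_high=1.0)
        cfg = dataclasses.replace(cfg, log_hazard_ratios={})
        ds = e.generate_trial(cfg)
        frame = ds.to_frame()
        d = (frame["event"] == "healed").sum()
        exposure = frame["time_days"].sum()
        fit = e.fit_weibull_ph(ds, family="exponential", covariates=())
        assert math.exp(fit.coeffs["const"]) == pytest.approx(
            d / exposure, rel=0.02)

    def test_duplication_keeps_estimates_and_halves_vcov(self,
                                                         default_dataset,
                                                         default_fit):
        doubled = e.TrialDataset(
            records=default_dataset.records + [
                dataclasses.replace(r, id=r.id + 1000)
                for r in default_dataset.records
            ]
        )
        fit2 = e.fit_weibull_ph(doubled)
        np.testing.assert_allclose(fit2.params, default_fit.params,
                                   rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(fit2.vcov, default_fit.vcov / 2,
                                   rtol=1e-3, atol=1e-9)
        assert fit2.loglik == pytest.approx(2 * default_fit.loglik, rel=1e-6)

    def test_no_events_rejected(self):
        cfg = dataclasses.replace(
            e.TrialConfig(), n_patients=10, seed=1,
            baseline_log_scale=-30.0,       # nobody heals
            daily_event_probs={"amputation": 0.0, "death": 0.0},
        )
        ds = e.generate_trial(cfg)
        with pytest.raises(ValueError, match="no healing events"):
            e.fit_weibull_ph(ds)

    def test_aic_identity(self, default_fit):
        assert default_fit.aic == pytest.approx(
            2 * default_fit.n_params - 2 * default_fit.loglik)
        assert default_fit.n_params == 7

    def test_matches_lifelines_aft(self):
        # independent cross-check: lifelines fits the AFT parameterisation;
        # map it back via gamma = rho, beta = -rho * beta_aft
        lifelines = pytest.importorskip("lifelines")
        ds = e.generate_trial(_recovery_config(seed=23, n=800))
        fit = e.fit_weibull_ph(ds)
        frame = ds.to_frame()
        df = pd.DataFrame({
            "t": frame["time_days"],
            "e": (frame["event"] == "healed").astype(int),
            "ulcer_age_days": frame["ulcer_age_days"],
            "ulcer_area_cm2": frame["ulcer_area_cm2"],
            "infected": frame["infected"],
            "low_dose": (frame["arm"] == "low_dose").astype(float),
            "high_dose": (frame["arm"] == "high_dose").astype(float),
        })
        aft = lifelines.WeibullAFTFitter()
        aft.fit(df, duration_col="t", event_col="e")
        rho = float(np.exp(aft.params_.loc[("rho_", "Intercept")]))
        assert fit.shape == pytest.approx(rho, rel=0.01)
        for name in COEF_NAMES[1:]:
            b_aft = float(aft.params_.loc[("lambda_", name)])
            assert fit.coeffs[name] == pytest.approx(-rho * b_aft, rel=0.02,
                                                     abs=5e-3)
        b0_aft = float(aft.params_.loc[("lambda_", "Intercept")])
        assert fit.coeffs["const"] == pytest.approx(-rho * b0_aft, rel=0.02)

    def test_recovery_coverage_over_replicates(self):
        """Fitted (shape, high-dose) within 3 SE of truth in >= 95% of
        seeded replicates."""
        hits = 0
        n_rep = 60
        for seed in range(100, 100 + n_rep):
            ds = e.generate_trial(_recovery_config(seed=seed, n=2000))
            fit = e.fit_weibull_ph(ds)
            se = np.sqrt(np.diag(fit.vcov))
            names = list(fit.param_names)
            i_shape = names.index("log_shape")
            i_high = names.index("high_dose")
            ok = (abs(math.log(fit.shape) - math.log(1.3))
                  <= 3 * se[i_shape]) and (
                abs(fit.coeffs["high_dose"] - math.log(2.0))
                <= 3 * se[i_high])
            hits += ok
        assert hits / n_rep >= 0.95


class TestCompareAic:
    def test_weibull_data_prefers_weibull(self):
        ds = e.generate_trial(_recovery_config(seed=31, n=2000, shape=2.0))
        table = e.compare_aic(ds)
        assert table.loc[0, "family"] == "weibull"

    def test_exponential_data_is_parsimonious(self):
        cfg = _recovery_config(seed=32, n=200, shape=1.0, hr_high=1.0)
        ds = e.generate_trial(cfg)
        table = e.compare_aic(ds)
        best = table.loc[0, "family"]
        delta = table.set_index("family")["delta_aic"]
        assert best == "exponential" or delta["exponential"] <= 2.0

    def test_single_candidate(self, default_dataset):
        table = e.compare_aic(default_dataset, families=("weibull",))
        assert len(table) == 1


class TestCholesky:
    def test_identity(self):
        L = e.cholesky(np.eye(3)).L
        np.testing.assert_allclose(L, np.eye(3))

    def test_diagonal(self):
        L = e.cholesky(np.diag([4.0, 9.0])).L
        np.testing.assert_allclose(L, np.diag([2.0, 3.0]))

    def test_random_spd_reconstruction(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((6, 6))
        sigma = A @ A.T + 0.1 * np.eye(6)
        L = e.cholesky(sigma).L
        assert np.max(np.abs(L @ L.T - sigma)) < 1e-8

    def test_semidefinite_gets_jitter(self, caplog):
        # rank-deficient PSD matrix: plain Cholesky fails, jitter succeeds
        v = np.array([[1.0], [2.0]])
        sigma = v @ v.T
        with caplog.at_level("WARNING", logger="eswtcea.survival"):
            L = e.cholesky(sigma).L
        assert np.max(np.abs(L @ L.T - sigma)) < 1e-4
        assert any("jitter" in r.message for r in caplog.records)

    def test_negative_diagonal_rejected(self):
        with pytest.raises(ValueError, match="not a covariance matrix"):
            e.cholesky(np.diag([1.0, -0.5]))


class TestSampleCoefficients:
    def test_zero_factor_gives_point_estimate(self, default_fit):
        L = e.CholeskyFactor(L=np.zeros((7, 7)))
        draws = e.sample_coefficients(default_fit, L, 10, seed=0)
        np.testing.assert_allclose(draws, np.tile(default_fit.params,
                                                  (10, 1)))

    def test_seed_reproducibility(self, default_fit):
        L = e.cholesky(default_fit)
        a = e.sample_coefficients(default_fit, L, 100, seed=4)
        b = e.sample_coefficients(default_fit, L, 100, seed=4)
        c = e.sample_coefficients(default_fit, L, 100, seed=5)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_empirical_covariance_converges(self):
        vcov = np.array([[0.04, 0.012], [0.012, 0.09]])
        fit = e.WeibullFit(shape=1.0,
                           coeffs=pd.Series({"const": -4.0, "x": 0.5}),
                           vcov=vcov, loglik=0.0, n_events=10, n_censored=0,
                           family="exponential")
        L = e.cholesky(fit)
        draws = e.sample_coefficients(fit, L, 50_000, seed=7)
        emp = np.cov(draws.T)
        np.testing.assert_allclose(emp, vcov, rtol=0.05)
        np.testing.assert_allclose(draws.mean(axis=0), fit.params, atol=0.01)


class TestDailyHealingProb:
    def test_constant_for_exponential(self):
        probs = [e.daily_healing_prob(1.0, 0.01, t) for t in (0, 5, 300)]
        assert all(p == pytest.approx(1 - math.exp(-0.01)) for p in probs)

    def test_increasing_hazard_for_shape_above_one(self):
        probs = e.daily_healing_prob(2.0, 1e-5, np.arange(366))
        assert np.all(np.diff(probs) > 0)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_vanishing_rate(self):
        assert e.daily_healing_prob(1.5, 0.0, 10) == 0.0

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError, match="day"):
            e.daily_healing_prob(1.0, 0.01, -1)

    def test_telescoping_survival_identity(self):
        # product of (1 - p_t) telescopes to S(365) exactly
        shape, rate = 1.4, 0.002
        probs = e.daily_healing_prob(shape, rate, np.arange(365))
        survival = np.prod(1.0 - probs)
        closed = math.exp(-rate * 365.0 ** shape)
        assert survival == pytest.approx(closed, abs=1e-12)
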