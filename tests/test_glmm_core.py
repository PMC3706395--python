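import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal

from grassrisk.glmm_core import (
    FitResult,
    ModelSpec,
    RankDeficientError,
    aicc,
    build_design,
    fit_binomial_glmm,
    fit_gaussian_lmm,
    predict_probability,
)
from grassrisk.species_table import Dataset

from conftest import make_dataset, random_grouped_dataset


def quadrature_loglik_binomial(dataset, fit):
    """Independent oracle: per-genus marginal likelihood by adaptive numerical
    quadrature over the genus intercept, at the fitted parameters."""
    df = dataset.frame
    X, _ = build_design(dataset, fit.spec.fixed_predictors)
    beta = np.array(list(fit.coefficients.values()))
    s = fit.genus_sd
    y_all = df[fit.spec.response].to_numpy(float)
    total = 0.0
    for _, idx in df.groupby("genus").groups.items():
        idx = np.asarray(idx)
        eta0 = X[idx] @ beta
        y = y_all[idx]

        def integrand(u):
            eta = eta0 + u
            return math.exp(
                float(np.sum(y * eta - np.logaddexp(0.0, eta))) - u**2 / (2 * s**2)
            ) / (s * math.sqrt(2 * math.pi))

        val, _ = integrate.quad(integrand, -12 * s, 12 * s, limit=300)
        total += math.log(val)
    return total


def closed_form_loglik_gaussian(dataset, fit):
    """Independent oracle: whole-vector Gaussian marginal density with the
    explicit block covariance sigma_e^2 I + sigma_u^2 Z Z'."""
    df = dataset.frame
    X, _ = build_design(dataset, fit.spec.fixed_predictors)
    beta = np.array(list(fit.coefficients.values()))
    y = np.log(df["spread_rate"].to_numpy(float))
    Z = (df["genus"].to_numpy()[:, None] == np.unique(df["genus"])[None, :]).astype(float)
    cov = fit.residual_sd**2 * np.eye(len(y)) + fit.genus_sd**2 * (Z @ Z.T)
    return float(multivariate_normal(mean=X @ beta, cov=cov).logpdf(y))


class TestAicc:
    def test_closed_form_value(self):
        assert aicc(-20.0, 3, 155) == pytest.approx(46.1589, abs=1e-4)

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError, match="k"):
            aicc(0.0, 0, 100)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(-5.0, 10, 11)

    def test_correction_vanishes_for_large_n(self):
        assert aicc(-20.0, 3, 10**9) == pytest.approx(-2 * -20.0 + 2 * 3, abs=1e-6)


class TestBinomialFitter:
    def test_matches_quadrature_oracle(self, rng):
        """Fitted log-likelihood agrees with numerical integration of the
        genus intercepts on random small datasets."""
        for _ in range(15):
            ds = random_grouped_dataset(rng, n_genera=int(rng.integers(2, 6)))
            if ds.frame["high_impact"].nunique() < 2:
                continue
            fit = fit_binomial_glmm(ds, ModelSpec("high_impact", ("spread_rate",)))
            if not fit.converged or fit.genus_sd < 1e-3:
                continue
            assert fit.loglik == pytest.approx(quadrature_loglik_binomial(ds, fit), abs=1e-3)

    def test_zero_variance_limit_is_plain_logistic(self, rng):
        """With the genus variance pinned at zero the fit collapses to
        ordinary logistic regression (statsmodels as the oracle)."""
        import statsmodels.api as sm

        ds = random_grouped_dataset(rng, n_genera=8, sigma=0.0)
        X, _ = build_design(ds, ("spread_rate",))
        sm_fit = sm.GLM(ds.frame["high_impact"], X, family=sm.families.Binomial()).fit()
        fit = fit_binomial_glmm(ds, ModelSpec("high_impact", ("spread_rate",)), fix_genus_sd=0.0)
        assert np.allclose(list(fit.coefficients.values()), sm_fit.params, atol=1e-5)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-6)

    def test_intercept_only_matches_observed_prevalence(self, fixture_dataset):
        fit = fit_binomial_glmm(
            fixture_dataset, ModelSpec("high_impact", ()), fix_genus_sd=0.0
        )
        prevalence = fixture_dataset.frame["high_impact"].mean()
        assert fit.coefficients["(intercept)"] == pytest.approx(
            math.log(prevalence / (1 - prevalence)), abs=1e-5
        )

    def test_nesting_monotonicity(self, fixture_dataset):
        """Adding a predictor never decreases the maximised log-likelihood."""
        chain = [
            (),
            ("spread_rate",),
            ("spread_rate", "semi_aquatic"),
            ("spread_rate", "actively_spread", "semi_aquatic"),
        ]
        lls = [
            fit_binomial_glmm(fixture_dataset, ModelSpec("high_impact", preds)).loglik
            for preds in chain
        ]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_laplace_single_node_close_to_full_quadrature(self, rng):
        """Optimising the one-node (Laplace) objective lands near the
        full-quadrature estimates on moderate data."""
        ds = random_grouped_dataset(rng, n_genera=12, max_size=10, sigma=0.5)
        spec = ModelSpec("high_impact", ("spread_rate",))
        full = fit_binomial_glmm(ds, spec, n_quad=15)
        laplace = fit_binomial_glmm(ds, spec, n_quad=1)
        assert laplace.coefficients["spread_rate"] == pytest.approx(
            full.coefficients["spread_rate"], abs=0.1
        )
        assert laplace.loglik == pytest.approx(full.loglik, abs=0.1)

    def test_rank_deficient_design_names_column(self):
        ds = make_dataset(["A", "A", "B", "B"], [1, 0, 1, 0])  # semi_aquatic all 0
        with pytest.raises(RankDeficientError, match="semi_aquatic"):
            fit_binomial_glmm(ds, ModelSpec("high_impact", ("spread_rate", "semi_aquatic")))

    def test_k_counts_genus_variance(self, fixture_dataset):
        fit = fit_binomial_glmm(fixture_dataset, ModelSpec("high_impact", ("spread_rate",)))
        assert fit.k == 2 + 1  # intercept + slope + genus variance
        assert fit.aicc == pytest.approx(aicc(fit.loglik, fit.k, fit.n))


class TestGaussianFitter:
    def test_matches_closed_form_marginal(self, rng):
        for _ in range(10):
            ds = random_grouped_dataset(rng, n_genera=int(rng.integers(2, 5)))
            fit = fit_gaussian_lmm(ds, ModelSpec("log_spread_rate", ("naturalisation_year",)))
            assert fit.loglik == pytest.approx(closed_form_loglik_gaussian(ds, fit), abs=1e-6)

    def test_matches_statsmodels_ml(self, rng):
        from statsmodels.regression.mixed_linear_model import MixedLM

        ds = random_grouped_dataset(rng, n_genera=6)
        df = ds.frame
        X, _ = build_design(ds, ("spread_rate",))
        sm_fit = MixedLM(np.log(df["spread_rate"]), X, groups=df["genus"]).fit(
            reml=False, method="powell"
        )
        fit = fit_gaussian_lmm(ds, ModelSpec("log_spread_rate", ("spread_rate",)))
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert np.allclose(list(fit.coefficients.values()), sm_fit.fe_params, atol=1e-3)

    def test_zero_variance_limit_is_ols(self, rng):
        ds = random_grouped_dataset(rng, n_genera=6, sigma=0.0)
        X, _ = build_design(ds, ("spread_rate",))
        y = np.log(ds.frame["spread_rate"].to_numpy(float))
        ols_beta = np.linalg.lstsq(X, y, rcond=None)[0]
        fit = fit_gaussian_lmm(ds, ModelSpec("log_spread_rate", ("spread_rate",)), fix_genus_sd=0.0)
        assert np.allclose(list(fit.coefficients.values()), ols_beta, atol=1e-6)

    def test_year_slope_recovered_from_synthetic_data(self, rng):
        """A positive year effect on log spread rate of the size the field
        reports (~0.0215 per year) is recovered within its 95% CI at n=2000."""
        from grassrisk.synthetic_data import SyntheticConfig, generate, random_genus_sizes

        slope = 0.0215
        sizes = random_genus_sizes(2000, rng)
        cfg = SyntheticConfig(n_species=2000, genus_sizes=sizes, seed=77)
        ds = generate(cfg)
        df = ds.frame.copy()
        # impose the generating relation with known noise around it
        log_spread = slope * (df["naturalisation_year"] - 1900) + rng.normal(0, 0.6, len(df))
        df["num_regions"] = 1  # neutralise stored regions; spread comes from below
        df["spread_rate"] = np.exp(log_spread)
        df["incidence_rate"] = df["incidence"] / ((2009 - df["naturalisation_year"]) / 10)
        ds2 = Dataset(df, census_year=2009, validate=False)
        fit = fit_gaussian_lmm(ds2, ModelSpec("log_spread_rate", ("naturalisation_year",)))
        est = fit.coefficients["naturalisation_year"]
        se_approx = 0.6 / np.std(df["naturalisation_year"]) / np.sqrt(len(df))
        assert est == pytest.approx(slope, abs=2.5 * se_approx)


class TestPrediction:
    @staticmethod
    def _manual_fit(dataset, coefficients, genus_effects=None):
        spec = ModelSpec("high_impact", ("spread_rate", "semi_aquatic"))
        _, cols = build_design(dataset, spec.fixed_predictors)
        return FitResult(
            spec=spec,
            coefficients=coefficients,
            genus_effects=genus_effects or {},
            genus_sd=0.0,
            residual_sd=None,
            loglik=0.0,
            k=3,
            n=len(dataset),
            aicc=0.0,
            converged=True,
            _columns=cols,
        )

    def test_reported_baseline_probabilities(self):
        """At the reported coefficients, near-zero spread gives ~0.029 for
        terrestrial species and ~0.188 for semi-aquatic ones."""
        ds = make_dataset(["A", "A"], [0, 1], semi_aquatic=[0, 1])
        coefs = {"(intercept)": -3.512, "spread_rate": 0.63, "semi_aquatic": 2.05}
        fit = self._manual_fit(ds, coefs, {"A": 0.0})
        terrestrial, aquatic = ds.records
        t = replace(terrestrial, spread_rate=1e-9)
        a = replace(aquatic, spread_rate=1e-9)
        assert predict_probability(fit, t) == pytest.approx(0.029, abs=0.001)
        assert predict_probability(fit, a) == pytest.approx(0.188, abs=0.001)

    def test_all_zero_coefficients_give_half(self):
        ds = make_dataset(["A"], [1])
        fit = self._manual_fit(ds, {"(intercept)": 0.0, "spread_rate": 0.0, "semi_aquatic": 0.0}, {"A": 0.0})
        assert predict_probability(fit, ds.records[0]) == pytest.approx(0.5)

    def test_monotone_in_spread_rate(self, fixture_dataset):
        fit = fit_binomial_glmm(fixture_dataset, ModelSpec("high_impact", ("spread_rate",)))
        assert fit.coefficients["spread_rate"] > 0
        rec = fixture_dataset.records[0]
        probs = [
            predict_probability(fit, replace(rec, spread_rate=sr))
            for sr in (0.5, 1.5, 3.0, 6.0)
        ]
        assert probs == sorted(probs)
        assert all(0 < p < 1 for p in probs)

    def test_unseen_genus_rejected(self, fixture_dataset):
        fit = fit_binomial_glmm(fixture_dataset, ModelSpec("high_impact", ("spread_rate",)))
        rec = fixture_dataset.records[0]
        alien = replace(rec, genus="Neverseen")
        with pytest.raises(KeyError, match="Neverseen"):
            predict_probability(fit, alien)
        # fixed-effects-only prediction still works
        assert 0 < predict_probability(fit, alien, use_genus_effect=False) < 1


def test_num_regions_rejected_for_impact_response():
    with pytest.raises(ValueError, match="num_regions"):
        ModelSpec("high_impact", ("num_regions",))


def test_fit_summary_serialises(fixture_dataset):
    import json

    fit = fit_binomial_glmm(fixture_dataset, ModelSpec("high_impact", ("spread_rate",)))
    payload = json.loads(fit.to_json())
    assert payload["k"] == fit.k
    assert payload["coefficients"]["spread_rate"] == pytest.approx(
        fit.coefficients["spread_rate"]
    )
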