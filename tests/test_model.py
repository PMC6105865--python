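"""Poisson GLM machinery: IRLS fits, IRR reporting, model selection,
likelihood-ratio tests, pseudo r-squared and the outlier screen."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize
from scipy.special import gammaln

from geodens import (
    PoissonGLM,
    SLOT_LABELS,
    backward_eliminate_aic,
    bonferroni_outlier_test,
    fit_null,
    fit_poisson,
    irr_table,
    irr_to_percent_change,
    likelihood_ratio_test,
    mcfadden_r2,
)
from geodens.model import TIME_TERM


def simulate_design(
    rng: np.random.Generator,
    n: int,
    beta: dict[str, float],
    intercept: float = 1.0,
    outcome: str = "density",
) -> pd.DataFrame:
    """Design-level Poisson simulation: random covariates, random slots,
    outcomes drawn from the exact model being fitted."""
    df = pd.DataFrame({name: rng.normal(0, 1, n) for name in beta})
    slots = rng.integers(0, len(SLOT_LABELS), n)
    eta = intercept + sum(df[name].to_numpy() * b for name, b in beta.items())
    for k, s in enumerate(SLOT_LABELS[1:], start=1):
        df[f"slot_{s}"] = (slots == k).astype(float)
    df[outcome] = rng.poisson(np.exp(eta))
    df.index.name = "point_id"
    return df


class TestPoissonGLM:
    def test_intercept_only_mle_is_log_mean(self):
        df = pd.DataFrame({"density": [3, 5, 4]})
        fit = fit_poisson(df, terms=(), forced_terms=())
        assert fit.params["intercept"] == pytest.approx(math.log(4.0), abs=1e-8)
        assert np.allclose(fit.mu, 4.0)

    def test_constant_covariate_is_rank_deficient(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": np.ones(30), "density": rng.poisson(3.0, 30)})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_poisson(df, terms=("x",), forced_terms=())

    def test_matches_direct_likelihood_maximization(self, rng):
        df = simulate_design(rng, 250, {"a": 0.4, "b": -0.3})
        fit = fit_poisson(df, ("a", "b", TIME_TERM))
        X = np.column_stack([np.ones(len(df)), df[list(fit.columns)].to_numpy()])
        y = df["density"].to_numpy(float)

        def negll(beta):
            eta = X @ beta
            return -(y @ eta - np.exp(eta).sum() - gammaln(y + 1).sum())

        res = optimize.minimize(negll, np.zeros(X.shape[1]), method="BFGS")
        assert np.max(np.abs(fit.params.to_numpy() - res.x)) <= 1e-4

    def test_matches_statsmodels_glm(self, rng):
        df = simulate_design(rng, 300, {"a": 0.3, "b": -0.2, "c": 0.0})
        fit = fit_poisson(df, ("a", "b", "c", TIME_TERM))
        X = sm.add_constant(df[list(fit.columns)].to_numpy())
        ref = sm.GLM(df["density"].to_numpy(float), X,
                     family=sm.families.Poisson()).fit()
        assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-8)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-8)
        assert fit.aic == pytest.approx(ref.aic, abs=1e-6)
        assert np.allclose(fit.glm.cov_params_, ref.cov_params(), atol=1e-8)

    def test_offset_model_matches_statsmodels(self, rng):
        df = simulate_design(rng, 200, {"a": 0.5}, outcome="user_count")
        df["land_area"] = rng.uniform(0.5, 3.0, len(df))
        fit = fit_poisson(df, ("a", TIME_TERM), outcome="user_count",
                          offset_col="land_area")
        X = sm.add_constant(df[list(fit.columns)].to_numpy())
        ref = sm.GLM(df["user_count"].to_numpy(float), X,
                     family=sm.families.Poisson(),
                     offset=np.log(df["land_area"])).fit()
        assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-8)

    def test_aic_identity(self, rng):
        df = simulate_design(rng, 120, {"a": 0.2})
        for terms in [(), ("a",)]:
            fit = fit_poisson(df, terms, forced_terms=())
            assert fit.aic == -2.0 * fit.llf + 2.0 * fit.k

    def test_sklearn_estimator_api(self, rng):
        X = rng.normal(size=(80, 2))
        y = rng.poisson(np.exp(0.5 + X @ np.array([0.3, -0.2])))
        est = PoissonGLM()
        assert est.get_params()["max_iter"] == 100
        est.fit(X, y)
        assert est.coef_.shape == (2,)
        mu = est.predict(X)
        assert np.all(mu > 0)
        assert est.set_params(max_iter=50).max_iter == 50


class TestIrr:
    def test_ci_endpoints_match_wald_arithmetic(self, rng):
        df = simulate_design(rng, 200, {"a": 0.3, "b": -0.4})
        fit = fit_poisson(df, ("a", "b", TIME_TERM))
        table = irr_table(fit)
        for name in table.index:
            b = fit.params[name]
            se = fit.bse[name]
            assert table.loc[name, "irr"] == pytest.approx(math.exp(b), rel=1e-12)
            assert table.loc[name, "ci_low"] == pytest.approx(
                math.exp(b - 1.96 * se), rel=1e-12
            )
            assert table.loc[name, "ci_high"] == pytest.approx(
                math.exp(b + 1.96 * se), rel=1e-12
            )
            # log of the reported IRR reproduces the coefficient
            assert math.log(table.loc[name, "irr"]) == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize(
        "irr, pct",
        [(0.26, -74), (1.00, 0), (1.08, 8), (2.16, 116)],
    )
    def test_percent_change(self, irr, pct):
        assert irr_to_percent_change(irr) == pct

    def test_percent_change_unrounded_and_errors(self):
        assert irr_to_percent_change(1.5, rounded=False) == pytest.approx(50.0)
        with pytest.raises(ValueError):
            irr_to_percent_change(0.0)


class TestBackwardElimination:
    def test_strong_signals_keep_full_model(self, rng):
        df = simulate_design(rng, 400, {"a": 0.8, "b": -0.7, "c": 0.9},
                             intercept=2.0)
        fit = backward_eliminate_aic(df, ("a", "b", "c"))
        assert set(fit.terms) == {TIME_TERM, "a", "b", "c"}

    def test_noise_term_is_first_drop_candidate(self):
        """Among strong signals, the pure-noise term is the best first drop
        in nearly every replicate, and is actually removed at the rate
        chi-square theory predicts (an AIC drop improves iff the term's
        deviance contribution is below 2, i.e. P(chi2_1 < 2) = 0.843)."""
        rng = np.random.default_rng(314)
        best_is_noise = 0
        removed = 0
        n_rep = 100
        for _ in range(n_rep):
            df = simulate_design(rng, 500, {"a": 0.5, "b": -0.5, "noise": 0.0},
                                 intercept=1.5)
            full = fit_poisson(df, ("a", "b", "noise", TIME_TERM))
            drops = {
                t: fit_poisson(
                    df, tuple(x for x in ("a", "b", "noise") if x != t) + (TIME_TERM,)
                ).aic
                for t in ("a", "b", "noise")
            }
            best = min(drops, key=drops.get)
            if best == "noise":
                best_is_noise += 1
                if drops["noise"] < full.aic:
                    removed += 1
        assert best_is_noise >= 90
        # 0.843 +/- 3 binomial SE over 100 replicates
        assert 73 <= removed <= 95

    def test_greedy_path_matches_independent_oracle(self, rng):
        df = simulate_design(
            rng, 300, {"a": 0.4, "b": 0.0, "c": -0.3, "d": 0.0, "e": 0.02}
        )
        candidates = ("a", "b", "c", "d", "e")
        fit = backward_eliminate_aic(df, candidates)

        def sm_aic(terms):
            cols = []
            for t in terms:
                cols.extend(
                    [f"slot_{s}" for s in SLOT_LABELS[1:]] if t == TIME_TERM else [t]
                )
            X = sm.add_constant(df[cols].to_numpy())
            return sm.GLM(df["density"].to_numpy(float), X,
                          family=sm.families.Poisson()).fit().aic

        # independent greedy re-implementation on statsmodels fits
        remaining = list(candidates)
        current_aic = sm_aic((TIME_TERM, *remaining))
        path = []
        while remaining:
            aics = {t: sm_aic((TIME_TERM, *(x for x in remaining if x != t)))
                    for t in remaining}
            best = min(remaining, key=lambda t: aics[t])
            if aics[best] < current_aic:
                remaining.remove(best)
                current_aic = aics[best]
                path.append(best)
            else:
                break
        oracle_terms = {TIME_TERM, *remaining}

        assert set(fit.terms) == oracle_terms
        assert fit.aic == pytest.approx(current_aic, abs=1e-6)
        full_aic = sm_aic((TIME_TERM, *candidates))
        assert fit.aic <= full_aic + 1e-9
        # exhaustive enumeration: greedy result is no worse than the full model
        # and matches the best AIC among the subsets on its own path
        from itertools import combinations

        best_subset_aic = min(
            sm_aic((TIME_TERM, *sub))
            for r in range(len(candidates) + 1)
            for sub in combinations(candidates, r)
        )
        assert fit.aic >= best_subset_aic - 1e-9

    def test_forced_terms_never_dropped(self, rng):
        df = simulate_design(rng, 200, {"a": 0.0})
        fit = backward_eliminate_aic(df, ("a",))
        assert TIME_TERM in fit.terms


class TestLikelihoodRatio:
    def test_identical_models_give_zero_statistic_unit_p(self, rng):
        df = simulate_design(rng, 100, {"a": 0.3})
        fit = fit_poisson(df, ("a", TIME_TERM))
        stat, dof, p = likelihood_ratio_test(fit, fit)
        assert (stat, dof, p) == (0.0, 0, 1.0)

    def test_statistic_is_twice_log_likelihood_gap(self, rng):
        df = simulate_design(rng, 250, {"a": 0.4, "b": 0.2})
        full = fit_poisson(df, ("a", "b", TIME_TERM))
        reduced = fit_poisson(df, ("a", TIME_TERM))
        stat, dof, p = likelihood_ratio_test(full, reduced)
        assert stat == pytest.approx(2.0 * (full.llf - reduced.llf), abs=1e-10)
        assert dof == 1
        assert stat >= 0.0
        assert 0.0 <= p <= 1.0

    def test_non_nested_rejected(self, rng):
        df = simulate_design(rng, 100, {"a": 0.3, "b": 0.1})
        fa = fit_poisson(df, ("a", TIME_TERM))
        fb = fit_poisson(df, ("b", TIME_TERM))
        with pytest.raises(ValueError):
            likelihood_ratio_test(fa, fb)


class TestMcFadden:
    def test_null_against_itself_is_zero(self, rng):
        df = simulate_design(rng, 100, {"a": 0.3})
        null = fit_null(df)
        assert mcfadden_r2(null, null) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_under_nesting(self, rng):
        df = simulate_design(rng, 300, {"a": 0.5, "b": -0.4})
        null = fit_null(df)
        small = fit_poisson(df, ("a", TIME_TERM))
        big = fit_poisson(df, ("a", "b", TIME_TERM))
        r_small = mcfadden_r2(small, null)
        r_big = mcfadden_r2(big, null)
        assert 0.0 <= r_small <= r_big < 1.0


class TestOutlierScreen:
    def test_perfectly_fitted_data_has_no_flags(self):
        df = pd.DataFrame({"density": [4, 4, 4, 4, 4]})
        fit = fit_poisson(df, terms=(), forced_terms=())
        report = bonferroni_outlier_test(fit)
        assert report.n_flagged == 0
        assert np.allclose(report.table["residual"], 0.0)

    def test_inflated_observation_is_flagged(self, rng):
        df = simulate_design(rng, 150, {"a": 0.4}, intercept=2.5)
        victim = df.index[17]
        df.loc[victim, "density"] = max(10, int(df.loc[victim, "density"]) * 10)
        fit = fit_poisson(df, ("a", TIME_TERM))
        report = bonferroni_outlier_test(fit)
        assert victim in report.flagged_ids

    def test_null_calibration_controls_family_wise_flags(self):
        """Without outliers, the mean number of Bonferroni flags stays near
        the family-wise level alpha."""
        rng = np.random.default_rng(77)
        flags = 0
        n_rep = 200
        for _ in range(n_rep):
            df = simulate_design(rng, 100, {"a": 0.3}, intercept=3.0)
            fit = fit_poisson(df, ("a", TIME_TERM))
            flags += bonferroni_outlier_test(fit, alpha=0.05).n_flagged
        assert flags / n_rep <= 0.05 * 2.0

    def test_adjusted_p_dominates_raw_p(self, rng):
        df = simulate_design(rng, 80, {"a": 0.2}, intercept=2.0)
        report = bonferroni_outlier_test(fit_poisson(df, ("a", TIME_TERM)))
        assert (report.table["p_bonferroni"] >= report.table["p"] - 1e-15).all()
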