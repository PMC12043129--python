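"""The quantile g-computation engine: GLM fitting, weights, MSM, bootstrap,
chemical-specific models and stepwise selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

import qgcmix as qm
from qgcmix.design import DEFAULT_COVARIATES, build_design, encode_covariates
from qgcmix.exposures import quantize_frame
from qgcmix.qgc import (
    DegenerateWeightsError,
    GLMFit,
    NonConvergenceError,
    _fit_once,
    _prepare_arrays,
)


def _make_glmfit(coefs: dict) -> GLMFit:
    s = pd.Series(coefs, dtype=float)
    return GLMFit(params=s, bse=s * 0 + 0.1, deviance=100.0, aic=110.0,
                  converged=True, n=100, design_columns=list(s.index))


class TestFitGlmLogistic:
    def test_two_by_two_log_odds_ratio(self):
        """Single binary predictor: the coefficient equals the log odds
        ratio of the contingency table, closed form."""
        # table: x=0 -> 30/70 events, x=1 -> 55/45 events
        x = np.repeat([0.0, 1.0], 100)
        y = np.concatenate([
            np.repeat([1.0, 0.0], [30, 70]), np.repeat([1.0, 0.0], [55, 45])
        ])
        X = pd.DataFrame({"const": np.ones(200), "x": x})
        fit = qm.fit_glm_logistic(X, y)
        log_or = np.log((55 / 45) / (30 / 70))
        assert fit.params["x"] == pytest.approx(log_or, abs=1e-6)
        assert fit.params["const"] == pytest.approx(np.log(30 / 70), abs=1e-6)

    def test_null_predictors_near_zero(self):
        rng = np.random.default_rng(60)
        X = pd.DataFrame(rng.normal(size=(10_000, 3)), columns=list("abc"))
        X.insert(0, "const", 1.0)
        y = rng.binomial(1, 0.3, size=10_000)
        fit = qm.fit_glm_logistic(X, y)
        for c in "abc":
            assert abs(fit.params[c]) < 3 * fit.bse[c]

    def test_deviance_nesting(self, small_cohort):
        qz = quantize_frame(small_cohort[list(qm.CHEMICALS)])
        y = small_cohort["imp_language"].to_numpy()
        full = qm.fit_glm_logistic(build_design(qz.scores), y)
        null = qm.fit_glm_logistic(
            pd.DataFrame({"const": np.ones(len(y))}), y)
        assert full.deviance <= null.deviance

    def test_aliased_column_dropped(self):
        rng = np.random.default_rng(61)
        x = rng.normal(size=300)
        X = pd.DataFrame({"const": 1.0, "x": x, "x2": 2 * x})
        y = rng.binomial(1, 0.5, size=300)
        with pytest.warns(UserWarning, match="aliased"):
            fit = qm.fit_glm_logistic(X, y)
        assert fit.dropped_columns == ["x2"]
        assert fit.converged

    def test_separation_flagged(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()  # perfectly separated
        X = pd.DataFrame({"const": np.ones(40), "x": x})
        fit = qm.fit_glm_logistic(X, y)
        assert not fit.converged
        with pytest.raises(NonConvergenceError):
            qm.psi_and_weights(fit, ["x"])

    def test_nonbinary_outcome_rejected(self):
        X = pd.DataFrame({"const": np.ones(10)})
        with pytest.raises(ValueError):
            qm.fit_glm_logistic(X, np.arange(10.0))


class TestPsiAndWeights:
    def test_single_member(self):
        fit = _make_glmfit({"const": -1.0, "pb": 0.5})
        pw = qm.psi_and_weights(fit, ["pb"])
        assert pw.psi_conditional == pytest.approx(0.5)
        assert pw.weights == {"pb": 1.0}
        assert pw.positive_partial == pytest.approx(np.exp(0.5))
        assert pw.negative_partial is None

    def test_mixed_direction_arithmetic(self):
        """beta = (0.2, -0.3, 0.1): positive weights 2/3 and 1/3, negative
        weight 1, psi_conditional exactly zero."""
        fit = _make_glmfit({"const": 0.0, "a": 0.2, "b": -0.3, "c": 0.1})
        pw = qm.psi_and_weights(fit, ["a", "b", "c"])
        assert pw.psi_conditional == pytest.approx(0.0)
        assert pw.weights["a"] == pytest.approx(2 / 3)
        assert pw.weights["c"] == pytest.approx(1 / 3)
        assert pw.weights["b"] == pytest.approx(-1.0)
        assert pw.positive_partial == pytest.approx(np.exp(0.3))
        assert pw.negative_partial == pytest.approx(np.exp(-0.3))

    def test_directional_sums_on_fitted_cohorts(self):
        """On every converged fit the |weights| sum to 1 within each sign
        class, and psi_conditional equals the sum of the two partial sums."""
        truth = qm.MixtureTruth(
            beta0=-1.2, beta={"pb": -0.25, "hg": -0.1, "cd": 0.15, "as": -0.02})
        for seed in range(5):
            coh = qm.generate_cohort(1200, truths={"y": truth}, seed=70 + seed)
            f = qm.fit_mixture_model(coh, "y", B=0)
            pos = sum(w for w in f.weights.values() if w > 0)
            neg = sum(-w for w in f.weights.values() if w < 0)
            if f.positive_members:
                assert pos == pytest.approx(1.0, abs=1e-12)
            if f.negative_members:
                assert neg == pytest.approx(1.0, abs=1e-12)
            log_sum = (np.log(f.positive_partial or 1.0)
                       + np.log(f.negative_partial or 1.0))
            assert f.psi_conditional == pytest.approx(log_sum, abs=1e-12)

    def test_all_zero_betas_signalled(self):
        fit = _make_glmfit({"const": -1.0, "a": 0.0, "b": 0.0})
        with pytest.raises(DegenerateWeightsError):
            qm.psi_and_weights(fit, ["a", "b"])


class TestMsmPr:
    def test_null_model_flat_curve(self):
        """Zero exposure coefficients: the curve is flat at the standardized
        mean and PR is exactly 1."""
        rng = np.random.default_rng(62)
        design = pd.DataFrame({
            "const": np.ones(200),
            "pb": rng.integers(0, 4, 200).astype(float),
            "z": rng.normal(size=200),
        })
        fit = _make_glmfit({"const": -0.7, "pb": 0.0, "z": 0.4})
        curve = qm.msm_pr(fit, design, ["pb"], q=4)
        assert curve.pr == pytest.approx(1.0)
        assert np.ptp(curve.probabilities) == pytest.approx(0.0)

    def test_matches_exhaustive_subject_loop(self):
        """Standardized probabilities equal a brute-force loop over subjects
        and joint levels on a 50-subject cohort."""
        truth = qm.MixtureTruth.from_psi_weights(beta0=-0.8, psi=-0.3)
        coh = qm.generate_cohort(50, truths={"y": truth}, seed=63)
        f = qm.fit_mixture_model(coh, "y", B=0)
        qz = quantize_frame(coh[list(qm.CHEMICALS)])
        cov = encode_covariates(coh, DEFAULT_COVARIATES)
        design = build_design(qz.scores, cov)
        beta = f.glm.params
        for s in range(4):
            acc = 0.0
            for i in range(50):
                eta = 0.0
                for col in f.glm.design_columns:
                    x = s if col in qm.CHEMICALS else design[col].iloc[i]
                    eta += beta[col] * x
                acc += 1.0 / (1.0 + np.exp(-eta))
            assert f.curve.probabilities[s] == pytest.approx(acc / 50, abs=1e-12)

    def test_marginal_sign_matches_conditional(self):
        """sign(psi_marginal) == sign(psi_conditional) across seeded
        simulations with a real joint effect."""
        truth = qm.MixtureTruth.from_psi_weights(beta0=-1.0, psi=-0.35)
        for seed in range(10):
            coh = qm.generate_cohort(1000, truths={"y": truth}, seed=80 + seed)
            f = qm.fit_mixture_model(coh, "y", B=0)
            assert np.sign(f.psi_marginal) == np.sign(f.psi_conditional)


class TestBootstrap:
    def test_same_seed_identical_ci(self, small_cohort):
        a = qm.bootstrap_ci(small_cohort, "imp_language", B=50, seed=7)
        b = qm.bootstrap_ci(small_cohort, "imp_language", B=50, seed=7)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[2], b[2])
        c = qm.bootstrap_ci(small_cohort, "imp_language", B=50, seed=8)
        assert a[0] != c[0]

    def test_ci_contains_point_estimate(self, small_cohort):
        f = qm.fit_mixture_model(small_cohort, "imp_language", B=199, seed=9)
        lo, hi = f.pr_ci
        assert lo <= f.pr <= hi
        assert f.pr > 0

    def test_width_shrinks_with_n(self):
        """Median CI width at n=2000 is below the median width at n=500
        over matched simulated cohorts."""
        truth = qm.MixtureTruth.from_psi_weights(beta0=-1.0, psi=-0.2)
        widths = {500: [], 2000: []}
        for seed in range(10):
            for n in (500, 2000):
                coh = qm.generate_cohort(n, truths={"y": truth}, seed=90 + seed)
                (lo, hi), _, _ = qm.bootstrap_ci(
                    coh, "y", B=60, seed=seed)
                widths[n].append(hi - lo)
        assert np.median(widths[2000]) < np.median(widths[500])

    def test_b_below_two_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            qm.bootstrap_ci(small_cohort, "imp_language", B=1)

    def test_normal_method_available(self, small_cohort):
        (lo, hi), _, _ = qm.bootstrap_ci(
            small_cohort, "imp_language", B=100, seed=3, method="normal")
        assert 0 < lo < hi


class TestChemicalSpecific:
    def test_d1_mixture_equals_chemical_specific(self, small_cohort):
        mix = qm.fit_mixture_model(
            small_cohort, "imp_language", chemicals=["pb"], B=50, seed=5)
        chem = qm.chemical_specific_fit(
            small_cohort, "pb", "imp_language", B=50, seed=5)
        assert chem.pr == mix.pr
        assert chem.pr_ci == mix.pr_ci
        assert chem.psi_conditional == mix.psi_conditional
        assert chem.weights == mix.weights == {"pb": mix.weights["pb"]}

    def test_null_chemical_pr_near_one(self):
        """A chemical with no effect: PR within 3 bootstrap SEs of 1."""
        truth = qm.MixtureTruth(
            beta0=-1.0, beta={"pb": -0.4, "hg": 0.0, "cd": 0.0, "as": 0.0},
            covariate_effects={})
        coh = qm.generate_cohort(4000, truths={"y": truth}, seed=64)
        f = qm.chemical_specific_fit(coh, "hg", "y", adjusted=False,
                                     B=100, seed=1)
        _, _, prs = qm.bootstrap_ci(coh, "y", chemicals=["hg"],
                                    covariates=None, B=100, seed=1)
        assert abs(f.pr - 1.0) < 3 * prs.std(ddof=1)


class TestStepwise:
    def test_planted_signal_retained(self):
        """One strongly predictive covariate among noise is retained."""
        truth = qm.MixtureTruth.from_psi_weights(
            beta0=-1.0, psi=-0.2,
            covariate_effects={"sex_female": 1.2})
        coh = qm.generate_cohort(2000, truths={"y": truth}, seed=65)
        rng = np.random.default_rng(66)
        coh["noise1"] = rng.normal(size=2000)
        coh["noise2"] = rng.normal(size=2000)
        sel = qm.stepwise_select(
            coh, "y", candidates=["sex_female", "noise1", "noise2"])
        assert "sex_female" in sel.retained
        assert sel.steps[-1].action == "stop"

    def test_no_improving_candidate_keeps_empty_set(self):
        """A candidate that cannot change the likelihood (constant, hence
        aliased with the intercept) is never added."""
        truth = qm.MixtureTruth.from_psi_weights(
            beta0=-1.0, psi=-0.2, covariate_effects={})
        coh = qm.generate_cohort(600, truths={"y": truth}, seed=67)
        coh["constant_asset"] = 1.0
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            sel = qm.stepwise_select(coh, "y", candidates=["constant_asset"])
        assert sel.retained == []

    def test_greedy_reaches_exhaustive_best(self):
        """With <= 5 candidates the selected model's criterion matches the
        best among all subsets reachable by the greedy path (here: the
        global exhaustive optimum, computed by brute force)."""
        truth = qm.MixtureTruth.from_psi_weights(
            beta0=-1.0, psi=-0.2,
            covariate_effects={"sex_female": 0.8, "age_c": 0.08})
        coh = qm.generate_cohort(1500, truths={"y": truth}, seed=69)
        rng = np.random.default_rng(70)
        coh["noise1"] = rng.normal(size=1500)
        candidates = ["sex_female", "age_months", "noise1"]
        sel = qm.stepwise_select(coh, "y", candidates=candidates)

        def crit(subset):
            cov = encode_covariates(coh, subset) if subset else None
            qz = quantize_frame(coh[list(qm.CHEMICALS)])
            design = build_design(qz.scores, cov)
            fit = qm.fit_glm_logistic(design, coh["y"].to_numpy())
            return fit.deviance + 2 * len(fit.design_columns)

        best = min(
            (crit(list(sub)) for r in range(len(candidates) + 1)
             for sub in itertools.combinations(candidates, r))
        )
        assert crit(sel.retained) == pytest.approx(best, abs=1e-8)

    def test_empty_candidates_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            qm.stepwise_select(small_cohort, "imp_language", candidates=[])

    def test_step_log_frame(self, small_cohort):
        sel = qm.stepwise_select(
            small_cohort, "imp_language",
            candidates=["sex_female", "age_months"])
        log = sel.log_frame()
        assert {"step", "action", "covariate", "criterion"} <= set(log.columns)
        assert (log["action"] == "start").iloc[0]


class TestMixtureFitContract:
    def test_missing_outcome_column_named(self, small_cohort):
        with pytest.raises(KeyError, match="imp_social"):
            qm.fit_mixture_model(small_cohort, "imp_social", B=0)

    def test_permuted_outcome_centers_pr_at_one(self, small_cohort):
        """Breaking the exposure-outcome link by permutation yields a PR
        distribution centered at 1."""
        rng = np.random.default_rng(71)
        prs = []
        coh = small_cohort.copy()
        for _ in range(20):
            coh["y_perm"] = rng.permutation(
                small_cohort["imp_language"].to_numpy())
            prs.append(qm.fit_mixture_model(coh, "y_perm", B=0).pr)
        assert np.median(prs) == pytest.approx(1.0, abs=0.05)

    def test_unadjusted_matches_adjusted_without_confounding(self):
        """When the truth has no covariate effects, adjusted and unadjusted
        PRs agree within Monte-Carlo tolerance."""
        truth = qm.MixtureTruth.from_psi_weights(
            beta0=np.log(0.30), psi=-0.25, link="log", covariate_effects={})
        coh = qm.generate_cohort(20_000, truths={"y": truth}, seed=72)
        adj = qm.fit_mixture_model(coh, "y", adjusted=True, B=0)
        unadj = qm.fit_mixture_model(coh, "y", adjusted=False, B=0)
        assert adj.pr == pytest.approx(unadj.pr, abs=0.03)

    def test_fast_path_agrees_with_public_pipeline(self, small_cohort):
        """The bootstrap's internal fit path reproduces the public
        fit_mixture_model PR on the original (unresampled) data."""
        conc, cov, y, _ = _prepare_arrays(
            small_cohort, "imp_language", qm.CHEMICALS, DEFAULT_COVARIATES)
        pr, betas = _fit_once(conc, cov, y, q=4, d=4)
        f = qm.fit_mixture_model(small_cohort, "imp_language", B=0)
        assert pr == pytest.approx(f.pr, abs=1e-10)
        np.testing.assert_allclose(
            betas, f.glm.params[list(qm.CHEMICALS)], atol=1e-10)
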