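"""Quantile g-computation for binary outcomes.

The estimator scores each exposure into q quantile categories, fits a joint
logistic model, and summarizes the mixture through:

* ``psi_conditional`` — the sum of the exposure coefficients, the conditional
  log-odds change per simultaneous one-quantile increase in every exposure;
* directional weights — each chemical's share of the positive or negative
  part of the joint effect (magnitudes sum to 1 within each sign class);
* ``psi_marginal`` / PR — g-computation standardization: set every subject's
  mixture scores to a common level s, average the fitted probabilities,
  regress the log of the standardized probabilities on s (the marginal
  structural model), and anti-log the slope into a prevalence ratio;
* a subject-resampling bootstrap percentile CI for the PR.

Chemical-specific models are the d=1 special case of the same pipeline, and
forward-backward stepwise AIC selection chooses the adjustment set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .design import DEFAULT_COVARIATES, build_design, encode_covariates
from .exposures import CHEMICALS, quantize_frame

#: |coefficient| above which a logistic fit is treated as separated.
_SEPARATION_LIMIT = 30.0


class DegenerateWeightsError(ValueError):
    """All exposure coefficients are exactly zero: weights are undefined."""


class NonConvergenceError(RuntimeError):
    """Logistic fit failed to converge (or shows complete separation)."""


# --------------------------------------------------------------------------
# GLM fitting
# --------------------------------------------------------------------------

@dataclass
class GLMFit:
    params: pd.Series
    bse: pd.Series
    deviance: float
    aic: float
    converged: bool
    n: int
    dropped_columns: list[str] = field(default_factory=list)
    design_columns: list[str] = field(default_factory=list)


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove linearly dependent columns, keeping the leftmost of each
    dependent group (modified Gram-Schmidt rank screen)."""
    n = X.shape[0]
    keep: list[int] = []
    basis = np.empty((n, 0))
    for j in range(X.shape[1]):
        x = X[:, j].astype(float)
        resid = x - basis @ (basis.T @ x)
        norm = np.linalg.norm(resid)
        if norm > 1e-8 * max(np.linalg.norm(x), 1.0):
            keep.append(j)
            basis = np.column_stack([basis, resid / norm])
    dropped = [names[j] for j in range(len(names)) if j not in keep]
    return X[:, keep], [names[j] for j in keep], dropped


def fit_glm_logistic(X: pd.DataFrame, y: Sequence[int] | np.ndarray) -> GLMFit:
    """Maximum-likelihood logistic fit with alias handling.

    Aliased (linearly dependent) design columns are dropped and logged on the
    result.  Non-convergence or apparent complete separation marks the fit
    ``converged=False``; downstream consumers refuse such fits.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    names = list(X.columns)
    arr = X.to_numpy(dtype=float)
    arr, kept, dropped = _drop_aliased(arr, names)
    if dropped:
        warnings.warn(f"dropped aliased design columns: {dropped}",
                      UserWarning, stacklevel=2)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, arr, family=sm.families.Binomial()).fit(maxiter=100)
        params = res.params
        bse = res.bse
        if (not res.converged or not np.all(np.isfinite(params))
                or np.abs(params).max() > _SEPARATION_LIMIT
                or not np.all(np.isfinite(bse))):
            converged = False
        deviance, aic = float(res.deviance), float(res.aic)
    except Exception:
        converged = False
        params = np.full(len(kept), np.nan)
        bse = np.full(len(kept), np.nan)
        deviance = aic = np.nan
    return GLMFit(
        params=pd.Series(params, index=kept),
        bse=pd.Series(bse, index=kept),
        deviance=deviance,
        aic=aic,
        converged=converged,
        n=len(y),
        dropped_columns=dropped,
        design_columns=kept,
    )


# --------------------------------------------------------------------------
# psi and directional weights
# --------------------------------------------------------------------------

@dataclass
class PsiWeights:
    psi_conditional: float                  # sum of exposure coefficients
    positive_partial: float | None          # exp(sum of positive betas), None if class empty
    positive_members: list[str]
    negative_partial: float | None          # exp(sum of negative betas)
    negative_members: list[str]
    weights: dict[str, float]               # signed; |w| sums to 1 per sign class


def psi_and_weights(fit: GLMFit, members: Sequence[str] = CHEMICALS) -> PsiWeights:
    """Decompose the joint effect into directional partial effects and weights.

    Within each sign class the weight of chemical k is beta_k divided by that
    class's coefficient sum, so each class's magnitudes sum to one; the sign
    of the stored weight records the class.
    """
    if not fit.converged:
        raise NonConvergenceError("refusing to decompose a non-converged fit")
    missing = [m for m in members if m not in fit.params.index]
    if missing:
        raise KeyError(f"members absent from the fitted design: {missing}")
    betas = fit.params[list(members)]
    if (betas == 0).all():
        raise DegenerateWeightsError(
            "all exposure coefficients are exactly zero; psi = 0 and the "
            "directional weights are undefined"
        )
    pos = betas[betas > 0]
    neg = betas[betas < 0]
    weights: dict[str, float] = {}
    for k, b in betas.items():
        if b > 0:
            weights[k] = float(b / pos.sum())
        elif b < 0:
            weights[k] = float(-abs(b / neg.sum()))
        else:
            weights[k] = 0.0
    return PsiWeights(
        psi_conditional=float(betas.sum()),
        positive_partial=float(np.exp(pos.sum())) if len(pos) else None,
        positive_members=list(pos.index),
        negative_partial=float(np.exp(neg.sum())) if len(neg) else None,
        negative_members=list(neg.index),
        weights=weights,
    )


# --------------------------------------------------------------------------
# marginal structural model / prevalence ratio
# --------------------------------------------------------------------------

@dataclass
class MSMCurve:
    levels: np.ndarray          # joint quantile levels 0..q-1
    probabilities: np.ndarray   # standardized outcome probability per level
    psi_marginal: float         # slope of log(prob) on level (log RR / quantile)
    pr: float                   # exp(psi_marginal)
    intercept: float            # fitted MSM intercept (log scale)


def _standardized_probs(
    beta: np.ndarray, X: np.ndarray, member_idx: np.ndarray, q: int
) -> np.ndarray:
    """g-computation: for each joint level s, set every mixture column to s
    for all subjects and average the fitted probabilities."""
    probs = np.empty(q)
    Xs = X.copy()
    for s in range(q):
        Xs[:, member_idx] = s
        probs[s] = expit(Xs @ beta).mean()
    return probs


def msm_pr(
    fit: GLMFit,
    design: pd.DataFrame,
    members: Sequence[str] = CHEMICALS,
    q: int = 4,
) -> MSMCurve:
    """Standardize over joint quantile levels and fit the MSM line.

    The returned PR is the anti-log of the log-linear slope: the factor by
    which the standardized outcome prevalence changes per simultaneous
    one-quantile increase in all mixture members.
    """
    if not fit.converged:
        raise NonConvergenceError("refusing to standardize a non-converged fit")
    cols = fit.design_columns
    X = design[cols].to_numpy(dtype=float)
    beta = fit.params[cols].to_numpy()
    member_idx = np.array([cols.index(m) for m in members])
    probs = _standardized_probs(beta, X, member_idx, q)
    if np.any(probs <= 0.0) or np.any(probs >= 1.0):
        raise ValueError(
            "standardized probability hit 0 or 1; log-RR slope undefined"
        )
    levels = np.arange(q, dtype=float)
    slope, intercept = np.polyfit(levels, np.log(probs), 1)
    return MSMCurve(
        levels=levels,
        probabilities=probs,
        psi_marginal=float(slope),
        pr=float(np.exp(slope)),
        intercept=float(intercept),
    )


# --------------------------------------------------------------------------
# the orchestrated mixture fit
# --------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Complete output of one quantile g-computation run."""

    outcome: str
    chemicals: list[str]
    adjusted: bool
    q: int
    n: int
    psi_conditional: float
    psi_marginal: float
    pr: float
    pr_ci: tuple[float, float] | None
    positive_partial: float | None
    positive_members: list[str]
    negative_partial: float | None
    negative_members: list[str]
    weights: dict[str, float]
    curve: MSMCurve
    glm: GLMFit
    B: int = 0
    seed: int | None = None
    n_boot_failed: int = 0
    boot_unreliable: bool = False
    ci_method: str = "percentile"

    @property
    def percent_change(self) -> float:
        """Percent reduction when PR < 1, percent increase otherwise."""
        return (1.0 - self.pr) * 100.0 if self.pr < 1.0 else (self.pr - 1.0) * 100.0


def _prepare_arrays(
    cohort: pd.DataFrame,
    outcome: str,
    chemicals: Sequence[str],
    covariates: Sequence[str] | None,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, list[str]]:
    """Raw concentration block, encoded covariate block, outcome vector."""
    if outcome not in cohort.columns:
        raise KeyError(f"cohort table lacks outcome column {outcome!r}")
    missing = [c for c in chemicals if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table lacks exposure columns: {missing}")
    conc = cohort[list(chemicals)].to_numpy(dtype=float)
    y = cohort[outcome].to_numpy(dtype=float)
    if covariates:
        cov_df = encode_covariates(cohort, covariates)
        return conc, cov_df.to_numpy(dtype=float), y, list(cov_df.columns)
    return conc, None, y, []


def _quantize_block(conc: np.ndarray, q: int) -> np.ndarray:
    """Column-wise quantile scoring (same rule as exposures.quantize)."""
    scores = np.empty_like(conc, dtype=float)
    probs = np.arange(1, q) / q
    for j in range(conc.shape[1]):
        cuts = np.quantile(conc[:, j], probs, method="linear")
        scores[:, j] = np.searchsorted(cuts, conc[:, j], side="left")
    return scores


def _fit_once(
    conc: np.ndarray,
    cov: np.ndarray | None,
    y: np.ndarray,
    q: int,
    d: int,
) -> tuple[float, np.ndarray] | None:
    """Fast path: quantize -> logistic fit -> MSM slope.  Returns
    (pr, exposure betas) or None when the replicate fails."""
    scores = _quantize_block(conc, q)
    parts = [np.ones((len(y), 1)), scores]
    if cov is not None:
        parts.append(cov)
    X = np.concatenate(parts, axis=1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception:
        return None
    beta = res.params
    if (not res.converged or not np.all(np.isfinite(beta))
            or np.abs(beta).max() > _SEPARATION_LIMIT):
        return None
    member_idx = np.arange(1, 1 + d)
    probs = _standardized_probs(beta, X, member_idx, q)
    if np.any(probs <= 0.0) or np.any(probs >= 1.0):
        return None
    slope = np.polyfit(np.arange(q, dtype=float), np.log(probs), 1)[0]
    return float(np.exp(slope)), beta[member_idx]


def bootstrap_ci(
    cohort: pd.DataFrame,
    outcome: str,
    chemicals: Sequence[str] = CHEMICALS,
    covariates: Sequence[str] | None = DEFAULT_COVARIATES,
    q: int = 4,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    method: str = "percentile",
) -> tuple[tuple[float, float], int, np.ndarray]:
    """Subject-resampling bootstrap for the PR.

    The whole pipeline — quantile scoring, logistic fit, MSM — is refit per
    replicate.  Non-converged replicates are dropped and counted; more than
    20% failures flags the interval unreliable (raised as a warning by the
    caller).  Returns ((low, high), n_failed, pr_samples).

    ``method``: ``"percentile"`` (default) or ``"normal"`` (log-scale normal
    approximation around the median of the bootstrap distribution).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    conc, cov, y, _ = _prepare_arrays(cohort, outcome, chemicals, covariates)
    rng = np.random.default_rng(seed)
    n = len(y)
    prs = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        out = _fit_once(conc[idx], None if cov is None else cov[idx],
                        y[idx], q, len(chemicals))
        if out is None:
            n_failed += 1
        else:
            prs.append(out[0])
    prs = np.asarray(prs)
    if prs.size < 2:
        raise NonConvergenceError(
            f"bootstrap produced {prs.size} converged replicates out of {B}"
        )
    alpha = 1.0 - level
    if method == "percentile":
        lo, hi = np.percentile(prs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    elif method == "normal":
        from scipy import stats as _st
        logs = np.log(prs)
        z = _st.norm.ppf(1 - alpha / 2)
        lo, hi = np.exp(logs.mean() - z * logs.std(ddof=1)), \
            np.exp(logs.mean() + z * logs.std(ddof=1))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return (float(lo), float(hi)), n_failed, prs


def fit_mixture_model(
    cohort: pd.DataFrame,
    outcome: str,
    chemicals: Sequence[str] = CHEMICALS,
    adjusted: bool = True,
    covariates: Sequence[str] | None = None,
    q: int = 4,
    B: int = 1000,
    seed: int = 0,
    ci_method: str = "percentile",
) -> MixtureFit:
    """Run the full pipeline and return a complete :class:`MixtureFit`.

    ``adjusted=True`` uses the study's default adjustment set (child sex,
    birth weight, maternal education, child age, SES) unless ``covariates``
    overrides it; ``adjusted=False`` fits exposures only.  ``B=0`` skips the
    bootstrap (no CI).
    """
    if adjusted:
        covs: Sequence[str] | None = tuple(covariates) if covariates else DEFAULT_COVARIATES
    else:
        covs = None
    conc_df = cohort[list(chemicals)]
    qz = quantize_frame(conc_df, chemicals=chemicals, q=q)
    cov_design = encode_covariates(cohort, covs) if covs else None
    design = build_design(qz.scores, cov_design)
    y = cohort[outcome].to_numpy(dtype=float)
    fit = fit_glm_logistic(design, y)
    if not fit.converged:
        raise NonConvergenceError(
            f"logistic fit for outcome {outcome!r} did not converge"
        )
    pw = psi_and_weights(fit, chemicals)
    curve = msm_pr(fit, design, chemicals, q)
    ci = None
    n_failed = 0
    unreliable = False
    if B:
        ci, n_failed, _ = bootstrap_ci(
            cohort, outcome, chemicals, covs, q=q, B=B, seed=seed,
            method=ci_method,
        )
        unreliable = n_failed > 0.2 * B
        if unreliable:
            warnings.warn(
                f"{n_failed}/{B} bootstrap replicates failed to converge; "
                "CI flagged unreliable",
                UserWarning,
                stacklevel=2,
            )
    return MixtureFit(
        outcome=outcome,
        chemicals=list(chemicals),
        adjusted=bool(covs),
        q=q,
        n=fit.n,
        psi_conditional=pw.psi_conditional,
        psi_marginal=curve.psi_marginal,
        pr=curve.pr,
        pr_ci=ci,
        positive_partial=pw.positive_partial,
        positive_members=pw.positive_members,
        negative_partial=pw.negative_partial,
        negative_members=pw.negative_members,
        weights=pw.weights,
        curve=curve,
        glm=fit,
        B=B,
        seed=seed,
        n_boot_failed=n_failed,
        boot_unreliable=unreliable,
        ci_method=ci_method,
    )


def chemical_specific_fit(
    cohort: pd.DataFrame,
    chemical: str,
    outcome: str,
    adjusted: bool = True,
    covariates: Sequence[str] | None = None,
    q: int = 4,
    B: int = 1000,
    seed: int = 0,
) -> MixtureFit:
    """One chemical at a time, same pipeline (the d=1 mixture)."""
    return fit_mixture_model(
        cohort, outcome, chemicals=[chemical], adjusted=adjusted,
        covariates=covariates, q=q, B=B, seed=seed,
    )


# --------------------------------------------------------------------------
# stepwise covariate selection
# --------------------------------------------------------------------------

@dataclass
class StepRecord:
    step: int
    action: str                 # "add" | "drop" | "stop"
    covariate: str | None
    criterion: float
    retained: list[str]


@dataclass
class SelectionResult:
    retained: list[str]
    criterion: str
    steps: list[StepRecord]

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"step": s.step, "action": s.action, "covariate": s.covariate,
             "criterion": s.criterion, "retained": "+".join(s.retained)}
            for s in self.steps
        ])


def stepwise_select(
    cohort: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str] = DEFAULT_COVARIATES,
    chemicals: Sequence[str] = CHEMICALS,
    criterion: str = "aic",
    penalty: float = 2.0,
    q: int = 4,
) -> SelectionResult:
    """Forward-backward stepwise covariate selection.

    Starting from the exposure-only model, alternately consider adding any
    excluded candidate and dropping any retained one; take the single move
    that most improves the criterion, stop when none improves it.  Candidates
    are covariate *groups* (a categorical enters or leaves with all its
    dummies).  Criterion: ``"aic"`` (deviance + 2k) or ``"deviance"`` with a
    stated per-parameter ``penalty``.  Ties resolve by candidate order.
    """
    if criterion not in ("aic", "deviance"):
        raise ValueError("criterion must be 'aic' or 'deviance'")
    if not candidates:
        raise ValueError("need at least one candidate covariate")
    pen = 2.0 if criterion == "aic" else float(penalty)
    qz = quantize_frame(cohort[list(chemicals)], chemicals=chemicals, q=q)
    y = cohort[outcome].to_numpy(dtype=float)

    def crit(retained: Sequence[str]) -> float:
        cov = encode_covariates(cohort, retained) if retained else None
        design = build_design(qz.scores, cov)
        fit = fit_glm_logistic(design, y)
        if not fit.converged:
            return np.inf
        k = len(fit.design_columns)
        return fit.deviance + pen * k

    retained: list[str] = []
    current = crit(retained)
    steps = [StepRecord(0, "start", None, current, [])]
    step = 0
    while True:
        step += 1
        best_move: tuple[str, str, float] | None = None  # (action, cov, crit)
        for cand in candidates:                      # deterministic order
            if cand in retained:
                trial = [c for c in retained if c != cand]
                action = "drop"
            else:
                trial = retained + [cand]
                action = "add"
            c = crit(trial)
            if c < current - 1e-9 and (best_move is None or c < best_move[2] - 1e-9):
                best_move = (action, cand, c)
        if best_move is None:
            steps.append(StepRecord(step, "stop", None, current, list(retained)))
            break
        action, cand, current = best_move
        if action == "add":
            retained.append(cand)
        else:
            retained.remove(cand)
        steps.append(StepRecord(step, action, cand, current, list(retained)))
    return SelectionResult(retained=retained, criterion=criterion, steps=steps)


# --------------------------------------------------------------------------
# study-data reproduction (requires the deposited subject-level table)
# --------------------------------------------------------------------------

#: Expected columns of a prepared study table (CSV export of the deposited
#: .sav, or the .sav itself via the optional pyreadstat reader).
STUDY_OUTCOMES = ("imp_global", "imp_social", "imp_language",
                  "imp_gross_motor", "imp_fine_motor")


def reproduce_study_tables(
    path: str,
    B: int = 1000,
    seed: int = 0,
) -> dict[str, dict[str, MixtureFit]]:
    """Re-run the published mixture models on the deposited participant table.

    Expects exposure columns pb/hg/cd/as (µg/L), the covariate columns of the
    default adjustment set, and the five binary impairment outcomes.  Returns
    ``{outcome: {"unadjusted": fit, "adjusted": fit}}`` plus the Pb-specific
    adjusted language fit under ``"pb_language"``.
    """
    from .exposures import load_cohort_csv, load_cohort_sav

    if str(path).endswith(".sav"):
        cohort = load_cohort_sav(path)
    else:
        cohort = load_cohort_csv(path)
    out: dict[str, dict[str, MixtureFit]] = {}
    for outcome in STUDY_OUTCOMES:
        out[outcome] = {
            "unadjusted": fit_mixture_model(
                cohort, outcome, adjusted=False, B=B, seed=seed),
            "adjusted": fit_mixture_model(
                cohort, outcome, adjusted=True, B=B, seed=seed),
        }
    out["pb_language"] = {
        "adjusted": chemical_specific_fit(
            cohort, "pb", "imp_language", adjusted=True, B=B, seed=seed),
    }
    return out
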