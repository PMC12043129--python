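"""Exposure preparation: quantile scoring, reference-value dichotomies and
descriptive percentile summaries.

Biomarker concentrations (blood Pb, Hg, Cd and urinary As, all in µg/L) enter
the mixture model as integer quantile scores ``0..q-1``.  This module owns the
quantization rule (empirical quantiles with linear interpolation; values equal
to a cut point fall in the lower bin), the human-biomonitoring dichotomies
used for descriptive tables, and Table-2-style percentile summaries with an
order-statistic confidence interval for the median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Default mixture members, in reporting order.
CHEMICALS = ("pb", "hg", "cd", "as")

#: Human-biomonitoring (GerES IV) reference values, µg/L.  "Elevated" means
#: concentration >= threshold for every chemical.
GERES_IV_THRESHOLDS: Mapping[str, float] = {
    "pb": 35.0,
    "hg": 0.80,
    "cd": 0.30,
    "as": 15.0,
}


class QuantizationWarning(UserWarning):
    """Raised when quantile bins collapse (too few distinct values)."""


@dataclass(frozen=True)
class ReferenceThresholds:
    """Chemical -> reference value (µg/L); indicator is 1 when value >= threshold."""

    thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(GERES_IV_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        for name, t in self.thresholds.items():
            if not t > 0:
                raise ValueError(f"threshold for {name!r} must be positive, got {t}")

    def __getitem__(self, chemical: str) -> float:
        try:
            return self.thresholds[chemical]
        except KeyError:
            raise KeyError(
                f"no reference threshold for chemical {chemical!r}; "
                f"known: {sorted(self.thresholds)}"
            ) from None


@dataclass
class QuantizedColumn:
    """Quantile scores for one chemical."""

    scores: np.ndarray          # integer scores in 0..q-1
    cut_points: np.ndarray      # q-1 interior cut points, non-decreasing
    q: int
    bin_counts: np.ndarray      # occupancy of each of the q bins
    collapsed: bool = False     # True when distinct values < q


@dataclass
class QuantizedExposures:
    """Quantile scores for the whole mixture, with stored cut points."""

    scores: pd.DataFrame        # one integer column per chemical
    cut_points: dict[str, np.ndarray]
    q: int

    @property
    def chemicals(self) -> list[str]:
        return list(self.scores.columns)


def quantize(values: Sequence[float] | np.ndarray, q: int = 4) -> QuantizedColumn:
    """Score values into ``q`` empirical quantile bins.

    Cut points are the empirical quantiles at probabilities k/q (k = 1..q-1)
    under the linear-interpolation quantile definition (numpy's default).  A
    value exactly equal to a cut point is assigned to the lower bin.  Fewer
    than ``q`` distinct values collapses bins; a :class:`QuantizationWarning`
    is emitted and the result flagged, per-subject scores remain valid.
    """
    values = np.asarray(values, dtype=float)
    if q < 2:
        raise ValueError(f"q must be >= 2, got {q}")
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-d array")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite; handle missing data upstream")

    cuts = np.quantile(values, np.arange(1, q) / q, method="linear")
    # side="left": value == cut point -> lower bin
    scores = np.searchsorted(cuts, values, side="left").astype(np.int64)
    counts = np.bincount(scores, minlength=q)
    collapsed = np.unique(values).size < q
    if collapsed:
        warnings.warn(
            f"fewer than q={q} distinct values; quantile bins collapsed",
            QuantizationWarning,
            stacklevel=2,
        )
    return QuantizedColumn(scores=scores, cut_points=cuts, q=q,
                           bin_counts=counts, collapsed=collapsed)


def quantize_frame(
    concentrations: pd.DataFrame,
    chemicals: Sequence[str] = CHEMICALS,
    q: int = 4,
) -> QuantizedExposures:
    """Quantize each chemical column of a cohort table."""
    missing = [c for c in chemicals if c not in concentrations.columns]
    if missing:
        raise KeyError(f"cohort table lacks exposure columns: {missing}")
    scores = {}
    cuts = {}
    for chem in chemicals:
        col = quantize(concentrations[chem].to_numpy(), q=q)
        scores[chem] = col.scores
        cuts[chem] = col.cut_points
    return QuantizedExposures(
        scores=pd.DataFrame(scores, index=concentrations.index),
        cut_points=cuts,
        q=q,
    )


@dataclass
class DichotomyResult:
    """Reference-value split of one chemical."""

    chemical: str
    threshold: float
    indicator: np.ndarray       # 1 = elevated (>= threshold)
    n_elevated: int
    n_below: int
    pct_elevated: float         # one decimal place
    pct_below: float


def dichotomize(
    values: Sequence[float] | np.ndarray,
    chemical: str,
    thresholds: ReferenceThresholds | None = None,
) -> DichotomyResult:
    """Split concentrations at the biomonitoring reference value.

    Percentages are rounded to one decimal place, matching the descriptive
    table convention; counts are exact.
    """
    thresholds = thresholds or ReferenceThresholds()
    t = thresholds[chemical]
    values = np.asarray(values, dtype=float)
    ind = (values >= t).astype(np.int64)
    n_hi = int(ind.sum())
    n = values.size
    return DichotomyResult(
        chemical=chemical,
        threshold=t,
        indicator=ind,
        n_elevated=n_hi,
        n_below=n - n_hi,
        pct_elevated=round(100.0 * n_hi / n, 1),
        pct_below=round(100.0 * (n - n_hi) / n, 1),
    )


@dataclass
class PercentileSummary:
    """Table-2-style row: P10 / P25 / median (95% CI) / P75 / P95 / max."""

    n: int
    p10: float
    p25: float
    median: float
    median_ci: tuple[float, float] | None
    p75: float
    p95: float
    max: float


def _median_ci_order_statistic(
    sorted_values: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Distribution-free CI for the median from binomial order statistics.

    The interval (x_(l+1), x_(u)) has coverage >= level, where l and u are the
    largest/smallest integers with Binom(n, 1/2) tail mass <= (1-level)/2.
    """
    n = sorted_values.size
    alpha = 1.0 - level
    lo_rank = int(stats.binom.ppf(alpha / 2, n, 0.5))          # l
    hi_rank = int(stats.binom.isf(alpha / 2, n, 0.5)) + 1      # u (1-based)
    lo_rank = max(lo_rank, 0)
    hi_rank = min(hi_rank, n)
    return float(sorted_values[lo_rank]), float(sorted_values[hi_rank - 1])


def summarize_percentiles(values: Sequence[float] | np.ndarray) -> PercentileSummary:
    """Percentiles of one exposure under the linear-interpolation definition.

    The median 95% CI uses the distribution-free order-statistic (binomial)
    method; for n < 2 the CI is omitted with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty vector")
    srt = np.sort(values)
    p10, p25, med, p75, p95 = np.quantile(srt, [0.10, 0.25, 0.50, 0.75, 0.95],
                                          method="linear")
    if values.size < 2:
        warnings.warn("n < 2: median CI omitted", UserWarning, stacklevel=2)
        ci = None
    else:
        ci = _median_ci_order_statistic(srt)
    return PercentileSummary(
        n=values.size, p10=float(p10), p25=float(p25), median=float(med),
        median_ci=ci, p75=float(p75), p95=float(p95), max=float(srt[-1]),
    )


def summarize_exposure_table(
    cohort: pd.DataFrame,
    chemicals: Sequence[str] = CHEMICALS,
    thresholds: ReferenceThresholds | None = None,
) -> pd.DataFrame:
    """Descriptive exposure table: percentiles plus reference-value strata."""
    thresholds = thresholds or ReferenceThresholds()
    rows = []
    for chem in chemicals:
        vals = cohort[chem].to_numpy()
        s = summarize_percentiles(vals)
        d = dichotomize(vals, chem, thresholds)
        rows.append({
            "chemical": chem, "n": s.n,
            "p10": s.p10, "p25": s.p25, "median": s.median,
            "median_ci_low": s.median_ci[0] if s.median_ci else np.nan,
            "median_ci_high": s.median_ci[1] if s.median_ci else np.nan,
            "p75": s.p75, "p95": s.p95, "max": s.max,
            "threshold": d.threshold,
            "n_elevated": d.n_elevated, "pct_elevated": d.pct_elevated,
            "n_below": d.n_below, "pct_below": d.pct_below,
        })
    return pd.DataFrame(rows)


def load_cohort_csv(path: str) -> pd.DataFrame:
    """Read a subject-level cohort table from CSV (complete cases only).

    Rows with missing exposure values are dropped and the count logged via a
    warning; the study design has no imputation step.
    """
    df = pd.read_csv(path)
    present = [c for c in CHEMICALS if c in df.columns]
    if present:
        n0 = len(df)
        df = df.dropna(subset=present).reset_index(drop=True)
        if len(df) < n0:
            warnings.warn(
                f"dropped {n0 - len(df)} rows with missing exposures "
                "(complete-case analysis)",
                UserWarning,
                stacklevel=2,
            )
    return df


def load_cohort_sav(path: str) -> pd.DataFrame:
    """Read a cohort table from an SPSS .sav file (requires pyreadstat)."""
    try:
        import pyreadstat
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading .sav files requires the optional dependency pyreadstat "
            "(pip install qgcmix[sav]); alternatively export the table to CSV"
        ) from exc
    df, _meta = pyreadstat.read_sav(path)
    df.columns = [str(c).lower() for c in df.columns]
    return df
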