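"""Household wealth score and three-level socioeconomic-status classification.

The wealth score is the integer sum of household asset indicators (DHS-style
wealth-quintile instrument; the asset list is user-supplied).  The default
partition of scores is ``>9 -> high``, ``6-9 -> moderate``, ``<6 -> low``,
the only non-overlapping reading of the study instrument's published cut
points.  A ``high_at_nine=True`` switch moves 9 into the high category for
users following the alternative ">=9 is high" convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

SES_CATEGORIES = ("low", "moderate", "high")


@dataclass(frozen=True)
class WealthScore:
    assets: tuple[int, ...]
    score: int
    category: str


def classify_ses(score: int, high_at_nine: bool = False) -> str:
    """Map a non-negative wealth score to low / moderate / high.

    Default: score > 9 -> high, 6 <= score <= 9 -> moderate, score < 6 -> low.
    With ``high_at_nine`` the high boundary becomes score >= 9.
    """
    score = int(score)
    if score < 0:
        raise ValueError(f"wealth score must be non-negative, got {score}")
    high_cut = 9 if high_at_nine else 10
    if score >= high_cut:
        return "high"
    if score >= 6:
        return "moderate"
    return "low"


def score_assets(
    indicators: Sequence[int] | np.ndarray, high_at_nine: bool = False
) -> WealthScore:
    """Sum binary asset indicators into a wealth score and classify it."""
    arr = np.asarray(indicators, dtype=int)
    if arr.ndim != 1:
        raise ValueError("asset indicators must be 1-d")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("asset indicators must be binary 0/1")
    total = int(arr.sum())
    return WealthScore(
        assets=tuple(int(a) for a in arr),
        score=total,
        category=classify_ses(total, high_at_nine=high_at_nine),
    )


def classify_ses_column(
    scores: Sequence[int] | np.ndarray | pd.Series, high_at_nine: bool = False
) -> pd.Series:
    """Vectorized SES classification for a cohort column."""
    s = pd.Series(scores)
    return s.map(lambda x: classify_ses(x, high_at_nine=high_at_nine)).rename(
        "ses_category"
    )
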