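"""Rendering of model tables, weight bar-chart data and MSM curve data.

Everything here is a direct re-arrangement of :class:`~qgcmix.qgc.MixtureFit`
fields — no quantity is recomputed at render time.  Tables round the
percent-change column to one decimal; the JSON serialization keeps full
precision and round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qgc import GLMFit, MSMCurve, MixtureFit


def percent_change(pr: float) -> float:
    """(1 - PR)*100 for PR < 1 (percent reduction), (PR - 1)*100 otherwise."""
    return (1.0 - pr) * 100.0 if pr < 1.0 else (pr - 1.0) * 100.0


# --------------------------------------------------------------------------
# model tables
# --------------------------------------------------------------------------

def render_model_table(fits: Sequence[MixtureFit]) -> pd.DataFrame:
    """Tidy model table: one row per term per fit.

    Terms per fit: ``psi1`` (the joint effect, with CI and percent change),
    the directional partial-effect rows (positive / negative, with member
    lists), and one signed weight row per chemical.  All fits must share q.
    """
    qs = {f.q for f in fits}
    if len(qs) > 1:
        raise ValueError(f"cannot tabulate fits with mixed q: {sorted(qs)}")
    rows = []
    for f in fits:
        model = "adjusted" if f.adjusted else "unadjusted"
        ci_lo, ci_hi = (f.pr_ci if f.pr_ci else (np.nan, np.nan))
        rows.append({
            "outcome": f.outcome, "model": model, "term": "psi1",
            "estimate": f.pr, "ci_low": ci_lo, "ci_high": ci_hi,
            "percent_change": round(percent_change(f.pr), 1),
            "members": "+".join(f.chemicals), "direction": "",
        })
        if f.positive_partial is not None:
            rows.append({
                "outcome": f.outcome, "model": model, "term": "partial_positive",
                "estimate": f.positive_partial, "ci_low": np.nan, "ci_high": np.nan,
                "percent_change": np.nan,
                "members": "+".join(f.positive_members), "direction": "+",
            })
        if f.negative_partial is not None:
            rows.append({
                "outcome": f.outcome, "model": model, "term": "partial_negative",
                "estimate": f.negative_partial, "ci_low": np.nan, "ci_high": np.nan,
                "percent_change": np.nan,
                "members": "+".join(f.negative_members), "direction": "-",
            })
        for chem, w in f.weights.items():
            rows.append({
                "outcome": f.outcome, "model": model, "term": f"weight_{chem}",
                "estimate": abs(w), "ci_low": np.nan, "ci_high": np.nan,
                "percent_change": np.nan, "members": chem,
                "direction": "+" if w > 0 else ("-" if w < 0 else "0"),
            })
    return pd.DataFrame(rows)


def export_weight_plot_data(fit: MixtureFit) -> pd.DataFrame:
    """Signed bar data: one row per chemical, magnitude = directional weight.

    Bars with positive sign point right (chemicals pushing risk up); negative
    sign points left.  Magnitudes within each direction sum to 1.
    """
    if not fit.weights:
        return pd.DataFrame(columns=["chemical", "weight", "direction"])
    return pd.DataFrame([
        {"chemical": c, "weight": w,
         "direction": "positive" if w > 0 else ("negative" if w < 0 else "null")}
        for c, w in fit.weights.items()
    ])


def export_msm_curve(fit: MixtureFit) -> pd.DataFrame:
    """Per-level standardized probabilities plus the fitted MSM line."""
    c = fit.curve
    fitted = np.exp(c.intercept + c.psi_marginal * c.levels)
    return pd.DataFrame({
        "level": c.levels.astype(int),
        "standardized_probability": c.probabilities,
        "msm_fit": fitted,
    })


# --------------------------------------------------------------------------
# JSON serialization (lossless round trip)
# --------------------------------------------------------------------------

def mixture_fit_to_dict(fit: MixtureFit) -> dict:
    return {
        "outcome": fit.outcome,
        "chemicals": fit.chemicals,
        "adjusted": fit.adjusted,
        "q": fit.q,
        "n": fit.n,
        "psi_conditional": fit.psi_conditional,
        "psi_marginal": fit.psi_marginal,
        "pr": fit.pr,
        "pr_ci": list(fit.pr_ci) if fit.pr_ci else None,
        "positive_partial": fit.positive_partial,
        "positive_members": fit.positive_members,
        "negative_partial": fit.negative_partial,
        "negative_members": fit.negative_members,
        "weights": fit.weights,
        "curve": {
            "levels": fit.curve.levels.tolist(),
            "probabilities": fit.curve.probabilities.tolist(),
            "psi_marginal": fit.curve.psi_marginal,
            "pr": fit.curve.pr,
            "intercept": fit.curve.intercept,
        },
        "glm": {
            "params": fit.glm.params.to_dict(),
            "bse": fit.glm.bse.to_dict(),
            "deviance": fit.glm.deviance,
            "aic": fit.glm.aic,
            "converged": fit.glm.converged,
            "n": fit.glm.n,
            "dropped_columns": fit.glm.dropped_columns,
            "design_columns": fit.glm.design_columns,
        },
        "B": fit.B,
        "seed": fit.seed,
        "n_boot_failed": fit.n_boot_failed,
        "boot_unreliable": fit.boot_unreliable,
        "ci_method": fit.ci_method,
    }


def mixture_fit_from_dict(d: Mapping) -> MixtureFit:
    curve = MSMCurve(
        levels=np.asarray(d["curve"]["levels"], dtype=float),
        probabilities=np.asarray(d["curve"]["probabilities"], dtype=float),
        psi_marginal=d["curve"]["psi_marginal"],
        pr=d["curve"]["pr"],
        intercept=d["curve"]["intercept"],
    )
    g = d["glm"]
    glm = GLMFit(
        params=pd.Series(g["params"]),
        bse=pd.Series(g["bse"]),
        deviance=g["deviance"],
        aic=g["aic"],
        converged=g["converged"],
        n=g["n"],
        dropped_columns=list(g["dropped_columns"]),
        design_columns=list(g["design_columns"]),
    )
    return MixtureFit(
        outcome=d["outcome"],
        chemicals=list(d["chemicals"]),
        adjusted=d["adjusted"],
        q=d["q"],
        n=d["n"],
        psi_conditional=d["psi_conditional"],
        psi_marginal=d["psi_marginal"],
        pr=d["pr"],
        pr_ci=tuple(d["pr_ci"]) if d["pr_ci"] else None,
        positive_partial=d["positive_partial"],
        positive_members=list(d["positive_members"]),
        negative_partial=d["negative_partial"],
        negative_members=list(d["negative_members"]),
        weights=dict(d["weights"]),
        curve=curve,
        glm=glm,
        B=d["B"],
        seed=d["seed"],
        n_boot_failed=d["n_boot_failed"],
        boot_unreliable=d["boot_unreliable"],
        ci_method=d["ci_method"],
    )


def save_fit(fit: MixtureFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(mixture_fit_to_dict(fit), indent=2))


def load_fit(path: str | Path) -> MixtureFit:
    return mixture_fit_from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# run manifest
# --------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record written next to every emitted artifact set."""

    config_hash: str
    seeds: dict[str, int] = field(default_factory=dict)
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    package_version: str = ""
    timestamp: str = ""

    @classmethod
    def create(
        cls,
        config: Mapping | None = None,
        seeds: Mapping[str, int] | None = None,
        inputs: Sequence[str] = (),
    ) -> "RunManifest":
        from . import __version__

        blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
        return cls(
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            seeds=dict(seeds or {}),
            inputs=[str(p) for p in inputs],
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))
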