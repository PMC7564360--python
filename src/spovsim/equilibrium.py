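"""Frequency-dependence diagnostics for oscillating trajectories.

A polymorphic trajectory that oscillates around a high spillover allele
frequency can be split into TOP generations (p above a threshold, default
0.85) and BOTTOM generations (p below it).  Negative frequency dependence
predicts a fitness reversal between the two phases: when the spillover
allele is close to fixation, the rare MFCL females mate more often (scarce
males find mostly aggressive females, so a docile female is a safe harbor)
and spillover relative fitness drops.

The comparison follows a generation-level GLM: the metric is regressed on
phase (TOP/BOTTOM) plus generation number (temporal trend control) and the
allele frequency p itself (so the phase term captures the discontinuity
beyond the smooth frequency effect), with a likelihood-ratio test for the
phase term and covariate-adjusted ("least-squares") means evaluated at the
grand mean of the covariates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .experiments import GenerationRecord, Trajectory

__all__ = [
    "EquilibriumReport",
    "label_positions",
    "relative_fitness_spillover",
    "mfcl_mating_percentage",
    "compare_positions",
]

TOP = "TOP"
BOTTOM = "BOTTOM"

METRICS = ("mfcl_mating", "spillover_relative_fitness")


def label_positions(trajectory: Trajectory | Sequence[float], threshold: float = 0.85) -> np.ndarray:
    """Label each generation TOP (p > threshold, strictly) or BOTTOM."""
    p = trajectory.p_series if isinstance(trajectory, Trajectory) else np.asarray(trajectory, float)
    if p.size < 2:
        raise ValueError("need at least two generations to label positions")
    return np.where(p > threshold, TOP, BOTTOM)


def relative_fitness_spillover(record: GenerationRecord) -> float:
    """Spillover relative fitness for one generation (see GenerationRecord)."""
    value = record.relative_fitness_spillover
    if math.isnan(value):
        raise ValueError("relative fitness undefined: no surviving females")
    return value


def mfcl_mating_percentage(record: GenerationRecord) -> float:
    """Percent of that generation's MFCL females that mated; NaN if none present."""
    return record.mfcl_mating_pct


@dataclass
class EquilibriumReport:
    """Covariate-adjusted TOP-vs-BOTTOM comparison for one metric."""

    metric: str
    threshold: float
    n_top: int
    n_bottom: int
    adjusted_mean_top: float
    adjusted_se_top: float
    adjusted_mean_bottom: float
    adjusted_se_bottom: float
    lr_statistic: float  # likelihood-ratio statistic for the phase term, ~chi2(1)
    lr_pvalue: float
    position_effect: float  # linear-predictor coefficient of TOP vs BOTTOM
    labels: np.ndarray = field(repr=False)
    degenerate: bool = False  # one phase absent: no comparison possible

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "metric", "threshold", "n_top", "n_bottom",
                "adjusted_mean_top", "adjusted_se_top",
                "adjusted_mean_bottom", "adjusted_se_bottom",
                "lr_statistic", "lr_pvalue", "position_effect", "degenerate",
            )
        }
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _metric_frame(trajectory: Trajectory, metric: str, threshold: float, burn_in: int) -> pd.DataFrame:
    rows = []
    for r in trajectory.records:
        if r.generation < burn_in:
            continue
        row = {"generation": float(r.generation), "p": r.p, "top": float(r.p > threshold)}
        if metric == "mfcl_mating":
            if r.n_females_mfcl == 0:
                continue  # flagged-missing generations: no MFCL females present
            row["successes"] = r.matings_mfcl
            row["trials"] = r.n_females_mfcl
        elif metric == "spillover_relative_fitness":
            if r.n_females_mfcl + r.n_females_spillover == 0:
                continue
            row["y"] = r.relative_fitness_spillover
        else:
            raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
        rows.append(row)
    return pd.DataFrame(rows)


def compare_positions(
    trajectory: Trajectory,
    metric: str = "mfcl_mating",
    threshold: float = 0.85,
    burn_in: int = 0,
) -> EquilibriumReport:
    """Fit the phase-comparison GLM on a trajectory and adjust the means.

    ``metric="mfcl_mating"`` uses a binomial GLM (logit link) on per
    generation mated/unmated MFCL counts, with adjusted means back
    transformed to the percentage scale; ``"spillover_relative_fitness"``
    uses a Gaussian GLM with identity link.  Generations where the metric is
    undefined (no MFCL females) are excluded.  If one phase is absent the
    report is returned with ``degenerate=True`` and NaN statistics rather
    than silently dropping the comparison.
    """
    data = _metric_frame(trajectory, metric, threshold, burn_in)
    labels = label_positions(trajectory, threshold)
    n_top = int((data["top"] == 1.0).sum())
    n_bottom = int((data["top"] == 0.0).sum())

    if n_top == 0 or n_bottom == 0:
        return EquilibriumReport(
            metric=metric, threshold=threshold, n_top=n_top, n_bottom=n_bottom,
            adjusted_mean_top=math.nan, adjusted_se_top=math.nan,
            adjusted_mean_bottom=math.nan, adjusted_se_bottom=math.nan,
            lr_statistic=math.nan, lr_pvalue=math.nan, position_effect=math.nan,
            labels=labels, degenerate=True,
        )

    covariates = ["generation", "p"]
    X_full = sm.add_constant(data[["top"] + covariates], has_constant="add")
    X_null = sm.add_constant(data[covariates], has_constant="add")
    if metric == "mfcl_mating":
        endog = np.column_stack([data["successes"], data["trials"] - data["successes"]])
        family = sm.families.Binomial()
    else:
        endog = data["y"].to_numpy()
        family = sm.families.Gaussian()

    fit_full = sm.GLM(endog, X_full, family=family).fit()
    fit_null = sm.GLM(endog, X_null, family=family).fit()
    lr = 2.0 * (fit_full.llf - fit_null.llf)
    lr = max(lr, 0.0)
    pvalue = float(scipy.stats.chi2.sf(lr, df=1))

    # least-squares means: predict each phase at the grand mean of covariates
    grand = data[covariates].mean()
    pred_rows = pd.DataFrame(
        {
            "const": [1.0, 1.0],
            "top": [1.0, 0.0],
            **{c: [grand[c], grand[c]] for c in covariates},
        }
    )[X_full.columns]
    pred = fit_full.get_prediction(pred_rows).summary_frame()
    mean_top, mean_bottom = pred["mean"].to_numpy()
    se_top, se_bottom = pred["mean_se"].to_numpy()
    if metric == "mfcl_mating":
        # report on the percentage scale the study uses
        mean_top, mean_bottom = 100.0 * mean_top, 100.0 * mean_bottom
        se_top, se_bottom = 100.0 * se_top, 100.0 * se_bottom

    return EquilibriumReport(
        metric=metric,
        threshold=threshold,
        n_top=n_top,
        n_bottom=n_bottom,
        adjusted_mean_top=float(mean_top),
        adjusted_se_top=float(se_top),
        adjusted_mean_bottom=float(mean_bottom),
        adjusted_se_bottom=float(se_bottom),
        lr_statistic=float(lr),
        lr_pvalue=pvalue,
        position_effect=float(fit_full.params["top"]),
        labels=labels,
    )
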