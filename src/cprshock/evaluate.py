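"""Shock-advisory performance evaluation.

Sensitivity Se = TP/(TP+FN) is reported for the shockable class (VF) and
specificity Sp = TN/(TN+FP) for each non-shockable class (NSR, ONR,
ASYS), with two-sided 90% Wilson score intervals. Two stratifications
mirror the two questions the sliding analysis raises:

* by decision time — one observation per period per time, over the grid
  [-15, ..., +10], showing how performance recovers once compressions
  stop;
* by sHOT — all 26 decisions of every period pooled and grouped into the
  12 hands-off bins 0, (0-1], ..., (9-10], >10 s, showing how much
  artefact-free signal the classifier needs.

The AHA rhythm-analysis goals (Se(VF) > 90%, Sp(ASYS) > 95%,
Sp(ONR) > 95%, Sp(NSR) > 99%) are flagged per group; a metric exactly at
the printed goal is treated as passing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from statsmodels.stats.proportion import proportion_confint

from .sliding import SUPPORTED_DURATIONS
from .types import CprShockError, RhythmLabel

__all__ = [
    "SHOT_BINS",
    "AHA_GOALS",
    "ConfusionCounts",
    "se_sp",
    "ci90",
    "bin_shot",
    "performance_vs_time",
    "performance_vs_shot",
    "roc_curve",
    "aha_check",
]

#: Ordered sHOT bin labels; together they partition [0, ∞).
SHOT_BINS = ["0"] + [f"({k}-{k + 1}]" for k in range(10)] + [">10"]

#: Minimum performance goals for AED rhythm analysis, per rhythm class.
AHA_GOALS = {
    RhythmLabel.VF: ("Se", 0.90),
    RhythmLabel.NSR: ("Sp", 0.99),
    RhythmLabel.ONR: ("Sp", 0.95),
    RhythmLabel.ASYS: ("Sp", 0.95),
}


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary shock-decision confusion counts (Sh positive)."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise CprShockError("confusion counts must be non-negative")


def se_sp(counts: ConfusionCounts) -> tuple[float, float]:
    """(Se, Sp) = (TP/(TP+FN), TN/(TN+FP)); NaN where the denominator is 0."""
    se = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else math.nan
    sp = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp > 0 else math.nan
    return se, sp


def ci90(successes: int, n: int) -> tuple[float, float]:
    """Two-sided 90% Wilson score interval for a binomial proportion."""
    if n <= 0 or not 0 <= successes <= n:
        raise CprShockError(f"invalid proportion {successes}/{n}")
    lo, hi = proportion_confint(successes, n, alpha=0.10, method="wilson")
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def bin_shot(value: float, tol: float = 1e-9) -> str:
    """Map an sHOT value (s) to its bin: 0, (0-1], ..., (9-10], >10."""
    if value < -tol:
        raise CprShockError(f"sHOT cannot be negative, got {value}")
    if value <= tol:
        return "0"
    if value > 10 + tol:
        return ">10"
    k = int(math.ceil(value - tol))
    return f"({k - 1}-{k}]"


def _metric_rows(frame: pd.DataFrame, group_col: str, group_values) -> pd.DataFrame:
    """Per (class, group) Se or Sp with Wilson CI; one row per combination."""
    rows = []
    for lab in RhythmLabel:
        sub = frame[frame["label"] == lab.value]
        if sub.empty:
            continue
        metric_name = AHA_GOALS[lab][0]
        correct_decision = "Sh" if lab.shockable else "NSh"
        for gv in group_values:
            grp = sub[sub[group_col] == gv]
            n = len(grp)
            if n == 0:
                rows.append({"label": lab.value, group_col: gv, "n": 0,
                             "metric_name": metric_name, "metric": math.nan,
                             "ci_lo": math.nan, "ci_hi": math.nan})
                continue
            good = int((grp["decision"] == correct_decision).sum())
            lo, hi = ci90(good, n)
            rows.append({"label": lab.value, group_col: gv, "n": n,
                         "metric_name": metric_name, "metric": good / n,
                         "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def performance_vs_time(advices: pd.DataFrame, duration: int) -> pd.DataFrame:
    """Se/Sp (+90% CI) per rhythm class and decision time.

    ``advices`` is the concatenation of per-period sliding predictions
    (columns poi_id, label, decision_time, decision). Every period must
    contribute exactly one decision per time on the grid.
    """
    from .sliding import decision_grid

    grid = decision_grid(duration)
    counts = advices.groupby("poi_id")["decision_time"].nunique()
    if (counts != len(grid)).any():
        bad = counts[counts != len(grid)].index.tolist()[:3]
        raise CprShockError(f"periods with missing decisions: {bad}")
    table = _metric_rows(advices, "decision_time", grid)
    return _attach_aha(table)


def performance_vs_shot(advices: pd.DataFrame, duration: int) -> pd.DataFrame:
    """Se/Sp (+90% CI) per rhythm class and sHOT bin, pooling all decisions.

    All 26 decisions of every period are pooled and stratified by the 12
    sHOT bins; bins unreachable for the given analysis duration (or
    simply unpopulated) are reported with n = 0 and an undefined metric.
    """
    if duration not in SUPPORTED_DURATIONS:
        raise CprShockError(f"unsupported analysis duration {duration}")
    frame = advices.copy()
    frame["shot_bin"] = [bin_shot(v) for v in frame["shot"]]
    table = _metric_rows(frame, "shot_bin", SHOT_BINS)
    table["shot_bin"] = pd.Categorical(table["shot_bin"], categories=SHOT_BINS,
                                       ordered=True)
    return _attach_aha(table.sort_values(["label", "shot_bin"]).reset_index(drop=True))


def roc_curve(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC (trapezoidal) for the validation pSh scores."""
    labels = np.asarray(labels).ravel().astype(int)
    if len(np.unique(labels)) < 2:
        raise CprShockError("ROC analysis needs both classes present")
    fpr, tpr, thr = skmetrics.roc_curve(labels, np.asarray(scores, dtype=float).ravel())
    auc = float(skmetrics.auc(fpr, tpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


def aha_check(label: RhythmLabel | str, metric: float) -> bool:
    """True iff the class metric meets its AHA goal (boundary passes).

    Goals: Se(VF) ≥ 90%, Sp(ASYS) ≥ 95%, Sp(ONR) ≥ 95%, Sp(NSR) ≥ 99%.
    ``metric`` is a fraction in [0, 1]; NaN raises (undefined metrics
    carry no flag).
    """
    lab = RhythmLabel(label)
    if math.isnan(metric):
        raise CprShockError("cannot apply an AHA goal to an undefined metric")
    return metric >= AHA_GOALS[lab][1] - 1e-12


def _attach_aha(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["aha_pass"] = [
        aha_check(lab, m) if not math.isnan(m) else None
        for lab, m in zip(table["label"], table["metric"])
    ]
    return table
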