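"""Confusion-matrix evaluation for four-tier usage prediction.

Beyond standard multiclass accuracy and one-vs-rest AUROC, this module
implements program metrics designed for population-health planning.  With
tier 0 meaning "no usage", actual users (tiers 1-3) partition into

* **correct** — predicted into their true tier,
* **under** — predicted into a lower usage tier (but not tier 0),
* **over** — predicted into a higher tier,
* **missed** — predicted into tier 0 (no intervention offered),

with **identified = correct + under + over** (the complement of missed), all
as percentages of actual users.  Actual non-users (tier 0) predicted into any
usage tier are **unnecessary** predictions, as a percentage of non-users.
These identities close to 100 on every matrix and are enforced by the tests.

Accuracy CIs are exact binomial (Clopper-Pearson); AUROC CIs use the DeLong
covariance for each one-vs-rest task, macro-averaged over tiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, EmptyInputError, ShapeError, UndefinedMetricError

__all__ = [
    "ConfusionMatrix4",
    "ProgramMetrics",
    "confusion",
    "program_metrics",
    "accuracy_with_ci",
    "binary_auroc_delong",
    "multiclass_auroc",
    "per_class_metrics",
]


@dataclass(frozen=True)
class ConfusionMatrix4:
    """4x4 confusion counts; rows = actual tier, columns = predicted tier."""

    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.shape != (4, 4):
            raise ShapeError(f"confusion matrix must be 4x4, got {arr.shape}")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            if np.any(np.asarray(arr, dtype=float) % 1 != 0) or np.any(arr < 0):
                raise DomainError("confusion counts must be non-negative integers")
            arr = arr.astype(np.int64)
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, labels=("tier0", "tier1", "tier2", "tier3")) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"actual_{l}" for l in labels],
            columns=[f"predicted_{l}" for l in labels],
        )

    def to_csv(self, path, labels=("tier0", "tier1", "tier2", "tier3")) -> None:
        self.to_frame(labels).to_csv(path)


@dataclass(frozen=True)
class ProgramMetrics:
    """Program metrics in percent (see module docstring for definitions)."""

    correct_pct: float
    under_pct: float
    over_pct: float
    missed_pct: float
    identified_pct: float
    unnecessary_pct: float

    def rounded(self, ndigits: int = 1) -> "ProgramMetrics":
        """Rounded copy for reporting (1 decimal place by convention)."""
        return ProgramMetrics(*(round(v, ndigits) for v in self.astuple()))

    def astuple(self):
        return (
            self.correct_pct,
            self.under_pct,
            self.over_pct,
            self.missed_pct,
            self.identified_pct,
            self.unnecessary_pct,
        )

    def to_dict(self) -> dict:
        return {
            "correct_pct": self.correct_pct,
            "under_pct": self.under_pct,
            "over_pct": self.over_pct,
            "missed_pct": self.missed_pct,
            "identified_pct": self.identified_pct,
            "unnecessary_pct": self.unnecessary_pct,
        }


def confusion(actual_tiers, predicted_tiers) -> ConfusionMatrix4:
    """Count (actual, predicted) tier pairs into a 4x4 matrix."""
    a = np.asarray(actual_tiers)
    p = np.asarray(predicted_tiers)
    if a.shape != p.shape:
        raise ShapeError(f"label sequences disagree in length: {a.shape} vs {p.shape}")
    if a.size == 0:
        return ConfusionMatrix4(np.zeros((4, 4), dtype=np.int64))
    for name, arr in (("actual", a), ("predicted", p)):
        if np.any((arr < 0) | (arr > 3)) or np.any(np.asarray(arr, dtype=float) % 1 != 0):
            raise DomainError(f"{name} tiers must be integers in {{0,1,2,3}}")
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (a.astype(int), p.astype(int)), 1)
    return ConfusionMatrix4(counts)


def program_metrics(cm: ConfusionMatrix4) -> ProgramMetrics:
    """Program metrics from a 4x4 confusion matrix.

    Requires at least one actual user (rows 1-3) and one actual non-user
    (row 0); the respective percentages are undefined otherwise.
    """
    c = cm.counts
    users = int(c[1:, :].sum())
    nonusers = int(c[0, :].sum())
    if users == 0:
        raise UndefinedMetricError("no actual users; user metrics undefined")
    if nonusers == 0:
        raise UndefinedMetricError("no actual non-users; unnecessary-prediction metric undefined")

    correct = int(np.trace(c)) - int(c[0, 0])
    under = sum(int(c[i, j]) for i in range(2, 4) for j in range(1, i))
    over = sum(int(c[i, j]) for i in range(1, 4) for j in range(i + 1, 4))
    missed = int(c[1:, 0].sum())
    identified = users - missed
    unnecessary = int(c[0, 1:].sum())

    f = 100.0 / users
    return ProgramMetrics(
        correct_pct=correct * f,
        under_pct=under * f,
        over_pct=over * f,
        missed_pct=missed * f,
        identified_pct=identified * f,
        unnecessary_pct=100.0 * unnecessary / nonusers,
    )


def accuracy_with_ci(cm: ConfusionMatrix4, level: float = 0.95):
    """Overall accuracy with an exact binomial (Clopper-Pearson) CI."""
    n = cm.total
    if n == 0:
        raise EmptyInputError("empty confusion matrix")
    k = int(np.trace(cm.counts))
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return k / n, lo, hi


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks of ties), 1-based."""
    return stats.rankdata(x, method="average")


def binary_auroc_delong(scores, labels):
    """Binary AUROC with its DeLong variance.

    Returns ``(auc, variance)``; the AUROC equals the Mann-Whitney U statistic
    normalized by the number of (positive, negative) pairs, and the variance
    is the DeLong structural-components estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise UndefinedMetricError("AUROC requires at least one positive and one negative")
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n          # structural components of positives
    v10 = 1.0 - (tz[m:] - ty) / m    # structural components of negatives
    var01 = np.var(v01, ddof=1) if m > 1 else 0.0
    var10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return float(auc), float(var01 / m + var10 / n)


def multiclass_auroc(tier_scores, actual_tiers, level: float = 0.95):
    """Macro one-vs-rest multiclass AUROC with a DeLong-based CI.

    ``tier_scores`` has one column per tier.  Each tier with both positives
    and negatives contributes a one-vs-rest AUROC and DeLong variance; tiers
    lacking either are dropped from the average with a warning.  The macro
    AUROC is the unweighted mean; its variance averages the per-tier DeLong
    variances (variance of the mean under tier independence).
    """
    scores = np.asarray(tier_scores, dtype=float)
    actual = np.asarray(actual_tiers).astype(int)
    if scores.ndim != 2:
        raise ShapeError("tier_scores must be 2-D (records x tiers)")
    if scores.shape[0] != actual.shape[0]:
        raise ShapeError("tier_scores and actual_tiers disagree in length")
    if np.unique(actual).size < 2:
        raise UndefinedMetricError("at least 2 tiers must be present")

    aucs, variances = [], []
    for t in range(scores.shape[1]):
        y = (actual == t).astype(int)
        if y.sum() == 0 or y.sum() == y.size:
            warnings.warn(f"tier {t} has no positives or no negatives; dropped from macro AUROC")
            continue
        auc, var = binary_auroc_delong(scores[:, t], y)
        aucs.append(auc)
        variances.append(var)
    k = len(aucs)
    macro = float(np.mean(aucs))
    var_macro = float(np.sum(variances) / k**2)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var_macro)
    return macro, max(0.0, macro - half), min(1.0, macro + half)


def per_class_metrics(cm: ConfusionMatrix4) -> pd.DataFrame:
    """One-vs-rest diagnostics per tier.

    Collapses each tier against the rest into a 2x2 table and reports
    sensitivity, specificity, PPV, NPV and balanced accuracy; ratios with a
    zero denominator are NaN (explicit not-available markers, never silent
    zeros).
    """
    c = cm.counts
    if c.sum() == 0:
        raise EmptyInputError("empty confusion matrix")
    rows = []
    for t in range(4):
        tp = int(c[t, t])
        fn = int(c[t, :].sum()) - tp
        fp = int(c[:, t].sum()) - tp
        tn = int(c.sum()) - tp - fn - fp

        def ratio(num, den):
            return num / den if den > 0 else np.nan

        sens = ratio(tp, tp + fn)
        spec = ratio(tn, tn + fp)
        rows.append(
            {
                "tier": t,
                "sensitivity": sens,
                "specificity": spec,
                "ppv": ratio(tp, tp + fp),
                "npv": ratio(tn, tn + fn),
                "balanced_accuracy": (sens + spec) / 2.0,
            }
        )
    return pd.DataFrame(rows).set_index("tier")
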