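"""Empirical ROC analysis: curve, AUC, DeLong/Hanley–McNeil inference,
and optimal-cutoff selection.

Conventions
-----------
* A subject is test-positive when score >= threshold, and higher scores
  are taken to indicate the positive class ("higher_is_positive"). No
  automatic direction flip is applied: a score negatively associated with
  the outcome is reported with AUC < 0.5 as-is. Pass
  ``direction="lower_is_positive"`` to invert explicitly.
* Candidate thresholds are the midpoints between consecutive distinct
  sorted scores, with -inf/+inf sentinels closing the curve at (1,1) and
  (0,0). The trapezoidal area over this curve equals the Mann-Whitney
  U-statistic probability (ties counted 1/2) exactly.
* The optimal cutoff maximises Youden's J = sensitivity + specificity - 1
  over the finite midpoint grid (or minimises distance to the (0,1)
  corner with ``criterion="closest_to_01"``); ties break toward the
  smallest cutoff, i.e. maximal sensitivity.

AUC standard errors: DeLong's nonparametric estimator (default) or the
Hanley–McNeil exponential approximation; both yield normal-theory 95%
CIs truncated to [0,1] and a two-sided z test of AUC = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RocCurve",
    "AucSummary",
    "CutoffResult",
    "roc_curve",
    "auc_trapezoid",
    "mann_whitney_auc",
    "auc_inference",
    "optimal_cutoff",
]


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve over descending candidate thresholds."""

    thresholds: np.ndarray  # descending, +inf first, -inf last
    sens: np.ndarray  # sensitivity at each threshold
    fpr: np.ndarray  # 1 - specificity at each threshold
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy (threshold, sens, fpr) table for export/plotting."""
        return pd.DataFrame(
            {"threshold": self.thresholds, "sens": self.sens, "fpr": self.fpr}
        )


@dataclass(frozen=True)
class AucSummary:
    auc: float
    se: float
    ci_lower: float
    ci_upper: float
    p_vs_half: float
    n_pos: int
    n_neg: int
    method: str


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    one_minus_specificity: float
    youden_j: float


def _validate(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return scores, labels, n_pos, n_neg


def roc_curve(scores, labels, direction: str = "higher_is_positive") -> RocCurve:
    """Empirical ROC curve; test-positive means score >= threshold."""
    if direction not in ("higher_is_positive", "lower_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    scores, labels, n_pos, n_neg = _validate(scores, labels)
    if direction == "lower_is_positive":
        scores = -scores

    distinct = np.unique(scores)  # ascending
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))

    pos_sorted = np.sort(scores[labels])
    neg_sorted = np.sort(scores[~labels])
    # score >= t  <=>  count of scores < t is to the left of searchsorted
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / n_pos
    fpr = 1.0 - np.searchsorted(neg_sorted, thresholds, side="left") / n_neg

    if direction == "lower_is_positive":
        thresholds = -thresholds
    return RocCurve(thresholds=thresholds, sens=sens, fpr=fpr, n_pos=n_pos, n_neg=n_neg)


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area under the empirical curve.

    Equals the Mann-Whitney probability P(score_pos > score_neg) +
    0.5 * P(tie) to floating-point accuracy.
    """
    return float(np.trapezoid(curve.sens, curve.fpr))


def mann_whitney_auc(scores, labels) -> float:
    """Rank-based AUC (ties 1/2), the Mann-Whitney route.

    Independent of the curve construction; used as the consistency anchor
    for :func:`auc_trapezoid`.
    """
    scores, labels, n_pos, n_neg = _validate(scores, labels)
    ranks = sps.rankdata(scores)  # midranks
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _delong_se(scores, labels):
    """DeLong variance via midrank placements (Sun & Xu formulation)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    tz = sps.rankdata(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # placement of each positive among negatives
    v10 = 1.0 - (tz[m:] - ty) / m  # placement of each negative among positives
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(np.sqrt(s01 / m + s10 / n))


def auc_inference(scores, labels, method: str = "delong") -> AucSummary:
    """AUC with SE, 95% CI and a two-sided test of AUC = 0.5.

    ``method="delong"`` (default) or ``"hanley_mcneil"``.
    """
    if method not in ("delong", "hanley_mcneil"):
        raise ValueError(f"unknown method {method!r}")
    scores, labels, n_pos, n_neg = _validate(scores, labels)
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 subjects per class for a standard error")
    if method == "delong":
        auc, se = _delong_se(scores, labels)
    else:
        auc = mann_whitney_auc(scores, labels)
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc**2 / (1.0 + auc)
        var = (
            auc * (1 - auc)
            + (n_pos - 1) * (q1 - auc**2)
            + (n_neg - 1) * (q2 - auc**2)
        ) / (n_pos * n_neg)
        se = float(np.sqrt(max(var, 0.0)))
    z = sps.norm.ppf(0.975)
    if se > 0:
        p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return AucSummary(
        auc=auc,
        se=se,
        ci_lower=float(max(0.0, auc - z * se)),
        ci_upper=float(min(1.0, auc + z * se)),
        p_vs_half=p,
        n_pos=n_pos,
        n_neg=n_neg,
        method=method,
    )


def optimal_cutoff(
    scores,
    labels,
    criterion: str = "youden",
    direction: str = "higher_is_positive",
) -> CutoffResult:
    """Optimal operating point over the finite midpoint threshold grid.

    ``criterion="youden"`` maximises J = sens - fpr; ``"closest_to_01"``
    minimises Euclidean distance to the ideal (fpr=0, sens=1) corner.
    Ties break toward the smallest cutoff (maximal sensitivity).

    Candidates are the curve's full threshold grid, sentinels included:
    for a score anti-associated with the outcome the best achievable J
    can be 0, attained only by the degenerate classify-everyone
    thresholds, and that is reported honestly (cutoff -inf, sens 1).
    """
    if criterion not in ("youden", "closest_to_01"):
        raise ValueError(f"unknown criterion {criterion!r}")
    curve = roc_curve(scores, labels, direction=direction)
    thr = curve.thresholds
    sens = curve.sens
    fpr = curve.fpr
    if criterion == "youden":
        objective = sens - fpr  # maximise
    else:
        objective = -np.sqrt(fpr**2 + (1.0 - sens) ** 2)
    best = objective.max()
    idx = np.flatnonzero(objective == best)
    pick = idx[np.argmin(thr[idx])]
    return CutoffResult(
        cutoff=float(thr[pick]),
        sensitivity=float(sens[pick]),
        one_minus_specificity=float(fpr[pick]),
        youden_j=float(sens[pick] - fpr[pick]),
    )
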