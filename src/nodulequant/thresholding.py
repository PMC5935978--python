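"""ROC-based derivation of the GGOc and Sc Hounsfield-unit thresholds.

The GGOc threshold separates pure ground-glass nodules (low HU, the positive
class) from everything else; the Sc threshold separates solid nodules (high
HU) from everything else. Each cutoff is the Youden-optimal operating point of
the ROC over a per-tumor predictor (the tumor mean CT value by default, or
pooled per-voxel HU). Cutoffs are reported as midpoints between adjacent
observed predictor values, which is why HU cutoffs are typically
half-integral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ROCCurve", "ThresholdResult", "roc_curve", "youden_cutoff",
           "derive_component_thresholds"]


@dataclass(frozen=True)
class ROCCurve:
    """ROC over all distinct cutpoints of a scalar predictor.

    ``direction`` is "low" when low predictor values indicate the positive
    class. ``cutpoints`` are midpoints between adjacent distinct observed
    values, flanked by sentinels below/above the observed range; sensitivity
    and specificity are evaluated at each cutpoint. The AUC is the
    Mann-Whitney pair statistic (ties counted 1/2).
    """

    cutpoints: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ThresholdResult:
    """A component HU cutoff with its ROC summary statistics."""

    cutoff: float
    auc: float
    sensitivity: float
    specificity: float
    direction: str
    n_pos: int
    n_neg: int


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the fraction of (pos, neg) pairs ranked concordantly, ties 1/2."""
    from scipy.stats import rankdata

    combined = np.concatenate([pos, neg])
    ranks = rankdata(combined)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_curve(
    values: np.ndarray,
    labels: np.ndarray,
    direction: str = "high",
) -> ROCCurve:
    """ROC curve of a scalar predictor against binary labels.

    ``direction="high"`` calls a case positive when the predictor is at or
    above a cutpoint; ``"low"`` when at or below. A constant predictor yields
    AUC 0.5 with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if values.shape != labels.shape:
        raise ValueError("values and labels must be the same length")
    if direction not in ("high", "low"):
        raise ValueError(f"direction must be 'high' or 'low', got {direction!r}")
    pos = values[labels == 1]
    neg = values[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")

    score = values if direction == "high" else -values
    auc = _mann_whitney_auc(score[labels == 1], score[labels == 0])
    if np.ptp(values) == 0:
        warnings.warn("constant predictor: ROC is uninformative (AUC 0.5)",
                      stacklevel=2)

    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    span = max(np.ptp(distinct), 1.0)
    cutpoints = np.concatenate(
        [[distinct[0] - span], mids, [distinct[-1] + span]]
    )
    if direction == "high":
        sens = np.array([(pos >= c).mean() for c in cutpoints])
        spec = np.array([(neg < c).mean() for c in cutpoints])
    else:
        sens = np.array([(pos <= c).mean() for c in cutpoints])
        spec = np.array([(neg > c).mean() for c in cutpoints])
    return ROCCurve(
        cutpoints=cutpoints,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        direction=direction,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def youden_cutoff(roc: ROCCurve) -> ThresholdResult:
    """Operating point maximizing the Youden index J = sens + spec - 1.

    Among cutpoints tied on J the one with higher specificity wins (and the
    first such on a residual tie). The returned cutoff is a midpoint between
    two adjacent observed values, hence typically half-integral on integer HU.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best_j = j.max()
    tied = np.flatnonzero(np.isclose(j, best_j))
    winner = tied[np.argmax(roc.specificity[tied])]
    return ThresholdResult(
        cutoff=float(roc.cutpoints[winner]),
        auc=roc.auc,
        sensitivity=float(roc.sensitivity[winner]),
        specificity=float(roc.specificity[winner]),
        direction=roc.direction,
        n_pos=roc.n_pos,
        n_neg=roc.n_neg,
    )


def derive_component_thresholds(
    cohort: pd.DataFrame,
    predictor: str = "mean_hu",
) -> tuple[ThresholdResult, ThresholdResult]:
    """GGOc and Sc HU thresholds from an appearance-labeled cohort.

    The GGOc threshold is the Youden cutoff of ``predictor`` with pGGO as the
    positive class (low HU positive) against part-solid and solid nodules; the
    Sc threshold takes solid nodules as positive (high HU positive) against
    the rest. ``cohort`` needs columns ``appearance`` (pGGO/PSN/SN) and the
    predictor; all three classes must be present.

    Returns ``(t_ggo, t_sc)``.
    """
    present = set(cohort["appearance"].unique())
    missing = {"pGGO", "PSN", "SN"} - present
    if missing:
        raise ValueError(f"appearance classes missing from cohort: {sorted(missing)}")
    values = cohort[predictor].to_numpy(dtype=float)

    ggo_labels = (cohort["appearance"] == "pGGO").to_numpy().astype(int)
    t_ggo = youden_cutoff(roc_curve(values, ggo_labels, direction="low"))

    sn_labels = (cohort["appearance"] == "SN").to_numpy().astype(int)
    t_sc = youden_cutoff(roc_curve(values, sn_labels, direction="high"))
    return t_ggo, t_sc
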