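"""ROC curve, AUC and Youden-index optimal cutoff from first principles.

One behavioral measure at a time discriminates stressed (CUMS, positive)
from control (Ctrl, negative) animals. Measures are first *oriented* so that
larger values mean "more depressive" — sucrose preference and open-arm time
are negated, immobility time passes through — after which a single ROC
convention applies: an animal is called positive when its oriented value is
``>= threshold``.

Thresholds are the unique observed values (plus a +inf sentinel), so the
reported cutoff is always an attained data value. The AUC is computed two
ways — the trapezoidal integral of the ROC polygon, and the Mann-Whitney
concordance probability P(score_pos > score_neg) + 1/2 P(tie) — and the two
are asserted equal; ties between classes receive half credit in both.

The optimal cutoff maximizes the Youden index J = TPR - FPR = sensitivity +
specificity - 1 over all thresholds. Ties in J are broken in favor of higher
sensitivity (a screening context favors catching susceptible animals), then
lower oriented threshold; the result is deterministic and identical to an
exhaustive scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import rankdata

from .cohort import MeasureSpec
from .errors import SingleClassError

Orientation = Literal["identity", "flipped"]


@dataclass(frozen=True)
class OrientedScores:
    """Scores oriented so larger = more depressive, with binary labels
    (True/1 = CUMS, False/0 = Ctrl)."""

    values: np.ndarray
    labels: np.ndarray
    orientation: Orientation

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=bool))
        if self.values.shape != self.labels.shape:
            raise ValueError("values and labels must have equal length")
        if np.isnan(self.values).any():
            i = int(np.where(np.isnan(self.values))[0][0])
            raise ValueError(f"NaN score at record index {i}")
        if self.labels.all() or not self.labels.any():
            raise SingleClassError(
                "ROC needs at least one positive (CUMS) and one negative (Ctrl) label"
            )

    def unorient(self, oriented_value: float) -> float:
        """Map a value on the oriented scale back to the original scale."""
        return -oriented_value if self.orientation == "flipped" else oriented_value


@dataclass(frozen=True)
class RocCurve:
    """ROC sweep: descending thresholds (rule: oriented value >= threshold
    => predicted positive) with aligned FPR/TPR and the trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class CutoffCriterion:
    """Youden-optimal cutoff of one measure, reported on the original scale
    together with its operating characteristics."""

    measure: str
    direction: Literal["low", "high"]
    cutoff_original_scale: float
    sensitivity: float
    specificity: float
    youden_j: float
    auc: float

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "direction": self.direction,
            "cutoff": self.cutoff_original_scale,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden_j": self.youden_j,
            "auc": self.auc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutoffCriterion":
        return cls(
            measure=d["measure"],
            direction=d["direction"],
            cutoff_original_scale=float(d["cutoff"]),
            sensitivity=float(d["sensitivity"]),
            specificity=float(d["specificity"]),
            youden_j=float(d["youden_j"]),
            auc=float(d["auc"]),
        )


def orient(values, spec: MeasureSpec, labels) -> OrientedScores:
    """Orient raw measure values so that larger = more depressive.

    direction "high" (immobility): identity. direction "low" (sucrose
    preference, open-arm time): negate. Applying :meth:`OrientedScores.
    unorient` to an oriented value restores the original scale.
    """
    values = np.asarray(values, dtype=float)
    if spec.direction == "low":
        return OrientedScores(-values, labels, "flipped")
    return OrientedScores(values, labels, "identity")


def _sweep(scores: OrientedScores) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thresholds (desc, +inf sentinel first) and aligned FPR/TPR."""
    thresholds = np.concatenate(
        ([np.inf], np.unique(scores.values)[::-1])
    )
    pos = scores.values[scores.labels]
    neg = scores.values[~scores.labels]
    tpr = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= thresholds[:, None]).mean(axis=1)
    return thresholds, fpr, tpr


def mann_whitney_auc(scores: OrientedScores) -> float:
    """AUC as the concordance probability P(pos > neg) + 1/2 P(pos = neg),
    via midranks (the Mann-Whitney U identity)."""
    ranks = rankdata(scores.values)  # midranks share credit at ties
    n_pos = int(scores.labels.sum())
    n_neg = scores.labels.size - n_pos
    u = ranks[scores.labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores: OrientedScores) -> RocCurve:
    """Full ROC sweep with trapezoidal AUC.

    The trapezoidal AUC is cross-checked against the Mann-Whitney
    concordance AUC (they are mathematically identical on this threshold
    grid); a mismatch raises, which would indicate an implementation bug.
    """
    thresholds, fpr, tpr = _sweep(scores)
    auc = float(np.trapezoid(tpr, fpr))
    auc_mw = mann_whitney_auc(scores)
    if not np.isclose(auc, auc_mw, rtol=0, atol=1e-12):
        raise AssertionError(
            f"trapezoidal AUC {auc!r} != Mann-Whitney AUC {auc_mw!r}"
        )
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def youden_optimal(
    roc: RocCurve, scores: OrientedScores, spec: MeasureSpec
) -> CutoffCriterion:
    """Youden-optimal cutoff: argmax of J = TPR - FPR over all observed
    thresholds, ties broken by higher sensitivity then lower oriented
    threshold; the cutoff is reported back on the measure's original scale.
    """
    j = roc.tpr - roc.fpr
    # lexicographic: maximize (J, sensitivity, -threshold); the sweep is in
    # descending threshold order so later indices have lower thresholds
    best = 0
    for i in range(1, len(roc.thresholds)):
        key = (j[i], roc.tpr[i], -roc.thresholds[i])
        if key > (j[best], roc.tpr[best], -roc.thresholds[best]):
            best = i
    threshold = roc.thresholds[best]
    if not np.isfinite(threshold):
        # J = 0 everywhere and only the sentinel attains the max; report the
        # highest observed value (predicting nothing positive) explicitly
        threshold = float(np.max(scores.values))
    return CutoffCriterion(
        measure=spec.name,
        direction=spec.direction,
        cutoff_original_scale=scores.unorient(float(threshold)),
        sensitivity=float(roc.tpr[best]),
        specificity=float(1.0 - roc.fpr[best]),
        youden_j=float(j[best]),
        auc=roc.auc,
    )


def derive_criterion(values, spec: MeasureSpec, labels) -> CutoffCriterion:
    """Convenience: orient, sweep, and pick the Youden-optimal cutoff."""
    scores = orient(values, spec, labels)
    return youden_optimal(roc_curve(scores), scores, spec)


def bootstrap_ci(
    scores: OrientedScores,
    statistic: Literal["auc", "cutoff", "youden_j"],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
    spec: MeasureSpec | None = None,
) -> tuple[float, float]:
    """Stratified bootstrap percentile interval for an ROC statistic.

    Resampling is within label classes (so both classes are always present),
    the interval is the ``(1-level)/2`` and ``1-(1-level)/2`` percentiles of
    the bootstrap distribution, and the draw is deterministic given ``seed``.
    ``spec`` is required for the ``cutoff`` statistic (to report it on the
    original scale).
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if statistic not in ("auc", "cutoff", "youden_j"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "cutoff" and spec is None:
        raise ValueError("spec is required for the 'cutoff' statistic")
    rng = np.random.default_rng(seed)
    pos = scores.values[scores.labels]
    neg = scores.values[~scores.labels]
    stats_out = np.empty(n_boot)
    if spec is None:
        spec = MeasureSpec("score", "", -np.inf, np.inf, "high")
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        bs = OrientedScores(
            np.concatenate([bp, bn]),
            np.concatenate([np.ones(bp.size, bool), np.zeros(bn.size, bool)]),
            scores.orientation,
        )
        if statistic == "auc":
            stats_out[b] = mann_whitney_auc(bs)
        else:
            crit = youden_optimal(roc_curve(bs), bs, spec)
            stats_out[b] = (
                crit.cutoff_original_scale if statistic == "cutoff" else crit.youden_j
            )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats_out, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
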