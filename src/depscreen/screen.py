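"""Composite depression scoring and subgroup assignment.

Each animal is flagged positive or negative on each behavioral criterion by
comparing its raw value with the Youden-optimal cutoff (equality counts as
positive, matching the ">= threshold" ROC convention after un-orienting):
direction "low" measures flag at ``value <= cutoff``, direction "high"
measures at ``value >= cutoff``. The depression score (D-score) is the count
of positive flags, 0-3 for the three standard criteria.

Subgroups follow the screen's published definitions: CUMS animals with
D-score 3 are depressive (Dep), with D-score 0 or 1 non-depressive (noDep),
and with D-score 2 excluded; control animals are retained as Ctrl only at
D-score 0 and excluded otherwise. Exclusions are always reported, never
silent.

:class:`DepressionScreen` packages the whole procedure as a scikit-learn
estimator: ``fit(X, y)`` derives the per-measure cutoffs from a labeled
cohort, ``transform`` returns per-criterion flags plus the D-score, and
``predict`` returns the D-score. Frozen criteria can be applied to a second
cohort, which is how recovery of the latent susceptibility label is scored
on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import DEFAULT_MEASURES, Cohort, MeasureSpec
from .errors import MissingLatentError, MissingMeasureError, UnknownGroupError
from .roc import CutoffCriterion, derive_criterion

SUBGROUPS = ("Dep", "noDep", "Ctrl", "excluded")


@dataclass(frozen=True)
class DScoreRecord:
    """Per-animal criterion flags and their sum (the D-score)."""

    mouse_id: str
    flags: Mapping[str, bool]
    dscore: int


@dataclass(frozen=True)
class SubgroupAssignment:
    mouse_id: str
    subgroup: str


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well the screen's Dep label recovers the generator's latent
    susceptibility tag among CUMS animals. Sensitivity is None when the
    cohort contains no susceptible animals (undefined, not zero)."""

    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None
    tp: int
    fp: int
    tn: int
    fn: int


def _flag(value: float, criterion: CutoffCriterion) -> bool:
    if criterion.direction == "low":
        return value <= criterion.cutoff_original_scale
    return value >= criterion.cutoff_original_scale


def score_animal(
    mouse_id: str,
    measures: Mapping[str, float],
    criteria: Sequence[CutoffCriterion],
) -> DScoreRecord:
    """Flag one animal on every criterion and sum the flags."""
    flags = {}
    for crit in criteria:
        if crit.measure not in measures or not np.isfinite(measures[crit.measure]):
            raise MissingMeasureError(
                f"animal {mouse_id!r} lacks a value for measure {crit.measure!r}"
            )
        flags[crit.measure] = _flag(float(measures[crit.measure]), crit)
    return DScoreRecord(mouse_id=mouse_id, flags=flags, dscore=sum(flags.values()))


def score_cohort(
    cohort: Cohort, criteria: Sequence[CutoffCriterion]
) -> list[DScoreRecord]:
    return [
        score_animal(rec.mouse_id, rec.measures, criteria)
        for rec in cohort.records()
    ]


def assign_subgroup(group: str, dscore: int) -> str:
    """Map one (group, D-score) pair to its subgroup."""
    if group == "CUMS":
        if dscore == 3:
            return "Dep"
        if dscore in (0, 1):
            return "noDep"
        return "excluded"  # D-score 2
    if group == "Ctrl":
        return "Ctrl" if dscore == 0 else "excluded"
    raise UnknownGroupError(f"unknown group label {group!r}")


def assign_subgroups(
    cohort: Cohort, dscores: Sequence[DScoreRecord]
) -> list[SubgroupAssignment]:
    by_id = {d.mouse_id: d for d in dscores}
    out = []
    for rec in cohort.records():
        if rec.mouse_id not in by_id:
            raise MissingMeasureError(f"no D-score record for animal {rec.mouse_id!r}")
        out.append(
            SubgroupAssignment(
                rec.mouse_id, assign_subgroup(rec.group, by_id[rec.mouse_id].dscore)
            )
        )
    return out


def summarize(
    assignments: Sequence[SubgroupAssignment],
    dscores: Sequence[DScoreRecord],
    cohort: Cohort,
) -> dict:
    """Per-group D-score histogram with proportions, plus subgroup counts.

    Proportions are within-group and rounded to 0.1%.
    """
    sub_by_id = {a.mouse_id: a.subgroup for a in assignments}
    d_by_id = {d.mouse_id: d.dscore for d in dscores}
    df = cohort.data.assign(
        dscore=[d_by_id[m] for m in cohort.data["mouse_id"]],
        subgroup=[sub_by_id[m] for m in cohort.data["mouse_id"]],
    )
    if not (df["group"] == "CUMS").any():
        raise ValueError("cannot summarize: cohort contains no CUMS animals")
    summary: dict = {"groups": {}, "subgroup_counts": {}}
    max_score = max(
        [3]
        + [len(dd.flags) for dd in dscores if dd.flags]
        + [dd.dscore for dd in dscores]
    )
    for group, sub in df.groupby("group"):
        counts = {
            s: int((sub["dscore"] == s).sum()) for s in range(max_score + 1)
        }
        n = len(sub)
        summary["groups"][group] = {
            "n": n,
            "dscore_counts": counts,
            "dscore_pct": {s: round(100.0 * c / n, 1) for s, c in counts.items()},
        }
    for sg in SUBGROUPS:
        summary["subgroup_counts"][sg] = int((df["subgroup"] == sg).sum())
    n_cums = summary["groups"]["CUMS"]["n"]
    summary["dep_pct_of_cums"] = round(
        100.0 * summary["subgroup_counts"]["Dep"] / n_cums, 1
    )
    summary["nodep_pct_of_cums"] = round(
        100.0 * summary["subgroup_counts"]["noDep"] / n_cums, 1
    )
    if "Ctrl" in summary["groups"]:
        summary["ctrl_dscore0_pct"] = summary["groups"]["Ctrl"]["dscore_pct"].get(0, 0.0)
    return summary


def pairwise_correlations(
    cohort: Cohort,
    measures: Sequence[str] | None = None,
    per_group: bool = False,
    holm: bool = False,
) -> pd.DataFrame:
    """Pearson and Spearman correlations for every measure pair.

    Computed on all animals pooled (the cross-measure coherence check), on
    raw un-oriented scales; ``per_group=True`` computes within groups
    instead. Constant columns yield an explicit "undefined" flag rather than
    a silent NaN. ``holm=True`` adds Holm-adjusted p-values.
    """
    measures = list(measures or cohort.measure_names)
    if len(cohort) < 3:
        raise ValueError("need at least 3 animals for correlations")
    frames = (
        [(g, cohort.subset(g)) for g in ("Ctrl", "CUMS")]
        if per_group
        else [("pooled", cohort.data)]
    )
    rows = []
    for scope, df in frames:
        for i, a in enumerate(measures):
            for b in measures[i + 1 :]:
                x, y = df[a].to_numpy(float), df[b].to_numpy(float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    rows.append(
                        {"scope": scope, "measure_a": a, "measure_b": b,
                         "pearson_r": np.nan, "pearson_p": np.nan,
                         "spearman_rho": np.nan, "spearman_p": np.nan,
                         "defined": False}
                    )
                    continue
                pr = stats.pearsonr(x, y)
                sr = stats.spearmanr(x, y)
                rows.append(
                    {"scope": scope, "measure_a": a, "measure_b": b,
                     "pearson_r": pr.statistic, "pearson_p": pr.pvalue,
                     "spearman_rho": sr.statistic, "spearman_p": sr.pvalue,
                     "defined": True}
                )
    out = pd.DataFrame(rows)
    if holm and len(out):
        from statsmodels.stats.multitest import multipletests

        mask = out["defined"].to_numpy()
        for col in ("pearson_p", "spearman_p"):
            adj = np.full(len(out), np.nan)
            if mask.any():
                adj[mask] = multipletests(out.loc[mask, col], method="holm")[1]
            out[col.replace("_p", "_p_holm")] = adj
    return out


def evaluate_recovery(
    assignments: Sequence[SubgroupAssignment], cohort: Cohort
) -> RecoveryMetrics:
    """Score the Dep label against the latent susceptibility tag.

    Among CUMS animals, Dep counts as "predicted susceptible"; noDep and
    excluded count as "predicted not susceptible". With zero latent
    positives (or negatives) the corresponding rate is undefined and
    reported as None, with the other rate still computed.
    """
    sub_by_id = {a.mouse_id: a.subgroup for a in assignments}
    cums = cohort.subset("CUMS")
    if "latent" not in cums.columns or cums["latent"].isna().any():
        raise MissingLatentError(
            "recovery evaluation requires latent tags on all CUMS animals"
        )
    truth = (cums["latent"] == "susceptible").to_numpy()
    pred = np.array([sub_by_id[m] == "Dep" for m in cums["mouse_id"]])
    tp = int((truth & pred).sum())
    fn = int((truth & ~pred).sum())
    fp = int((~truth & pred).sum())
    tn = int((~truth & ~pred).sum())
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    bal = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    return RecoveryMetrics(
        sensitivity=sens, specificity=spec, balanced_accuracy=bal,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


class DepressionScreen(BaseEstimator, TransformerMixin):
    """ROC/Youden behavioral screen as a scikit-learn estimator.

    Parameters
    ----------
    measures : sequence of MeasureSpec, default the SPT/EPM/FST triple
        Measures to score, each with its depressive direction.

    Attributes
    ----------
    criteria_ : dict of str -> CutoffCriterion
        Youden-optimal cutoff per measure, fitted on the labeled cohort.
    feature_names_in_ : ndarray of str
        Measure column names seen during fit.

    Examples
    --------
    >>> screen = DepressionScreen().fit(X, y)       # y in {"Ctrl", "CUMS"}
    >>> screen.transform(X)                          # flags + dscore
    >>> screen.predict(X)                            # dscore 0..3
    >>> screen.assign(X, y)                          # Dep/noDep/Ctrl/excluded
    """

    def __init__(self, measures: Sequence[MeasureSpec] = DEFAULT_MEASURES):
        self.measures = measures

    def _frame(self, X) -> pd.DataFrame:
        names = [m.name for m in self.measures]
        if isinstance(X, pd.DataFrame):
            missing = [n for n in names if n not in X.columns]
            if missing:
                raise MissingMeasureError(f"X lacks measure columns {missing}")
            return X[names].astype(float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(names):
            raise ValueError(
                f"X must be 2-D with {len(names)} columns {names}, got shape {X.shape}"
            )
        return pd.DataFrame(X, columns=names)

    def fit(self, X, y):
        """Derive per-measure Youden-optimal cutoffs.

        ``y`` holds the group labels: "CUMS" (positive) and "Ctrl"
        (negative), or equivalently booleans/0-1 with 1 = CUMS.
        """
        df = self._frame(X)
        y = np.asarray(y)
        if y.dtype.kind in "OUS":
            y = y.astype(str)
            bad = set(np.unique(y)) - {"Ctrl", "CUMS"}
            if bad:
                raise UnknownGroupError(f"unknown group labels {sorted(bad)}")
            labels = y == "CUMS"
        else:
            labels = y.astype(bool)
        self.criteria_ = {
            m.name: derive_criterion(df[m.name].to_numpy(), m, labels)
            for m in self.measures
        }
        self.feature_names_in_ = np.asarray([m.name for m in self.measures])
        self.n_features_in_ = len(self.measures)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Per-criterion flags (``flag_<measure>``) plus the D-score."""
        check_is_fitted(self, "criteria_")
        df = self._frame(X)
        out = pd.DataFrame(index=df.index)
        for name, crit in self.criteria_.items():
            vals = df[name].to_numpy()
            if crit.direction == "low":
                out[f"flag_{name}"] = vals <= crit.cutoff_original_scale
            else:
                out[f"flag_{name}"] = vals >= crit.cutoff_original_scale
        out["dscore"] = out.sum(axis=1).astype(int)
        return out

    def predict(self, X) -> np.ndarray:
        """D-score (0..n_measures) per animal."""
        return self.transform(X)["dscore"].to_numpy()

    def assign(self, X, groups) -> np.ndarray:
        """Subgroup label per animal given its group membership."""
        dscores = self.predict(X)
        groups = np.asarray(groups)
        return np.array(
            [assign_subgroup(str(g), int(d)) for g, d in zip(groups, dscores)]
        )


def screen_cohort(
    cohort: Cohort, criteria: Sequence[CutoffCriterion] | None = None
) -> pd.DataFrame:
    """End-to-end screen of a cohort: derive cutoffs (unless frozen criteria
    are supplied), score, and assign subgroups.

    Returns one row per animal: ``mouse_id, group, flag_*, dscore, subgroup``.
    """
    if criteria is None:
        screen = DepressionScreen(cohort.measure_specs).fit(
            cohort.data, cohort.data["group"].to_numpy()
        )
        criteria = list(screen.criteria_.values())
    dscores = score_cohort(cohort, criteria)
    assignments = assign_subgroups(cohort, dscores)
    rows = []
    for rec, d, a in zip(cohort.records(), dscores, assignments):
        row = {"mouse_id": rec.mouse_id, "group": rec.group}
        row |= {f"flag_{m}": bool(v) for m, v in d.flags.items()}
        row |= {"dscore": d.dscore, "subgroup": a.subgroup}
        rows.append(row)
    return pd.DataFrame(rows)
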