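"""Pair/nonpair classification of scans: pair tables, ROC curves, splits.

Every eligible pair of scans for a comparison type (same-day pre vs post on a
visit, or one of the four cross-visit session combinations) is scored with
the dot-product similarity.  Pairs of scans from the same subject are the
positives; sweeping a threshold over the scores traces the empirical ROC
curve.  The reported operating point is the Youden-optimal threshold (max
TPR - FPR, ties broken toward higher specificity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import ScanRecord, similarity

__all__ = [
    "COMPARISON_TYPES",
    "SAME_DAY_TYPES",
    "CROSS_VISIT_TYPES",
    "SELECTION_TYPES",
    "build_pairs",
    "ROCResult",
    "roc_from_pairs",
    "roc_from_scores",
    "auc_mann_whitney",
    "split_groups",
]

# comparison type -> ((visit_a, session_a), (visit_b, session_b))
COMPARISON_TYPES: dict[str, tuple[tuple[int, str], tuple[int, str]]] = {
    "V1_pre_post": ((1, "pre"), (1, "post")),
    "V2_pre_post": ((2, "pre"), (2, "post")),
    "X_pre_pre": ((1, "pre"), (2, "pre")),
    "X_post_post": ((1, "post"), (2, "post")),
    "X_pre_post": ((1, "pre"), (2, "post")),
    "X_post_pre": ((1, "post"), (2, "pre")),
}
SAME_DAY_TYPES = ("V1_pre_post", "V2_pre_post")
CROSS_VISIT_TYPES = ("X_pre_pre", "X_post_post", "X_pre_post", "X_post_pre")
#: the four comparison types used for predictive-edge selection
#: (cross-session cross-visit pairs excluded)
SELECTION_TYPES = ("V1_pre_post", "V2_pre_post", "X_pre_pre", "X_post_post")


def build_pairs(scans: Sequence[ScanRecord],
                comparison_types: Iterable[str] = SAME_DAY_TYPES) -> pd.DataFrame:
    """Score every eligible scan pair for each requested comparison type.

    Returns a pair table with one row per (scan_a, scan_b, type): the full
    cross product of the type's two scan pools, with ``is_same_subject``
    labels and similarity ``score``.  Subjects missing a scan of the type
    contribute no rows for it.
    """
    comparison_types = list(comparison_types)
    unknown = set(comparison_types) - set(COMPARISON_TYPES)
    if unknown:
        raise ValueError(f"unknown comparison types: {sorted(unknown)}")
    if len(scans) == 0:
        raise ValueError("no scans supplied")

    pool: dict[tuple[int, str], list[ScanRecord]] = {}
    for s in scans:
        pool.setdefault((s.visit, s.session), []).append(s)

    frames = []
    for ctype in comparison_types:
        key_a, key_b = COMPARISON_TYPES[ctype]
        a_scans = pool.get(key_a, [])
        b_scans = pool.get(key_b, [])
        if not a_scans or not b_scans:
            raise ValueError(f"comparison type {ctype!r} has no eligible scans")
        va = np.stack([s.norm_vector for s in a_scans])
        vb = np.stack([s.norm_vector for s in b_scans])
        scores = va @ vb.T / va.shape[1]  # all-pairs dot-product similarity
        subs_a = np.array([s.subject_id for s in a_scans], dtype=object)
        subs_b = np.array([s.subject_id for s in b_scans], dtype=object)
        ia, ib = np.meshgrid(np.arange(len(a_scans)), np.arange(len(b_scans)),
                             indexing="ij")
        frames.append(pd.DataFrame({
            "scan_a": [a_scans[i].scan_id for i in ia.ravel()],
            "scan_b": [b_scans[j].scan_id for j in ib.ravel()],
            "subject_a": subs_a[ia.ravel()],
            "subject_b": subs_b[ib.ravel()],
            "comparison_type": ctype,
            "is_same_subject": subs_a[ia.ravel()] == subs_b[ib.ravel()],
            "score": scores.ravel(),
            "index_a": ia.ravel(),
            "index_b": ib.ravel(),
        }))
    table = pd.concat(frames, ignore_index=True)
    table["is_same_subject"] = table["is_same_subject"].astype(bool)
    return table


@dataclass
class ROCResult:
    """Empirical ROC curve with its AUC and Youden-optimal operating point."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_t: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int
    pos_scores: np.ndarray
    neg_scores: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "optimal_t": self.optimal_t,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def roc_from_scores(pos: np.ndarray, neg: np.ndarray) -> ROCResult:
    """ROC by sweeping the decision threshold over all observed scores.

    A pair is called positive when ``score >= t``.  Thresholds run over the
    distinct observed values plus a +inf sentinel (the all-negative corner),
    yielding the exact empirical curve; the trapezoidal area then equals the
    Mann-Whitney AUC.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative pair")
    thresholds = np.concatenate([[np.inf], np.unique(np.concatenate([pos, neg]))[::-1]])
    tpr = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= thresholds[:, None]).mean(axis=1)
    auc = auc_mann_whitney(pos, neg)
    youden = tpr - fpr
    best = np.flatnonzero(youden == youden.max())
    # ties toward higher specificity = larger threshold = smaller index
    pick = best.min()
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        optimal_t=float(thresholds[pick]),
        sensitivity=float(tpr[pick]),
        specificity=float(1 - fpr[pick]),
        n_pos=pos.size,
        n_neg=neg.size,
        pos_scores=pos,
        neg_scores=neg,
    )


def roc_from_pairs(pairs: pd.DataFrame, score_col: str = "score") -> ROCResult:
    """ROC/AUC of a scored pair table (see :func:`roc_from_scores`)."""
    labels = pairs["is_same_subject"].to_numpy(dtype=bool)
    scores = pairs[score_col].to_numpy(dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("pair table must contain both positives and negatives")
    return roc_from_scores(scores[labels], scores[~labels])


def split_groups(scans: Sequence[ScanRecord],
                 by: str = "median_age") -> tuple[list[ScanRecord], list[ScanRecord]]:
    """Partition scans into two groups of whole subjects.

    ``median_age`` / ``mean_age``: cut at the median / mean of visit-1 subject
    ages; below the cut is the first group ("youths"), at or above is the
    second ("adults").  ``age18``: adults are subjects aged >= 18.  ``sex``:
    females first, males second.  A subject stays in one group across visits.
    """
    meta: dict[str, tuple[float, str]] = {}
    for s in scans:
        if s.visit == 1 or s.subject_id not in meta:
            meta[s.subject_id] = (s.age_years, s.sex)
    ages = np.array([meta[sid][0] for sid in meta])

    if by == "median_age":
        cut = float(np.median(ages))
        first = {sid for sid, (a, _) in meta.items() if a < cut}
    elif by == "mean_age":
        cut = float(np.mean(ages))
        first = {sid for sid, (a, _) in meta.items() if a < cut}
    elif by == "age18":
        first = {sid for sid, (a, _) in meta.items() if a < 18.0}
    elif by == "sex":
        first = {sid for sid, (_, x) in meta.items() if x == "F"}
    else:
        raise ValueError(f"unknown split rule {by!r}")

    group_a = [s for s in scans if s.subject_id in first]
    group_b = [s for s in scans if s.subject_id not in first]
    for g, name in ((group_a, "first"), (group_b, "second")):
        if len({s.subject_id for s in g}) < 2:
            raise ValueError(f"{name} group has fewer than 2 subjects")
    return group_a, group_b
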