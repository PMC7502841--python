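"""Selection of the edges most predictive of same-subject scan pairs.

Three selection routes are implemented:

* **finn** — the differential-power (DP) statistic: for each edge, how
  improbable it is that a cross-subject product of normalized edge values
  matches or exceeds the within-subject product, aggregated over subjects as
  a sum of negative log probabilities.  Edges are ranked by DP and the top
  fraction retained.
* **elastic_net** — penalized logistic regression on the per-edge dot-product
  terms V_e * U_e of each comparison, with a mixed L1/L2 penalty
  (``alpha`` is the L1 mixing weight, default 0.1 = 10% L1 / 90% L2) and the
  penalty strength lambda chosen by cross-validation over a log-spaced path.
* **svm** — a linear hinge-loss model with the same mixed penalty.

Class imbalance is handled before fitting by nearest-nonpair undersampling:
all same-subject pairs are kept and only the ``ratio`` * n_pairs nonpairs
closest (Euclidean distance in feature space) to a pair are retained.
The per-edge product features are already on a common scale (products of
z-scored edge values), so no per-column standardization is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .core import ScanRecord
from .identify import ROCResult, auc_mann_whitney, roc_from_scores
from .solvers import fit_enet_path

__all__ = [
    "PairFeatureSet",
    "EdgeModel",
    "pair_features",
    "rebalance",
    "split_train_test",
    "finn_rank",
    "fit_penalized",
    "apply_model",
]

_SESSION_ORDER = {"pre": 0, "post": 1}


@dataclass
class PairFeatureSet:
    """Per-comparison feature rows: one row per scan pair, one column per edge.

    Row ``i`` holds the element-wise products V_e * U_e of the two scans'
    normalized edge vectors, so ``X[i].sum() / E`` is the pair's similarity.
    """

    X: np.ndarray            # (n_rows, E)
    y: np.ndarray            # bool, same-subject labels
    pairs: pd.DataFrame      # aligned pair-table rows

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=bool)
        if self.X.shape[0] != self.y.size or len(self.pairs) != self.y.size:
            raise ValueError("X, y and pairs must agree on the number of rows")

    @property
    def n_edges(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "PairFeatureSet":
        return PairFeatureSet(self.X[idx], self.y[idx],
                              self.pairs.iloc[idx].reset_index(drop=True))


@dataclass
class EdgeModel:
    """Per-edge scores and the retained edge set from one selection method."""

    method: str                       # finn | elastic_net | svm
    scores: np.ndarray                # per-edge DP value or weight, shape (E,)
    retained: np.ndarray              # retained edge ids (ascending)
    tuning: dict = field(default_factory=dict)
    intercept: float = 0.0

    def __post_init__(self):
        self.retained = np.asarray(self.retained, dtype=int)
        if self.retained.size and (self.retained.min() < 0
                                   or self.retained.max() >= self.scores.size):
            raise ValueError("retained edge ids out of range")

    @property
    def n_edges(self) -> int:
        return self.scores.size

    def to_frame(self, edge_table: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"edge_id": np.arange(self.n_edges), "score": self.scores})
        df["retained"] = np.isin(df["edge_id"].to_numpy(), self.retained)
        if edge_table is not None:
            df = edge_table.merge(df, on="edge_id")
        return df


def pair_features(pairs: pd.DataFrame, scans: Sequence[ScanRecord]) -> PairFeatureSet:
    """Expand a scored pair table into per-edge product features."""
    vecs = {s.scan_id: s.norm_vector for s in scans}
    e_total = next(iter(vecs.values())).size
    x = np.empty((len(pairs), e_total))
    for i, (a, b) in enumerate(zip(pairs["scan_a"], pairs["scan_b"])):
        x[i] = vecs[a] * vecs[b]
    return PairFeatureSet(x, pairs["is_same_subject"].to_numpy(dtype=bool),
                          pairs.reset_index(drop=True))


def rebalance(fs: PairFeatureSet, ratio: int = 3, chunk: int = 2048) -> PairFeatureSet:
    """Nearest-nonpair undersampling: keep all pairs and the ``ratio`` * n_pos
    nonpairs closest (Euclidean, in feature space) to any pair.

    Deterministic given input order; distance ties are broken by row index.
    """
    pos_idx = np.flatnonzero(fs.y)
    neg_idx = np.flatnonzero(~fs.y)
    n_keep = ratio * pos_idx.size
    if neg_idx.size < n_keep:
        raise ValueError(
            f"need at least {n_keep} nonpairs for ratio {ratio}, have {neg_idx.size}")
    xp = fs.X[pos_idx]
    sq_p = np.einsum("ij,ij->i", xp, xp)
    min_d = np.empty(neg_idx.size)
    for start in range(0, neg_idx.size, chunk):
        xn = fs.X[neg_idx[start:start + chunk]]
        d2 = (np.einsum("ij,ij->i", xn, xn)[:, None]
              - 2 * xn @ xp.T + sq_p[None, :])
        min_d[start:start + chunk] = d2.min(axis=1)
    order = np.argsort(min_d, kind="stable")[:n_keep]
    keep = np.sort(np.concatenate([pos_idx, neg_idx[order]]))
    return fs.subset(keep)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_train_test(fs: PairFeatureSet, train_frac: float = 2 / 3,
                     seed: int = 0) -> tuple[PairFeatureSet, PairFeatureSet]:
    """Stratified train/test split; train class counts are round-half-up of
    class size * ``train_frac`` (532 pairs at 2/3 -> 355 train / 177 test).
    """
    rng = np.random.default_rng(seed)
    train_mask = np.zeros(fs.y.size, dtype=bool)
    for label in (True, False):
        idx = np.flatnonzero(fs.y == label)
        n_train = _round_half_up(idx.size * train_frac)
        if n_train == 0 or n_train == idx.size:
            raise ValueError(f"class {label} empty in train or test split")
        train_mask[rng.permutation(idx)[:n_train]] = True
    return fs.subset(np.flatnonzero(train_mask)), fs.subset(np.flatnonzero(~train_mask))


def _scan_pairs_by_subject(scans: Sequence[ScanRecord]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """First two scans (canonical visit/session order) per subject."""
    by_subject: dict[str, list[ScanRecord]] = {}
    for s in scans:
        by_subject.setdefault(s.subject_id, []).append(s)
    z1, z2, subjects = [], [], []
    for sid, ss in by_subject.items():
        if len(ss) < 2:
            warnings.warn(f"subject {sid} has a single scan; excluded from DP ranking")
            continue
        ss = sorted(ss, key=lambda s: (s.visit, _SESSION_ORDER[s.session]))
        z1.append(ss[0].norm_vector)
        z2.append(ss[1].norm_vector)
        subjects.append(sid)
    if len(subjects) < 3:
        raise ValueError("differential power needs >= 3 subjects with >= 2 scans")
    return np.stack(z1), np.stack(z2), subjects


def differential_power(z1: np.ndarray, z2: np.ndarray) -> np.ndarray:
    """Differential power DP(e) from per-subject scan pairs (rows of z1/z2).

    For subject s with within-subject product w = z1[s]*z2[s],
    P_s(e) = [#{j != s: z1[s]z2[j] >= w} + #{j != s: z1[j]z2[s] >= w}]
             / (2(S-1)),
    floored at 1/(20(S-1)) to keep the log finite, and
    DP(e) = sum_s -ln P_s(e).  Uninformative edges (all products equal) score
    0; edges whose within-subject product beats every cross-subject product
    hit the floor for every subject.
    """
    s_count, e_total = z1.shape
    floor = 1.0 / (2 * (s_count - 1) * 10)
    w = z1 * z2
    dp = np.zeros(e_total)
    for s in range(s_count):
        c1 = (z1[s][None, :] * z2 >= w[s][None, :]).sum(axis=0) - 1
        c2 = (z1 * z2[s][None, :] >= w[s][None, :]).sum(axis=0) - 1
        p = (c1 + c2) / (2 * (s_count - 1))
        dp -= np.log(np.maximum(p, floor))
    return dp


def group_consistency(z1: np.ndarray, z2: np.ndarray) -> np.ndarray:
    """Group consistency Phi(e): mean within-subject product of normalized
    edge values — high for edges strong and stable across *everyone*, the
    complement of the individuality that DP captures."""
    return (z1 * z2).mean(axis=0)


def finn_rank(scans: Sequence[ScanRecord], top_frac: float = 0.05,
              statistic: str = "dp") -> EdgeModel:
    """Rank edges by differential power and retain the top fraction.

    Uses each training subject's first two scans (canonical visit/session
    order); subjects with fewer than two scans are excluded with a warning.
    The default retained fraction is 5%.  ``statistic='group_consistency'``
    ranks by the group-consistency score instead (non-default; selects
    group-stable rather than individually distinctive edges).
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    z1, z2, subjects = _scan_pairs_by_subject(scans)
    if statistic == "dp":
        scores = differential_power(z1, z2)
    elif statistic == "group_consistency":
        scores = group_consistency(z1, z2)
    else:
        raise ValueError(f"unknown ranking statistic {statistic!r}")
    n_keep = max(1, _round_half_up(top_frac * scores.size))
    order = np.argsort(-scores, kind="stable")  # ties broken by edge id
    retained = np.sort(order[:n_keep])
    return EdgeModel(method="finn", scores=scores, retained=retained,
                     tuning={"top_frac": top_frac, "statistic": statistic,
                             "n_subjects": len(subjects)})


def _lambda_path(x: np.ndarray, y: np.ndarray, alpha: float,
                 n_lambdas: int, lambda_min_ratio: float) -> np.ndarray:
    resid = y.astype(float) - y.mean()
    lam_max = np.abs(x.T @ resid).max() / (len(y) * max(alpha, 1e-3))
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)


_METHOD_LOSS = {"elastic_net": "logistic", "svm": "huber_hinge"}


def _fit_path(x: np.ndarray, y: np.ndarray, method: str, alpha: float,
              lambdas: np.ndarray, tol: float = 1e-8,
              max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started mixed-penalty path, strongest penalty first."""
    if method not in _METHOD_LOSS:
        raise ValueError(f"unknown penalized method {method!r}")
    return fit_enet_path(x, y, lambdas, alpha=alpha, loss=_METHOD_LOSS[method],
                         tol=tol, max_iter=max_iter)


def fit_penalized(fs: PairFeatureSet, method: str = "elastic_net",
                  alpha: float = 0.1, cv_folds: int = 10, seed: int = 0,
                  n_lambdas: int = 20, lambda_min_ratio: float = 1e-2,
                  stratify_by_subject: bool = True) -> EdgeModel:
    """Fit a penalized linear classifier of pair vs nonpair on edge products.

    ``alpha`` is the L1 share of the mixed penalty (0.1 = mostly ridge, the
    convention of the glmnet family).  The penalty strength is chosen by
    ``cv_folds``-fold cross-validation over a log-spaced path, maximizing
    validation AUC (minimal CV error); folds are stratified by label and, by
    default, grouped by the first subject of each pair so one subject's
    comparisons stay within a fold.  Retained edges are those with nonzero
    weight at the chosen penalty.
    """
    x, y = fs.X, fs.y
    if y.all() or not y.any():
        raise ValueError("training rows must contain both classes")
    lambdas = _lambda_path(x, y, alpha, n_lambdas, lambda_min_ratio)

    if stratify_by_subject and "subject_a" in fs.pairs:
        groups = fs.pairs["subject_a"].to_numpy()
        splitter = StratifiedGroupKFold(n_splits=cv_folds, shuffle=True,
                                        random_state=seed)
        folds = list(splitter.split(x, y.astype(int), groups))
    else:
        splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                                   random_state=seed)
        folds = list(splitter.split(x, y.astype(int)))
    for tr, va in folds:
        if y[tr].all() or not y[tr].any() or y[va].all() or not y[va].any():
            raise ValueError("a CV fold lost one class; reduce cv_folds")

    cv_auc = np.zeros(lambdas.size)
    for tr, va in folds:
        # lambda selection scores by rank (AUC), so the fold fits can run at
        # a looser tolerance than the final model
        coefs, intercepts = _fit_path(x[tr], y[tr], method, alpha, lambdas,
                                      tol=3e-7, max_iter=300)
        scores = x[va] @ coefs.T + intercepts  # (n_va, n_lambdas)
        for li in range(lambdas.size):
            cv_auc[li] += auc_mann_whitney(scores[y[va], li], scores[~y[va], li])
    cv_auc /= len(folds)
    best = int(np.argmax(cv_auc))  # first (largest lambda) among ties
    lam = float(lambdas[best])
    coefs, intercepts = _fit_path(x, y, method, alpha, lambdas[: best + 1])
    weights = coefs[best].copy()
    return EdgeModel(
        method=method, scores=weights, retained=np.flatnonzero(weights != 0),
        intercept=float(intercepts[best]),
        tuning={"alpha": alpha, "lambda": lam, "cv_folds": cv_folds,
                "cv_auc": float(cv_auc[best]),
                "lambda_path": lambdas.tolist(), "cv_auc_path": cv_auc.tolist()})


def score_pairs(model: EdgeModel, fs: PairFeatureSet) -> np.ndarray:
    """Model score for each pair row.

    finn: similarity restricted to the retained edges (sum of the retained
    dot-product terms, renormalized by the retained count); penalized models:
    the linear score intercept + sum_e w_e (V_e U_e).
    """
    if fs.n_edges != model.n_edges:
        raise ValueError(
            f"edge count mismatch: model {model.n_edges}, features {fs.n_edges}"
            " (parcellation mismatch?)")
    if model.method == "finn":
        if model.retained.size == 0:
            raise ValueError("finn model retains no edges")
        return fs.X[:, model.retained].sum(axis=1) / model.retained.size
    return model.intercept + fs.X @ model.scores


def apply_model(model: EdgeModel, fs: PairFeatureSet) -> tuple[np.ndarray, ROCResult]:
    """Score a (new) pair feature set and compute a fresh ROC on it.

    The operating threshold is re-derived on the new cohort's scores, never
    carried over from the cohort the model was fitted on.
    """
    scores = score_pairs(model, fs)
    roc = roc_from_scores(scores[fs.y], scores[~fs.y])
    return scores, roc
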