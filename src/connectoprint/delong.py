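"""DeLong's nonparametric test for comparing two ROC AUCs.

The AUC of a score-based classifier is the Mann-Whitney concordance
probability.  DeLong's method estimates its sampling variance from the
*placement values* (structural components): for each positive score, the
fraction of negatives it beats (ties counting 1/2), and symmetrically for
each negative.  Two AUCs are compared with the normal-deviate statistic

    D = (AUC_1 - AUC_2) / sqrt(var_1 + var_2 - 2 cov_12),

where the covariance term is estimated from shared placement values when the
two curves are computed over the same units (paired) and is zero otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["DeLongResult", "delong_variance", "delong_test", "placement_values"]


@dataclass(frozen=True)
class DeLongResult:
    auc_1: float
    auc_2: float
    var_1: float
    var_2: float
    cov_12: float
    D: float
    p: float
    paired: bool

    def summary(self) -> dict:
        return {
            "auc_1": self.auc_1, "auc_2": self.auc_2, "D": self.D,
            "p": self.p, "paired": self.paired,
        }


def placement_values(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Placement values V10 (one per positive) and V01 (one per negative).

    V10[i] is the fraction of negatives scored below positive i (ties = 1/2);
    mean(V10) = mean(1 - V01) = AUC.  Computed via midranks in O(n log n).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    m, n = pos.size, neg.size
    if m < 1 or n < 1:
        raise ValueError("need at least one score in each class")
    all_scores = np.concatenate([pos, neg])
    r_all = rankdata(all_scores)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01


def delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance estimate S10/m + S01/n.

    Requires >= 2 scores per class (the structural-component variances are
    sample variances).  Perfect separation yields variance 0.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 positives and >= 2 negatives")
    v10, v01 = placement_values(pos, neg)
    auc = float(v10.mean())
    var = float(v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size)
    return auc, var


def delong_test(pos_1: np.ndarray, neg_1: np.ndarray,
                pos_2: np.ndarray, neg_2: np.ndarray,
                paired: bool = False) -> DeLongResult:
    """Compare the AUCs of two score sets.

    With ``paired=True`` the two score sets must be defined over the same
    units in the same order (e.g., the same pairs scored by two models); the
    covariance of their placement values then enters the variance of the
    difference.  Unpaired curves set the covariance to zero.
    """
    pos_1 = np.asarray(pos_1, float); neg_1 = np.asarray(neg_1, float)
    pos_2 = np.asarray(pos_2, float); neg_2 = np.asarray(neg_2, float)
    auc1, var1 = delong_variance(pos_1, neg_1)
    auc2, var2 = delong_variance(pos_2, neg_2)
    cov = 0.0
    if paired:
        if pos_1.size != pos_2.size or neg_1.size != neg_2.size:
            raise ValueError("paired comparison requires equal class sizes on shared units")
        v10_1, v01_1 = placement_values(pos_1, neg_1)
        v10_2, v01_2 = placement_values(pos_2, neg_2)
        s10 = np.cov(v10_1, v10_2, ddof=1)[0, 1]
        s01 = np.cov(v01_1, v01_2, ddof=1)[0, 1]
        cov = float(s10 / pos_1.size + s01 / neg_1.size)
    denom_sq = var1 + var2 - 2 * cov
    diff = auc1 - auc2
    if denom_sq <= 0:
        # degenerate: no estimated sampling variability in the difference
        d = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        d = diff / np.sqrt(denom_sq)
    p = float(2 * norm.sf(abs(d))) if np.isfinite(d) else 0.0
    if d == 0:
        p = 1.0
    return DeLongResult(auc_1=auc1, auc_2=auc2, var_1=var1, var_2=var2,
                        cov_12=cov, D=float(d), p=p, paired=paired)
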