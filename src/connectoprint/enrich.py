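"""Over-representation of network connectivity among predictive edges.

Each edge belongs to one category: a within-network cell (both endpoints in
the same network) or an unordered between-network pair.  Given a set of
predictive edges, a 2 x K contingency table (predictive vs not, by category)
is tested with a chi-square statistic, and the cells driving it are read off
the *adjusted standardized residuals*

    r_k = (obs_k - exp_k) / sqrt(exp_k (1 - row_frac)(1 - col_frac)),

with |r| > 3.0 flagging over/under-representation.  Three tests mirror the
natural structure: within vs between connectivity, among the within-network
categories, and among the between-network categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .core import ParcellationScheme, edge_index_table

__all__ = ["EnrichmentTable", "classify_edges", "enrichment_test", "enrichment_suite"]

RESIDUAL_FLAG = 3.0


def classify_edges(edge_table: pd.DataFrame,
                   parcellation: ParcellationScheme | None = None) -> pd.Series:
    """Category label per edge: ``within:NET`` or ``between:A|B`` (sorted pair).

    Accepts an edge index table (from :func:`~connectoprint.core.edge_index_table`)
    or builds one from the parcellation.
    """
    if edge_table is None:
        if parcellation is None:
            raise ValueError("need an edge table or a parcellation")
        edge_table = edge_index_table(parcellation)
    if edge_table[["network_i", "network_j"]].isna().any().any():
        raise ValueError("edge table contains unlabeled nodes")
    within = edge_table["within"].to_numpy()
    cats = np.where(within,
                    "within:" + edge_table["network_i"].astype(str),
                    "between:" + edge_table["network_pair"].astype(str))
    return pd.Series(cats, index=edge_table["edge_id"].to_numpy(), name="category")


@dataclass
class EnrichmentTable:
    """One chi-square test of predictive-edge representation across categories."""

    table: pd.DataFrame       # per-category counts, residuals, flags
    chi2: float
    df: int
    p: float
    n_predictive: int
    n_edges: int

    def flagged(self) -> list[str]:
        """Categories over-represented (residual > 3.0)."""
        hit = self.table[self.table["flagged"] & (self.table["residual"] > 0)]
        return hit["category"].tolist()


def enrichment_test(predictive: np.ndarray, categories: pd.Series) -> EnrichmentTable:
    """Chi-square test of a predictive edge set against edge categories.

    ``predictive`` is a boolean mask or an array of edge ids over the edges
    indexed by ``categories``.  Cells with expected predictive count < 1 are
    computed anyway but flagged ``low_expected`` with a warning.
    Also exports the normalized enrichment ratio
    (predictive_k / total_k) / (predictive_all / total_all) used for
    heatmap-style displays.
    """
    cats = categories.to_numpy()
    e_total = cats.size
    predictive = np.asarray(predictive)
    if predictive.dtype == bool:
        mask = predictive
        if mask.size != e_total:
            raise ValueError("boolean mask length must equal edge count")
    else:
        mask = np.zeros(e_total, dtype=bool)
        mask[predictive] = True
    n_pred = int(mask.sum())
    if n_pred == 0:
        raise ValueError("empty predictive edge set")
    uniq = pd.unique(cats)
    if uniq.size < 2:
        raise ValueError("need at least 2 categories")

    total = pd.Series(cats).value_counts().reindex(uniq).to_numpy(dtype=float)
    obs = pd.Series(cats[mask]).value_counts().reindex(uniq).fillna(0).to_numpy(dtype=float)
    row_frac = n_pred / e_total                      # predictive row margin
    exp = total * row_frac
    if (exp < 1).any():
        warnings.warn("expected predictive count < 1 in some categories; "
                      "their residuals are unstable")
    col_frac = total / e_total
    # adjusted standardized residuals (Agresti)
    denom = np.sqrt(exp * (1 - row_frac) * (1 - col_frac))
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.where(denom > 0, (obs - exp) / denom, 0.0)
        ratio = np.where(exp > 0, (obs / total) / row_frac, np.nan)
    # 2xK chi-square over both rows (predictive and non-predictive)
    obs2 = np.vstack([obs, total - obs])
    exp2 = np.vstack([exp, total - exp])
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(exp2 > 0, (obs2 - exp2) ** 2 / exp2, 0.0)
    chi2 = float(cells.sum())
    df = int(uniq.size - 1)
    p = float(chi2_dist.sf(chi2, df))

    table = pd.DataFrame({
        "category": uniq,
        "observed": obs.astype(int),
        "total": total.astype(int),
        "expected": exp,
        "chi2_contribution": cells[0],
        "residual": resid,
        "enrichment_ratio": ratio,
        "flagged": np.abs(resid) > RESIDUAL_FLAG,
        "low_expected": exp < 1,
    })
    return EnrichmentTable(table=table, chi2=chi2, df=df, p=p,
                           n_predictive=n_pred, n_edges=e_total)


def enrichment_suite(predictive: np.ndarray, edge_table: pd.DataFrame) -> dict[str, EnrichmentTable]:
    """The three over-representation tests run on one predictive edge set:
    within vs between, among within-network cells, among between-network cells.
    """
    cats = classify_edges(edge_table)
    predictive = np.asarray(predictive)
    if predictive.dtype != bool:
        mask = np.zeros(cats.size, dtype=bool)
        mask[predictive] = True
    else:
        mask = predictive
    within = cats.str.startswith("within:").to_numpy()

    coarse = pd.Series(np.where(within, "within", "between"), index=cats.index)
    out = {"within_vs_between": enrichment_test(mask, coarse)}
    for name, sel in (("within", within), ("between", ~within)):
        if mask[sel].sum() > 0 and pd.unique(cats[sel]).size >= 2:
            out[name] = enrichment_test(mask[sel], cats[sel].reset_index(drop=True))
    return out
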