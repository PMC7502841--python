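"""Connectome vectorization and the dot-product similarity measure.

A parcellated resting-state scan enters the pipeline either as a node x time
series matrix or as a node x node Pearson correlation matrix.  The strict
upper triangle of the correlation matrix is stacked row-major into an edge
vector (a 333-node parcellation yields 333*332/2 = 55,278 edges), the vector
is normalized to mean zero and *population* variance one, and the similarity
between two scans is the dot product of their normalized vectors divided by
the edge count:

    corr(V, U) = sum_e V_e * U_e / E

With the population (1/E) variance convention this equals the Pearson
correlation of the raw edge vectors and satisfies corr(V, V) = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParcellationScheme",
    "ScanRecord",
    "n_edges",
    "edge_index_table",
    "correlate_timeseries",
    "vectorize",
    "devectorize",
    "normalize",
    "similarity",
    "fisher_z",
]


@dataclass(frozen=True)
class ParcellationScheme:
    """Fixed assignment of nodes to functional networks.

    Node order is shared by every scan; the edge order it induces is therefore
    stable across the whole analysis.
    """

    node_ids: tuple
    network_labels: tuple
    name: str = "custom"

    def __post_init__(self):
        if len(self.node_ids) != len(self.network_labels):
            raise ValueError("node_ids and network_labels must have equal length")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids in parcellation")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def networks(self) -> tuple:
        """Unique network labels in first-appearance order."""
        seen: dict = {}
        for lab in self.network_labels:
            seen.setdefault(lab, None)
        return tuple(seen)

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_nodes)


# The 13 resting-state networks of the Gordon 333-region cortical
# parcellation, with their region counts (used as default size proportions).
GORDON_NETWORK_SIZES = {
    "Default": 41,
    "SMhand": 38,
    "SMmouth": 8,
    "Visual": 39,
    "FrontoParietal": 24,
    "Auditory": 24,
    "CinguloParietal": 5,
    "RetrosplenialTemporal": 8,
    "CinguloOperc": 40,
    "VentralAttn": 23,
    "Salience": 4,
    "DorsalAttn": 32,
    "None": 47,
}
GORDON_NETWORKS = tuple(GORDON_NETWORK_SIZES)


def make_parcellation(
    n_nodes: int,
    networks: Sequence[str] = GORDON_NETWORKS,
    proportions: Sequence[float] | None = None,
    name: str = "synthetic",
) -> ParcellationScheme:
    """Build a block parcellation assigning ``n_nodes`` to ``networks``.

    Network block sizes follow ``proportions`` (largest-remainder rounding,
    minimum one node per network).  By default the 13 networks get the size
    proportions of the Gordon scheme, so synthetic parcellations keep the
    realistic feature that some networks are several times larger than
    others; pass equal proportions for even blocks.
    """
    networks = list(networks)
    k = len(networks)
    if n_nodes < k:
        raise ValueError(f"need at least {k} nodes for {k} networks")
    if proportions is None:
        if tuple(networks) == GORDON_NETWORKS:
            proportions = [GORDON_NETWORK_SIZES[n] for n in networks]
        else:
            proportions = [1.0] * k
    props = np.asarray(proportions, dtype=float)
    if props.size != k or (props <= 0).any():
        raise ValueError("proportions must be positive, one per network")
    quota = props / props.sum() * n_nodes
    sizes = np.maximum(np.floor(quota).astype(int), 1)
    rema = quota - np.floor(quota)
    while sizes.sum() < n_nodes:
        i = int(np.argmax(np.where(sizes >= 1, rema, -np.inf)))
        sizes[i] += 1
        rema[i] = -np.inf
    while sizes.sum() > n_nodes:  # min-1 clamping can overshoot
        i = int(np.argmax(sizes))
        sizes[i] -= 1
    labels: list[str] = []
    for net, sz in zip(networks, sizes):
        labels.extend([net] * int(sz))
    return ParcellationScheme(tuple(range(n_nodes)), tuple(labels), name=name)


def n_edges(n_nodes: int) -> int:
    """Number of strict upper-triangle edges for ``n_nodes`` regions."""
    if n_nodes < 3:
        raise ValueError("a connectome needs at least 3 nodes")
    return n_nodes * (n_nodes - 1) // 2


def edge_index_table(parcellation: ParcellationScheme) -> pd.DataFrame:
    """Edge table mapping edge_id -> (node_i, node_j, network pair).

    Edge order is row-major over the strict upper triangle: (0,1), (0,2), ...,
    (0,n-1), (1,2), ...  ``network_pair`` is the unordered label pair joined
    with '|' (sorted); ``within`` marks same-network edges.
    """
    n = parcellation.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    labels = np.asarray(parcellation.network_labels, dtype=object)
    li, lj = labels[iu], labels[ju]
    pair = np.array(["|".join(sorted((a, b))) for a, b in zip(li, lj)], dtype=object)
    return pd.DataFrame(
        {
            "edge_id": np.arange(iu.size),
            "node_i": iu,
            "node_j": ju,
            "network_i": li,
            "network_j": lj,
            "network_pair": pair,
            "within": li == lj,
        }
    )


def correlate_timeseries(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a node x time series matrix.

    Raises if any node's series is constant (correlation undefined), naming
    the offending node.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D node x time matrix")
    n_nodes_, n_t = ts.shape
    if n_t < 3:
        raise ValueError("need at least 3 time points")
    sd = ts.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant time series at node(s) {bad.tolist()}")
    r = np.corrcoef(ts)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def vectorize(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Stack the strict upper triangle of a symmetric matrix row-major."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("matrix is not symmetric")
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return m[iu, ju].copy()


def devectorize(vector: np.ndarray, n_nodes: int, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize`: rebuild the symmetric matrix."""
    v = np.asarray(vector, dtype=float)
    if v.size != n_edges(n_nodes):
        raise ValueError(f"expected {n_edges(n_nodes)} edges for {n_nodes} nodes, got {v.size}")
    m = np.full((n_nodes, n_nodes), diagonal, dtype=float)
    iu, ju = np.triu_indices(n_nodes, k=1)
    m[iu, ju] = v
    m[ju, iu] = v
    return m


def normalize(raw: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to population variance 1 (1/E denominator)."""
    v = np.asarray(raw, dtype=float)
    if v.ndim != 1:
        raise ValueError("edge vector must be 1-D")
    sd = v.std()  # population convention
    if sd == 0:
        raise ValueError("degenerate scan: edge vector has zero variance")
    return (v - v.mean()) / sd


def similarity(v: np.ndarray, u: np.ndarray) -> float:
    """Dot-product similarity of two normalized edge vectors: sum(V_e U_e)/E.

    Equal to the Pearson correlation of the raw vectors; self-similarity is
    exactly 1 under the population-variance normalization.
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    if v.shape != u.shape:
        raise ValueError(f"length mismatch: {v.shape} vs {u.shape}")
    return float(v @ u / v.size)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z-transform (arctanh), clipping away exact +/-1."""
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-12, 1 - 1e-12)
    return np.arctanh(r)


@dataclass
class ScanRecord:
    """One scan's edge vector plus its cohort metadata.

    ``raw_vector`` holds correlation-scale edge values in [-1, 1];
    ``norm_vector`` is its mean-0 / population-variance-1 normalization and is
    computed lazily on first access.
    """

    subject_id: str
    visit: int
    session: str  # "pre" | "post"
    age_years: float
    sex: str
    raw_vector: np.ndarray
    _norm: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.visit not in (1, 2):
            raise ValueError("visit must be 1 or 2")
        if self.session not in ("pre", "post"):
            raise ValueError("session must be 'pre' or 'post'")
        self.raw_vector = np.asarray(self.raw_vector, dtype=float)

    @property
    def norm_vector(self) -> np.ndarray:
        if self._norm is None:
            self._norm = normalize(self.raw_vector)
        return self._norm

    @property
    def scan_id(self) -> str:
        return f"{self.subject_id}_V{self.visit}_{self.session}"

    @property
    def n_edges(self) -> int:
        return self.raw_vector.size
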