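"""Synthetic two-visit, two-session cohorts with planted individual signatures.

The generator emulates the statistical structure the fingerprinting analysis
assumes, so every downstream stage is testable without imaging data:

* a fixed group component ``G`` (canonical network structure: within-network
  edges elevated over between-network edges, plus edge-level variation),
* a sparse subject-specific *signature*: a global 0/1 edge mask ``s_e`` drawn
  with elevated probability on within-network edges of designated signature
  networks, carrying per-subject stable offsets ``u_{s,e}``,
* per-subject-per-visit drift ``d_{s,v,e}`` shared by that day's two sessions
  (the source of the same-day vs long-interval accuracy gap), and
* independent per-scan session noise ``eps``.

Edge values are assembled additively in Fisher-z space and squashed through
tanh into (-1, 1) so they remain correlation-like.  Each subject receives a
visit-1 pre and post scan; a configurable fraction returns for both visit-2
scans (attrition removes whole visits, never single sessions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (
    ParcellationScheme,
    ScanRecord,
    devectorize,
    edge_index_table,
    make_parcellation,
    n_edges,
)

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "generate_timeseries",
           "replication_spec", "default_spec"]

SESSIONS = ("pre", "post")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    All standard deviations are in Fisher-z units.  ``signature_frac`` is the
    expected overall fraction of edges carrying a subject signature;
    ``signature_enrichment`` multiplies the per-edge signature probability on
    within-network edges of ``signature_networks`` (probabilities are then
    rescaled so the overall expectation stays at ``signature_frac``).
    """

    n_subjects: int
    n_nodes: int = 333
    parcellation: ParcellationScheme | None = None
    age_range: tuple[float, float] = (12.0, 30.0)
    v2_retention: float = 93 / 140
    sigma_group: float = 0.10
    sigma_signature: float = 0.38
    signature_networks: tuple[str, ...] = ("FrontoParietal", "Default", "DorsalAttn")
    signature_frac: float = 0.04
    signature_enrichment: float = 25.0
    sigma_session: float = 0.35
    sigma_visit: float = 0.05
    ts_length: int | None = None
    seed: int = 0
    #: seed of the *population* structure (group component and signature mask),
    #: shared by replication cohorts so predictive edges can transfer between
    #: samples the way they do between real cohorts
    structure_seed: int = 0
    # canonical group structure (Fisher-z means before edge-level variation)
    group_within_mean: float = 0.35
    group_between_mean: float = 0.05

    def __post_init__(self):
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        for name in ("sigma_group", "sigma_signature", "sigma_session", "sigma_visit"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.v2_retention <= 1:
            raise ValueError("v2_retention must be in (0, 1]")
        if not 0 <= self.signature_frac <= 1:
            raise ValueError("signature_frac must be in [0, 1]")
        if self.signature_enrichment < 1:
            raise ValueError("signature_enrichment must be >= 1")
        if self.signature_enrichment > 1 and not self.signature_networks:
            raise ValueError("signature_enrichment > 1 requires signature_networks")
        if self.parcellation is not None:
            if self.parcellation.n_nodes != self.n_nodes:
                raise ValueError("parcellation size does not match n_nodes")
            missing = set(self.signature_networks) - set(self.parcellation.networks)
            if missing:
                raise ValueError(f"signature networks not in parcellation: {sorted(missing)}")

    def resolve_parcellation(self) -> ParcellationScheme:
        if self.parcellation is not None:
            return self.parcellation
        return make_parcellation(self.n_nodes)


@dataclass
class SyntheticCohort:
    """Generated scans plus the ground truth needed for recovery tests."""

    scans: list[ScanRecord]
    spec: CohortSpec
    parcellation: ParcellationScheme
    signature_mask: np.ndarray          # bool, shape (E,)
    signature_values: np.ndarray        # float, shape (n_subjects, E); 0 off-mask
    subjects: list[str] = field(default_factory=list)

    @property
    def truth_edges(self) -> np.ndarray:
        """Edge ids carrying subject signatures."""
        return np.flatnonzero(self.signature_mask)

    def scans_of(self, subject_id: str) -> list[ScanRecord]:
        return [s for s in self.scans if s.subject_id == subject_id]


def _signature_mask(spec: CohortSpec, parcellation: ParcellationScheme,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw the global signature mask with within-network enrichment.

    Per-edge probabilities are signature_frac * enrichment on within-network
    edges of the signature networks and signature_frac elsewhere, rescaled so
    the expected overall fraction equals signature_frac, then capped at 1.
    """
    edges = edge_index_table(parcellation)
    hot = (
        edges["within"].to_numpy()
        & edges["network_i"].isin(spec.signature_networks).to_numpy()
    )
    e_total = len(edges)
    p = np.where(hot, spec.signature_frac * spec.signature_enrichment, spec.signature_frac)
    expected = p.mean()
    if expected > 0:
        p = p * (spec.signature_frac / expected)
    p = np.minimum(p, 1.0)
    return rng.random(e_total) < p


def _group_component(spec: CohortSpec, parcellation: ParcellationScheme,
                     rng: np.random.Generator) -> np.ndarray:
    edges = edge_index_table(parcellation)
    base = np.where(edges["within"].to_numpy(),
                    spec.group_within_mean, spec.group_between_mean)
    return base + rng.normal(0.0, spec.sigma_group, size=len(edges))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort deterministically from ``spec.seed``.

    Edge values in Fisher-z space are
    ``G + s_e * u_{s,e} + d_{s,v,e} + eps_{scan,e}`` mapped through tanh.
    """
    parcellation = spec.resolve_parcellation()
    e_total = n_edges(spec.n_nodes)
    # population structure: deterministic given structure_seed only, so
    # cohorts drawn with different seeds share it (replication transfer)
    structure_rng = np.random.default_rng(spec.structure_seed)
    g = _group_component(spec, parcellation, structure_rng)
    mask = _signature_mask(spec, parcellation, structure_rng)
    rng = np.random.default_rng(spec.seed)

    subjects = [f"sub{idx:04d}" for idx in range(spec.n_subjects)]
    ages = rng.uniform(spec.age_range[0], spec.age_range[1], size=spec.n_subjects)
    sexes = rng.choice(["M", "F"], size=spec.n_subjects)
    returns = rng.random(spec.n_subjects) < spec.v2_retention

    u = np.zeros((spec.n_subjects, e_total))
    u[:, mask] = rng.normal(0.0, spec.sigma_signature, size=(spec.n_subjects, int(mask.sum())))

    scans: list[ScanRecord] = []
    for s_idx, sid in enumerate(subjects):
        visits = (1, 2) if returns[s_idx] else (1,)
        for visit in visits:
            drift = rng.normal(0.0, spec.sigma_visit, size=e_total)
            for session in SESSIONS:
                eps = rng.normal(0.0, spec.sigma_session, size=e_total)
                z = g + u[s_idx] + drift + eps
                scans.append(
                    ScanRecord(
                        subject_id=sid,
                        visit=visit,
                        session=session,
                        age_years=float(ages[s_idx]),
                        sex=str(sexes[s_idx]),
                        raw_vector=np.tanh(z),
                    )
                )
    return SyntheticCohort(
        scans=scans,
        spec=spec,
        parcellation=parcellation,
        signature_mask=mask,
        signature_values=u,
        subjects=subjects,
    )


def _nearest_pd(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive-definite repair of a correlation matrix."""
    sym = (corr + corr.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    vals = np.maximum(vals, floor)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def generate_timeseries(spec: CohortSpec, scan: ScanRecord,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Gaussian node x time series whose sample correlation converges to the
    scan's correlation matrix as ``ts_length`` grows.

    Supports testing the time-series entry point; makes no claim to BOLD
    realism (no autocorrelation, no hemodynamics).
    """
    if spec.ts_length is None:
        raise ValueError("spec.ts_length must be set to generate time series")
    if spec.ts_length <= spec.n_nodes:
        raise ValueError("ts_length must exceed n_nodes")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    target = devectorize(scan.raw_vector, spec.n_nodes)
    chol = np.linalg.cholesky(_nearest_pd(target))
    return chol @ rng.standard_normal((spec.n_nodes, spec.ts_length))


def default_spec(n_subjects: int = 60, n_nodes: int = 78, seed: int = 0,
                 **overrides) -> CohortSpec:
    """The package's default study-sized cohort: 13 networks of 6 nodes each.

    Sized so a full end-to-end study (identification, DeLong contrasts, all
    three edge-selection methods, enrichment) runs in minutes on one CPU while
    keeping a realistic network structure.
    """
    parc = make_parcellation(n_nodes)
    return CohortSpec(n_subjects=n_subjects, n_nodes=n_nodes, parcellation=parc,
                      seed=seed, **overrides)


def replication_spec(discovery: CohortSpec, seed: int | None = None,
                     noise_factor: float = 1.5) -> CohortSpec:
    """Replication-style cohort: same design, new seed, noisier sessions.

    Emulates transferring edge models to an independent sample acquired with a
    less optimized protocol (longer TR, shorter scans), which shows lower
    baseline identifiability.
    """
    if seed is None:
        seed = discovery.seed + 10_000
    return replace(discovery, seed=seed,
                   sigma_session=discovery.sigma_session * noise_factor)
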