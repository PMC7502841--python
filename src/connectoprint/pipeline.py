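"""End-to-end fingerprinting study on a synthetic or user-supplied cohort.

``run_study`` reproduces the full design: per-comparison ROC curves (same-day
on each visit, the four long-interval session combinations), DeLong contrasts
(same-day vs long-interval; youths vs adults), predictive-edge selection by
the three methods with rebalancing and a stratified train/test split,
transfer of the fitted edge models to a replication cohort, and network
over-representation of each method's retained edges.  Every stage is
deterministic given the configuration seed, and the report carries the
configuration echo so a run can be reproduced from the JSON alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, SyntheticCohort, generate_cohort, replication_spec
from .core import ScanRecord, edge_index_table, make_parcellation
from .delong import DeLongResult, delong_test
from .edges import (EdgeModel, PairFeatureSet, apply_model, finn_rank,
                    fit_penalized, pair_features, rebalance, split_train_test)
from .enrich import enrichment_suite
from .identify import (CROSS_VISIT_TYPES, SAME_DAY_TYPES, SELECTION_TYPES,
                       ROCResult, build_pairs, roc_from_pairs, split_groups)

__all__ = ["StudyConfig", "StudyReport", "run_study", "run_replication_transfer"]

log = logging.getLogger("connectoprint")

PRIMARY_TYPES = SAME_DAY_TYPES + CROSS_VISIT_TYPES
METHODS = ("finn", "elastic_net", "svm")


@dataclass
class StudyConfig:
    """Declarative description of one study run (cohort + analysis options)."""

    cohort: dict = field(default_factory=dict)   # CohortSpec overrides
    seed: int = 0
    ratio: int = 3                # nonpairs kept per pair
    train_frac: float = 2 / 3
    alpha: float = 0.1            # L1 share of the mixed penalty
    top_frac: float = 0.05        # retained fraction for the DP ranking
    cv_folds: int = 10
    n_lambdas: int = 20
    methods: tuple[str, ...] = METHODS
    group_split: str = "median_age"
    replication: bool = True
    replication_noise_factor: float = 1.5
    crossvisit_only_variant: bool = False

    def cohort_spec(self) -> CohortSpec:
        params = dict(self.cohort)
        params.setdefault("n_subjects", 60)
        params.setdefault("n_nodes", 78)
        params.setdefault("seed", self.seed)
        if "parcellation" not in params:
            params["parcellation"] = make_parcellation(params["n_nodes"])
        return CohortSpec(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps({k: v for k, v in asdict(self).items()},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    """Structured results of one study run."""

    roc: dict[str, ROCResult]
    delong_timescale: dict[str, DeLongResult]
    delong_groups: dict[str, DeLongResult]
    group_sizes: dict[str, int]
    group_auc: dict[str, dict[str, float]]
    models: dict[str, EdgeModel]
    test_auc: dict[str, float]            # per method + "all_edges"
    replication_auc: dict[str, float]
    enrichment: dict[str, dict]
    counts: dict[str, int]
    config: StudyConfig
    seed: int
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config_digest": self.config.digest(),
            "config": asdict(self.config) | {"cohort": {
                k: (v if not hasattr(v, "n_nodes") else f"parcellation[{v.n_nodes}]")
                for k, v in self.config.cohort.items()}},
            "roc": {k: r.summary() for k, r in self.roc.items()},
            "delong_timescale": {k: d.summary() for k, d in self.delong_timescale.items()},
            "delong_groups": {k: d.summary() for k, d in self.delong_groups.items()},
            "group_sizes": self.group_sizes,
            "group_auc": self.group_auc,
            "models": {
                m: {"n_retained": int(mod.retained.size),
                    "tuning": {k: v for k, v in mod.tuning.items()
                               if not isinstance(v, list)}}
                for m, mod in self.models.items()},
            "test_auc": self.test_auc,
            "replication_auc": self.replication_auc,
            "enrichment": self.enrichment,
            "counts": self.counts,
        }

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(self.to_dict(), indent=2))
        for name, roc in self.roc.items():
            roc.to_frame().to_csv(outdir / f"roc_{name}.tsv", sep="\t", index=False)
        return report_path


def _roc_by_type(scans: Sequence[ScanRecord],
                 types: Sequence[str]) -> dict[str, ROCResult]:
    out = {}
    for ctype in types:
        pairs = build_pairs(scans, [ctype])
        out[ctype] = roc_from_pairs(pairs)
        log.info("ROC %s: %d pairs / %d nonpairs, AUC %.3f",
                 ctype, out[ctype].n_pos, out[ctype].n_neg, out[ctype].auc)
    return out


def _timescale_contrasts(roc: dict[str, ROCResult]) -> dict[str, DeLongResult]:
    """Same-day vs long-interval AUC contrasts (unpaired: distinct pair sets)."""
    out = {}
    for sd in SAME_DAY_TYPES:
        for xv in ("X_pre_pre", "X_post_post"):
            if sd in roc and xv in roc:
                out[f"{sd}_vs_{xv}"] = delong_test(
                    roc[sd].pos_scores, roc[sd].neg_scores,
                    roc[xv].pos_scores, roc[xv].neg_scores, paired=False)
    return out


def _group_contrasts(scans: Sequence[ScanRecord], types: Sequence[str],
                     by: str) -> tuple[dict[str, DeLongResult], dict[str, int],
                                       dict[str, dict[str, float]]]:
    """Per-comparison DeLong contrasts between the two subject groups.

    D is oriented as group 2 minus group 1 (adults minus youths for the age
    splits).  Also returns each group's per-comparison AUC.
    """
    young, old = split_groups(scans, by=by)
    sizes = {"group_1": len({s.subject_id for s in young}),
             "group_2": len({s.subject_id for s in old})}
    out = {}
    auc: dict[str, dict[str, float]] = {"group_1": {}, "group_2": {}}
    for ctype in types:
        try:
            roc_y = roc_from_pairs(build_pairs(young, [ctype]))
            roc_o = roc_from_pairs(build_pairs(old, [ctype]))
        except ValueError:
            continue
        auc["group_1"][ctype] = roc_y.auc
        auc["group_2"][ctype] = roc_o.auc
        out[ctype] = delong_test(roc_o.pos_scores, roc_o.neg_scores,
                                 roc_y.pos_scores, roc_y.neg_scores, paired=False)
    return out, sizes, auc


def _all_edges_auc(fs: PairFeatureSet) -> float:
    scores = fs.X.sum(axis=1) / fs.n_edges
    from .identify import auc_mann_whitney
    return auc_mann_whitney(scores[fs.y], scores[~fs.y])


def fit_edge_models(cohort_scans: Sequence[ScanRecord], config: StudyConfig,
                    pair_types: Sequence[str] = SELECTION_TYPES,
                    ) -> tuple[dict[str, EdgeModel], dict[str, float], PairFeatureSet, dict[str, int]]:
    """Rebalance, split, and fit the requested selection methods.

    Returns (models, test-set AUCs incl. 'all_edges', the held-out feature
    rows, and the pair/nonpair bookkeeping counts).
    """
    pairs = build_pairs(cohort_scans, pair_types)
    fs = pair_features(pairs, cohort_scans)
    counts = {"comparisons": len(pairs), "pairs": int(fs.y.sum()),
              "nonpairs": int((~fs.y).sum())}
    balanced = rebalance(fs, ratio=config.ratio)
    counts["nonpairs_retained"] = int((~balanced.y).sum())
    train, test = split_train_test(balanced, train_frac=config.train_frac,
                                   seed=config.seed)
    counts["train_pairs"] = int(train.y.sum())
    counts["train_nonpairs"] = int((~train.y).sum())
    counts["test_pairs"] = int(test.y.sum())
    counts["test_nonpairs"] = int((~test.y).sum())
    log.info("selection bookkeeping: %s", counts)

    train_subjects = set(train.pairs.loc[train.y, "subject_a"])
    finn_scans = [s for s in cohort_scans if s.subject_id in train_subjects]

    models: dict[str, EdgeModel] = {}
    test_auc: dict[str, float] = {"all_edges": _all_edges_auc(test)}
    for method in config.methods:
        if method == "finn":
            model = finn_rank(finn_scans, top_frac=config.top_frac)
        else:
            model = fit_penalized(train, method=method, alpha=config.alpha,
                                  cv_folds=config.cv_folds, seed=config.seed,
                                  n_lambdas=config.n_lambdas)
        models[method] = model
        _, roc = apply_model(model, test)
        test_auc[method] = roc.auc
        log.info("method %s: %d edges retained, test AUC %.3f",
                 method, model.retained.size, roc.auc)
    return models, test_auc, test, counts


def run_replication_transfer(models: dict[str, EdgeModel],
                             replication_scans: Sequence[ScanRecord],
                             pair_types: Sequence[str] = SELECTION_TYPES,
                             ) -> dict[str, float]:
    """Apply discovery edge models to a replication cohort.

    Each model is scored on the replication cohort's pair set with a freshly
    derived operating threshold; 'all_edges' is the unselected similarity AUC.
    """
    pairs = build_pairs(replication_scans, pair_types)
    fs = pair_features(pairs, replication_scans)
    out = {"all_edges": _all_edges_auc(fs)}
    for method, model in models.items():
        _, roc = apply_model(model, fs)
        out[method] = roc.auc
    return out


def run_study(config: StudyConfig,
              scans: Sequence[ScanRecord] | None = None,
              replication_scans: Sequence[ScanRecord] | None = None) -> StudyReport:
    """Run the complete study.  With no ``scans`` a synthetic cohort is
    generated from the config; the replication cohort defaults to the same
    design with a distinct seed and noisier sessions.
    """
    spec = config.cohort_spec()
    cohort: SyntheticCohort | None = None
    if scans is None:
        cohort = generate_cohort(spec)
        scans = cohort.scans
        log.info("generated cohort: %d subjects, %d scans, %d edges",
                 spec.n_subjects, len(scans), spec.resolve_parcellation().n_edges)

    roc = _roc_by_type(scans, PRIMARY_TYPES)
    delong_ts = _timescale_contrasts(roc)
    delong_groups, group_sizes, group_auc = _group_contrasts(
        scans, PRIMARY_TYPES, config.group_split)

    models, test_auc, _, counts = fit_edge_models(scans, config)

    replication_auc: dict[str, float] = {}
    if config.replication:
        if replication_scans is None:
            rep_spec = replication_spec(spec,
                                        noise_factor=config.replication_noise_factor)
            replication_scans = generate_cohort(rep_spec).scans
        replication_auc = run_replication_transfer(models, replication_scans)
        if config.crossvisit_only_variant:
            xv_models, _, _, _ = fit_edge_models(
                scans, config, pair_types=("X_pre_pre", "X_post_post"))
            xv = run_replication_transfer(xv_models, replication_scans)
            replication_auc.update({f"crossvisit_{k}": v for k, v in xv.items()})

    edge_table = edge_index_table(spec.resolve_parcellation())
    enrichment: dict[str, dict] = {}
    for method, model in models.items():
        suite = enrichment_suite(model.retained, edge_table)
        enrichment[method] = {
            name: {"chi2": t.chi2, "df": t.df, "p": t.p,
                   "flagged": t.flagged()}
            for name, t in suite.items()}

    return StudyReport(roc=roc, delong_timescale=delong_ts,
                       delong_groups=delong_groups, group_sizes=group_sizes,
                       group_auc=group_auc, models=models, test_auc=test_auc,
                       replication_auc=replication_auc,
                       enrichment=enrichment, counts=counts,
                       config=config, seed=config.seed)
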