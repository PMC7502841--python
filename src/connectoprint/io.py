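"""Plain-text readers and writers for scans, manifests and parcellations.

Formats are deliberately simple TSV/CSV/JSON so cohorts round-trip through
the filesystem and user-supplied data can enter the pipeline at either the
time-series or the correlation-matrix stage.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import SyntheticCohort
from .core import (
    ParcellationScheme,
    ScanRecord,
    correlate_timeseries,
    devectorize,
    edge_index_table,
    vectorize,
)

__all__ = [
    "read_parcellation", "write_parcellation",
    "read_matrix", "write_matrix", "read_timeseries", "write_timeseries",
    "write_edge_vector", "read_edge_vector",
    "write_cohort", "load_scans",
]


def write_parcellation(parcellation: ParcellationScheme, path: str | Path) -> None:
    pd.DataFrame({
        "node_id": parcellation.node_ids,
        "network": parcellation.network_labels,
    }).to_csv(path, sep="\t", index=False)


def read_parcellation(path: str | Path, name: str | None = None) -> ParcellationScheme:
    # keep_default_na: a network literally named "None" must stay a string
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"network": str})
    if not {"node_id", "network"} <= set(df.columns):
        raise ValueError("parcellation TSV needs columns node_id, network")
    return ParcellationScheme(tuple(int(n) for n in df["node_id"]),
                              tuple(df["network"]),
                              name=name or Path(path).stem)


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter="\t", fmt="%.10g")


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


write_timeseries = write_matrix
read_timeseries = read_matrix


def write_edge_vector(raw_vector: np.ndarray, edge_table: pd.DataFrame,
                      path: str | Path) -> None:
    out = edge_table[["edge_id", "node_i", "node_j"]].copy()
    out = out.rename(columns={"edge_id": "edge_index"})
    out["value"] = np.asarray(raw_vector)
    out.to_csv(path, sep="\t", index=False)


def read_edge_vector(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.sort_values("edge_index")["value"].to_numpy(dtype=float)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path,
                 fmt: str = "edges") -> Path:
    """Persist a cohort: per-scan files, manifest CSV, parcellation TSV and
    signature-truth JSON.  ``fmt``: 'edges' (edge-vector TSV) or 'matrix'.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    (outdir / "scans").mkdir(parents=True, exist_ok=True)
    edge_table = edge_index_table(cohort.parcellation)
    rows = []
    for scan in cohort.scans:
        rel = Path("scans") / f"{scan.scan_id}.tsv"
        if fmt == "edges":
            write_edge_vector(scan.raw_vector, edge_table, outdir / rel)
        elif fmt == "matrix":
            write_matrix(devectorize(scan.raw_vector, cohort.parcellation.n_nodes),
                         outdir / rel)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        rows.append({"subject_id": scan.subject_id, "visit": scan.visit,
                     "session": scan.session, "age_years": scan.age_years,
                     "sex": scan.sex, "path": str(rel)})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    write_parcellation(cohort.parcellation, outdir / "parcellation.tsv")
    truth = {
        "signature_edges": cohort.truth_edges.tolist(),
        "subjects": cohort.subjects,
        "seed": cohort.spec.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth))
    return manifest


def load_scans(manifest_path: str | Path, fmt: str | None = None) -> list[ScanRecord]:
    """Load scans listed in a manifest CSV.

    Each scan file may be an edge-vector TSV, a node x node matrix TSV, or a
    node x time series TSV (detected by shape unless ``fmt`` is given:
    'edges', 'matrix' or 'timeseries').
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "visit", "session", "path"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    scans = []
    for _, row in df.iterrows():
        path = base / row["path"]
        raw = _load_scan_file(path, fmt)
        scans.append(ScanRecord(
            subject_id=str(row["subject_id"]), visit=int(row["visit"]),
            session=str(row["session"]),
            age_years=float(row.get("age_years", np.nan)),
            sex=str(row.get("sex", "")), raw_vector=raw))
    sizes = {s.n_edges for s in scans}
    if len(sizes) > 1:
        raise ValueError(f"scans disagree on edge count: {sorted(sizes)}")
    return scans


def _load_scan_file(path: Path, fmt: str | None) -> np.ndarray:
    if fmt == "edges":
        return read_edge_vector(path)
    if fmt == "matrix":
        return vectorize(read_matrix(path))
    if fmt == "timeseries":
        return vectorize(correlate_timeseries(read_matrix(path)))
    with open(path) as fh:
        header = fh.readline()
    if header.startswith("edge_index"):
        return read_edge_vector(path)
    m = read_matrix(path)
    if m.shape[0] == m.shape[1] and np.allclose(np.diag(m), 1.0):
        return vectorize(m)
    return vectorize(correlate_timeseries(m))
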