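"""File formats, run configuration, and cohort assembly.

CSV is the canonical interchange format (inspectable at desk scale);
HDF5 is an optional container for timecourses.  All edge files use the
package-wide convention: 0-based node indices, upper triangle, i < j,
lexicographic order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .connectivity import (
    BandSpec,
    CANONICAL_BANDS,
    ConnectivityMatrix,
    NodeTimecourses,
    edge_pairs,
)
from .groupstats import CohortData, EdgeGroupStats, RegressionEdgeStats
from .synthetic import SubjectRecord

__all__ = [
    "SCHEMA_TAG",
    "RunConfig",
    "write_timecourses_csv",
    "read_timecourses_csv",
    "write_timecourses_h5",
    "read_timecourses_h5",
    "write_connectivity",
    "read_connectivity",
    "write_manifest",
    "read_manifest",
    "write_edge_index_list",
    "read_edge_index_list",
    "edge_stats_frame",
    "write_edge_stats",
    "regression_stats_frame",
    "write_feature_table",
    "read_feature_table",
    "write_feature_table_tidy",
    "write_cohort",
    "assemble_cohort",
]

SCHEMA_TAG = "envnet/1"


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every stage parameter of the pipeline, serializable to YAML."""

    # synthetic cohort
    n_per_group: int = 42
    n_nodes: int = 90
    sampling_rate: float = 600.0
    duration: float = 250.0
    baseline_corr: float = 0.3
    baseline_spread: float = 0.5
    affected_edge_count: int = 30
    effect_delta: float = 0.5
    leakage_lambda: float = 0.1
    envelope_bandwidth: float = 0.5
    bands: list[list] = field(
        default_factory=lambda: [
            [b.name, b.f_lo, b.f_hi] for b in CANONICAL_BANDS
        ]
    )
    # connectivity
    filter_order: int = 4
    median_window: float = 0.25
    trim: float = 2.0
    orthogonalize: bool = True
    combine_method: str = "norm"
    # group stats
    rank_fraction: float = 0.20
    alpha: float = 0.05
    n_perm: int = 10_000
    n_iter_split: int = 10_000
    n_iter_regression: int = 1_000
    consistency: float = 0.95
    # graphs
    graph_fraction: float = 0.20
    graph_mode: str = "thresholded"
    # classification
    n_folds: int = 5
    n_reps: int = 100
    n_perm_classifier: int = 5_000
    n_reps_perm: int = 10
    # global
    seed: int = 0

    def band_specs(self) -> list[BandSpec]:
        return [BandSpec(str(n), float(lo), float(hi))
                for n, lo, hi in self.bands]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# --------------------------------------------------------------------------
# Timecourses
# --------------------------------------------------------------------------

def _node_labels(n: int) -> list[str]:
    return [f"node_{k:03d}" for k in range(n)]


def write_timecourses_csv(tc: NodeTimecourses, path: str | Path) -> None:
    pd.DataFrame(tc.data, columns=_node_labels(tc.n_nodes)).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_timecourses_csv(
    path: str | Path,
    fs: float,
    subject_id: str = "",
    band: BandSpec | None = None,
) -> NodeTimecourses:
    df = pd.read_csv(path)
    return NodeTimecourses(subject_id, fs, df.to_numpy(dtype=float),
                           band=band)


def write_timecourses_h5(tc: NodeTimecourses, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=tc.data)
        d.attrs["fs"] = tc.fs
        d.attrs["subject_id"] = tc.subject_id
        if tc.band is not None:
            d.attrs["band_name"] = tc.band.name
            d.attrs["band_edges"] = [tc.band.f_lo, tc.band.f_hi]


def read_timecourses_h5(path: str | Path) -> NodeTimecourses:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["data"]
        band = None
        if "band_name" in d.attrs:
            lo, hi = d.attrs["band_edges"]
            band = BandSpec(str(d.attrs["band_name"]), float(lo),
                            float(hi))
        return NodeTimecourses(
            str(d.attrs["subject_id"]), float(d.attrs["fs"]), d[()],
            band=band,
        )


# --------------------------------------------------------------------------
# Connectivity matrices (CSV matrix + JSON sidecar)
# --------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_connectivity(m: ConnectivityMatrix, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(m.values, columns=_node_labels(m.n_nodes)).to_csv(
        path, index=False, float_format="%.12g"
    )
    band = m.band
    if isinstance(band, BandSpec):
        band = [band.name, band.f_lo, band.f_hi]
    _sidecar(path).write_text(json.dumps({
        "schema": SCHEMA_TAG,
        "subject_id": m.subject_id,
        "band": band,
        "stage": m.stage,
    }, indent=1))


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    values = pd.read_csv(path).to_numpy(dtype=float)
    meta = json.loads(_sidecar(path).read_text())
    band = meta.get("band")
    if isinstance(band, list):
        band = BandSpec(str(band[0]), float(band[1]), float(band[2]))
    return ConnectivityMatrix(meta["subject_id"], band, values,
                              stage=meta["stage"])


# --------------------------------------------------------------------------
# Manifest and ground-truth edges
# --------------------------------------------------------------------------

def write_manifest(manifest: Sequence[dict], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"schema": SCHEMA_TAG, "subjects": list(manifest)},
                   indent=1, ensure_ascii=False)
    )


def read_manifest(path: str | Path) -> list[dict]:
    raw = json.loads(Path(path).read_text())
    return raw["subjects"]


def write_edge_index_list(
    edge_indices: np.ndarray, n_nodes: int, path: str | Path
) -> None:
    """Edge indices -> two-column CSV of 0-based node pairs (i < j)."""
    i, j = edge_pairs(n_nodes)
    pd.DataFrame({
        "node_i": i[edge_indices], "node_j": j[edge_indices]
    }).to_csv(path, index=False)


def read_edge_index_list(path: str | Path, n_nodes: int) -> np.ndarray:
    """Node-pair CSV -> sorted edge indices; rejects i >= j rows."""
    df = pd.read_csv(path)
    ii = df["node_i"].to_numpy(int)
    jj = df["node_j"].to_numpy(int)
    bad = np.nonzero(ii >= jj)[0]
    if bad.size:
        raise ValueError(
            f"{path}: edge convention violated (need node_i < node_j) "
            f"at data line(s) {[int(b) + 2 for b in bad]}"
        )
    if (jj >= n_nodes).any():
        raise ValueError(f"{path}: node index out of range for n={n_nodes}")
    # lexicographic (i, j) -> flat upper-triangle index
    flat = ii * n_nodes - ii * (ii + 1) // 2 + (jj - ii - 1)
    return np.sort(flat)


# --------------------------------------------------------------------------
# Edge statistics tables
# --------------------------------------------------------------------------

def edge_stats_frame(
    stats: EdgeGroupStats, n_nodes: int
) -> pd.DataFrame:
    """Tidy one-row-per-valid-edge table of the group-test results."""
    i, j = edge_pairs(n_nodes)
    idx = stats.edge_indices
    df = pd.DataFrame({
        "node_i": i[idx],
        "node_j": j[idx],
        "t": stats.t,
        "df": stats.df,
        "p": stats.p,
    })
    if stats.omnibus_significant is not None:
        df["omnibus_significant"] = stats.omnibus_significant
    if stats.consistency is not None:
        df["consistency"] = stats.consistency
        df["robust"] = stats.robust
        df["sign"] = stats.sign
    return df


def regression_stats_frame(
    stats: RegressionEdgeStats, n_nodes: int
) -> pd.DataFrame:
    i, j = edge_pairs(n_nodes)
    idx = stats.edge_indices
    df = pd.DataFrame({
        "node_i": i[idx],
        "node_j": j[idx],
        "group_slope": stats.group_slope,
        "consistency": stats.consistency,
        "robust": stats.robust,
        "sign": stats.sign,
    })
    for name, slopes in stats.covariate_slopes.items():
        df[f"slope_{name}"] = slopes
    return df


def write_edge_stats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


# --------------------------------------------------------------------------
# Feature tables
# --------------------------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Wide subject x (metric, node) table -> flat-column CSV."""
    flat = table.copy()
    flat.columns = [f"{m}__{n}" for m, n in table.columns]
    flat.to_csv(path, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    flat = pd.read_csv(path, index_col=0)
    cols = [c.rsplit("__", 1) for c in flat.columns]
    flat.columns = pd.MultiIndex.from_tuples(
        [(m, int(n)) for m, n in cols], names=["metric", "node"]
    )
    flat.index.name = "subject_id"
    return flat


def write_feature_table_tidy(table: pd.DataFrame, path: str | Path) -> None:
    tidy = table.stack(["metric", "node"], future_stack=True)
    tidy.name = "value"
    tidy.reset_index().to_csv(path, index=False, float_format="%.12g")


# --------------------------------------------------------------------------
# Cohort persistence + assembly
# --------------------------------------------------------------------------

def write_cohort(
    subjects: Sequence[SubjectRecord],
    manifest: Sequence[dict],
    affected_edges: np.ndarray,
    outdir: str | Path,
    fmt: str = "csv",
) -> None:
    """Write one file per subject per band plus manifest + ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = [dict(m) for m in manifest]
    by_id = {m["subject_id"]: m for m in manifest}
    for rec in subjects:
        files = {}
        for band_name, tc in rec.timecourses.items():
            fname = f"{rec.subject_id}_{band_name}.{fmt if fmt == 'csv' else 'h5'}"
            if fmt == "csv":
                write_timecourses_csv(tc, outdir / fname)
            elif fmt == "h5":
                write_timecourses_h5(tc, outdir / fname)
            else:
                raise ValueError(f"unknown format {fmt!r}")
            files[band_name] = fname
        by_id[rec.subject_id]["files"] = files
        by_id[rec.subject_id]["sampling_rate"] = rec.timecourses[
            next(iter(rec.timecourses))
        ].fs
    write_manifest(manifest, outdir / "manifest.json")
    n_nodes = subjects[0].timecourses[
        next(iter(subjects[0].timecourses))
    ].n_nodes
    write_edge_index_list(affected_edges, n_nodes,
                          outdir / "affected_edges.csv")


def assemble_cohort(
    maps: Sequence[ConnectivityMatrix],
    manifest: Sequence[dict],
) -> CohortData:
    """Stack per-subject maps into a CohortData, in manifest order."""
    by_id = {m.subject_id: m for m in maps}
    ids, rows, is_case = [], [], []
    age, gender, icv = [], [], []
    have_cov = all(
        all(k in m for k in ("age", "gender", "icv")) for m in manifest
    )
    for m in manifest:
        sid = m["subject_id"]
        if sid not in by_id:
            raise ValueError(f"no connectivity map for subject {sid!r}")
        ids.append(sid)
        rows.append(by_id[sid].edge_vector())
        is_case.append(m["group"] != "control")
        if have_cov:
            age.append(m["age"])
            gender.append(m["gender"])
            icv.append(m["icv"])
    return CohortData(
        subject_ids=ids,
        values=np.array(rows),
        is_case=np.array(is_case),
        age=np.array(age) if have_cov else None,
        gender=np.array(gender) if have_cov else None,
        icv=np.array(icv) if have_cov else None,
    )
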