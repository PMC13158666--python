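"""Data model for 3D spatial single-cell data.

A :class:`TissueSample` wraps a per-molecule transcript table (gene, 3D
position in pre-expansion micrometres, cell assignment, field of view,
optional nuclear/cytoplasmic compartment and bacterial flag) together with
the derived cell-by-gene count matrix and per-cell metadata.  All distance
computations run in full 3D.

Two distance conventions are supported:

* ``boundary`` — the minimal Euclidean distance between any RNA molecule of
  one cell and any RNA molecule of the other (the native convention for
  expansion-sequencing data, where transcript clouds delineate the cell);
* ``centroid`` — the distance between cell centroids, used for
  lower-resolution platforms (MERFISH/Xenium/STARmap style), optionally
  capped (default 145 um, about the diagonal of a 100 um field of view).

Proximity stratification ("proximal" = within <= 1 um boundary distance of
the other type) and neighbour counting (cells of a target type within a
distance cutoff) are built on the same distance primitives.  Thresholds are
inclusive throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

REQUIRED_COLUMNS = ("gene", "x", "y", "z", "cell_id", "fov_id")
COMPARTMENTS = ("nuclear", "cytoplasmic", "unassigned")
CENTROID_PLATFORMS = ("MERFISH", "Xenium", "STARmap")
DEFAULT_DISTANCE_CAP_UM = 145.0
DEFAULT_FOV_SIZE_UM = 100.0
DEFAULT_MIN_TRANSCRIPTS = 50
UNASSIGNED = ""


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class PairNotAnalyzable(RuntimeError):
    """A cell-type pair cannot be analysed (missing type or empty stratum)."""


@dataclass(frozen=True)
class ProximityStratification:
    """Partition of type-i cells into proximal/distant w.r.t. type-ii."""

    type_i: str
    type_ii: str
    threshold_um: float
    proximal_ids: tuple
    distant_ids: tuple

    @property
    def n_proximal(self) -> int:
        return len(self.proximal_ids)

    @property
    def n_distant(self) -> int:
        return len(self.distant_ids)

    @property
    def analyzable(self) -> bool:
        return self.n_proximal >= 1 and self.n_distant >= 1


@dataclass
class TissueSample:
    """A segmented tissue: transcripts, cells, counts and annotations."""

    tissue_id: str
    transcripts: pd.DataFrame  # gene,x,y,z,cell_id,fov_id,compartment,bacterial
    counts: pd.DataFrame  # cells x genes, non-bacterial transcripts only
    cell_meta: pd.DataFrame  # index cell_id: fov_id, type_label, cx, cy, cz, n_transcripts
    platform: str = "synthetic"
    fov_size_um: float = DEFAULT_FOV_SIZE_UM
    expansion_factor: float = 1.0
    distance_cap_um: float | None = None
    _trees: dict = field(default_factory=dict, repr=False)

    @property
    def distance_convention(self) -> str:
        return "centroid" if self.platform in CENTROID_PLATFORMS else "boundary"

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cell_meta.index.to_numpy()

    @property
    def genes(self) -> np.ndarray:
        return self.counts.columns.to_numpy()

    @property
    def cell_types(self) -> list:
        labs = self.cell_meta["type_label"]
        return sorted(set(labs[labs != UNASSIGNED]))

    def cells_of_type(self, type_label: str) -> np.ndarray:
        return self.cell_meta.index[self.cell_meta["type_label"] == type_label].to_numpy()

    def centroids(self, cell_ids=None) -> np.ndarray:
        meta = self.cell_meta if cell_ids is None else self.cell_meta.loc[cell_ids]
        return meta[["cx", "cy", "cz"]].to_numpy()

    def set_type_labels(self, labels: pd.Series | dict) -> None:
        lab = pd.Series(labels)
        self.cell_meta.loc[lab.index, "type_label"] = lab.values

    # -- transcript access -------------------------------------------------
    def cell_points(self, cell_id: str) -> np.ndarray:
        t = self.transcripts
        sub = t[(t["cell_id"] == cell_id) & (~t["bacterial"])]
        return sub[["x", "y", "z"]].to_numpy()

    def _type_point_table(self, type_label: str, fov_id: str | None = None):
        """(points, owning cell ids) of all non-bacterial transcripts of the
        given cell type, optionally restricted to one FOV."""
        cells = set(self.cells_of_type(type_label))
        t = self.transcripts
        mask = t["cell_id"].isin(cells) & (~t["bacterial"])
        if fov_id is not None:
            mask &= t["fov_id"] == fov_id
        sub = t[mask]
        return sub[["x", "y", "z"]].to_numpy(), sub["cell_id"].to_numpy()

    def _tree(self, key, points):
        if key not in self._trees:
            self._trees[key] = cKDTree(points) if len(points) else None
        return self._trees[key]


# -- ingest ----------------------------------------------------------------


def _build_cells(transcripts: pd.DataFrame, tissue_id: str, min_transcripts: int):
    host = transcripts[(~transcripts["bacterial"]) & (transcripts["cell_id"] != UNASSIGNED)]
    n_per_cell = host.groupby("cell_id").size()
    keep = n_per_cell[n_per_cell >= min_transcripts].index
    host = host[host["cell_id"].isin(keep)]
    counts = (
        host.groupby(["cell_id", "gene"]).size().unstack(fill_value=0).sort_index()
    )
    counts.columns.name = None
    counts.index.name = "cell_id"
    cent = host.groupby("cell_id")[["x", "y", "z"]].mean()
    cent.columns = ["cx", "cy", "cz"]
    # FOV of the majority of a cell's transcripts
    fov = (
        host.groupby(["cell_id", "fov_id"]).size().reset_index(name="n")
        .sort_values(["cell_id", "n", "fov_id"], ascending=[True, False, True])
        .drop_duplicates("cell_id").set_index("cell_id")["fov_id"]
    )
    meta = cent.copy()
    meta["fov_id"] = fov
    meta["n_transcripts"] = host.groupby("cell_id").size()
    meta["type_label"] = UNASSIGNED
    meta["tissue_id"] = tissue_id
    return counts, meta.loc[counts.index]


def sample_from_transcripts(
    transcripts: pd.DataFrame,
    tissue_id: str = "tissue",
    platform: str = "synthetic",
    expansion_factor: float = 1.0,
    fov_size_um: float = DEFAULT_FOV_SIZE_UM,
    min_transcripts: int = DEFAULT_MIN_TRANSCRIPTS,
    gene_panel=None,
) -> TissueSample:
    """Build a :class:`TissueSample` from an in-memory transcript table.

    Coordinates are divided by ``expansion_factor`` so that everything
    stored downstream is in pre-expansion micrometres.  Cells with fewer
    than ``min_transcripts`` detected molecules are dropped (quality
    control; configurable).
    """
    t = transcripts.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
    if missing:
        raise SchemaError(f"transcript table missing required column(s): {missing}")
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(t[col], errors="coerce")
        bad = vals.index[~np.isfinite(vals)]
        if len(bad):
            raise SchemaError(f"non-numeric/non-finite coordinate {col!r} at row {bad[0]}")
        t[col] = vals.astype(float) / float(expansion_factor)
    if "compartment" not in t.columns:
        t["compartment"] = "unassigned"
    else:
        bad = set(t["compartment"].unique()) - set(COMPARTMENTS)
        if bad:
            raise SchemaError(f"unknown compartment value(s): {sorted(bad)}")
    if "bacterial" not in t.columns:
        t["bacterial"] = False
    t["bacterial"] = t["bacterial"].astype(bool)
    t["cell_id"] = t["cell_id"].fillna(UNASSIGNED).astype(str)
    t["gene"] = t["gene"].astype(str)
    t["fov_id"] = t["fov_id"].astype(str)
    counts, meta = _build_cells(t, tissue_id, min_transcripts)
    if gene_panel is not None:
        counts = counts.reindex(columns=list(gene_panel), fill_value=0)
    cap = DEFAULT_DISTANCE_CAP_UM if platform in CENTROID_PLATFORMS else None
    return TissueSample(
        tissue_id=tissue_id,
        transcripts=t.reset_index(drop=True),
        counts=counts,
        cell_meta=meta,
        platform=platform,
        fov_size_um=fov_size_um,
        expansion_factor=float(expansion_factor),
        distance_cap_um=cap,
    )


def ingest_transcripts(path, expansion_factor: float = 1.0, platform: str = "ExSeq",
                       tissue_id: str | None = None, **kwargs) -> TissueSample:
    """Read a delimited transcript table (CSV/TSV by extension) into a sample."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep)
    return sample_from_transcripts(
        table,
        tissue_id=tissue_id or path.stem,
        platform=platform,
        expansion_factor=expansion_factor,
        **kwargs,
    )


def write_sample(sample: TissueSample, out_dir, manifest: dict | None = None) -> Path:
    """Serialize a sample to plain-text files (transcripts, counts, annotations)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sample.transcripts.to_csv(out / "transcripts.csv", index=False)
    sample.counts.to_csv(out / "counts.csv")
    ann = sample.cell_meta[["tissue_id", "fov_id", "type_label"]].copy()
    ann.to_csv(out / "annotations.csv")
    info = {
        "tissue_id": sample.tissue_id,
        "platform": sample.platform,
        "fov_size_um": sample.fov_size_um,
        "expansion_factor": sample.expansion_factor,
        "distance_cap_um": sample.distance_cap_um,
    }
    if manifest:
        info["manifest"] = manifest
    (out / "sample.json").write_text(json.dumps(info, indent=1))
    return out


def read_sample(in_dir) -> TissueSample:
    """Load a sample previously written by :func:`write_sample`."""
    ind = Path(in_dir)
    info = json.loads((ind / "sample.json").read_text())
    t = pd.read_csv(ind / "transcripts.csv")
    t["cell_id"] = t["cell_id"].fillna(UNASSIGNED).astype(str)
    t["fov_id"] = t["fov_id"].astype(str)
    t["bacterial"] = t["bacterial"].astype(bool)
    counts = pd.read_csv(ind / "counts.csv", index_col=0)
    counts.index = counts.index.astype(str)
    ann = pd.read_csv(ind / "annotations.csv", index_col=0)
    ann.index = ann.index.astype(str)
    ann["type_label"] = ann["type_label"].fillna(UNASSIGNED).astype(str)
    host = t[(~t["bacterial"]) & (t["cell_id"] != UNASSIGNED)]
    host = host[host["cell_id"].isin(counts.index)]
    cent = host.groupby("cell_id")[["x", "y", "z"]].mean()
    cent.columns = ["cx", "cy", "cz"]
    meta = cent.loc[counts.index].copy()
    meta["fov_id"] = ann["fov_id"]
    meta["n_transcripts"] = host.groupby("cell_id").size().loc[counts.index]
    meta["type_label"] = ann["type_label"]
    meta["tissue_id"] = ann["tissue_id"]
    return TissueSample(
        tissue_id=info["tissue_id"],
        transcripts=t,
        counts=counts,
        cell_meta=meta,
        platform=info["platform"],
        fov_size_um=info["fov_size_um"],
        expansion_factor=info["expansion_factor"],
        distance_cap_um=info["distance_cap_um"],
    )


# -- distances -------------------------------------------------------------


def pair_distance(sample: TissueSample, a: str, b: str, convention: str | None = None) -> float:
    """Distance between two cells under the given convention.

    ``boundary``: minimal Euclidean distance over all 3D transcript pairs.
    ``centroid``: Euclidean distance between centroids.
    """
    if a == b:
        raise ValueError("pair_distance requires two distinct cells")
    convention = convention or sample.distance_convention
    if convention == "centroid":
        ca, cb = sample.centroids([a])[0], sample.centroids([b])[0]
        return float(np.linalg.norm(ca - cb))
    pa, pb = sample.cell_points(a), sample.cell_points(b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("boundary distance requires >= 1 transcript per cell")
    return float(cdist(pa, pb).min())


def _check_type(sample: TissueSample, label: str) -> None:
    if label not in sample.cell_types:
        raise KeyError(
            f"unknown cell type {label!r}; known types: {sample.cell_types}"
        )


def min_distances_to_type(
    sample: TissueSample,
    cell_ids,
    target_type: str,
    scope: str = "tissue",
    convention: str | None = None,
    cap_um: float | None = None,
) -> pd.Series:
    """Minimum distance from each query cell to the nearest target-type cell.

    Vectorised over query cells.  ``scope='same_fov'`` restricts candidate
    targets to the query cell's FOV.  Distances above ``cap_um`` (or with no
    eligible target) come back as NaN.  A query cell that itself has the
    target type is matched against the *other* target cells.
    """
    _check_type(sample, target_type)
    convention = convention or sample.distance_convention
    cell_ids = np.asarray(cell_ids)
    out = pd.Series(np.nan, index=cell_ids, dtype=float)
    fovs = (
        sample.cell_meta.loc[cell_ids, "fov_id"].to_numpy()
        if scope == "same_fov"
        else np.array([None] * len(cell_ids), dtype=object)
    )
    if convention == "centroid":
        targets = sample.cells_of_type(target_type)
        tmeta = sample.cell_meta.loc[targets]
        for fov in set(fovs):
            qmask = fovs == fov
            tsel = tmeta if fov is None else tmeta[tmeta["fov_id"] == fov]
            qids = cell_ids[qmask]
            if len(tsel) == 0:
                continue
            tpts = tsel[["cx", "cy", "cz"]].to_numpy()
            tids = tsel.index.to_numpy()
            tree = cKDTree(tpts)
            qpts = sample.centroids(qids)
            d, j = tree.query(qpts, k=min(2, len(tids)))
            d = np.atleast_2d(d.T).T if d.ndim == 1 else d
            j = np.atleast_2d(j.T).T if j.ndim == 1 else j
            best = np.full(len(qids), np.inf)
            for col in range(d.shape[1]):
                hit_self = tids[j[:, col]] == qids
                cand = np.where(hit_self, np.inf, d[:, col])
                best = np.minimum(best, cand)
            out.loc[qids] = np.where(np.isfinite(best), best, np.nan)
    else:
        for fov in set(fovs):
            qids = cell_ids[fovs == fov]
            tpts, towner = sample._type_point_table(target_type, fov_id=fov)
            if len(tpts) == 0:
                continue
            tree = cKDTree(tpts)
            t = sample.transcripts
            sub = t[t["cell_id"].isin(set(qids)) & (~t["bacterial"])]
            qpts = sub[["x", "y", "z"]].to_numpy()
            qcells = sub["cell_id"].to_numpy()
            if len(qpts) == 0:
                continue
            k = min(2, len(tpts))
            d, j = tree.query(qpts, k=k)
            if k == 1:
                d, j = d[:, None], j[:, None]
            best = np.full(len(qpts), np.inf)
            for col in range(d.shape[1]):
                same_cell = towner[j[:, col]] == qcells
                best = np.minimum(best, np.where(same_cell, np.inf, d[:, col]))
            # exact min over all target transcripts is the 1-NN unless the
            # nearest points belong to the query cell itself (same-type
            # queries); fall back to a filtered query for those points.
            unresolved = ~np.isfinite(best)
            if np.any(unresolved):
                for i in np.flatnonzero(unresolved):
                    mask = towner != qcells[i]
                    if np.any(mask):
                        best[i] = cdist(qpts[i : i + 1], tpts[mask]).min()
            per_cell = pd.Series(best).groupby(qcells).min()
            out.loc[per_cell.index] = per_cell.values
    if cap_um is not None:
        out[out > cap_um] = np.nan
    return out


def min_distance_to_type(
    sample: TissueSample,
    cell_id: str,
    target_type: str,
    scope: str = "tissue",
    cap_um: float | None = None,
    convention: str | None = None,
) -> float | None:
    """Scalar convenience wrapper around :func:`min_distances_to_type`."""
    d = min_distances_to_type(
        sample, [cell_id], target_type, scope=scope, convention=convention, cap_um=cap_um
    ).iloc[0]
    return None if np.isnan(d) else float(d)


def stratify_by_proximity(
    sample: TissueSample,
    type_i: str,
    type_ii: str,
    threshold_um: float = 1.0,
) -> ProximityStratification:
    """Split type-i cells into proximal (<= threshold boundary/centroid
    distance to any type-ii cell, inclusive) and distant."""
    _check_type(sample, type_i)
    _check_type(sample, type_ii)
    cells_i = sample.cells_of_type(type_i)
    d = min_distances_to_type(sample, cells_i, type_ii, scope="tissue",
                              cap_um=sample.distance_cap_um)
    dv = d.to_numpy()
    proximal = cells_i[np.isfinite(dv) & (dv <= threshold_um)]
    distant = cells_i[~(np.isfinite(dv) & (dv <= threshold_um))]
    return ProximityStratification(
        type_i=type_i,
        type_ii=type_ii,
        threshold_um=threshold_um,
        proximal_ids=tuple(proximal),
        distant_ids=tuple(distant),
    )


def count_neighbors(
    sample: TissueSample,
    cell_id: str,
    target_type: str,
    cutoff_um: float,
    convention: str | None = None,
) -> int:
    """Number of target-type cells within ``cutoff_um`` (inclusive); the
    query cell itself never counts."""
    counts = count_neighbors_all(sample, [cell_id], target_type, cutoff_um, convention)
    return int(counts.iloc[0])


def count_neighbors_all(
    sample: TissueSample,
    cell_ids,
    target_type: str,
    cutoff_um: float,
    convention: str | None = None,
) -> pd.Series:
    """Vectorised neighbour counting for many query cells."""
    if cutoff_um <= 0:
        raise ValueError("cutoff must be positive")
    _check_type(sample, target_type)
    convention = convention or sample.distance_convention
    cell_ids = np.asarray(cell_ids)
    out = pd.Series(0, index=cell_ids, dtype=int)
    if convention == "centroid":
        targets = sample.cells_of_type(target_type)
        tree = cKDTree(sample.centroids(targets))
        qpts = sample.centroids(cell_ids)
        hits = tree.query_ball_point(qpts, r=cutoff_um)
        for i, cid in enumerate(cell_ids):
            out.loc[cid] = sum(1 for j in hits[i] if targets[j] != cid)
        return out
    tpts, towner = sample._type_point_table(target_type)
    if len(tpts) == 0:
        return out
    tree = cKDTree(tpts)
    t = sample.transcripts
    sub = t[t["cell_id"].isin(set(cell_ids)) & (~t["bacterial"])]
    qpts = sub[["x", "y", "z"]].to_numpy()
    qcells = sub["cell_id"].to_numpy()
    hits = tree.query_ball_point(qpts, r=cutoff_um)
    found: dict = {cid: set() for cid in cell_ids}
    for i in range(len(qpts)):
        cid = qcells[i]
        if hits[i]:
            found[cid].update(towner[hits[i]])
    for cid in cell_ids:
        found[cid].discard(cid)
        out.loc[cid] = len(found[cid])
    return out
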