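"""Detection of significant bacterial transcript objects in 3D.

16S-barcode reads are clustered with DBSCAN (min_samples = 3, the
neighbourhood count including the point itself) over a grid of radii.
Each candidate cluster's compactness — the sum of all pairwise Euclidean
member distances — is referred to a null of equal-size random draws from
the most frequent host gene's transcripts in the same field of view
(falling back to the whole tissue when the FOV reference is too small);
smaller sums mean tighter objects, so the lower normal tail of the
permuted compactness distribution gives the p-value.  Precision
(significant / detected clusters) and recall (clustered / all bacterial
transcripts) are swept over the radius grid and the F1-maximising radius
selected.  Host cells are then classed as containing ('include'),
touching ('proximal', <= 1 um) or 'distant' from significant bacterial
transcripts, which feeds the shared DE engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN

from .spatial import TissueSample
from .stats import normal_approx_p

DEFAULT_MIN_SAMPLES = 3
DEFAULT_EPS_GRID = tuple(float(e) for e in range(1, 151))


@dataclass
class BacterialObject:
    cluster_id: int
    fov_id: str
    member_index: np.ndarray  # row positions into the bacterial point table
    compactness: float
    p: float
    n_members: int

    @property
    def significant(self) -> bool:
        return self.p <= 0.05


def bacterial_points(sample: TissueSample) -> pd.DataFrame:
    t = sample.transcripts
    return t[t["bacterial"]].reset_index(drop=True)


def dbscan_cluster(points: np.ndarray, epsilon: float,
                   min_samples: int = DEFAULT_MIN_SAMPLES) -> np.ndarray:
    """Density-based clustering of 3D points; -1 labels noise."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=epsilon, min_samples=min_samples).fit(points).labels_


def compactness(points: np.ndarray) -> float:
    """Sum of all pairwise Euclidean distances within a cluster."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(pdist(points).sum())


def host_reference_points(sample: TissueSample, fov_id: str,
                          min_size: int) -> np.ndarray:
    """Transcript positions of the most frequent host gene in the FOV
    (whole-tissue fallback when the FOV reference is smaller than the
    cluster)."""
    t = sample.transcripts
    host = t[(~t["bacterial"])]
    for scope in (host[host["fov_id"] == fov_id], host):
        if len(scope) == 0:
            continue
        gene = scope["gene"].value_counts().index[0]
        pts = scope[scope["gene"] == gene][["x", "y", "z"]].to_numpy()
        if len(pts) >= min_size:
            return pts
    return np.empty((0, 3))


def object_significance(
    cluster_points: np.ndarray,
    reference_points: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
):
    """Lower-tail compactness test against size-matched random reference
    draws.  Returns ``(compactness, p, null_samples)``."""
    m = len(cluster_points)
    if len(reference_points) < m:
        raise ValueError("host reference smaller than the cluster")
    rng = np.random.default_rng(seed)
    obs = compactness(cluster_points)
    idx = np.stack([rng.choice(len(reference_points), size=m, replace=False)
                    for _ in range(n_perm)])
    pts = np.asarray(reference_points, dtype=float)[idx]  # n_perm x m x 3
    iu, ju = np.triu_indices(m, k=1)
    null = np.linalg.norm(pts[:, iu] - pts[:, ju], axis=2).sum(axis=1)
    res = normal_approx_p(obs, null, tail="lower", seed=seed)
    return obs, res.p_one_sided, null


def detect_objects(
    sample: TissueSample,
    epsilon: float,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> list:
    """Cluster the bacterial reads at one radius and test every cluster."""
    bac = bacterial_points(sample)
    pts = bac[["x", "y", "z"]].to_numpy()
    labels = dbscan_cluster(pts, epsilon, min_samples)
    rng = np.random.default_rng(seed)
    objects = []
    for cid in sorted(set(labels) - {-1}):
        members = np.flatnonzero(labels == cid)
        cpts = pts[members]
        fov = bac.iloc[members]["fov_id"].mode().iloc[0]
        ref = host_reference_points(sample, fov, len(members))
        if len(ref) < len(members):
            objects.append(BacterialObject(cid, fov, members,
                                           compactness(cpts), np.nan,
                                           len(members)))
            continue
        obs, p, _ = object_significance(
            cpts, ref, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
        )
        objects.append(BacterialObject(cid, fov, members, obs, p, len(members)))
    return objects


def epsilon_sweep(
    sample: TissueSample,
    eps_grid=DEFAULT_EPS_GRID,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    n_perm: int = 2000,
    seed: int | None = None,
):
    """Sweep the DBSCAN radius, score precision/recall/F1, pick the argmax
    (ties to the smallest radius).

    Returns ``(sweep_df, selected_eps, objects_at_selected)``.
    """
    if len(eps_grid) == 0:
        raise ValueError("empty epsilon grid")
    bac = bacterial_points(sample)
    n_total = len(bac)
    rows = []
    per_eps_objects = {}
    rng = np.random.default_rng(seed)
    for eps in eps_grid:
        objs = detect_objects(sample, eps, min_samples, n_perm=n_perm,
                              seed=int(rng.integers(0, 2**31 - 1)))
        per_eps_objects[eps] = objs
        n_clustered = int(sum(o.n_members for o in objs))
        n_clusters = len(objs)
        n_sig = sum(1 for o in objs if o.significant)
        recall = n_clustered / n_total if n_total else 0.0
        precision = n_sig / n_clusters if n_clusters else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        rows.append({"eps": eps, "n_clustered_transcripts": n_clustered,
                     "recall": recall, "n_clusters": n_clusters,
                     "precision": precision, "f1": f1})
    sweep = pd.DataFrame(rows)
    best = sweep.loc[sweep["f1"].idxmax()]  # idxmax takes the first max
    eps_sel = float(best["eps"])
    return sweep, eps_sel, per_eps_objects[eps_sel]


def classify_cells(
    sample: TissueSample,
    objects,
    threshold_um: float = 1.0,
) -> pd.DataFrame:
    """Host-cell classification relative to significant bacterial reads.

    'include': the cell contains at least one significant bacterial
    transcript.  Containment is decided from the transcript cloud: a
    bacterial read belongs to the cell owning its nearest host transcript,
    provided that transcript lies within the cell's envelope (the per-cell
    95th percentile of transcript distance to centroid).  'proximal': no
    internal reads but a significant bacterial transcript within
    ``threshold_um`` of any of the cell's transcripts; otherwise
    'distant'.
    """
    bac = bacterial_points(sample)
    sig_idx = np.concatenate([o.member_index for o in objects
                              if o.significant]) if objects else np.array([], int)
    meta = sample.cell_meta
    out = pd.DataFrame(index=meta.index)
    out["n_internal_bacterial"] = 0
    out["min_external_bacterial_distance"] = np.nan
    if len(sig_idx) == 0:
        out["bacteria_class"] = "distant"
        return out
    spts = bac.iloc[sig_idx][["x", "y", "z"]].to_numpy()
    t = sample.transcripts
    host = t[(~t["bacterial"]) & t["cell_id"].isin(meta.index)]
    hpts = host[["x", "y", "z"]].to_numpy()
    howner = host["cell_id"].to_numpy()
    tree = cKDTree(hpts)
    # a significant bacterial read is "internal" to the cell owning its
    # nearest host transcript when that transcript is within the cell's
    # envelope; envelope = per-cell 95th percentile of transcript distance
    # to centroid
    cent = meta[["cx", "cy", "cz"]]
    d_cent = np.linalg.norm(
        hpts - cent.loc[howner].to_numpy(), axis=1
    )
    envelope = pd.Series(d_cent).groupby(howner).quantile(0.95)
    d_near, j_near = tree.query(spts, k=1)
    owner = howner[j_near]
    internal = d_near <= envelope.loc[owner].to_numpy()
    internal_counts = pd.Series(owner[internal]).value_counts()
    out.loc[internal_counts.index, "n_internal_bacterial"] = internal_counts.values
    # minimum distance from any transcript of each cell to a significant read
    btree = cKDTree(spts)
    d_b, _ = btree.query(hpts, k=1)
    min_d = pd.Series(d_b).groupby(howner).min()
    out.loc[min_d.index, "min_external_bacterial_distance"] = min_d.values
    cls = np.where(
        out["n_internal_bacterial"] >= 1, "include",
        np.where(out["min_external_bacterial_distance"] <= threshold_um,
                 "proximal", "distant"),
    )
    out["bacteria_class"] = cls
    return out


def bacteria_de(
    sample: TissueSample,
    classes: pd.DataFrame,
    cell_type: str | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """'Include' vs 'distant' differential expression via the shared NB
    engine (optionally within one cell type)."""
    from .de import permutation_de

    ids = classes.index
    if cell_type is not None:
        ids = ids[sample.cell_meta.loc[ids, "type_label"] == cell_type]
    cls = classes.loc[ids, "bacteria_class"]
    use = cls.isin(["include", "distant"])
    ids = ids[use]
    labels = (classes.loc[ids, "bacteria_class"] == "include").to_numpy()
    counts = sample.counts.loc[ids]
    return permutation_de(counts, labels, n_perm=n_perm, seed=seed, **kwargs)
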