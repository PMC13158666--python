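"""Marker-driven consensus cell typing for targeted in-situ count data.

Reference markers come from matched single-cell DE tables, filtered hard
(average log2 fold change > 5, adjusted p <= 1e-200 standing in for
"adjusted p of zero") and de-duplicated: a gene marking several types is
kept only for the sole type where its adjusted p is ~0, otherwise dropped.
Cells are clustered over a grid of (number of PCs, resolution)
combinations — normalise, log-transform, scale, PCA, KNN graph, modularity
community detection — and each cluster is assigned a type only on
unambiguous marker overexpression (one-vs-rest rank-sum, q <= 1e-9, with a
log-ratio dominance rule for competing markers).  Solutions with more than
three inferred types vote; a cell's consensus label must appear in at
least 20% of retained solutions and at least 10 solutions.  A
shuffle-within-gene permutation of the whole pipeline validates that the
number of assignable cells far exceeds chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import PermutationTestResult, bh_adjust, normal_approx_p

MARKER_LOG2FC_MIN = 5.0
P_NEAR_ZERO = 1e-200
ASSIGN_Q_MAX = 1e-9
CONSENSUS_MIN_FRACTION = 0.20
CONSENSUS_MIN_COUNT = 10
MIN_INFERRED_TYPES = 3  # retained solutions need strictly more than this
DEFAULT_PCS_GRID = tuple(range(6, 31, 2))
DEFAULT_RESOLUTION_GRID = tuple(np.round(np.arange(0.2, 2.01, 0.2), 1))
UNASSIGNED = ""


def extract_markers(reference_de: pd.DataFrame,
                    canonical: pd.DataFrame | None = None) -> pd.DataFrame:
    """Filter a reference DE table into a marker panel.

    ``reference_de`` columns: gene, cell_type, avg_log2FC, adjusted_p.
    Entries must pass avg_log2FC > 5 and adjusted_p <= 1e-200; a duplicated
    gene survives only if exactly one of its entries reaches p ~ 0, and
    then only for that type.  ``canonical`` rows (gene, cell_type) are
    appended by union and exempt from the thresholds.
    """
    need = {"gene", "cell_type", "avg_log2FC", "adjusted_p"}
    if not need <= set(reference_de.columns):
        raise ValueError(f"marker table needs columns {sorted(need)}")
    filt = reference_de[
        (reference_de["avg_log2FC"] > MARKER_LOG2FC_MIN)
        & (reference_de["adjusted_p"] <= P_NEAR_ZERO)
    ].copy()
    keep_rows = []
    for gene, sub in reference_de.groupby("gene"):
        in_filtered = filt[filt["gene"] == gene]
        if len(in_filtered) == 0:
            continue
        near_zero = sub[sub["adjusted_p"] <= P_NEAR_ZERO]
        if len(sub["cell_type"].unique()) == 1:
            keep_rows.append(in_filtered.iloc[0])
        elif len(near_zero) == 1:
            row = in_filtered[in_filtered["cell_type"]
                              == near_zero.iloc[0]["cell_type"]]
            if len(row):
                keep_rows.append(row.iloc[0])
        # otherwise: duplicated with ambiguous support -> exclude entirely
    markers = pd.DataFrame(keep_rows).reset_index(drop=True) if keep_rows else \
        pd.DataFrame(columns=list(need))
    markers["provenance"] = "tissue_matched"
    if canonical is not None and len(canonical):
        can = canonical[["gene", "cell_type"]].copy()
        can["avg_log2FC"] = np.nan
        can["adjusted_p"] = np.nan
        can["provenance"] = "canonical"
        can = can[~can["gene"].isin(markers["gene"])]
        markers = pd.concat([markers, can], ignore_index=True)
    return markers


@dataclass
class ClusteringSolution:
    n_pcs: int
    resolution: float
    cluster_of: pd.Series  # cell -> cluster id
    assignment: dict  # cluster id -> type label or UNASSIGNED

    @property
    def n_inferred_types(self) -> int:
        return len({t for t in self.assignment.values() if t != UNASSIGNED})

    @property
    def retained(self) -> bool:
        return self.n_inferred_types > MIN_INFERRED_TYPES

    def cell_labels(self) -> pd.Series:
        return self.cluster_of.map(lambda c: self.assignment.get(c, UNASSIGNED))


def _preprocess(counts: pd.DataFrame, n_pcs_max: int, seed: int):
    import scanpy as sc
    from anndata import AnnData

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ad = AnnData(counts.to_numpy(dtype=np.float32))
        ad.obs_names = counts.index.astype(str)
        ad.var_names = counts.columns.astype(str)
        sc.pp.normalize_total(ad, target_sum=1e4)
        sc.pp.log1p(ad)
        sc.pp.scale(ad, max_value=10)
        n_comp = min(n_pcs_max, min(ad.shape) - 1)
        sc.tl.pca(ad, n_comps=n_comp, svd_solver="arpack", random_state=seed)
    return ad.obsm["X_pca"]


def _graph_communities(pcs: np.ndarray, resolution: float, seed: int,
                       n_neighbors: int = 15) -> np.ndarray:
    """KNN graph + modularity community detection (Leiden with an RB
    configuration partition, the modularity-style objective)."""
    import igraph as ig
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    k = min(n_neighbors, pcs.shape[0] - 1)
    adj = kneighbors_graph(pcs, n_neighbors=k, mode="connectivity")
    sym = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(sym.row, sym.col) if i < j]
    g = ig.Graph(n=pcs.shape[0], edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2,
    )
    return np.asarray(part.membership)


def cluster_counts(counts: pd.DataFrame, n_pcs: int, resolution: float,
                   seed: int) -> pd.Series:
    """One clustering solution's raw labels for a QC-filtered count matrix."""
    pcs = _preprocess(counts, n_pcs, seed)[:, :n_pcs]
    labels = _graph_communities(pcs, resolution, seed)
    return pd.Series(labels, index=counts.index)


def marker_overexpression_q(counts: pd.DataFrame, clusters: pd.Series,
                            marker_genes) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum q-values for marker genes per cluster
    (alternative: greater in-cluster), BH-corrected over the whole
    cluster x marker family."""
    genes = [g for g in marker_genes if g in counts.columns]
    # normalised expression for the test
    depth = counts.sum(axis=1).replace(0, 1)
    norm = counts[genes].div(depth, axis=0) * depth.mean()
    rows = []
    for cl in sorted(clusters.unique()):
        mask = (clusters == cl).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            for g in genes:
                rows.append((cl, g, 1.0))
            continue
        for g in genes:
            a = norm[g].to_numpy()[mask]
            b = norm[g].to_numpy()[~mask]
            if a.max() == a.min() == b.max() == b.min():
                p = 1.0
            else:
                p = sps.mannwhitneyu(a, b, alternative="greater").pvalue
            rows.append((cl, g, float(p)))
    df = pd.DataFrame(rows, columns=["cluster", "gene", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def assign_cluster_types(q_table: pd.DataFrame, markers: pd.DataFrame) -> dict:
    """Cluster -> type assignment from marker q-values.

    Rules, per cluster over its supporting markers (q <= 1e-9):
    a single supporting marker assigns directly; several markers of one
    type assign if the best q passes; markers of different types assign
    only when exactly one reaches q ~ 0, or when the leader dominates
    (log10(q1/q2) < 0.3*log10(q2) and q1 <= 1e-9); two q ~ 0 competitors of
    different types leave the cluster unassigned.
    """
    marker_type = dict(zip(markers["gene"], markers["cell_type"]))
    out = {}
    tiny = 1e-320  # representable floor for log10 of "exact zero" q-values
    for cl, sub in q_table.groupby("cluster"):
        sub = sub[sub["gene"].isin(marker_type)]
        support = sub[sub["q"] <= ASSIGN_Q_MAX].sort_values("q")
        if len(support) == 0:
            out[cl] = UNASSIGNED
            continue
        types = [marker_type[g] for g in support["gene"]]
        if len(set(types)) == 1:
            out[cl] = types[0]
            continue
        qs = support["q"].to_numpy()
        near_zero = qs <= P_NEAR_ZERO
        zero_types = {marker_type[g] for g, z in
                      zip(support["gene"], near_zero) if z}
        if len(zero_types) == 1 and near_zero.any():
            out[cl] = next(iter(zero_types))
            continue
        if len(zero_types) > 1:
            out[cl] = UNASSIGNED
            continue
        # competing markers of different types, none at q ~ 0: the leading
        # marker must dominate the best competitor of a different type
        lead = support.iloc[0]
        lead_type = marker_type[lead["gene"]]
        comp = support[[marker_type[g] != lead_type for g in support["gene"]]]
        q1 = max(float(lead["q"]), tiny)
        q2 = max(float(comp.iloc[0]["q"]), tiny)
        if (np.log10(q1 / q2) < 0.3 * np.log10(q2)) and q1 <= ASSIGN_Q_MAX:
            out[cl] = lead_type
        else:
            out[cl] = UNASSIGNED
    return out


def cluster_parameter_grid(
    counts: pd.DataFrame,
    markers: pd.DataFrame,
    pcs_grid=DEFAULT_PCS_GRID,
    resolution_grid=DEFAULT_RESOLUTION_GRID,
    seed: int = 0,
) -> list:
    """All (n_pcs, resolution) solutions with marker-based assignments.

    Combinations with more PCs than cells are skipped.  Deterministic for
    a fixed seed.
    """
    if len(pcs_grid) == 0 or len(resolution_grid) == 0:
        raise ValueError("parameter grids must be non-empty")
    marker_genes = list(markers["gene"])
    solutions = []
    pcs_cache = _preprocess(counts, max(pcs_grid), seed)
    for n_pcs in pcs_grid:
        if n_pcs >= counts.shape[0] or n_pcs > pcs_cache.shape[1]:
            continue
        for res in resolution_grid:
            labels = pd.Series(
                _graph_communities(pcs_cache[:, :n_pcs], res, seed),
                index=counts.index,
            )
            q_table = marker_overexpression_q(counts, labels, marker_genes)
            assignment = assign_cluster_types(q_table, markers)
            solutions.append(ClusteringSolution(
                n_pcs=n_pcs, resolution=float(res),
                cluster_of=labels, assignment=assignment,
            ))
    return solutions


@dataclass
class ConsensusAnnotation:
    labels: pd.Series  # cell -> final label or UNASSIGNED
    support_fraction: pd.Series
    support_count: pd.Series
    n_retained_solutions: int

    @property
    def n_assigned(self) -> int:
        return int((self.labels != UNASSIGNED).sum())


def consensus_labels(solutions,
                     min_fraction: float = CONSENSUS_MIN_FRACTION,
                     min_count: int = CONSENSUS_MIN_COUNT) -> ConsensusAnnotation:
    """Modal per-cell label over retained solutions, subject to both
    support thresholds (defaults: >= 20% of retained solutions and >= 10
    solutions, sized for a ~200-combination grid); ties break to
    unassigned."""
    retained = [s for s in solutions if s.retained]
    if not retained:
        warnings.warn("no retained clustering solutions; all cells unassigned")
        idx = solutions[0].cluster_of.index if solutions else pd.Index([])
        empty = pd.Series(UNASSIGNED, index=idx)
        zeros = pd.Series(0.0, index=idx)
        return ConsensusAnnotation(empty, zeros, zeros, 0)
    votes = pd.concat([s.cell_labels() for s in retained], axis=1)
    n_ret = len(retained)
    final, frac, cnt = {}, {}, {}
    for cell, row in votes.iterrows():
        counts = row[row != UNASSIGNED].value_counts()
        if len(counts) == 0:
            final[cell], frac[cell], cnt[cell] = UNASSIGNED, 0.0, 0
            continue
        top = counts.iloc[0]
        tied = counts[counts == top]
        if len(tied) > 1:
            final[cell], frac[cell], cnt[cell] = UNASSIGNED, top / n_ret, int(top)
            continue
        label = counts.index[0]
        ok = (top / n_ret >= min_fraction) and (top >= min_count)
        final[cell] = label if ok else UNASSIGNED
        frac[cell], cnt[cell] = top / n_ret, int(top)
    idx = votes.index
    return ConsensusAnnotation(
        labels=pd.Series(final).loc[idx],
        support_fraction=pd.Series(frac).loc[idx],
        support_count=pd.Series(cnt).loc[idx],
        n_retained_solutions=n_ret,
    )


def annotate(counts: pd.DataFrame, markers: pd.DataFrame,
             pcs_grid=DEFAULT_PCS_GRID, resolution_grid=DEFAULT_RESOLUTION_GRID,
             seed: int = 0,
             min_fraction: float = CONSENSUS_MIN_FRACTION,
             min_count: int = CONSENSUS_MIN_COUNT) -> ConsensusAnnotation:
    """Grid clustering + marker assignment + consensus, end to end."""
    sols = cluster_parameter_grid(counts, markers, pcs_grid, resolution_grid, seed)
    return consensus_labels(sols, min_fraction=min_fraction, min_count=min_count)


def shuffle_within_genes(counts: pd.DataFrame,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Permute each gene's counts across cells (per-gene multiset kept)."""
    mat = counts.to_numpy().copy()
    for j in range(mat.shape[1]):
        rng.shuffle(mat[:, j])
    return pd.DataFrame(mat, index=counts.index, columns=counts.columns)


def permutation_validate(
    counts: pd.DataFrame,
    markers: pd.DataFrame,
    pcs_grid=DEFAULT_PCS_GRID,
    resolution_grid=DEFAULT_RESOLUTION_GRID,
    n_perm: int = 20,
    seed: int = 0,
    min_count: int = CONSENSUS_MIN_COUNT,
) -> PermutationTestResult:
    """Shuffle counts within each gene, rerun the full pipeline, and test
    whether the observed number of consensus-labelled cells exceeds the
    shuffled null (upper tail)."""
    rng = np.random.default_rng(seed)
    observed = annotate(counts, markers, pcs_grid, resolution_grid, seed,
                        min_count=min_count).n_assigned
    null = []
    for i in range(n_perm):
        shuf = shuffle_within_genes(counts, rng)
        ann = annotate(shuf, markers, pcs_grid, resolution_grid,
                       seed=int(rng.integers(0, 2**31 - 1)),
                       min_count=min_count)
        null.append(ann.n_assigned)
    return normal_approx_p(observed, null, tail="upper",
                           n_permutations=n_perm, seed=seed)
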