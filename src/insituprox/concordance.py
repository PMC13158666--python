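"""Cross-tissue / cross-platform comparison of proximity programs.

Per-tissue DE p-values for one cell-type pair become row profiles of a
tissue-by-gene matrix: genes are intersected across tissues (expressed
everywhere), exact zero p-values are replaced by 0.8x the global minimum
nonzero p for the cell type, values are -log10-transformed and z-scored
per gene across tissues, and the matrix is projected into PCA space.
Permutation nulls shuffle each gene's values independently across tissues
(preserving gene-wise distributions, destroying tissue structure):
explained-variance significance per PC, and paired / group mean-distance
tests in PC1-PC2 with each permuted axis affinely rescaled (min/max of
the permuted axis mapped onto the observed axis) so distances are
numerically comparable across permutations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import (
    Embedding,
    PermutationTestResult,
    normal_approx_p,
    pca_embed,
    standardize,
)


def build_program_matrix(de_results: dict, expressed: dict | None = None) -> pd.DataFrame:
    """Tissue-by-gene z-scored -log10(p) program matrix.

    ``de_results``: mapping profile name -> DataFrame with a ``p_nominal``
    (or ``p``) column indexed by gene.  ``expressed`` optionally maps
    profile name -> set of genes expressed in that tissue; the matrix keeps
    the intersection over profiles.  Raises when fewer than 3 profiles or
    an empty gene intersection remain.
    """
    if len(de_results) < 3:
        raise ValueError("need >= 3 profiles to build a program matrix")
    pcol = {}
    for name, df in de_results.items():
        col = "p_nominal" if "p_nominal" in df.columns else "p"
        pcol[name] = df[col]
    genes = None
    for name, p in pcol.items():
        g = set(p.index)
        if expressed is not None:
            g &= set(expressed[name])
        genes = g if genes is None else genes & g
    if not genes:
        raise ValueError("empty gene intersection across profiles")
    genes = sorted(genes)
    mat = pd.DataFrame({name: p.loc[genes] for name, p in pcol.items()}).T
    vals = mat.to_numpy(dtype=float)
    nonzero_min = vals[vals > 0].min() if np.any(vals > 0) else 1.0
    vals = np.where(vals == 0.0, 0.8 * nonzero_min, vals)
    neglog = -np.log10(vals)
    z, kept = standardize(neglog)
    return pd.DataFrame(z, index=mat.index, columns=np.array(genes)[kept])


def _shuffle_columns(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(z)
    n = z.shape[0]
    for j in range(z.shape[1]):
        out[:, j] = z[rng.permutation(n), j]
    return out


def embedding_significance(
    matrix: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    n_components: int = 2,
) -> pd.DataFrame:
    """Permutation p per PC for the explained-variance fraction (upper
    tail), shuffling each gene independently across tissues."""
    z = matrix.to_numpy(dtype=float)
    emb = pca_embed(z, n_components=n_components)
    k = emb.component_count
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, k))
    for i in range(n_perm):
        perm = _shuffle_columns(z, rng)
        null[i] = pca_embed(perm, n_components=k).explained_variance_fraction
    rows = []
    for c in range(k):
        res = normal_approx_p(emb.explained_variance_fraction[c], null[:, c],
                              tail="upper", n_permutations=n_perm, seed=seed)
        rows.append({"component": f"PC{c + 1}",
                     "explained_variance_fraction":
                         float(emb.explained_variance_fraction[c]),
                     "p": res.p_one_sided, "z": res.z})
    return pd.DataFrame(rows)


def _affine_rescale(perm_axis: np.ndarray, obs_axis: np.ndarray) -> np.ndarray:
    """Map the permuted axis's [min, max] onto the observed axis's
    [min, max]; degenerate permuted axes collapse to the observed
    midpoint."""
    pmin, pmax = perm_axis.min(), perm_axis.max()
    omin, omax = obs_axis.min(), obs_axis.max()
    if pmax == pmin:
        return np.full_like(perm_axis, 0.5 * (omin + omax))
    return (perm_axis - pmin) / (pmax - pmin) * (omax - omin) + omin


def _pc12(z: np.ndarray) -> np.ndarray:
    return pca_embed(z, n_components=2).scores


def paired_or_group_distance_test(
    matrix: pd.DataFrame,
    pairs: list | None = None,
    group: list | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Closeness of paired or grouped profiles in PC1-PC2.

    ``pairs``: list of (row_a, row_b) names — statistic is the mean paired
    Euclidean distance.  ``group``: list of row names — statistic is the
    mean pairwise distance within the group.  The null shuffles each gene
    across tissues, re-standardises, re-projects, affinely rescales each
    permuted PC axis onto the observed axis and recomputes the statistic;
    p is the lower tail (closer than chance).
    """
    if (pairs is None) == (group is None):
        raise ValueError("provide exactly one of pairs= or group=")
    names = list(matrix.index)
    if pairs is not None:
        for a, b in pairs:
            if a not in names or b not in names:
                raise KeyError(f"pairing id {a!r}/{b!r} not in the matrix rows")
        idx = [(names.index(a), names.index(b)) for a, b in pairs]
    else:
        if len(group) < 2:
            raise ValueError("group mode needs >= 2 members")
        gidx = [names.index(g) for g in group]
        idx = [(a, b) for i, a in enumerate(gidx) for b in gidx[i + 1:]]
    z = matrix.to_numpy(dtype=float)
    obs_scores = _pc12(z)

    def statistic(scores):
        return float(np.mean([
            np.linalg.norm(scores[a] - scores[b]) for a, b in idx
        ]))

    obs = statistic(obs_scores)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = _shuffle_columns(z, rng)
        perm, _ = standardize(perm)
        ps = _pc12(perm)
        ps = np.column_stack([
            _affine_rescale(ps[:, c], obs_scores[:, c]) for c in range(2)
        ])
        null[i] = statistic(ps)
    return normal_approx_p(obs, null, tail="lower", n_permutations=n_perm,
                           seed=seed)


def program_embedding(matrix: pd.DataFrame, n_components: int = 2) -> Embedding:
    """PCA of a built program matrix (already z-scored per gene)."""
    return pca_embed(matrix.to_numpy(dtype=float), n_components=n_components)
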