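"""Within-cell-type variability explained by proximity to another type.

For a (tissue, type-i, type-ii) pair, type-i cells are z-scored, embedded
by PCA, and stratified by boundary-distance proximity to type-ii.  Two
statistics are computed in PC1-PC2:

* single-centroid dispersion — the summed Euclidean distance of proximal
  cells from the centroid of *all* type-i cells;
* two-centroid separation — the distance between the proximal and distant
  subgroup centroids.

Both are z-scored against a label-shuffling null that preserves the
proximal subset size, combined as Z_max = max(z_single, z_two) (the two
measures are correlated, so the max is taken rather than both tested), and
the observed Z_max is referred to the normal fit of the per-permutation
Z_max null.  The proximity contribution to variance is the ratio of
proximal to total dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spatial import ProximityStratification, TissueSample, stratify_by_proximity
from .stats import bh_adjust, binomial_tail, normal_approx_p, standardize_and_embed

MIN_CELLS_FOR_EMBEDDING = 3


@dataclass
class DispersionResult:
    tissue_id: str
    type_i: str
    type_ii: str
    n_proximal: int
    n_distant: int
    dispersion_proximal: float
    dispersion_total: float
    centroid_separation: float
    z_single: float
    z_two: float
    z_max: float
    p: float
    q: float = np.nan

    @property
    def variance_contribution(self) -> float:
        if self.dispersion_total == 0:
            return 0.0
        return self.dispersion_proximal / self.dispersion_total

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "tissue_id", "type_i", "type_ii", "n_proximal", "n_distant",
            "dispersion_proximal", "dispersion_total", "centroid_separation",
            "z_single", "z_two", "z_max", "p", "q")}
        d["variance_contribution"] = self.variance_contribution
        return d


def pair_embedding(sample: TissueSample, type_i: str,
                   exclude_genes=()) -> tuple[np.ndarray, np.ndarray]:
    """PC1-PC2 scores of z-scored type-i expression.

    ``exclude_genes`` supports the segmentation-artefact sensitivity mode:
    markers of the neighbouring type can be dropped before the embedding.
    """
    cells = sample.cells_of_type(type_i)
    counts = sample.counts.loc[cells]
    if exclude_genes:
        counts = counts.drop(columns=[g for g in exclude_genes
                                      if g in counts.columns])
    # genes undetected in this cell type carry no information and would
    # only trigger the zero-variance warning in the standardiser
    counts = counts.loc[:, counts.std() > 0]
    emb = standardize_and_embed(counts.to_numpy(), n_components=2)
    return emb.scores, cells


def dispersion_statistics(scores: np.ndarray, proximal_mask: np.ndarray):
    """(dispersion_proximal, dispersion_total, centroid_separation) in the
    PC1-PC2 plane; the reference centroid is the mean of all cells."""
    centroid = scores.mean(axis=0)
    dists = np.linalg.norm(scores - centroid, axis=1)
    disp_prox = float(dists[proximal_mask].sum())
    disp_total = float(dists.sum())
    if proximal_mask.all() or (~proximal_mask).all():
        sep = 0.0
    else:
        sep = float(np.linalg.norm(
            scores[proximal_mask].mean(axis=0) - scores[~proximal_mask].mean(axis=0)
        ))
    return disp_prox, disp_total, sep


def _null_statistics(scores: np.ndarray, k: int, n_perm: int,
                     rng: np.random.Generator):
    """Vectorised label-shuffling null preserving the proximal size k.

    Returns (disp_null, sep_null) arrays of length n_perm.
    """
    n = scores.shape[0]
    centroid = scores.mean(axis=0)
    d = np.linalg.norm(scores - centroid, axis=1)
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    disp_null = d[idx].sum(axis=1)
    sum_all = scores.sum(axis=0)
    sum_prox = scores[idx].sum(axis=1)  # n_perm x 2
    mean_prox = sum_prox / k
    mean_dist = (sum_all - sum_prox) / (n - k)
    sep_null = np.linalg.norm(mean_prox - mean_dist, axis=1)
    return disp_null, sep_null


def combined_proximity_test(
    scores: np.ndarray,
    stratification: ProximityStratification,
    cell_order,
    n_perm: int = 10_000,
    seed: int | None = None,
    tissue_id: str = "",
) -> DispersionResult:
    """Z_max permutation test for one (tissue, pair).

    Within each permutation both statistics are computed and z-scored
    against the full permuted distributions; the per-permutation maxima
    form the null to which the observed Z_max is referred (upper normal
    tail).
    """
    order = pd.Index(cell_order)
    prox_mask = np.asarray(order.isin(stratification.proximal_ids))
    k = int(prox_mask.sum())
    n = len(order)
    if k < 1 or n - k < 1 or n < MIN_CELLS_FOR_EMBEDDING:
        raise ValueError("pair not analyzable: need >=1 proximal, >=1 distant, >=3 cells")
    rng = np.random.default_rng(seed)
    disp_obs, disp_total, sep_obs = dispersion_statistics(scores, prox_mask)
    disp_null, sep_null = _null_statistics(scores, k, n_perm, rng)
    mu_d, sd_d = disp_null.mean(), disp_null.std(ddof=1)
    mu_s, sd_s = sep_null.mean(), sep_null.std(ddof=1)
    z_single = (disp_obs - mu_d) / sd_d if sd_d > 0 else 0.0
    z_two = (sep_obs - mu_s) / sd_s if sd_s > 0 else 0.0
    z_null_d = (disp_null - mu_d) / sd_d if sd_d > 0 else np.zeros(n_perm)
    z_null_s = (sep_null - mu_s) / sd_s if sd_s > 0 else np.zeros(n_perm)
    zmax_null = np.maximum(z_null_d, z_null_s)
    z_max = float(max(z_single, z_two))
    res = normal_approx_p(z_max, zmax_null, tail="upper",
                          n_permutations=n_perm, seed=seed)
    return DispersionResult(
        tissue_id=tissue_id,
        type_i=stratification.type_i,
        type_ii=stratification.type_ii,
        n_proximal=k,
        n_distant=n - k,
        dispersion_proximal=disp_obs,
        dispersion_total=disp_total,
        centroid_separation=sep_obs,
        z_single=float(z_single),
        z_two=float(z_two),
        z_max=z_max,
        p=res.p_one_sided,
    )


def run_pair(sample: TissueSample, type_i: str, type_ii: str,
             threshold_um: float = 1.0, n_perm: int = 10_000,
             seed: int | None = None, exclude_genes=()) -> DispersionResult:
    """Stratify, embed and test one cell-type pair in one tissue."""
    strat = stratify_by_proximity(sample, type_i, type_ii, threshold_um)
    if not strat.analyzable:
        raise ValueError(f"pair ({type_i}, {type_ii}) has an empty stratum")
    scores, cells = pair_embedding(sample, type_i, exclude_genes=exclude_genes)
    return combined_proximity_test(scores, strat, cells, n_perm=n_perm,
                                   seed=seed, tissue_id=sample.tissue_id)


def run_all_pairs(samples, threshold_um: float = 1.0, n_perm: int = 10_000,
                  seed: int | None = None) -> pd.DataFrame:
    """All ordered type pairs across tissues, BH-corrected jointly.

    Unanalyzable pairs (absent type, empty stratum, too few cells) are
    skipped.  Returns a DataFrame of DispersionResult rows with q filled.
    """
    if isinstance(samples, TissueSample):
        samples = [samples]
    rng = np.random.default_rng(seed)
    results = []
    for s in samples:
        types = s.cell_types
        for ti in types:
            if len(s.cells_of_type(ti)) < MIN_CELLS_FOR_EMBEDDING:
                continue
            scores, cells = pair_embedding(s, ti)
            for tj in types:
                if ti == tj:
                    continue
                strat = stratify_by_proximity(s, ti, tj, threshold_um)
                if not strat.analyzable:
                    continue
                sub_seed = int(rng.integers(0, 2**31 - 1))
                results.append(combined_proximity_test(
                    scores, strat, cells, n_perm=n_perm, seed=sub_seed,
                    tissue_id=s.tissue_id,
                ))
    if not results:
        return pd.DataFrame()
    df = pd.DataFrame([r.to_dict() for r in results])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def significance_enrichment(observed_significant: int, n_tested: int,
                            shuffled_significant: int) -> float:
    """Exact binomial tail for the observed number of significant pairs
    given the chance rate estimated from a shuffled control.

    A shuffled count of zero is floored at 0.5 to keep the chance rate
    positive (with a warning-free conservative convention).
    """
    if observed_significant > n_tested or shuffled_significant > n_tested:
        raise ValueError("counts cannot exceed the number of tested pairs")
    rate = max(shuffled_significant, 0.5) / n_tested
    return binomial_tail(observed_significant, n_tested, rate)


def shuffled_control(samples, threshold_um: float = 1.0, n_perm: int = 2000,
                     seed: int | None = None) -> pd.DataFrame:
    """Rerun the full pair analysis with proximal/distant labels shuffled
    once per pair; the q<=0.05 count estimates the chance rate."""
    if isinstance(samples, TissueSample):
        samples = [samples]
    rng = np.random.default_rng(seed)
    results = []
    for s in samples:
        types = s.cell_types
        for ti in types:
            if len(s.cells_of_type(ti)) < MIN_CELLS_FOR_EMBEDDING:
                continue
            scores, cells = pair_embedding(s, ti)
            for tj in types:
                if ti == tj:
                    continue
                strat = stratify_by_proximity(s, ti, tj, threshold_um)
                if not strat.analyzable:
                    continue
                # shuffle: draw a random proximal subset of the same size
                perm = rng.permutation(len(cells))
                k = strat.n_proximal
                shuffled = ProximityStratification(
                    type_i=ti, type_ii=tj, threshold_um=threshold_um,
                    proximal_ids=tuple(np.asarray(cells)[perm[:k]]),
                    distant_ids=tuple(np.asarray(cells)[perm[k:]]),
                )
                sub_seed = int(rng.integers(0, 2**31 - 1))
                results.append(combined_proximity_test(
                    scores, shuffled, cells, n_perm=n_perm, seed=sub_seed,
                    tissue_id=s.tissue_id,
                ))
    if not results:
        return pd.DataFrame()
    df = pd.DataFrame([r.to_dict() for r in results])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df
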