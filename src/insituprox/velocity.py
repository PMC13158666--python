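"""Spatial RNA velocity from nuclear/cytoplasmic compartment counts.

Nuclear reads stand in for unspliced (u) and cytoplasmic reads for spliced
(s) abundance.  The steady-state model v = u - gamma*s gives a per-gene
degradation rate gamma, fitted as the origin-constrained least-squares
slope of u on s over the extreme total-expression quantiles of
KNN-smoothed counts.  Future states S(T) = S(0) + v*T (floored at 0) are
projected into the PCA axes of the current normalised states, yielding a
per-cell magnitude (displacement length in PC1-PC2), a current-state
magnitude (distance from the origin) and a phase (displacement angle).
These responses are then correlated with the minimum physical distance to
other cell types under a distance-shuffling permutation null.

Note the steady-state fit direction: the velocity equation v = u - gamma*s
requires gamma to carry units of u per s, so u is regressed on s through
the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .spatial import TissueSample, min_distances_to_type
from .stats import bh_adjust, correlation_with_permutation, pca_embed, pearson_r

DEFAULT_K = 30
DEFAULT_QUANTILE = 0.075
DEFAULT_T = 3.0
DEFAULT_EXPRESSION_CUTOFF = 0.038


def compartment_counts(sample: TissueSample):
    """Split the count matrix by subcellular compartment.

    Returns ``(u, s)``: nuclear and cytoplasmic cells x genes count frames
    over the sample's cells and gene panel (bacterial reads excluded,
    compartment-unassigned reads ignored).
    """
    t = sample.transcripts
    host = t[(~t["bacterial"]) & t["cell_id"].isin(sample.cell_meta.index)]
    out = {}
    for comp in ("nuclear", "cytoplasmic"):
        sub = host[host["compartment"] == comp]
        mat = sub.groupby(["cell_id", "gene"]).size().unstack(fill_value=0)
        mat = mat.reindex(index=sample.cell_meta.index,
                          columns=sample.counts.columns, fill_value=0)
        out[comp] = mat.astype(float)
    return out["nuclear"], out["cytoplasmic"]


def normalize_cytoplasmic(s: pd.DataFrame) -> pd.DataFrame:
    """Depth normalisation: each cell's cytoplasmic vector is scaled by
    (global mean total) / (cell total)."""
    tot = s.sum(axis=1)
    tot = tot.replace(0, np.nan)
    scale = tot.mean() / tot
    return s.mul(scale.fillna(0.0), axis=0)


def normalize_and_smooth(u: pd.DataFrame, s: pd.DataFrame, K: int = DEFAULT_K):
    """KNN smoothing of compartment counts in expression space.

    Neighbours are found in the first three PCs of the normalised
    cytoplasmic matrix; each cell's u and s vectors are replaced by the
    mean over itself and its K nearest neighbours.  K is reduced (with the
    reduction recorded in ``attrs``) when fewer than K+1 cells exist.
    """
    n = u.shape[0]
    if K >= n:
        K = max(0, n - 1)
    s_norm = normalize_cytoplasmic(s)
    if K == 0:
        u_sm, s_sm = u.astype(float).copy(), s.astype(float).copy()
    else:
        z = s_norm.to_numpy()
        z = z - z.mean(axis=0)
        emb = pca_embed(z, n_components=min(3, min(z.shape) - 1) or 1)
        nn = NearestNeighbors(n_neighbors=K + 1).fit(emb.scores)
        _, idx = nn.kneighbors(emb.scores)
        u_sm = pd.DataFrame(u.to_numpy()[idx].mean(axis=1), index=u.index,
                            columns=u.columns)
        s_sm = pd.DataFrame(s.to_numpy()[idx].mean(axis=1), index=s.index,
                            columns=s.columns)
    u_sm.attrs["K"] = K
    return u_sm, s_sm, s_norm


@dataclass
class VelocityModel:
    gamma: pd.Series  # per-gene degradation rate
    reliable: pd.Series  # per-gene flag
    K: int = DEFAULT_K
    quantile_fraction: float = DEFAULT_QUANTILE
    T: float = DEFAULT_T
    expression_cutoff: float = DEFAULT_EXPRESSION_CUTOFF

    @property
    def reliable_genes(self) -> list:
        return list(self.reliable.index[self.reliable])


def _max_normalized_expression(u: pd.DataFrame, s: pd.DataFrame) -> pd.Series:
    """Per-gene max (over cells and compartments) of the within-cell
    expression fraction; the reliability cutoff is applied to this scale."""
    fracs = []
    for mat in (u, s):
        tot = mat.sum(axis=1).replace(0, np.nan)
        fracs.append(mat.div(tot, axis=0).max().fillna(0.0))
    return pd.concat(fracs, axis=1).max(axis=1)


def fit_gamma(
    u_sm: pd.DataFrame,
    s_sm: pd.DataFrame,
    quantile_fraction: float = DEFAULT_QUANTILE,
    expression_cutoff: float = DEFAULT_EXPRESSION_CUTOFF,
    K: int = DEFAULT_K,
    T: float = DEFAULT_T,
) -> VelocityModel:
    """Per-gene steady-state degradation rates.

    For each gene, cells in the top and bottom ``quantile_fraction`` of
    total (u + s) expression anchor the steady-state line; gamma is the
    least-squares slope of u on s through the origin over that subset.
    All-zero genes get gamma 0 and are flagged unreliable.
    """
    gam = {}
    un = u_sm.to_numpy()
    sn = s_sm.to_numpy()
    tot = un + sn
    n = un.shape[0]
    k = max(1, int(round(quantile_fraction * n)))
    for j, gene in enumerate(u_sm.columns):
        t = tot[:, j]
        if t.sum() == 0:
            gam[gene] = 0.0
            continue
        order = np.argsort(t, kind="mergesort")
        sel = np.concatenate([order[:k], order[-k:]])
        ss = sn[sel, j]
        uu = un[sel, j]
        denom = (ss**2).sum()
        gam[gene] = float((uu * ss).sum() / denom) if denom > 0 else 0.0
    gamma = pd.Series(gam, index=u_sm.columns)
    maxexpr = _max_normalized_expression(u_sm, s_sm)
    reliable = (maxexpr >= expression_cutoff) & (u_sm.sum() + s_sm.sum() > 0)
    return VelocityModel(gamma=gamma, reliable=reliable, K=K,
                         quantile_fraction=quantile_fraction, T=T,
                         expression_cutoff=expression_cutoff)


@dataclass
class StateChange:
    """Per-cell displacement between current and predicted future state."""

    magnitude_future: pd.Series
    magnitude_current: pd.Series
    phase: pd.Series  # radians in (-pi, pi]
    scores_current: np.ndarray = dc_field(default=None, repr=False)
    scores_future: np.ndarray = dc_field(default=None, repr=False)
    velocities: pd.DataFrame = dc_field(default=None, repr=False)


def compute_future_states(
    model: VelocityModel,
    u_sm: pd.DataFrame,
    s_sm: pd.DataFrame,
    T: float | None = None,
    max_total_deviation: float = 0.10,
) -> StateChange:
    """Project current and future states and measure displacement.

    v = u - gamma*s over reliable genes; S(T) = S(0) + v*T floored at 0.
    Cells whose total future expression deviates by more than 10% from the
    current total are counted; if every cell violates the constraint the
    chosen T is rejected.  Both matrices are scaled by their mean totals,
    PCA axes are fit on the current normalised states, and future states
    are projected into those fixed axes.
    """
    T = model.T if T is None else T
    genes = model.reliable_genes
    if not genes:
        raise ValueError("no reliable genes; lower the expression cutoff")
    u = u_sm[genes].to_numpy()
    s = s_sm[genes].to_numpy()
    gam = model.gamma[genes].to_numpy()
    v = u - gam[None, :] * s
    s_t = np.maximum(s + v * T, 0.0)
    tot0 = s.sum(axis=1)
    tot_t = s_t.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.abs(tot_t - tot0) / np.where(tot0 > 0, tot0, np.nan)
    violations = int(np.nansum(dev > max_total_deviation))
    if violations == len(tot0):
        raise ValueError(
            f"all cells violate the {max_total_deviation:.0%} total-expression "
            f"constraint at T={T}; use a smaller time step"
        )
    s0n = s / max(tot0.mean(), 1e-12)
    stn = s_t / max(tot_t.mean(), 1e-12)
    centre = s0n.mean(axis=0)
    emb = pca_embed(s0n - centre, n_components=2)
    cur = emb.scores
    fut = (stn - centre) @ emb.components.T
    disp = fut - cur
    mag_future = np.linalg.norm(disp, axis=1)
    mag_current = np.linalg.norm(cur, axis=1)
    phase = np.arctan2(disp[:, 1], disp[:, 0])
    idx = u_sm.index
    sc = StateChange(
        magnitude_future=pd.Series(mag_future, index=idx),
        magnitude_current=pd.Series(mag_current, index=idx),
        phase=pd.Series(phase, index=idx),
        scores_current=cur,
        scores_future=fut,
        velocities=pd.DataFrame(v, index=idx, columns=genes),
    )
    sc.magnitude_future.attrs["n_deviation_violations"] = violations
    return sc


def _circular_linear_r(theta: np.ndarray, x: np.ndarray) -> float:
    """Circular-linear correlation of an angle with a linear covariate."""
    rc = pearson_r(np.cos(theta), x)
    rs = pearson_r(np.sin(theta), x)
    rcs = pearson_r(np.cos(theta), np.sin(theta))
    denom = 1.0 - rcs**2
    if denom <= 0:
        return 0.0
    val = (rc**2 + rs**2 - 2.0 * rc * rs * rcs) / denom
    return float(np.sqrt(max(val, 0.0)))


def distance_state_correlations(
    state: StateChange,
    sample: TissueSample,
    primary_type: str,
    neighbor_type: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Correlate state-change responses with distance to a neighbour type.

    Magnitudes use Pearson correlation with a distance-shuffling null
    (two-sided); the phase uses a circular-linear correlation with the same
    null (upper tail, since the statistic is non-negative).
    """
    cells = sample.cells_of_type(primary_type)
    cells = [c for c in cells if c in state.magnitude_future.index]
    d = min_distances_to_type(sample, cells, neighbor_type).dropna()
    if len(d) < 3:
        raise ValueError("need >= 3 primary cells with a defined distance")
    x = d.to_numpy()
    rows = []
    rng = np.random.default_rng(seed)
    for name, series in (("magnitude_future", state.magnitude_future),
                         ("magnitude_current", state.magnitude_current)):
        y = series.loc[d.index].to_numpy()
        if y.std() == 0 or x.std() == 0:
            continue
        r, res = correlation_with_permutation(
            x, y, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)),
            alternative="two-sided",
        )
        rows.append({"response": name, "r": r, "p": res.p_one_sided,
                     "z": res.z, "n": len(d)})
    theta = state.phase.loc[d.index].to_numpy()
    if x.std() > 0:
        r_obs = _circular_linear_r(theta, x)
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = _circular_linear_r(theta, rng.permutation(x))
        from .stats import normal_approx_p

        res = normal_approx_p(r_obs, null, tail="upper")
        rows.append({"response": "phase", "r": r_obs, "p": res.p_one_sided,
                     "z": res.z, "n": len(d)})
    out = pd.DataFrame(rows)
    out.insert(0, "neighbor_type", neighbor_type)
    out.insert(0, "primary_type", primary_type)
    out.insert(0, "tissue_id", sample.tissue_id)
    return out


def gene_velocity_correlations(
    velocities: pd.DataFrame,
    distances: pd.Series,
    reference_detection: pd.Series | None = None,
    min_detect_frac: float = 0.20,
    exception_genes=(),
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of velocity with distance, BH within
    the pair.

    ``reference_detection`` maps gene -> fraction of matched reference
    single cells detecting it; genes under ``min_detect_frac`` are excluded
    unless listed in ``exception_genes``.  Constant-velocity genes are
    dropped with a flag.
    """
    common = velocities.index.intersection(distances.dropna().index)
    v = velocities.loc[common]
    x = distances.loc[common].to_numpy(dtype=float)
    genes = list(v.columns)
    if reference_detection is not None:
        genes = [g for g in genes
                 if g in exception_genes
                 or reference_detection.get(g, 0.0) >= min_detect_frac]
    rng = np.random.default_rng(seed)
    rows, dropped = [], []
    for g in genes:
        y = v[g].to_numpy(dtype=float)
        if y.std() == 0 or x.std() == 0:
            dropped.append(g)
            continue
        r, res = correlation_with_permutation(
            x, y, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)),
            alternative="two-sided",
        )
        rows.append({"gene": g, "r": r, "p": res.p_one_sided, "n": len(common)})
    out = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["r", "p", "n"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    out.attrs["dropped_constant"] = dropped
    return out


def run_velocity(
    sample: TissueSample,
    K: int = DEFAULT_K,
    quantile_fraction: float = DEFAULT_QUANTILE,
    T: float = DEFAULT_T,
    expression_cutoff: float = DEFAULT_EXPRESSION_CUTOFF,
):
    """Compartment split -> smoothing -> gamma fit -> future states."""
    u, s = compartment_counts(sample)
    u_sm, s_sm, _ = normalize_and_smooth(u, s, K=K)
    model = fit_gamma(u_sm, s_sm, quantile_fraction=quantile_fraction,
                      expression_cutoff=expression_cutoff,
                      K=u_sm.attrs.get("K", K), T=T)
    state = compute_future_states(model, u_sm, s_sm, T=T)
    return model, state
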