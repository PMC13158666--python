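"""Synthetic 3D tissues with planted spatial-transcriptional effects.

The generator emulates a targeted in-situ panel experiment: cells scattered
in a 3D slab, tiled into 100x100 um fields of view, each cell a Gaussian
cloud of transcript molecules whose gene identities are drawn from a
negative-binomial count model over a ~300-gene panel.  Ground truth for
every planted effect (proximity shift, distance-linear response,
neighbour-count response, triplet modulation, velocity, bacterial objects)
is returned alongside the sample so each analysis module can be tested for
recovery and calibration without any external data.

Planting happens in two passes: the bulk of the panel is drawn and placed
first, the spatial covariates (boundary distances, neighbour counts,
proximity / triplet conditions) are *measured* on those molecules through
the same code paths the analysis uses, and only then are the planted genes'
counts drawn from means that depend on the measured covariates.  Effects
therefore live on the same distance scale the analysis sees, and all
negative-binomial assumptions hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .spatial import (
    TissueSample,
    count_neighbors_all,
    min_distances_to_type,
    sample_from_transcripts,
)

DEFAULT_PANEL_SIZE = 299
DEFAULT_TYPES = {"tumor": 0.4, "T_cell": 0.2, "B_cell": 0.15,
                 "macrophage": 0.15, "endothelial": 0.1}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic tissue.

    Defaults emulate a targeted 299-gene panel with roughly 170 detected
    molecules per cell, five cell types, 100 um FOV tiling and a packing
    density at which a realistic fraction of cell pairs are in soma-soma
    contact (boundary distance <= 1 um).
    """

    n_cells: int = 600
    extent_um: tuple = (300.0, 300.0, 30.0)
    fov_size_um: float = 100.0
    cell_radius_um: float = 3.0
    type_proportions: dict = dc_field(default_factory=lambda: dict(DEFAULT_TYPES))
    n_genes: int = DEFAULT_PANEL_SIZE
    mean_transcripts_per_cell: float = 170.0
    nb_dispersion: float = 0.3
    cell_size_sigma: float = 0.25  # lognormal spread of per-cell depth
    marker_genes_per_type: int = 3
    marker_boost: float = 30.0
    nuclear_fraction: float = 0.25
    qc_min_transcripts: int = 50
    effects: list = dc_field(default_factory=list)

    @property
    def panel(self) -> list:
        return [f"G{i:03d}" for i in range(1, self.n_genes + 1)]

    def validate(self) -> None:
        props = np.array(list(self.type_proportions.values()))
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("type proportions must sum to 1")
        if np.any(props <= 0) or self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("all rates/sizes must be positive")
        panel = set(self.panel)
        for eff in self.effects:
            for g in effect_genes(eff):
                if g not in panel:
                    raise ValueError(f"planted effect names gene {g!r} outside the panel")


def effect_genes(effect: dict) -> list:
    g = effect.get("genes", effect.get("gene"))
    if g is None:
        return []
    return list(g) if isinstance(g, (list, tuple)) else [g]


def _nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """Gamma-Poisson draw: NB with Var = m + dispersion * m^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros_like(mean)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out.astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean[pos] * dispersion)
    out[pos] = rng.poisson(lam)
    return out.astype(np.int64)


def baseline_means(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-type per-gene NB mean vectors (types x genes).

    A shared lognormal expression backbone plus a few strongly boosted
    marker genes per type, rescaled so each type's means sum to the target
    molecules-per-cell.
    """
    genes = config.panel
    types = list(config.type_proportions)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    rows = {}
    marker_of = {}
    gi = 0
    for t in types:
        m = base.copy()
        idx = np.arange(gi, gi + config.marker_genes_per_type) % config.n_genes
        m[idx] = m[idx] * config.marker_boost + np.percentile(base, 90) * config.marker_boost
        marker_of[t] = [genes[i] for i in idx]
        gi += config.marker_genes_per_type
        rows[t] = m / m.sum() * config.mean_transcripts_per_cell
    df = pd.DataFrame(rows, index=genes).T
    df.attrs["markers"] = marker_of
    return df


def _place_cells(config: SimulationConfig, rng: np.random.Generator):
    ex, ey, ez = config.extent_um
    centers = rng.uniform([0, 0, 0], [ex, ey, ez], size=(config.n_cells, 3))
    types = list(config.type_proportions)
    probs = np.array([config.type_proportions[t] for t in types])
    labels = rng.choice(types, size=config.n_cells, p=probs)
    return centers, labels


def _transcript_rows(rng, cell_ids, centers, counts: pd.DataFrame, radius, fov,
                     compartment=None, nuclear_fraction=0.25):
    """Expand a count matrix into placed transcript molecules."""
    genes = counts.columns.to_numpy()
    mat = counts.to_numpy()
    per_cell_tot = mat.sum(axis=1)
    cell_rep = np.repeat(np.arange(len(cell_ids)), per_cell_tot)
    gene_rep = np.concatenate([np.repeat(genes, row) for row in mat]) if mat.size else np.array([], dtype=object)
    pos = centers[cell_rep] + rng.normal(0.0, radius, size=(len(cell_rep), 3))
    fov_id = (np.floor(pos[:, 0] / fov).astype(int).astype(str) + "_"
              + np.floor(pos[:, 1] / fov).astype(int).astype(str))
    if compartment is None:
        comp = np.where(rng.random(len(cell_rep)) < nuclear_fraction,
                        "nuclear", "cytoplasmic")
    else:
        comp = np.full(len(cell_rep), compartment)
    return pd.DataFrame({
        "gene": gene_rep,
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "cell_id": np.asarray(cell_ids)[cell_rep],
        "fov_id": fov_id,
        "compartment": comp,
        "bacterial": False,
    })


def _nb_sd(mean, dispersion):
    return np.sqrt(mean + dispersion * mean**2)


def _planted_means(effect, base_mean, cells, provisional, config, truth):
    """Per-cell mean vector for one planted gene under one effect."""
    kind = effect["kind"]
    mean = np.full(len(cells), base_mean, dtype=float)
    order = pd.Index(cells)
    if kind == "proximity_shift":
        strat = provisional["strat"][(effect["type_i"], effect["type_ii"])]
        prox = order.isin(strat.proximal_ids)
        delta = effect["delta_sd"] * _nb_sd(base_mean, config.nb_dispersion)
        mean[prox] = mean[prox] + delta
        truth["n_proximal"] = int(prox.sum())
    elif kind == "distance_linear":
        d = provisional["dist"][(effect["type_x"], effect["type_y"])].reindex(order)
        is_x = provisional["labels"].reindex(order) == effect["type_x"]
        valid = is_x & d.notna()
        mean[valid.to_numpy()] = np.maximum(
            0.0, effect["a"] + effect["b"] * d[valid].to_numpy()
        )
        truth["n_with_distance"] = int(valid.sum())
        truth["planted_distances"] = {c: float(v) for c, v in d[valid].items()}
    elif kind == "neighbor_linear":
        cnt = provisional["ncount"][(effect["type_x"], effect["type_y"])].reindex(order)
        is_x = (provisional["labels"].reindex(order) == effect["type_x"]).to_numpy()
        mean[is_x] = np.maximum(
            0.0, effect["a"] + effect["b"] * cnt[is_x].to_numpy()
        )
        truth["n_primary"] = int(is_x.sum())
    elif kind == "triplet":
        cond1, cond2 = provisional["triplet"][
            (effect["type_a"], effect["type_b"], effect["type_c"])
        ]
        in2 = order.isin(cond2)
        mean[in2] = mean[in2] * effect["factor"]
        truth["n_condition1"], truth["n_condition2"] = len(cond1), len(cond2)
    elif kind == "bacteria":
        hosts = provisional["bacteria_hosts"]
        inh = order.isin(hosts)
        mean[inh] = mean[inh] * effect["factor"]
        truth["n_host_cells"] = int(inh.sum())
    else:
        raise ValueError(f"unknown planted effect kind {kind!r}")
    return mean


def generate_tissue(config: SimulationConfig, seed: int, tissue_id: str = "sim"):
    """Generate one synthetic tissue.

    Returns ``(TissueSample, truth)`` where ``truth`` records cell types,
    planted-effect parameters and the measured covariates they were planted
    on.  Deterministic given ``(config, seed)``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    centers, labels = _place_cells(config, rng)
    cell_ids = np.array([f"c{i:05d}" for i in range(config.n_cells)])
    means = baseline_means(config, rng)

    planted = {}
    for eff in config.effects:
        for g in effect_genes(eff):
            if g in planted:
                raise ValueError(f"conflicting planted effects on gene {g}")
            planted[g] = eff

    # pass 1: background genes
    bg_genes = [g for g in config.panel if g not in planted]
    size_factor = rng.lognormal(0.0, config.cell_size_sigma, size=config.n_cells)
    mean_mat = means.loc[labels, bg_genes].to_numpy() * size_factor[:, None]
    counts_bg = pd.DataFrame(
        _nb_draw(rng, mean_mat, config.nb_dispersion), index=cell_ids, columns=bg_genes
    )
    tr_bg = _transcript_rows(rng, cell_ids, centers, counts_bg,
                             config.cell_radius_um, config.fov_size_um,
                             nuclear_fraction=config.nuclear_fraction)

    truth: dict = {
        "seed": seed,
        "cell_types": dict(zip(cell_ids, labels)),
        "markers": means.attrs.get("markers", {}),
        "baseline_means": {t: means.loc[t].to_dict() for t in means.index},
        "effects": [],
        "bacteria": None,
    }

    bacteria_df, bacteria_truth, bacteria_hosts = _plant_bacteria_points(
        config, rng, centers, labels, cell_ids
    )
    if bacteria_truth is not None:
        truth["bacteria"] = bacteria_truth

    if planted:
        provisional = _measure_covariates(
            config, tr_bg, cell_ids, labels, bacteria_hosts, tissue_id
        )
        extra_counts = {}
        for eff in config.effects:
            if eff["kind"] in ("velocity", "bacteria_points"):
                continue
            for g in effect_genes(eff):
                eff_truth = dict(eff)
                # effects may pin the gene's baseline mean; otherwise the
                # panel backbone mean for that gene is used
                base_mean = float(eff.get("base_mean",
                                          np.mean(means.loc[labels, g].to_numpy())))
                percell = _planted_means(eff, base_mean, cell_ids, provisional,
                                         config, eff_truth)
                extra_counts[g] = _nb_draw(rng, percell * 1.0, config.nb_dispersion)
                truth["effects"].append(eff_truth)
        if extra_counts:
            counts_pl = pd.DataFrame(extra_counts, index=cell_ids)
            # planted molecules sit deeper in the cell body (half spread):
            # the spatial covariates were measured on the background cloud,
            # and molecules near the centre never set the boundary minima,
            # so planting does not disturb the geometry it conditioned on
            tr_pl = _transcript_rows(rng, cell_ids, centers, counts_pl,
                                     0.5 * config.cell_radius_um,
                                     config.fov_size_um,
                                     nuclear_fraction=config.nuclear_fraction)
            tr_bg = pd.concat([tr_bg, tr_pl], ignore_index=True)

    if bacteria_df is not None:
        tr_bg = pd.concat([tr_bg, bacteria_df], ignore_index=True)

    sample = sample_from_transcripts(
        tr_bg, tissue_id=tissue_id, platform="synthetic",
        fov_size_um=config.fov_size_um,
        min_transcripts=config.qc_min_transcripts,
        gene_panel=config.panel,
    )
    lab = pd.Series(labels, index=cell_ids)
    sample.set_type_labels(lab.loc[lab.index.intersection(sample.cell_meta.index)])
    truth["cell_types"] = {c: t for c, t in truth["cell_types"].items()
                           if c in sample.cell_meta.index}
    return sample, truth


def _measure_covariates(config, transcripts, cell_ids, labels, bacteria_hosts, tissue_id):
    """Measure spatial covariates on the pass-1 molecules via the analysis
    code paths themselves."""
    prov_sample = sample_from_transcripts(
        transcripts, tissue_id=tissue_id, platform="synthetic",
        fov_size_um=config.fov_size_um, min_transcripts=1,
    )
    prov_sample.set_type_labels(pd.Series(labels, index=cell_ids))
    out = {"labels": pd.Series(labels, index=cell_ids), "strat": {}, "dist": {},
           "ncount": {}, "triplet": {}, "bacteria_hosts": bacteria_hosts}
    from .spatial import stratify_by_proximity  # local import to avoid cycle noise

    for eff in config.effects:
        kind = eff["kind"]
        if kind == "proximity_shift":
            key = (eff["type_i"], eff["type_ii"])
            if key not in out["strat"]:
                out["strat"][key] = stratify_by_proximity(
                    prov_sample, *key, threshold_um=eff.get("threshold_um", 1.0)
                )
        elif kind == "distance_linear":
            key = (eff["type_x"], eff["type_y"])
            if key not in out["dist"]:
                xs = prov_sample.cells_of_type(eff["type_x"])
                out["dist"][key] = min_distances_to_type(
                    prov_sample, xs, eff["type_y"], scope="same_fov"
                )
        elif kind == "neighbor_linear":
            key = (eff["type_x"], eff["type_y"])
            if key not in out["ncount"]:
                xs = prov_sample.cells_of_type(eff["type_x"])
                out["ncount"][key] = count_neighbors_all(
                    prov_sample, xs, eff["type_y"], eff.get("cutoff_um", 15.0)
                )
        elif kind == "triplet":
            key = (eff["type_a"], eff["type_b"], eff["type_c"])
            if key not in out["triplet"]:
                thr = eff.get("threshold_um", 1.0)
                a_cells = prov_sample.cells_of_type(eff["type_a"])
                db = min_distances_to_type(prov_sample, a_cells, eff["type_b"])
                dc = min_distances_to_type(prov_sample, a_cells, eff["type_c"])
                near_b = db.notna() & (db <= thr)
                near_c = dc.notna() & (dc <= thr)
                cond1 = tuple(a_cells[(near_b & ~near_c).to_numpy()])
                cond2 = tuple(a_cells[(near_b & near_c).to_numpy()])
                out["triplet"][key] = (cond1, cond2)
    return out


# -- bacteria --------------------------------------------------------------


def _plant_bacteria_points(config, rng, centers, labels, cell_ids):
    spec = next((e for e in config.effects if e["kind"] == "bacteria_points"), None)
    if spec is None:
        return None, None, np.array([], dtype=object)
    n_clusters = spec.get("n_clusters", 0)
    scale = spec.get("cluster_scale_um", 1.0)
    size = spec.get("cluster_size", 12)
    n_noise = spec.get("n_noise", 0)
    ex, ey, ez = config.extent_um
    rows, members, hosts = [], [], []
    if n_clusters > 0:
        host_type = spec.get("host_type")
        eligible = (np.flatnonzero(labels == host_type)
                    if host_type else np.arange(len(cell_ids)))
        if len(eligible) < n_clusters:
            raise ValueError("fewer eligible host cells than clusters")
        host_idx = rng.choice(eligible, size=n_clusters, replace=False)
        for k, hi in enumerate(host_idx):
            c = centers[hi]
            pts = c + rng.normal(0.0, scale, size=(size, 3))
            rows.append(pts)
            members.append(np.full(size, k))
            hosts.append(cell_ids[hi])
    if n_noise > 0:
        rows.append(rng.uniform([0, 0, 0], [ex, ey, ez], size=(n_noise, 3)))
        members.append(np.full(n_noise, -1))
    pts = np.vstack(rows) if rows else np.empty((0, 3))
    member = np.concatenate(members) if members else np.array([], dtype=int)
    fov_id = (np.floor(pts[:, 0] / config.fov_size_um).astype(int).astype(str) + "_"
              + np.floor(pts[:, 1] / config.fov_size_um).astype(int).astype(str))
    df = pd.DataFrame({
        "gene": "16S",
        "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
        "cell_id": "",
        "fov_id": fov_id,
        "compartment": "unassigned",
        "bacterial": True,
    })
    t = {"n_clusters": n_clusters, "cluster_scale_um": scale,
         "cluster_size": size, "n_noise": n_noise,
         "membership": member.tolist(), "host_cells": list(hosts)}
    return df, t, np.array(hosts, dtype=object)


# -- velocity --------------------------------------------------------------


def generate_compartment_counts(
    n_cells: int,
    gamma: dict,
    seed: int,
    base_mean: float = 20.0,
    cell_size_sigma: float = 0.6,
    induced_fraction: float = 0.0,
    induction_factor: float = 2.5,
    n_background_genes: int = 20,
):
    """Nuclear (u) and cytoplasmic (s) count matrices with known per-gene
    degradation rates.

    Steady-state cells satisfy E[u | s] = gamma * s (u drawn Poisson around
    the steady-state line); an ``induced_fraction`` of cells has nuclear
    counts inflated by ``induction_factor`` so their velocity v = u - gamma*s
    is positive.  Cell-to-cell depth varies lognormally so the extreme
    total-expression quantiles used for the fit are well populated.

    Returns ``(u_df, s_df, truth)``.
    """
    rng = np.random.default_rng(seed)
    genes = list(gamma) + [f"BG{i:02d}" for i in range(n_background_genes)]
    gammas = {g: gamma.get(g, float(rng.uniform(0.3, 1.5))) for g in genes}
    depth = rng.lognormal(0.0, cell_size_sigma, size=n_cells)
    cells = [f"c{i:05d}" for i in range(n_cells)]
    induced = rng.random(n_cells) < induced_fraction
    u = {}
    s = {}
    for g in genes:
        s_mean = base_mean * depth
        s_g = rng.poisson(s_mean)
        u_mean = gammas[g] * s_g.astype(float)
        u_mean[induced] *= induction_factor
        u[g] = rng.poisson(u_mean)
        s[g] = s_g
    u_df = pd.DataFrame(u, index=cells)
    s_df = pd.DataFrame(s, index=cells)
    truth = {"gamma": gammas, "induced": dict(zip(cells, induced.tolist()))}
    return u_df, s_df, truth


def plant_velocity_tissue(
    config: SimulationConfig,
    gamma: dict,
    seed: int,
    induced_types: tuple = (),
    induced_rule: dict | None = None,
    induction_factor: float = 2.5,
    tissue_id: str = "sim-velocity",
):
    """Full spatial tissue whose nuclear/cytoplasmic split follows the
    steady-state velocity model with the given per-gene degradation rates.

    Induced cells get inflated nuclear counts (positive velocity).  They
    are selected either wholesale by type (``induced_types``) or by a
    spatial rule ``induced_rule = {"type_x", "near_type", "threshold_um"}``
    — type-X cells within the boundary-distance threshold of the neighbour
    type, measured on the placed cytoplasmic molecules, so that the
    magnitude of predicted state change correlates with proximity.
    Compartment labels are written onto the transcripts.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    centers, labels = _place_cells(config, rng)
    cell_ids = np.array([f"c{i:05d}" for i in range(config.n_cells)])
    means = baseline_means(config, rng)
    size_factor = rng.lognormal(0.0, config.cell_size_sigma, size=config.n_cells)
    s_mean = means.loc[labels, config.panel].to_numpy() * size_factor[:, None]
    s_counts = _nb_draw(rng, s_mean, config.nb_dispersion)
    s_df = pd.DataFrame(s_counts, index=cell_ids, columns=config.panel)
    tr_s = _transcript_rows(rng, cell_ids, centers, s_df, config.cell_radius_um,
                            config.fov_size_um, compartment="cytoplasmic")
    induced = np.isin(labels, list(induced_types))
    if induced_rule is not None:
        prov = sample_from_transcripts(
            tr_s, tissue_id=tissue_id, platform="synthetic",
            fov_size_um=config.fov_size_um, min_transcripts=1,
        )
        prov.set_type_labels(pd.Series(labels, index=cell_ids))
        xs = prov.cells_of_type(induced_rule["type_x"])
        d = min_distances_to_type(prov, xs, induced_rule["near_type"])
        near = set(d.index[(d.notna())
                           & (d <= induced_rule.get("threshold_um", 15.0))])
        induced |= np.isin(cell_ids, list(near))
        # induction is a cell state, not only a dynamic: induced cells also
        # up-shift the cytoplasmic expression of a gene subset, so that
        # expression-space neighbourhoods (used for count smoothing) keep
        # induced and uninduced cells apart
        shift = induced_rule.get("state_shift", 0.5)
        if shift > 0 and induced.any():
            n_shift = max(1, config.n_genes // 3)
            shift_genes = config.panel[:n_shift]
            extra_mean = s_mean[np.ix_(induced, np.arange(n_shift))] * shift
            extra = _nb_draw(rng, extra_mean, config.nb_dispersion)
            extra_df = pd.DataFrame(extra, index=cell_ids[induced],
                                    columns=shift_genes)
            tr_extra = _transcript_rows(
                rng, cell_ids[induced], centers[induced], extra_df,
                config.cell_radius_um, config.fov_size_um,
                compartment="cytoplasmic",
            )
            tr_s = pd.concat([tr_s, tr_extra], ignore_index=True)
            s_counts[np.ix_(induced, np.arange(n_shift))] += extra
            s_df = pd.DataFrame(s_counts, index=cell_ids, columns=config.panel)
    gam = np.array([gamma.get(g, 0.5) for g in config.panel])
    u_mean = s_counts * gam[None, :]
    u_mean[induced] *= induction_factor
    u_counts = rng.poisson(u_mean)
    u_df = pd.DataFrame(u_counts, index=cell_ids, columns=config.panel)
    tr_u = _transcript_rows(rng, cell_ids, centers, u_df, config.cell_radius_um,
                            config.fov_size_um, compartment="nuclear")
    tr = pd.concat([tr_s, tr_u], ignore_index=True)
    sample = sample_from_transcripts(
        tr, tissue_id=tissue_id, platform="synthetic",
        fov_size_um=config.fov_size_um,
        min_transcripts=config.qc_min_transcripts, gene_panel=config.panel,
    )
    lab = pd.Series(labels, index=cell_ids)
    sample.set_type_labels(lab.loc[lab.index.intersection(sample.cell_meta.index)])
    truth = {"gamma": dict(zip(config.panel, gam.tolist())),
             "induced_types": list(induced_types),
             "induced_cells": cell_ids[induced].tolist(),
             "induction_factor": induction_factor}
    return sample, truth


def generate_cohort(config: SimulationConfig, n_tissues: int, seed: int,
                    prefix: str = "sim"):
    """A list of (sample, truth) pairs with per-tissue derived seeds."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_tissues)
    return [
        generate_tissue(config, int(s), tissue_id=f"{prefix}{i:02d}")
        for i, s in enumerate(seeds)
    ]
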