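# insituprox

Quantifying how 3D spatial context shapes single-cell transcriptional
states in targeted in-situ spatial transcriptomics data.

Targeted in-situ platforms (expansion sequencing, MERFISH, Xenium,
STARmap) measure a few hundred genes per cell while preserving the 3D
positions of individual RNA molecules. `insituprox` asks what a cell's
*neighbourhood* does to its expression program, at single-cell resolution
and in full 3D, through seven connected analyses:

1. **Proximity dispersion** — how much of the within-cell-type spread in
   expression PCA space is explained by contact (boundary distance
   ≤ 1 µm) with another cell type, tested with a combined statistic
   `Z_max = max(Z_single-centroid, Z_two-centroid)` against a
   label-shuffling null that preserves the proximal subset size.
2. **Proximity differential expression** — negative-binomial Wald tests
   (median-of-ratios size factors, trended dispersion shrinkage) between
   proximal and distant cells, wrapped in a 1000-fold label-permutation
   empirical p-value; cross-tissue overlaps of the resulting gene sets are
   tested by gene-set resampling.
3. **Program concordance** — per-tissue DE p-value profiles become
   z-scored −log10(p) matrices projected into PCA space; paired
   (cross-platform) and grouped (clinical-subtype) distances are tested
   against per-gene shuffling nulls with affine axis rescaling.
4. **Spatial RNA velocity** — nuclear reads proxy unspliced (u) and
   cytoplasmic reads spliced (s) abundance; per-gene degradation rates γ
   come from the steady-state model v = u − γs fitted on extreme
   total-expression quantiles of KNN-smoothed counts; the magnitude and
   phase of predicted state change S(T) = S(0) + vT are correlated with
   distance to other cell types.
5. **Distance response** — per-gene linear regression of raw counts on
   the minimal distance to the nearest cell of another type (FOV-scoped
   boundary distances, or centroid distances capped at 145 µm), with a
   shuffled-distance R² control, a Gaussian-smoothing robustness filter
   (σ = 5 in rank units) and an eight-feature composite rank score.
6. **Neighbour response** — expression as a linear function of the number
   of neighbouring cells within a cutoff (10/15/20 µm), de-biased against
   the zero-inflated neighbour-count distribution by 1000 rounds of
   balanced bin sampling, with WLS and line-aggregation cross-checks and
   a consensus gene set.
7. **Microbial niches** — 16S transcript positions are clustered by
   DBSCAN over a radius sweep; each candidate object's compactness (sum of
   pairwise member distances) is tested against size-matched draws from
   the most abundant host gene in the same FOV; host cells are classed as
   containing / proximal to / distant from significant objects and fed to
   the shared DE engine.

Every statistical procedure is backed by a synthetic-tissue generator
(`insituprox.simulate`) that plants known effects — proximity state
shifts, distance and neighbour-count slopes, triplet modulations,
velocity rates, bacterial clusters — on measured spatial covariates, so
calibration and recovery are testable end to end without any external
download.

## Worked example

```python
from insituprox.simulate import SimulationConfig, generate_tissue
from insituprox import dispersion, distance

cfg = SimulationConfig(n_cells=600, n_genes=60, effects=[
    {"kind": "distance_linear", "type_x": "tumor", "type_y": "T_cell",
     "gene": "G050", "a": 10.0, "b": -0.33},
])
sample, truth = generate_tissue(cfg, seed=11)

rec = distance.run_pair(sample, "tumor", "T_cell", n_perm=100, seed=3)
print(rec.loc["G050", ["slope", "r2", "q", "gaussian_r2", "reported"]])
```

prints

```
slope         -0.232333
r2             0.046586
q               0.00305
gaussian_r2    0.390501
reported          False
```

The generator planted expression in tumour cells as
`mean = max(0, 10 − 0.33·d)` where `d` is the boundary distance to the
nearest T cell in the same field of view.  The regression recovers a
negative slope of about −0.23 with a globally FDR-adjusted q of 0.003; at
this particular seed the Gaussian-smoothed refit (R² = 0.39) falls below
the 0.5 robustness threshold so the record is not reported — across seeds
the planted gene passes the filter in the large majority of runs (see
`tests/test_distance.py`).

The same sample drives the proximity-dispersion test:

```python
res = dispersion.run_pair(sample, "tumor", "T_cell", n_perm=2000, seed=1)
print(f"z_max={res.z_max:.2f}  p={res.p:.3f}  "
      f"variance_contribution={res.variance_contribution:.2f}")
```

```
z_max=1.64  p=0.107  variance_contribution=0.34
```

— no proximity-linked *state* was planted here, so the dispersion test
correctly stays null while the distance-linear gene is found by the
regression module.

A shell interface mirrors the library
(`insituprox simulate|ingest|celltype|dispersion|proxde|triplets|distresp|neighbors|velocity|microbes`);
every command writes plain CSV/JSON outputs plus a `manifest.json` with
the seed and parameters.

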