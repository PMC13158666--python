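"""Distance-response regression: preparation, gene filters, permuted-R2
control, Gaussian-smoothing robustness filter and composite ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from insituprox.distance import (
    composite_score,
    distance_regression,
    filter_genes,
    prepare_distance_table,
    run_cohort,
    run_pair,
    smooth_and_filter,
)
from insituprox.simulate import SimulationConfig, generate_tissue


@pytest.fixture(scope="module")
def planted_distance_tissue():
    cfg = SimulationConfig(n_cells=600, n_genes=60, effects=[
        {"kind": "distance_linear", "type_x": "tumor", "type_y": "T_cell",
         "gene": "G050", "a": 10.0, "b": -0.33}])
    return generate_tissue(cfg, seed=301)


class TestPrepare:
    def test_cells_without_fov_neighbor_excluded(self):
        from insituprox.spatial import sample_from_transcripts

        rows = [("g1", 5, 5, 0, "x1", "f0"), ("g2", 6, 5, 0, "y1", "f0"),
                ("g1", 205, 5, 0, "x2", "f2")]
        df = pd.DataFrame(rows, columns=["gene", "x", "y", "z",
                                         "cell_id", "fov_id"])
        s = sample_from_transcripts(df, min_transcripts=1)
        s.set_type_labels(pd.Series({"x1": "X", "x2": "X", "y1": "Y"}))
        expr, d = prepare_distance_table(s, "X", "Y")
        assert list(d.index) == ["x1"]

    def test_centroid_cap_excludes_far_cells(self):
        from insituprox.spatial import sample_from_transcripts

        rows = [("g1", 0, 0, 0, "x1", "f0"), ("g1", 100, 0, 0, "x2", "f1"),
                ("g2", 10, 0, 0, "y1", "f0")]
        df = pd.DataFrame(rows, columns=["gene", "x", "y", "z",
                                         "cell_id", "fov_id"])
        s = sample_from_transcripts(df, min_transcripts=1, platform="MERFISH")
        s.set_type_labels(pd.Series({"x1": "X", "x2": "X", "y1": "Y"}))
        s.distance_cap_um = 50.0
        expr, d = prepare_distance_table(s, "X", "Y")
        assert list(d.index) == ["x1"]

    def test_distances_match_oracle(self, planted_distance_tissue):
        from insituprox.spatial import min_distances_to_type

        sample, _ = planted_distance_tissue
        _, d = prepare_distance_table(sample, "tumor", "T_cell")
        oracle = min_distances_to_type(
            sample, sample.cells_of_type("tumor"), "T_cell", scope="same_fov"
        ).dropna()
        pd.testing.assert_series_equal(d, oracle)


class TestFilterGenes:
    def _expr(self, p98_vals, detect_counts, n=200):
        rng = np.random.default_rng(0)
        cols = {}
        for i, (p98, det) in enumerate(zip(p98_vals, detect_counts)):
            v = np.zeros(n)
            v[:det] = p98
            cols[f"g{i}"] = v
        return pd.DataFrame(cols)

    def test_p98_boundary(self):
        expr = self._expr([10, 11], [100, 100])
        assert filter_genes(expr) == ["g1"]  # p98 == 10 is excluded

    def test_detection_boundary(self):
        expr = self._expr([20, 20], [20, 21])
        assert filter_genes(expr) == ["g1"]  # detected in exactly 20 excluded

    def test_retained_requires_failing_both_exclusions(self):
        expr = self._expr([11, 9, 30], [21, 300, 15])
        assert filter_genes(expr) == ["g0"]


class TestDistanceRegression:
    def test_constant_expression_has_zero_slope(self, rng):
        d = pd.Series(rng.uniform(0, 20, 50), index=range(50))
        expr = pd.DataFrame({"g": np.full(50, 3.0)}, index=range(50))
        rec = distance_regression(expr, d, n_perm=10, seed=0)
        assert rec.loc["g", "slope"] == pytest.approx(0.0)

    def test_planted_negative_slope_recovered(self, planted_distance_tissue):
        sample, _ = planted_distance_tissue
        expr, d = prepare_distance_table(sample, "tumor", "T_cell")
        rec = distance_regression(expr[["G050"]], d, n_perm=50, seed=1)
        assert -0.45 <= rec.loc["G050", "slope"] <= -0.2
        assert rec.loc["G050", "p"] < 1e-3

    def test_p_matches_statsmodels_default_ols(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        d = pd.Series(rng.uniform(0, 20, 80))
        expr = pd.DataFrame({"g": rng.poisson(5 + 0.3 * d)})
        rec = distance_regression(expr, d, n_perm=5, seed=0)
        fit = sm.OLS(expr["g"].to_numpy(),
                     sm.add_constant(d.to_numpy())).fit()
        assert rec.loc["g", "slope"] == pytest.approx(fit.params[1])
        assert rec.loc["g", "p"] == pytest.approx(fit.pvalues[1])
        assert rec.loc["g", "r2"] == pytest.approx(fit.rsquared)

    def test_mean_perm_r2_near_ols_expectation(self, rng):
        # under independence E[R^2] = 1/(n-1)
        n = 120
        d = pd.Series(rng.uniform(0, 20, n))
        expr = pd.DataFrame(rng.poisson(6.0, size=(n, 30)))
        rec = distance_regression(expr, d, n_perm=400, seed=2)
        expected = 1 / (n - 1)
        assert np.median(rec["mean_perm_r2"]) == pytest.approx(expected,
                                                               rel=0.5)

    def test_zero_variance_distance_rejected(self):
        d = pd.Series(np.full(20, 5.0))
        expr = pd.DataFrame({"g": np.arange(20.0)})
        with pytest.raises(ValueError, match="zero-variance"):
            distance_regression(expr, d, n_perm=5)


class TestSmoothing:
    def test_constant_vector_is_fixed_point(self):
        y = np.full(30, 4.0)
        x = np.linspace(0, 10, 30)
        g_r2, keep = smooth_and_filter(y, x)
        # smoothing leaves a constant unchanged; R^2 of a flat fit is 0
        assert g_r2 == pytest.approx(0.0) and not keep

    def test_clean_monotone_trend_kept(self, rng):
        x = np.sort(rng.uniform(0, 20, 100))
        y = 10 - 0.4 * x + rng.normal(0, 0.3, 100)
        g_r2, keep = smooth_and_filter(y, x)
        assert g_r2 > 0.9 and keep

    def test_noise_gene_dropped_in_most_replicates(self, rng):
        drops = 0
        n_rep = 30
        for _ in range(n_rep):
            x = rng.uniform(0, 20, 120)
            y = rng.poisson(5.0, 120).astype(float)
            _, keep = smooth_and_filter(y, x)
            drops += not keep
        assert drops >= 0.9 * n_rep

    def test_too_few_cells_dropped(self):
        g_r2, keep = smooth_and_filter(np.array([1.0, 2.0]),
                                       np.array([0.0, 1.0]))
        assert not keep


class TestCompositeScore:
    def _records(self, n, rng):
        return pd.DataFrame({
            "slope": rng.normal(0, 1, n),
            "r2": rng.random(n),
            "gaussian_r2": rng.random(n),
            "n_cells": rng.integers(10, 300, n),
            "p98_expression": rng.integers(5, 50, n),
            "p98_distance": rng.uniform(5, 40, n),
            "mean_perm_r2": rng.random(n) * 0.05,
            "q": rng.random(n),
        })

    def test_uniform_best_reaches_upper_bound(self, rng):
        rec = self._records(3, rng)
        rec.iloc[0] = [10.0, 0.99, 0.99, 500, 100, 50.0, 1e-6, 1e-9]
        rec.iloc[1] = [0.01, 0.01, 0.01, 5, 1, 1.0, 0.9, 0.99]
        scored = composite_score(rec)
        assert scored["composite_score"].max() == pytest.approx(16.0)
        assert scored["composite_score"].min() == pytest.approx(0.0)

    def test_bounds_and_order_invariance(self, rng):
        rec = self._records(12, rng)
        scored = composite_score(rec)
        n = len(rec)
        assert scored["composite_score"].between(0, 8 * (n - 1)).all()
        shuffled = composite_score(rec.sample(frac=1, random_state=0))
        assert np.allclose(
            scored["composite_score"].sort_index(),
            shuffled["composite_score"].sort_index(),
        )

    def test_ties_use_average_ranks(self):
        rec = pd.DataFrame({
            "slope": [1.0, 1.0, 2.0],
            "r2": [0.5, 0.5, 0.5],
            "gaussian_r2": [0.5, 0.5, 0.5],
            "n_cells": [10, 10, 10],
            "p98_expression": [5, 5, 5],
            "p98_distance": [10.0, 10.0, 10.0],
            "mean_perm_r2": [0.01, 0.01, 0.01],
            "q": [0.5, 0.5, 0.5],
        })
        scored = composite_score(rec).sort_index()
        # brute-force reversed average ranks
        feats = {"abs_slope": [1.0, 1.0, 2.0]}
        r = sps.rankdata([-v for v in feats["abs_slope"]], method="average")
        expected_slope_part = 3 - r
        tied_others = 3 - 2.0  # every other feature fully tied at rank 2
        expected = expected_slope_part + 7 * tied_others
        assert np.allclose(scored["composite_score"], expected)


class TestCohort:
    def test_planted_gene_reported_and_few_false_positives(
            self, planted_distance_tissue):
        sample, _ = planted_distance_tissue
        rec = run_pair(sample, "tumor", "T_cell", n_perm=50, seed=5)
        assert "G050" in rec.index
        false = rec[rec["reported"] & (rec.index != "G050")]
        assert len(false) <= 1

    def test_global_bh_family(self, planted_distance_tissue):
        sample, _ = planted_distance_tissue
        rec = run_cohort(sample, pairs=[("tumor", "T_cell"),
                                        ("T_cell", "tumor")],
                         n_perm=30, seed=6)
        assert {"tissue_id", "type_x", "type_y", "q",
                "composite_score"} <= set(rec.columns)
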