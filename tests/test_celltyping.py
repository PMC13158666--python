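"""Marker extraction, cluster-type assignment rules, consensus labelling
and permutation validation of the cell-typing pipeline."""

import numpy as np
import pandas as pd
import pytest

from insituprox.celltyping import (
    ClusteringSolution,
    assign_cluster_types,
    cluster_parameter_grid,
    consensus_labels,
    extract_markers,
    marker_overexpression_q,
    permutation_validate,
    shuffle_within_genes,
)
from insituprox.simulate import SimulationConfig, generate_tissue


def _ref_row(gene, cell_type, fc, p):
    return {"gene": gene, "cell_type": cell_type,
            "avg_log2FC": fc, "adjusted_p": p}


class TestExtractMarkers:
    def test_low_fold_change_dropped(self):
        ref = pd.DataFrame([_ref_row("g1", "A", 4.0, 0.0)])
        assert len(extract_markers(ref)) == 0

    def test_duplicate_kept_only_for_sole_near_zero_type(self):
        ref = pd.DataFrame([
            _ref_row("g1", "A", 8.0, 0.0),
            _ref_row("g1", "B", 8.0, 1e-150),
        ])
        m = extract_markers(ref)
        assert list(m["cell_type"]) == ["A"]

    def test_duplicate_near_zero_in_two_types_excluded(self):
        ref = pd.DataFrame([
            _ref_row("g1", "A", 8.0, 0.0),
            _ref_row("g1", "B", 8.0, 0.0),
        ])
        assert len(extract_markers(ref)) == 0

    def test_canonical_markers_appended_by_union(self):
        ref = pd.DataFrame([_ref_row("g1", "A", 8.0, 0.0)])
        canonical = pd.DataFrame([{"gene": "g2", "cell_type": "B"},
                                  {"gene": "g1", "cell_type": "A"}])
        m = extract_markers(ref, canonical)
        assert set(m["gene"]) == {"g1", "g2"}
        assert m.loc[m["gene"] == "g2", "provenance"].iloc[0] == "canonical"

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            extract_markers(pd.DataFrame({"gene": ["g1"]}))


class TestAssignmentRules:
    MARKERS = pd.DataFrame([
        {"gene": "m1", "cell_type": "A"},
        {"gene": "m2", "cell_type": "A"},
        {"gene": "m3", "cell_type": "B"},
    ])

    def _q_table(self, qs):
        rows = [{"cluster": 0, "gene": g, "p": q, "q": q}
                for g, q in qs.items()]
        return pd.DataFrame(rows)

    def test_sole_marker_below_threshold_assigns(self):
        out = assign_cluster_types(
            self._q_table({"m1": 1e-12, "m2": 1.0, "m3": 1.0}), self.MARKERS)
        assert out[0] == "A"

    def test_no_support_leaves_unassigned(self):
        out = assign_cluster_types(
            self._q_table({"m1": 1e-3, "m2": 1.0, "m3": 1.0}), self.MARKERS)
        assert out[0] == ""

    def test_same_type_markers_assign_on_best_q(self):
        out = assign_cluster_types(
            self._q_table({"m1": 1e-12, "m2": 1e-10, "m3": 1.0}),
            self.MARKERS)
        assert out[0] == "A"

    def test_log_ratio_dominance_rule(self):
        # q1=1e-20, q2=1e-4 is not competing support (q2 > 1e-9 threshold);
        # the arithmetic still holds: log10(q1/q2) = -16 < 0.3*log10(q2)
        out = assign_cluster_types(
            self._q_table({"m1": 1e-20, "m2": 1.0, "m3": 1e-10}),
            self.MARKERS)
        # competitor m3 (type B) supports at 1e-10; leader dominates:
        # log10(1e-20/1e-10) = -10 < 0.3 * log10(1e-10) = -3
        assert out[0] == "A"

    def test_weak_leader_leaves_unassigned(self):
        out = assign_cluster_types(
            self._q_table({"m1": 1e-10, "m2": 1.0, "m3": 1e-10}),
            self.MARKERS)
        assert out[0] == ""

    def test_single_near_zero_among_competitors_assigns(self):
        out = assign_cluster_types(
            self._q_table({"m1": 0.0, "m2": 1.0, "m3": 1e-50}),
            self.MARKERS)
        assert out[0] == "A"

    def test_two_near_zero_different_types_unassigned(self):
        out = assign_cluster_types(
            self._q_table({"m1": 0.0, "m2": 1.0, "m3": 0.0}), self.MARKERS)
        assert out[0] == ""


def _fake_solution(labels_dict, assignment, n_pcs=10, res=1.0):
    return ClusteringSolution(
        n_pcs=n_pcs, resolution=res,
        cluster_of=pd.Series(labels_dict), assignment=assignment,
    )


class TestConsensus:
    def test_support_thresholds(self):
        # 20 retained solutions; cell "c" labelled A in 8 (40%, >= 10 fails)
        cells = ["c"]
        sols = []
        four_types = {0: "A", 1: "B", 2: "C", 3: "D"}
        for i in range(20):
            assignment = dict(four_types)
            sols.append(_fake_solution({"c": 0 if i < 8 else 1}, assignment,
                                       n_pcs=6 + i))
        ann = consensus_labels(sols)
        # B has 12 of 20 = 60% and count 12 >= 10 -> assigned
        assert ann.labels["c"] == "B"

    def test_fraction_below_20_percent_unassigned(self):
        sols = []
        for i in range(60):
            lab = 0 if i < 11 else 1  # A: 11/60 = 18% (count passes, not %)
            assignment = {0: "A", 1: "", 2: "C", 3: "D", 4: "E"}
            sols.append(_fake_solution({"c": lab}, assignment, n_pcs=6 + i))
        ann = consensus_labels(sols)
        assert ann.labels["c"] == ""

    def test_solutions_with_three_types_excluded(self):
        three = {0: "A", 1: "B", 2: "C"}
        five = {0: "A", 1: "B", 2: "C", 3: "D", 4: "E"}
        sols = [_fake_solution({"c": 0}, three) for _ in range(30)]
        sols += [_fake_solution({"c": 1}, five) for _ in range(12)]
        ann = consensus_labels(sols)
        assert ann.n_retained_solutions == 12
        assert ann.labels["c"] == "B"

    def test_invariant_to_solution_order(self, rng):
        five = {0: "A", 1: "B", 2: "C", 3: "D", 4: "E"}
        sols = [_fake_solution({"c": int(rng.integers(0, 5)),
                                "d": int(rng.integers(0, 5))}, five,
                               n_pcs=6 + i)
                for i in range(40)]
        a = consensus_labels(sols).labels
        b = consensus_labels(sols[::-1]).labels
        pd.testing.assert_series_equal(a, b)

    def test_no_retained_solutions_warns_all_unassigned(self):
        three = {0: "A", 1: "B", 2: "C"}
        sols = [_fake_solution({"c": 0}, three)]
        with pytest.warns(UserWarning, match="no retained"):
            ann = consensus_labels(sols)
        assert (ann.labels == "").all()


@pytest.fixture(scope="module")
def typed_tissue():
    cfg = SimulationConfig(n_cells=300, n_genes=50, marker_boost=40.0)
    sample, truth = generate_tissue(cfg, seed=550)
    rows = []
    for t, genes in truth["markers"].items():
        for g in genes:
            rows.append({"gene": g, "cell_type": t,
                         "avg_log2FC": 8.0, "adjusted_p": 0.0})
    markers = extract_markers(pd.DataFrame(rows))
    return sample, truth, markers


class TestPipeline:
    GRID = dict(pcs_grid=(6, 10), resolution_grid=(0.6, 1.0, 1.4))

    def test_grid_produces_expected_combination_count(self, typed_tissue):
        sample, _, markers = typed_tissue
        sols = cluster_parameter_grid(sample.counts, markers, seed=0,
                                      **self.GRID)
        assert len(sols) == 6

    def test_deterministic_under_seed(self, typed_tissue):
        sample, _, markers = typed_tissue
        a = cluster_parameter_grid(sample.counts, markers, seed=1,
                                   pcs_grid=(8,), resolution_grid=(1.0,))
        b = cluster_parameter_grid(sample.counts, markers, seed=1,
                                   pcs_grid=(8,), resolution_grid=(1.0,))
        assert a[0].cluster_of.equals(b[0].cluster_of)
        assert a[0].assignment == b[0].assignment

    def test_planted_types_recovered_with_high_accuracy(self, typed_tissue):
        from sklearn.metrics import adjusted_rand_score

        sample, truth, markers = typed_tissue
        sols = cluster_parameter_grid(sample.counts, markers, seed=2,
                                      **self.GRID)
        # support-count threshold rescaled to this reduced 6-combination grid
        ann = consensus_labels(sols, min_count=3)
        truth_types = pd.Series(truth["cell_types"])
        assigned = ann.labels[ann.labels != ""]
        assert len(assigned) >= 0.5 * len(ann.labels)
        acc = (assigned == truth_types[assigned.index]).mean()
        assert acc >= 0.9
        best_ari = max(
            adjusted_rand_score(truth_types[s.cluster_of.index],
                                s.cluster_of) for s in sols)
        assert best_ari >= 0.9

    def test_shuffle_preserves_per_gene_multiset(self, typed_tissue, rng):
        sample, _, _ = typed_tissue
        shuf = shuffle_within_genes(sample.counts, rng)
        for g in sample.counts.columns[:10]:
            assert sorted(shuf[g]) == sorted(sample.counts[g])

    def test_permutation_validation_separates_structure_from_noise(
            self, typed_tissue):
        sample, _, markers = typed_tissue
        res = permutation_validate(
            sample.counts, markers, pcs_grid=(6,),
            resolution_grid=(0.8, 1.2), n_perm=5, seed=3, min_count=1)
        assert res.p_one_sided < 0.01
        assert res.observed > res.null_mean


class TestMarkerOverexpression:
    def test_q_values_flag_planted_marker(self, typed_tissue):
        sample, truth, markers = typed_tissue
        labels = pd.Series(truth["cell_types"]).loc[sample.counts.index]
        clusters = labels.map({t: i for i, t in
                               enumerate(sorted(labels.unique()))})
        q = marker_overexpression_q(sample.counts, clusters,
                                    markers["gene"])
        # each type's own marker must be overexpressed in its cluster
        tumor_cluster = clusters[labels == "tumor"].iloc[0]
        tumor_marker = truth["markers"]["tumor"][0]
        row = q[(q["cluster"] == tumor_cluster) & (q["gene"] == tumor_marker)]
        assert row["q"].iloc[0] < 1e-9
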