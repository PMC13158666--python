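"""Spatial data model: ingest, distances, proximity stratification and
neighbour counting."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from insituprox.spatial import (
    SchemaError,
    count_neighbors,
    count_neighbors_all,
    ingest_transcripts,
    min_distance_to_type,
    min_distances_to_type,
    pair_distance,
    read_sample,
    sample_from_transcripts,
    stratify_by_proximity,
    write_sample,
)


def _two_cell_sample(points_a, points_b, type_a="A", type_b="B"):
    rows = []
    for x, y, z in points_a:
        rows.append(("g1", x, y, z, "a", "f0"))
    for x, y, z in points_b:
        rows.append(("g2", x, y, z, "b", "f0"))
    df = pd.DataFrame(rows, columns=["gene", "x", "y", "z", "cell_id", "fov_id"])
    s = sample_from_transcripts(df, min_transcripts=1)
    s.set_type_labels(pd.Series({"a": type_a, "b": type_b}))
    return s


class TestIngest:
    def test_counts_and_cells(self, tiny_transcripts):
        s = sample_from_transcripts(tiny_transcripts, min_transcripts=1)
        assert len(s.cell_meta) == 2
        assert s.counts.to_numpy().sum() == 3  # unassigned molecule excluded

    def test_expansion_factor_rescales_coordinates(self, tiny_transcripts):
        s1 = sample_from_transcripts(tiny_transcripts, min_transcripts=1)
        s4 = sample_from_transcripts(tiny_transcripts, expansion_factor=4.0,
                                     min_transcripts=1)
        assert np.allclose(s4.transcripts[["x", "y", "z"]],
                           s1.transcripts[["x", "y", "z"]] * 0.25)
        assert s4.counts.equals(s1.counts)

    def test_missing_column_is_schema_error(self, tiny_transcripts):
        with pytest.raises(SchemaError, match="cell_id"):
            sample_from_transcripts(tiny_transcripts.drop(columns=["cell_id"]))

    def test_non_numeric_coordinate_reports_row(self, tiny_transcripts):
        bad = tiny_transcripts.copy()
        bad["x"] = bad["x"].astype(object)
        bad.loc[2, "x"] = "oops"
        with pytest.raises(SchemaError, match="row 2"):
            sample_from_transcripts(bad)

    def test_qc_drops_sparse_cells(self, tiny_transcripts):
        s = sample_from_transcripts(tiny_transcripts, min_transcripts=2)
        assert list(s.cell_meta.index) == ["a"]

    def test_centroid_is_mean_of_member_transcripts(self, tiny_transcripts):
        s = sample_from_transcripts(tiny_transcripts, min_transcripts=1)
        assert np.allclose(s.cell_meta.loc["a", ["cx", "cy", "cz"]],
                           [1.5, 2.0, 0.0])

    def test_roundtrip_serialization(self, tmp_path, small_tissue):
        sample, _ = small_tissue
        write_sample(sample, tmp_path / "s")
        back = read_sample(tmp_path / "s")
        assert back.counts.astype(int).equals(sample.counts.astype(int))
        assert (back.cell_meta["type_label"]
                == sample.cell_meta["type_label"]).all()
        assert np.allclose(back.transcripts[["x", "y", "z"]],
                           sample.transcripts[["x", "y", "z"]], atol=1e-9)
        assert back.platform == sample.platform

    def test_ingest_from_csv(self, tmp_path, tiny_transcripts):
        path = tmp_path / "t.csv"
        tiny_transcripts.to_csv(path, index=False)
        s = ingest_transcripts(path, min_transcripts=1)
        assert s.counts.to_numpy().sum() == 3


class TestPairDistance:
    def test_three_four_five_triangle(self):
        s = _two_cell_sample([(0, 0, 0)], [(3, 4, 0)])
        assert pair_distance(s, "a", "b", "boundary") == pytest.approx(5.0)

    def test_shared_coordinate_gives_zero(self):
        s = _two_cell_sample([(0, 0, 0), (1, 1, 1)], [(1, 1, 1), (9, 9, 9)])
        assert pair_distance(s, "a", "b", "boundary") == 0.0

    def test_matches_exhaustive_minimum(self, rng):
        pa = rng.normal(0, 5, (20, 3))
        pb = rng.normal(4, 5, (20, 3))
        s = _two_cell_sample(pa, pb)
        brute = cdist(pa, pb).min()
        assert pair_distance(s, "a", "b", "boundary") == pytest.approx(brute)

    def test_symmetry_and_nonnegativity(self, rng):
        s = _two_cell_sample(rng.normal(size=(8, 3)), rng.normal(3, 1, (9, 3)))
        d1 = pair_distance(s, "a", "b", "boundary")
        d2 = pair_distance(s, "b", "a", "boundary")
        assert d1 == pytest.approx(d2) and d1 >= 0

    def test_boundary_not_above_any_specific_transcript_pair(self, rng):
        pa = rng.normal(0, 3, (10, 3))
        pb = rng.normal(5, 3, (10, 3))
        s = _two_cell_sample(pa, pb)
        d = pair_distance(s, "a", "b", "boundary")
        assert d <= np.linalg.norm(pa[0] - pb[0]) + 1e-12

    def test_centroid_convention(self):
        s = _two_cell_sample([(0, 0, 0), (2, 0, 0)], [(10, 0, 0), (12, 0, 0)])
        assert pair_distance(s, "a", "b", "centroid") == pytest.approx(10.0)

    def test_identical_cell_rejected(self):
        s = _two_cell_sample([(0, 0, 0)], [(1, 0, 0)])
        with pytest.raises(ValueError):
            pair_distance(s, "a", "a")


class TestMinDistanceToType:
    def test_no_target_in_fov_returns_none(self):
        rows = [("g1", 0, 0, 0, "a", "f0"), ("g2", 200, 200, 0, "b", "f1")]
        df = pd.DataFrame(rows, columns=["gene", "x", "y", "z", "cell_id", "fov_id"])
        s = sample_from_transcripts(df, min_transcripts=1)
        s.set_type_labels(pd.Series({"a": "A", "b": "B"}))
        assert min_distance_to_type(s, "a", "B", scope="same_fov") is None

    def test_single_target_distance(self):
        s = _two_cell_sample([(0, 0, 0)], [(7, 0, 0)])
        assert min_distance_to_type(s, "a", "B") == pytest.approx(7.0)

    def test_centroid_cap_145(self):
        s = _two_cell_sample([(0, 0, 0)], [(150, 0, 0)])
        s.platform = "MERFISH"
        s.distance_cap_um = 145.0
        assert min_distance_to_type(s, "a", "B", cap_um=145.0,
                                    convention="centroid") is None

    def test_unknown_type_lists_known_labels(self, small_tissue):
        sample, _ = small_tissue
        with pytest.raises(KeyError, match="tumor"):
            min_distance_to_type(sample, sample.cell_ids[0], "astrocyte")

    def test_vectorised_matches_brute_force(self, small_tissue):
        sample, _ = small_tissue
        cells = sample.cells_of_type("tumor")[:15]
        d = min_distances_to_type(sample, cells, "T_cell")
        targets = sample.cells_of_type("T_cell")
        for cid in cells:
            brute = min(pair_distance(sample, cid, t, "boundary")
                        for t in targets)
            assert d.loc[cid] == pytest.approx(brute)


class TestStratifyByProximity:
    def test_threshold_is_inclusive_at_exactly_1um(self):
        s = _two_cell_sample([(0, 0, 0)], [(1.0, 0, 0)])
        st = stratify_by_proximity(s, "A", "B", threshold_um=1.0)
        assert st.proximal_ids == ("a",)

    def test_just_above_threshold_is_distant(self):
        s = _two_cell_sample([(0, 0, 0)], [(1.01, 0, 0)])
        st = stratify_by_proximity(s, "A", "B", threshold_um=1.0)
        assert st.distant_ids == ("a",) and st.n_proximal == 0

    def test_all_far_pair_flagged_unanalyzable(self):
        s = _two_cell_sample([(0, 0, 0)], [(50, 0, 0)])
        st = stratify_by_proximity(s, "A", "B")
        assert not st.analyzable and st.n_proximal == 0

    def test_partition_property(self, small_tissue):
        sample, _ = small_tissue
        for thr in (0.5, 1.0, 3.0, 10.0):
            st = stratify_by_proximity(sample, "tumor", "T_cell", thr)
            n_i = len(sample.cells_of_type("tumor"))
            assert st.n_proximal + st.n_distant == n_i
            assert not set(st.proximal_ids) & set(st.distant_ids)


class TestCountNeighbors:
    def _sample_three(self):
        rows = [("g1", 0, 0, 0, "x", "f0"),
                ("g2", 10, 0, 0, "y1", "f0"),
                ("g2", 14, 0, 0, "y2", "f0")]
        df = pd.DataFrame(rows, columns=["gene", "x", "y", "z", "cell_id", "fov_id"])
        s = sample_from_transcripts(df, min_transcripts=1)
        s.set_type_labels(pd.Series({"x": "X", "y1": "Y", "y2": "Y"}))
        return s

    def test_two_within_15(self):
        assert count_neighbors(self._sample_three(), "x", "Y", 15.0) == 2

    def test_one_within_10(self):
        assert count_neighbors(self._sample_three(), "x", "Y", 10.0) == 1

    def test_rejects_nonpositive_cutoff(self):
        with pytest.raises(ValueError):
            count_neighbors(self._sample_three(), "x", "Y", 0.0)

    def test_matches_brute_force_and_monotone(self, small_tissue):
        sample, _ = small_tissue
        cells = sample.cells_of_type("tumor")[:10]
        targets = sample.cells_of_type("T_cell")
        prev = None
        for cutoff in (5.0, 10.0, 20.0):
            counts = count_neighbors_all(sample, cells, "T_cell", cutoff)
            brute = pd.Series({
                c: sum(pair_distance(sample, c, t, "boundary") <= cutoff
                       for t in targets)
                for c in cells
            })
            assert counts.equals(brute.astype(counts.dtype))
            if prev is not None:
                assert (counts >= prev).all()
            prev = counts

    def test_self_excluded_for_same_type(self, small_tissue):
        sample, _ = small_tissue
        cells = sample.cells_of_type("tumor")[:5]
        counts = count_neighbors_all(sample, cells, "tumor", 10.0)
        brute = pd.Series({
            c: sum(pair_distance(sample, c, t, "boundary") <= 10.0
                   for t in sample.cells_of_type("tumor") if t != c)
            for c in cells
        })
        assert counts.equals(brute.astype(counts.dtype))
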