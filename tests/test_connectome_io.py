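"""Connectome file handling, normalization, density, correlation, extraction."""

import numpy as np
import pytest

from subcomm.connectome_io import (
    Cohort,
    ConnectivityMatrix,
    RegionAtlas,
    Subject,
    cohort_pairwise_correlation,
    density,
    extract_subnetwork,
    load_cohort,
    load_connectome,
    normalize_max,
    save_cohort,
    write_connectome,
)

from conftest import cohort_from_matrices, make_matrix


class TestAtlas:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            RegionAtlas(("a", "a", "b"), ("a",))

    def test_unknown_subcortical_rejected(self):
        with pytest.raises(ValueError, match="not in atlas"):
            RegionAtlas(("a", "b"), ("z",))

    def test_subcortical_order_must_match_atlas(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            RegionAtlas(("a", "b", "c"), ("c", "a"))

    def test_indices_resolve(self, atlas_mixed):
        assert atlas_mixed.subcortical_indices.tolist() == [1, 3]

    def test_label_file_round_trip(self, tmp_path, atlas_mixed):
        path = tmp_path / "labels.txt"
        atlas_mixed.to_label_file(path)
        again = RegionAtlas.from_label_file(path, atlas_mixed.subcortical_names)
        assert again == atlas_mixed


class TestLoadConnectome:
    @pytest.mark.parametrize("delim", [" ", ","])
    def test_round_trip_bit_identical(self, tmp_path, atlas3, delim):
        rng = np.random.default_rng(0)
        W = rng.random((3, 3))
        W = W + W.T
        m = make_matrix(W, atlas3)
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_connectome(m, p1, delimiter=delim)
        loaded = load_connectome(p1, atlas3)
        np.testing.assert_array_equal(loaded.weights, m.weights)
        write_connectome(loaded, p2, delimiter=delim)
        assert p1.read_bytes() == p2.read_bytes()

    def test_accepts_entries_and_scientific_notation(self, tmp_path, atlas3):
        (tmp_path / "m.txt").write_text("0 1 2e0\n1 0 0\n2 0 0\n")
        m = load_connectome(tmp_path / "m.txt", atlas3)
        assert m.weights[0, 2] == 2.0

    def test_negative_entry_rejected(self, tmp_path, atlas3):
        (tmp_path / "m.txt").write_text("0 1 2\n1 0 -1\n2 -1 0\n")
        with pytest.raises(ValueError, match="negative weight"):
            load_connectome(tmp_path / "m.txt", atlas3)

    def test_non_square_rejected(self, tmp_path, atlas3):
        (tmp_path / "m.txt").write_text("0 1 2\n1 0 0\n")
        with pytest.raises(ValueError, match="non-square|parse"):
            load_connectome(tmp_path / "m.txt", atlas3)

    def test_dimension_mismatch_rejected(self, tmp_path, atlas_mixed):
        (tmp_path / "m.txt").write_text("0 1\n1 0\n")
        with pytest.raises(ValueError, match="does not match atlas"):
            load_connectome(tmp_path / "m.txt", atlas_mixed)

    def test_non_numeric_token_rejected(self, tmp_path, atlas3):
        (tmp_path / "m.txt").write_text("0 1 x\n1 0 0\nx 0 0\n")
        with pytest.raises(ValueError, match="parse"):
            load_connectome(tmp_path / "m.txt", atlas3)

    def test_small_asymmetry_symmetrized(self, atlas3):
        W = np.array([[0, 1, 0], [1 + 4e-9, 0, 0], [0, 0, 0.0]])
        m = ConnectivityMatrix(W, atlas3)
        np.testing.assert_allclose(m.weights, m.weights.T)
        assert m.weights[0, 1] == pytest.approx(1 + 2e-9)

    def test_large_asymmetry_rejected(self, atlas3):
        W = np.array([[0, 1, 0], [2, 0, 0], [0, 0, 0.0]])
        with pytest.raises(ValueError, match="asymmetry"):
            ConnectivityMatrix(W, atlas3)


class TestNormalizeMax:
    def test_scales_by_global_max(self, atlas3):
        W = np.array([[0, 2, 8], [2, 0, 0], [8, 0, 0.0]])
        out = normalize_max(make_matrix(W, atlas3))
        np.testing.assert_array_equal(
            out.weights, [[0, 0.25, 1], [0.25, 0, 0], [1, 0, 0]]
        )

    def test_idempotent_and_pattern_preserving(self, atlas3):
        W = np.array([[0, 0.5, 1], [0.5, 0, 0], [1, 0, 0.0]])
        m = make_matrix(W, atlas3)
        once = normalize_max(m)
        np.testing.assert_array_equal(once.weights, W)
        np.testing.assert_array_equal(
            normalize_max(once).weights == 0, W == 0
        )
        assert once.weights.max() == 1.0

    def test_all_zero_rejected(self, atlas3):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_max(make_matrix(np.zeros((3, 3)), atlas3))


class TestDensity:
    @pytest.mark.parametrize(
        "edges, expected",
        [([(0, 1), (2, 3)], 2 / 6), ("complete", 1.0), ([], 0.0)],
    )
    def test_counts_positive_upper_triangle(self, edges, expected):
        atlas = RegionAtlas(tuple("abcd"), tuple("abcd"))
        W = np.zeros((4, 4))
        if edges == "complete":
            W = np.ones((4, 4))
        else:
            for i, j in edges:
                W[i, j] = W[j, i] = 1.0
        assert density(make_matrix(W, atlas)) == pytest.approx(expected)

    def test_invariant_under_normalization(self, atlas3):
        W = np.array([[0, 3, 0], [3, 0, 7], [0, 7, 0.0]])
        m = make_matrix(W, atlas3)
        assert density(m) == density(normalize_max(m))


class TestNormalizationProperties:
    """Property-based checks on arbitrary valid weight matrices."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @staticmethod
    def _matrix(raw):
        W = np.triu(raw, 1)
        return W + W.T

    # weights are streamline-count-like: zero or well away from denormals
    # (dividing a denormal by the max can underflow and break the pattern)
    @given(
        arrays(
            float,
            (3, 3),
            elements=st.one_of(
                st.just(0.0),
                st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False),
            ),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_normalize_idempotent_pattern_density_invariant(self, raw):
        atlas = RegionAtlas(("a", "b", "c"), ("a", "b", "c"))
        W = self._matrix(raw)
        if W.max() == 0:
            return
        m = ConnectivityMatrix(W, atlas)
        once = normalize_max(m)
        twice = normalize_max(once)
        np.testing.assert_array_equal(once.weights, twice.weights)
        np.testing.assert_array_equal(once.weights == 0, W == 0)
        assert once.weights.max() == 1.0
        assert density(once) == density(m)


class TestPairwiseCorrelation:
    def test_identical_matrices(self, atlas3):
        W = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        cohort = cohort_from_matrices([W, W], [W, W], atlas3)
        mean, sd = cohort_pairwise_correlation(cohort, "HC")
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair(self, atlas3):
        # upper triangles (1,2,3) and (3,2,1): hand Pearson = -1
        W1 = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        W2 = np.array([[0, 3, 2], [3, 0, 1], [2, 1, 0.0]])
        cohort = cohort_from_matrices([W1, W2], [W1, W2], atlas3)
        mean, _ = cohort_pairwise_correlation(cohort, "HC")
        assert mean == pytest.approx(-1.0)

    def test_single_subject_group_rejected(self, atlas3):
        W = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0.0]])
        cohort = cohort_from_matrices([W], [W, W], atlas3)
        with pytest.raises(ValueError, match=">= 2 subjects"):
            cohort_pairwise_correlation(cohort, "HC")

    def test_zero_variance_subject_skipped_with_warning(self, atlas3):
        W1 = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        flat = np.ones((3, 3))
        cohort = cohort_from_matrices([W1, 2 * W1, flat], [W1, W1], atlas3)
        with pytest.warns(UserWarning, match="zero-variance"):
            mean, _ = cohort_pairwise_correlation(cohort, "HC")
        assert mean == pytest.approx(1.0)


class TestExtractSubnetwork:
    def test_entries_match_index_map(self, atlas_mixed):
        rng = np.random.default_rng(3)
        W = rng.random((5, 5))
        W = W + W.T
        sub = extract_subnetwork(make_matrix(W, atlas_mixed))
        assert sub.weights.shape == (2, 2)
        idx = atlas_mixed.subcortical_indices
        for a in range(2):
            for b in range(2):
                assert sub.weights[a, b] == W[idx[a], idx[b]]

    def test_full_selection_is_identity(self, atlas3):
        W = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        sub = extract_subnetwork(make_matrix(W, atlas3))
        np.testing.assert_array_equal(sub.weights, W)

    def test_pipeline_normalizes_before_extraction(self, atlas_mixed):
        """The whole matrix is normalized by its global max, then extracted:
        when the global max lies outside the sub-network, the extracted block
        must NOT have max 1."""
        from subcomm.group_stats import subject_pair_matrix

        W = np.zeros((5, 5))
        W[0, 2] = W[2, 0] = 10.0  # global max on a cortical pair
        W[1, 3] = W[3, 1] = 2.0
        feats = subject_pair_matrix(make_matrix(W, atlas_mixed), "Wsub")
        assert feats.max() == pytest.approx(0.2)  # 2/10, not 2/2


class TestCohortIO:
    def test_manifest_round_trip(self, tmp_path, small_cohort):
        manifest = save_cohort(small_cohort, tmp_path / "cohort")
        again = load_cohort(manifest, small_cohort.atlas)
        assert again.subject_ids == small_cohort.subject_ids
        assert (again.labels == small_cohort.labels).all()
        for a, b in zip(again.subjects, small_cohort.subjects):
            np.testing.assert_array_equal(a.matrix.weights, b.matrix.weights)

    def test_mixed_atlases_rejected(self, atlas3, atlas_mixed):
        m3 = make_matrix(np.zeros((3, 3)), atlas3)
        m5 = make_matrix(np.zeros((5, 5)), atlas_mixed)
        with pytest.raises(ValueError, match="share one atlas"):
            Cohort([Subject("a", "HC", m3), Subject("b", "AD", m5)])

    def test_unknown_group_rejected(self, atlas3):
        m3 = make_matrix(np.zeros((3, 3)), atlas3)
        with pytest.raises(ValueError, match="unknown group"):
            Subject("a", "MCI", m3)
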