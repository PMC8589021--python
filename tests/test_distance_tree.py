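from __future__ import annotations

import numpy as np
import pytest
import dendropy

from ssrkit import distance_tree as dt
from ssrkit import genotype_io as gio

from conftest import random_matrix
from oracles import AdditiveTree, brute_jaccard


class TestJaccard:
    def test_identical_fingerprints(self, small_panel):
        row = [1, 0, 1, 0, 1]
        m = gio.AlleleMatrix(small_panel, ("a", "b"), np.array([row, row], dtype=np.int8))
        dm = dt.jaccard_matrix(m)
        assert dm.values[0, 1] == 0.0

    def test_disjoint_presence_sets(self, small_panel):
        m = gio.AlleleMatrix(
            small_panel, ("a", "b"),
            np.array([[1, 1, 0, 0, 0], [0, 0, 1, 1, 1]], dtype=np.int8),
        )
        assert dt.jaccard_matrix(m).values[0, 1] == 1.0

    def test_hand_built_half(self):
        # a=2 shared, b=1 only-first, c=1 only-second -> 1 - 2/4 = 0.5
        panel = gio.MarkerPanel.from_column_labels(["M_1", "M_2", "M_3", "M_4", "M_5"])
        m = gio.AlleleMatrix(
            panel, ("x", "y"),
            np.array([[1, 1, 1, 0, 0], [1, 1, 0, 1, 0]], dtype=np.int8),
        )
        assert dt.jaccard_matrix(m).values[0, 1] == pytest.approx(0.5)

    def test_shared_absence_ignored(self):
        panel = gio.MarkerPanel.from_column_labels(["M_1", "M_2", "M_3"])
        with_pad = gio.AlleleMatrix(
            panel, ("x", "y"), np.array([[1, 0, 0], [0, 1, 0]], dtype=np.int8)
        )
        assert dt.jaccard_matrix(with_pad).values[0, 1] == 1.0

    def test_zero_usable_columns_flagged(self, small_panel):
        m = gio.AlleleMatrix(
            small_panel, ("a", "b"),
            np.array([[1, 0, 0, 9, 9], [9, 9, 9, 0, 1]], dtype=np.int8),
        )
        dm = dt.jaccard_matrix(m)
        assert np.isnan(dm.values[0, 1])
        assert dm.n_shared_columns[0, 1] == 0
        assert dm.n_undefined_pairs == 1

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(10):
            m = random_matrix(rng, n_samples=7, missing_rate=0.2)
            dm = dt.jaccard_matrix(m)
            for i in range(m.n_samples):
                for j in range(i + 1, m.n_samples):
                    expected, n_cols = brute_jaccard(m, i, j)
                    if np.isnan(expected):
                        assert np.isnan(dm.values[i, j])
                    else:
                        assert dm.values[i, j] == pytest.approx(expected, abs=1e-12)
                    assert dm.n_shared_columns[i, j] == n_cols

    def test_similarity_is_one_minus_d(self, rng):
        m = random_matrix(rng)
        dm = dt.jaccard_matrix(m)
        sm = dt.similarity(dm)
        assert np.allclose(sm.values, 1.0 - dm.values, equal_nan=True)
        assert np.allclose(sm.values, sm.values.T, equal_nan=True)

    def test_distance_matrix_io_round_trip(self, rng, tmp_path):
        m = random_matrix(rng, missing_rate=0.0)
        dm = dt.jaccard_matrix(m)
        path = tmp_path / "dist.csv"
        dt.write_distance_matrix(dm, path)
        loaded = dt.read_distance_matrix(path)
        assert loaded.ids == dm.ids
        assert np.allclose(loaded.values, dm.values, atol=1e-12)

    def test_cross_jaccard_consistent_with_square_form(self, rng):
        m = random_matrix(rng, n_samples=6, missing_rate=0.2)
        dm = dt.jaccard_matrix(m)
        d, n_cols = dt.cross_jaccard(m, m)
        assert np.allclose(d, dm.values, equal_nan=True, atol=1e-12)
        assert (n_cols == dm.n_shared_columns).all()


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d_ab, d_ac, d_bc = 0.3, 0.5, 0.6
        dm = dt.DistanceMatrix(
            ("a", "b", "c"),
            np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]]),
        )
        tree = dt.nj_tree(dm)
        labels, paths = tree.path_lengths()
        idx = {lab: i for i, lab in enumerate(labels)}
        assert paths[idx["a"], idx["b"]] == pytest.approx(d_ab)
        assert paths[idx["a"], idx["c"]] == pytest.approx(d_ac)
        assert paths[idx["b"], idx["c"]] == pytest.approx(d_bc)
        # the unique internal node has degree 3
        internal = [n for n in tree.adjacency if n not in tree.leaf_labels]
        assert len(internal) == 1
        assert len(tree.adjacency[internal[0]]) == 3

    def test_four_taxon_additive_recovery(self):
        d = np.array(
            [
                [0, 0.5, 0.9, 0.9],
                [0.5, 0, 1.0, 1.0],
                [0.9, 1.0, 0, 0.8],
                [0.9, 1.0, 0.8, 0],
            ]
        )
        dm = dt.DistanceMatrix(("a", "b", "c", "d"), d)
        tree = dt.nj_tree(dm)
        labels, paths = tree.path_lengths()
        order = [labels.index(x) for x in ("a", "b", "c", "d")]
        assert np.allclose(paths[np.ix_(order, order)], d, atol=1e-12)
        assert frozenset({"c", "d"}) in tree.bipartitions()

    @pytest.mark.parametrize("trial", range(20))
    def test_random_additive_matrices_recovered(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_leaves = int(rng.integers(5, 9))
        truth = AdditiveTree(rng, n_leaves)
        d = truth.distance_matrix()
        scale = d.max()
        dm = dt.DistanceMatrix(tuple(truth.labels), d / scale)
        tree = dt.nj_tree(dm)
        assert tree.bipartitions() == truth.splits()
        labels, paths = tree.path_lengths()
        order = [labels.index(x) for x in truth.labels]
        assert np.allclose(paths[np.ix_(order, order)] * scale, d, atol=1e-9)

    def test_row_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(42)
        truth = AdditiveTree(rng, 6)
        d = truth.distance_matrix()
        d /= d.max()
        dm = dt.DistanceMatrix(tuple(truth.labels), d)
        tree = dt.nj_tree(dm)
        perm = rng.permutation(6)
        dm2 = dt.DistanceMatrix(
            tuple(truth.labels[i] for i in perm), d[np.ix_(perm, perm)]
        )
        tree2 = dt.nj_tree(dm2)
        assert tree.bipartitions() == tree2.bipartitions()

    def test_undefined_distance_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        dm = dt.DistanceMatrix(("a", "b", "c"), d)
        with pytest.raises(gio.ValidationError, match="impute or remove"):
            dt.nj_tree(dm)

    def test_fewer_than_three_rejected(self):
        dm = dt.DistanceMatrix(("a", "b"), np.array([[0, 0.5], [0.5, 0]]))
        with pytest.raises(gio.ValidationError):
            dt.nj_tree(dm)

    def test_negative_lengths_clamped_and_flagged(self):
        # strongly non-additive matrix forcing a negative NJ estimate
        d = np.array(
            [
                [0, 0.1, 0.9, 0.9],
                [0.1, 0, 0.1, 0.9],
                [0.9, 0.1, 0, 0.1],
                [0.9, 0.9, 0.1, 0],
            ]
        )
        tree = dt.nj_tree(dt.DistanceMatrix(("a", "b", "c", "d"), d))
        lengths = [l for _, _, l in tree.edges()]
        assert all(l >= 0 for l in lengths)
        assert tree.n_negative_clamped >= 1


class TestNewick:
    def test_three_leaf_output_parseable(self):
        dm = dt.DistanceMatrix(
            ("a", "b", "c"),
            np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        text = dt.nj_tree(dm).to_newick()
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == ["a", "b", "c"]

    def test_labels_with_spaces_quoted(self):
        dm = dt.DistanceMatrix(
            ("has space", "b", "c"),
            np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        text = dt.nj_tree(dm).to_newick()
        assert "'has space'" in text
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert "has space" in {t.label for t in parsed.taxon_namespace}

    def test_independent_parser_preserves_topology_and_lengths(self, tmp_path):
        rng = np.random.default_rng(7)
        truth = AdditiveTree(rng, 7)
        d = truth.distance_matrix()
        d /= d.max()
        tree = dt.nj_tree(dt.DistanceMatrix(tuple(truth.labels), d))
        path = tmp_path / "tree.nwk"
        dt.write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        labels, paths = tree.path_lengths()
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                if i < j:
                    assert pdm.patristic_distance(
                        taxa[li], taxa[lj]
                    ) == pytest.approx(paths[i, j], abs=1e-6)


class TestPcoa:
    def test_euclidean_line_round_trip(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        d /= d.max()
        dm = dt.DistanceMatrix(("p0", "p1", "p2", "p3"), d)
        ordination = dt.pcoa(dm, n_axes=3)
        assert ordination.percent_variation[0] == pytest.approx(100.0, abs=1e-6)
        coords = ordination.coordinates
        recovered = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        assert np.allclose(recovered, d, atol=1e-9)

    def test_euclidean_cloud_round_trip(self, rng):
        points = rng.normal(size=(10, 4))
        diff = points[:, None, :] - points[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        d /= d.max()
        dm = dt.DistanceMatrix(tuple(f"p{i}" for i in range(10)), d)
        ordination = dt.pcoa(dm, n_axes=10)
        coords = ordination.coordinates
        recovered = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        assert np.allclose(recovered, d, atol=1e-9)

    def test_duplicate_samples_coincide(self, small_panel):
        row = [1, 0, 1, 1, 0]
        other = [0, 1, 0, 0, 1]
        m = gio.AlleleMatrix(
            small_panel, ("a", "a2", "b"),
            np.array([row, row, other], dtype=np.int8),
        )
        ordination = dt.pcoa(dt.jaccard_matrix(m), n_axes=2)
        assert np.allclose(
            ordination.coordinates[0], ordination.coordinates[1], atol=1e-9
        )

    def test_percent_variation_non_increasing(self, rng):
        m = random_matrix(rng, n_samples=12, missing_rate=0.0)
        ordination = dt.pcoa(dt.jaccard_matrix(m), n_axes=5)
        percents = ordination.percent_variation
        assert all(percents[i] >= percents[i + 1] - 1e-12 for i in range(4))
        assert percents.sum() <= 100.0 + 1e-9

    def test_all_zero_distances_degenerate(self):
        dm = dt.DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        ordination = dt.pcoa(dm, n_axes=2)
        assert ordination.degenerate
        assert np.allclose(ordination.coordinates, 0.0)

    def test_agrees_with_scikit_bio(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix as SkbioDM

        m = random_matrix(rng, n_samples=10, missing_rate=0.0)
        dm = dt.jaccard_matrix(m)
        ours = dt.pcoa(dm, n_axes=3)
        theirs = skbio_pcoa(SkbioDM(dm.values, ids=list(dm.ids)))
        # eigenvalues agree; coordinates agree up to per-axis sign
        assert np.allclose(
            ours.eigenvalues[:3], theirs.eigvals.values[:3], atol=1e-9
        )
        for axis in range(3):
            a = ours.coordinates[:, axis]
            b = theirs.samples.values[:, axis]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)
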