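"""p-distances, neighbor joining, annotation and Newick serialisation."""

import numpy as np
import pytest

import blasttriage as bt
from blasttriage.errors import IntegrityError, SelectionError
from blasttriage.pseudo_msa import PseudoMsa
from blasttriage.similarity_tree import sanitize_label
from helpers import (
    path_distance_matrix,
    random_additive_matrix,
    rf_distance,
    similarity_tree_newick_ids,
    textbook_nj,
)


def msa_from_rows(query_row, rows):
    return PseudoMsa(column_count=len(query_row), query_row=query_row,
                     rows=dict(rows))


class TestPDistance:
    def test_identical_rows_have_zero_distance(self):
        msa = msa_from_rows("ACDE", {"a": "ACDE", "b": "ACDE"})
        dm = bt.p_distance_matrix(msa, ["a", "b"])
        assert dm.values[0, 1] == 0.0

    def test_one_mismatch_in_four(self):
        msa = msa_from_rows("ACDE", {"a": "ACDE", "b": "ACDK"})
        dm = bt.p_distance_matrix(msa, ["a", "b"])
        assert dm.values[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_ignores_gap_columns(self):
        msa = msa_from_rows("ACDE", {"a": "AC-E", "b": "ACDE"})
        dm = bt.p_distance_matrix(msa, ["a", "b"], site_mode="all_sites")
        assert dm.values[0, 1] == 0.0

    def test_gap_free_mode_uses_shared_columns_for_all_pairs(self):
        # column 2 has a gap in row a, so no pair may use it
        msa = msa_from_rows("ACDE", {"a": "AC-E", "b": "ACKE", "c": "ACKW"})
        dm = bt.p_distance_matrix(msa, ["a", "b", "c"], site_mode="gap_free")
        # 3 usable columns (0,1,3); b vs c differ at column 3 only
        i, j = dm.labels.index("b"), dm.labels.index("c")
        assert dm.values[i, j] == pytest.approx(1 / 3)

    def test_gap_free_with_no_columns_is_an_error(self):
        msa = msa_from_rows("ACDE", {"a": "AC--", "b": "--DE"})
        with pytest.raises(SelectionError, match="all_sites"):
            bt.p_distance_matrix(msa, ["a", "b"], site_mode="gap_free")

    def test_disjoint_rows_get_distance_one_with_warning(self):
        msa = msa_from_rows("ACDE", {"a": "AC--", "b": "--DE"})
        with pytest.warns(UserWarning, match="comparable"):
            dm = bt.p_distance_matrix(msa, ["a", "b"], site_mode="all_sites")
        assert dm.values[0, 1] == 1.0

    def test_fewer_than_two_labels_rejected(self):
        msa = msa_from_rows("ACDE", {"a": "ACDE"})
        with pytest.raises(SelectionError):
            bt.p_distance_matrix(msa, ["a"])

    def test_matrix_is_symmetric_and_bounded(self, mixed_result):
        msa = bt.stack(mixed_result)
        labels = [msa.query_label] + msa.labels[:10]
        dm = bt.p_distance_matrix(msa, labels)
        assert np.allclose(dm.values, dm.values.T)
        assert dm.values.min() >= 0 and dm.values.max() <= 1
        assert np.all(np.diag(dm.values) == 0)


class TestNeighborJoining:
    def test_two_leaves_split_distance_in_half(self):
        dm = bt.DistanceMatrix(labels=["A", "B"],
                               values=np.array([[0, 0.3], [0.3, 0]]))
        tree = bt.neighbor_joining(dm)
        (a, b) = tree.root.children
        assert a.length == pytest.approx(0.15)
        assert b.length == pytest.approx(0.15)

    def test_three_leaves_closed_form(self):
        vals = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = bt.neighbor_joining(bt.DistanceMatrix(labels=list("ABC"),
                                                     values=vals))
        lengths = {lf.label: lf.length for lf in tree.leaves()}
        assert lengths["A"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert lengths["B"] == pytest.approx(0.4 - lengths["A"])
        assert lengths["C"] == pytest.approx(0.6 - lengths["A"])

    def test_recovers_known_additive_quartet(self):
        # generated by tree ((A:0.02,B:0.03):0.01,C:0.04,D:0.05) scaled x1:
        # AB=0.05 AC=0.07 AD=0.08 BC=0.08 BD=0.09 CD=0.09
        vals = np.array([
            [0.00, 0.05, 0.07, 0.08],
            [0.05, 0.00, 0.08, 0.09],
            [0.07, 0.08, 0.00, 0.09],
            [0.08, 0.09, 0.09, 0.00],
        ])
        labels = list("ABCD")
        tree = bt.neighbor_joining(bt.DistanceMatrix(labels=labels, values=vals))
        nwk = bt.to_newick(tree)
        assert rf_distance(nwk, "((A:0.02,B:0.03):0.01,(C:0.04,D:0.05):0);") == 0
        got = path_distance_matrix(nwk, labels)
        assert np.allclose(got, vals, atol=1e-9)

    @pytest.mark.parametrize("n_leaves", [5, 6])
    def test_agrees_with_textbook_oracle(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(20):
            labels, mat, _ = random_additive_matrix(n_leaves, rng)
            mine = bt.to_newick(bt.neighbor_joining(
                bt.DistanceMatrix(labels=labels, values=mat)))
            oracle = textbook_nj(labels, mat)
            assert rf_distance(mine, oracle) == 0
            assert np.allclose(path_distance_matrix(mine, labels),
                               path_distance_matrix(oracle, labels),
                               atol=1e-9)

    def test_agrees_with_skbio(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        labels, mat, _ = random_additive_matrix(7, rng)
        mine = bt.to_newick(bt.neighbor_joining(
            bt.DistanceMatrix(labels=labels, values=mat)))
        other = str(skbio_nj(SkbioDM(mat, labels)))
        assert rf_distance(mine, other) == 0

    def test_additive_recovery_with_exact_branch_lengths(self):
        rng = np.random.default_rng(11)
        for n_leaves in range(5, 13):
            labels, mat, truth_nwk = random_additive_matrix(n_leaves, rng)
            tree = bt.neighbor_joining(
                bt.DistanceMatrix(labels=labels, values=mat))
            nwk = bt.to_newick(tree)
            assert rf_distance(nwk, truth_nwk) == 0
            assert np.allclose(path_distance_matrix(nwk, labels), mat,
                               atol=1e-6)

    def test_deterministic_under_ties(self):
        # perfectly symmetric inputs: repeated runs give identical output
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 0.0)
        dm = bt.DistanceMatrix(labels=list("ABCD"), values=vals)
        first = bt.to_newick(bt.neighbor_joining(dm))
        for _ in range(5):
            assert bt.to_newick(bt.neighbor_joining(dm)) == first

    def test_branch_lengths_never_negative(self, mixed_result):
        msa = bt.stack(mixed_result)
        labels = [msa.query_label] + msa.labels
        tree = bt.neighbor_joining(bt.p_distance_matrix(msa, labels))

        def walk(node):
            assert node.length >= 0
            for child in node.children:
                walk(child)

        walk(tree.root)

    def test_asymmetric_matrix_rejected(self):
        vals = np.array([[0, 0.1, 0.2], [0.3, 0, 0.2], [0.2, 0.2, 0]])
        with pytest.raises(IntegrityError):
            bt.DistanceMatrix(labels=list("ABC"), values=vals)


class TestNewick:
    def test_minimal_two_leaf_form(self):
        dm = bt.DistanceMatrix(labels=["A", "B"],
                               values=np.array([[0, 0.3], [0.3, 0]]))
        assert bt.to_newick(bt.neighbor_joining(dm)) == "(A:0.15,B:0.15);"

    def test_label_sanitization(self):
        assert sanitize_label("E. coli (K12)") == "E._coli_K12"
        assert sanitize_label("a:b,c;d") == "abcd"

    def test_round_trip_is_isomorphic(self):
        import dendropy

        rng = np.random.default_rng(2)
        for n_leaves in (4, 6, 9):
            labels, mat, _ = random_additive_matrix(n_leaves, rng)
            nwk = bt.to_newick(bt.neighbor_joining(
                bt.DistanceMatrix(labels=labels, values=mat)))
            reparsed = dendropy.Tree.get(data=nwk, schema="newick")
            again = reparsed.as_string(schema="newick").strip()
            assert rf_distance(nwk, again) == 0


class TestAnnotateAndRebuild:
    def test_species_collisions_get_accession_suffix(self, annotated_result):
        tree = bt.rebuild_tree(annotated_result)
        labels = tree.leaf_labels
        assert len(labels) == len(set(labels))  # all unique
        by_species = {}
        for leaf in tree.leaves():
            sp = leaf.annotations.get("species")
            if sp:
                by_species.setdefault(sp, []).append(leaf.label)
        for sp, lbs in by_species.items():
            if len(lbs) > 1:
                for lb in lbs:
                    # suffix = accession, so label != plain species name
                    assert lb != sanitize_label(sp.replace(" ", "_"))

    def test_rank_grouping_counts_match_taxonomy(self, annotated_result,
                                                 taxonomy_table):
        tree = bt.rebuild_tree(annotated_result, rank="phylum")
        got_groups = {lf.annotations["group"] for lf in tree.leaves()
                      if lf.label != tree.query_label}
        expected = set()
        for hit in annotated_result.hits:
            if hit.lineage:
                names = [nm for rk, nm in hit.lineage if rk == "phylum"]
                expected.add(names[0] if names else "unknown")
            else:
                expected.add("unknown")
        assert got_groups == expected

    def test_hit_without_taxonomy_is_unknown_group(self, mixed_xml):
        result = bt.parse_blast_xml(mixed_xml)  # no annotation step
        tree = bt.rebuild_tree(result)
        groups = {lf.annotations["group"] for lf in tree.leaves()
                  if lf.label != tree.query_label}
        assert groups == {"unknown"}

    def test_default_scope_is_top_100_plus_query(self, tmp_path):
        truth = bt.simulate_dataset(n_hits=250, query_len=120, sub_rate=0.1,
                                    seed=9)
        xml = bt.emit_blast_xml(truth, tmp_path / "big.xml")
        result = bt.parse_blast_xml(xml)
        tree = bt.rebuild_tree(result)
        assert len(tree) == 101
        assert tree.query_label in tree.leaf_labels

    def test_selection_of_five_hits_gives_six_leaves(self, annotated_result):
        chosen = [h.hit_id for h in annotated_result.hits[:5]]
        tree = bt.rebuild_tree(annotated_result, selection=chosen)
        assert len(tree) == 6
        assert tree.query_label in tree.leaf_labels

    def test_site_mode_change_preserves_leaf_set(self, annotated_result):
        chosen = [h.hit_id for h in annotated_result.hits[:8]]
        t_all = bt.rebuild_tree(annotated_result, selection=chosen,
                                site_mode="all_sites")
        t_gf = bt.rebuild_tree(annotated_result, selection=chosen,
                               site_mode="gap_free")
        assert sorted(t_all.leaf_labels) == sorted(t_gf.leaf_labels)

    def test_nj_on_msa_distances_matches_oracle(self, mixed_result):
        msa = bt.stack(mixed_result)
        labels = [msa.query_label] + msa.labels[:5]
        dm = bt.p_distance_matrix(msa, labels)
        mine = bt.to_newick(bt.neighbor_joining(dm))
        oracle = textbook_nj(labels, dm.values)
        assert rf_distance(mine, oracle) == 0
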