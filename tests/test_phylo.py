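"""Taxonomy trees, patristic distances, D and per-phylum Dp."""

import numpy as np
import pandas as pd
import pytest

from ecomandala import (
    TaxonomyTable,
    build_taxonomy_tree,
    distance_summary,
    effective_distance,
    generate_taxonomy,
    phylum_distance,
    tip_distance_matrix,
)
from ecomandala.errors import NoPairsError, PhylumNotFoundError, UnknownOTUError
from ecomandala.phylo import TIP_DEPTH


def taxonomy_from(rows: dict) -> TaxonomyTable:
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["kingdom", "phylum", "class", "order", "family", "genus"],
    )
    return TaxonomyTable(assignments=df)


def brute_force_distances(tree):
    """Oracle: shortest-path walk on the explicit tree graph (networkx)."""
    import networkx as nx

    g = nx.Graph()
    for otu in tree.tip_ids:
        chain = ["root", *[tree.paths[otu][: r + 1] for r in range(6)], otu]
        for a, b in zip(chain, chain[1:]):
            g.add_edge(a, b, weight=1.0)
    n = len(tree.tip_ids)
    out = np.zeros((n, n))
    for i in range(n):
        lengths = nx.single_source_dijkstra_path_length(g, tree.tip_ids[i])
        for j in range(n):
            out[i, j] = lengths[tree.tip_ids[j]]
    return out


class TestTreeDistances:
    def test_shared_genus_distance_two(self):
        tax = taxonomy_from({
            "A": ["B", "P1", "C1", "O1", "F1", "G1"],
            "B": ["B", "P1", "C1", "O1", "F1", "G1"],
        })
        m = tip_distance_matrix(build_taxonomy_tree(tax, ["A", "B"]))
        assert m.values[0, 1] == 2.0

    def test_shared_kingdom_only_distance_twelve(self):
        tax = taxonomy_from({
            "A": ["B", "P1", "C1", "O1", "F1", "G1"],
            "B": ["B", "P2", "C2", "O2", "F2", "G2"],
        })
        m = tip_distance_matrix(build_taxonomy_tree(tax, ["A", "B"]))
        assert m.values[0, 1] == 12.0  # 6 edges up to kingdom + 6 down

    def test_three_tip_hand_counted(self):
        # two tips under one genus, one under a sister phylum:
        # within-genus pair at 2; cross-phylum pairs at 2*(7-1) = 12
        tax = taxonomy_from({
            "A": ["B", "P1", "C1", "O1", "F1", "G1"],
            "B": ["B", "P1", "C1", "O1", "F1", "G1"],
            "C": ["B", "P2", "C2", "O2", "F2", "G2"],
        })
        m = tip_distance_matrix(build_taxonomy_tree(tax, ["A", "B", "C"]))
        assert m.values[0, 1] == 2.0
        assert m.values[0, 2] == 12.0
        assert m.values[1, 2] == 12.0

    def test_symmetry_zero_diagonal(self):
        tax = generate_taxonomy(30, 5, seed=1, p_unassigned=0.2)
        m = tip_distance_matrix(build_taxonomy_tree(tax, tax.otu_ids))
        assert np.array_equal(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)

    def test_unassigned_under_different_parents_do_not_merge(self):
        tax = taxonomy_from({
            "A": ["B", "P1", "C1", "O1", "F1", "unassigned"],
            "B": ["B", "P2", "C2", "O2", "F2", "unassigned"],
        })
        m = tip_distance_matrix(build_taxonomy_tree(tax, ["A", "B"]))
        assert m.values[0, 1] == 12.0  # placeholders stay lineage-specific

    def test_uniform_tip_depth_with_unassigned(self):
        tax = taxonomy_from({
            "A": ["B", "P1", "unassigned", "unassigned", "unassigned", "unassigned"],
            "B": ["B", "P1", "C1", "O1", "F1", "G1"],
        })
        tree = build_taxonomy_tree(tax, ["A", "B"])
        assert all(len(tree.paths[o]) == TIP_DEPTH - 1 for o in tree.tip_ids)
        m = tip_distance_matrix(tree)
        assert m.values[0, 1] == 2 * (TIP_DEPTH - 2)  # share kingdom+phylum

    @pytest.mark.parametrize("n_tips,n_phyla,seed", [(20, 4, 0), (97, 9, 1), (200, 12, 2)])
    def test_matches_brute_force_path_walk(self, n_tips, n_phyla, seed):
        tax = generate_taxonomy(n_tips, n_phyla, seed=seed, p_unassigned=0.1)
        tree = build_taxonomy_tree(tax, tax.otu_ids)
        m = tip_distance_matrix(tree)
        np.testing.assert_array_equal(m.values, brute_force_distances(tree))

    def test_single_tip_matrix_refused(self):
        tax = taxonomy_from({"A": ["B", "P1", "C1", "O1", "F1", "G1"]})
        tree = build_taxonomy_tree(tax, ["A"])
        assert tree.n_tips == 1
        with pytest.raises(NoPairsError):
            tip_distance_matrix(tree)

    def test_unknown_otu_raises(self):
        tax = taxonomy_from({"A": ["B", "P1", "C1", "O1", "F1", "G1"]})
        with pytest.raises(UnknownOTUError):
            build_taxonomy_tree(tax, ["A", "ZZZ"])

    def test_matches_dendropy_patristic_distances(self):
        dendropy = pytest.importorskip("dendropy")
        tax = generate_taxonomy(40, 6, seed=3, p_unassigned=0.2)
        tree = build_taxonomy_tree(tax, tax.otu_ids)
        m = tip_distance_matrix(tree)
        dt = dendropy.Tree.get(
            data=tree.to_newick(), schema="newick", preserve_underscores=True
        )
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        for i in range(0, 40, 7):
            for j in range(i + 1, 40, 5):
                d = pdm.patristic_distance(taxa[m.otu_ids[i]], taxa[m.otu_ids[j]])
                assert d == pytest.approx(m.values[i, j])


class TestEffectiveDistance:
    def test_mean_of_pairwise_distances(self):
        # pairwise distances {2, 4, 4} -> D = 10/3
        tax = taxonomy_from({
            "A": ["B", "P1", "C1", "O1", "F1", "G1"],
            "B": ["B", "P1", "C1", "O1", "F1", "G1"],
            "C": ["B", "P1", "C1", "O1", "F1", "G3"],
        })
        m = tip_distance_matrix(build_taxonomy_tree(tax, ["A", "B", "C"]))
        assert sorted(m.values[np.triu_indices(3, 1)]) == [2.0, 4.0, 4.0]
        assert effective_distance(m) == pytest.approx(10 / 3)

    def test_two_tips(self):
        tax = taxonomy_from({
            "A": ["B", "P1", "C1", "O1", "F1", "G1"],
            "B": ["B", "P1", "C1", "O1", "F1", "G2"],
        })
        m = tip_distance_matrix(build_taxonomy_tree(tax, ["A", "B"]))
        assert effective_distance(m) == m.values[0, 1]

    def test_invariant_to_tip_order(self):
        tax = generate_taxonomy(25, 5, seed=4)
        ids = tax.otu_ids
        d1 = effective_distance(tip_distance_matrix(build_taxonomy_tree(tax, ids)))
        d2 = effective_distance(tip_distance_matrix(build_taxonomy_tree(tax, ids[::-1])))
        assert d1 == pytest.approx(d2)

    def test_deeper_divergence_never_decreases_distance(self):
        base = ["B", "P1", "C1", "O1", "F1", "G1"]
        prev = 0.0
        for split_rank in range(5, -1, -1):  # diverge at genus ... kingdom
            other = list(base)
            for r in range(split_rank, 6):
                other[r] = other[r] + "x"
            if split_rank == 0:
                other[0] = "Ax"
            tax = taxonomy_from({"A": base, "B": other})
            m = tip_distance_matrix(build_taxonomy_tree(tax, ["A", "B"]))
            assert m.values[0, 1] >= prev
            prev = m.values[0, 1]


class TestPhylumDistance:
    def test_single_phylum_all_others_equals_D(self):
        tax = taxonomy_from({
            "A": ["B", "P1", "C1", "O1", "F1", "G1"],
            "B": ["B", "P1", "C1", "O1", "F1", "G2"],
            "C": ["B", "P1", "C2", "O2", "F2", "G3"],
        })
        m = tip_distance_matrix(build_taxonomy_tree(tax, ["A", "B", "C"]))
        dp = phylum_distance(m, tax, "P1", pair_set="all_others")
        assert dp == pytest.approx(effective_distance(m))

    def test_between_phylum_enumeration_oracle(self):
        tax = taxonomy_from({
            "A": ["B", "P1", "C1", "O1", "F1", "G1"],
            "B": ["B", "P1", "C1", "O2", "F2", "G2"],
            "C": ["B", "P2", "C2", "O3", "F3", "G3"],
            "D": ["B", "P2", "C2", "O3", "F3", "G3"],
        })
        ids = ["A", "B", "C", "D"]
        m = tip_distance_matrix(build_taxonomy_tree(tax, ids))
        pairs = [
            m.values[i, j]
            for i, o1 in enumerate(ids) for j, o2 in enumerate(ids)
            if tax.phylum_of(o1) == "P1" and tax.phylum_of(o2) == "P2"
        ]
        assert phylum_distance(m, tax, "P1") == pytest.approx(np.mean(pairs))

    def test_absent_phylum_raises(self):
        tax = taxonomy_from({
            "A": ["B", "P1", "C1", "O1", "F1", "G1"],
            "B": ["B", "P2", "C1", "O1", "F1", "G1"],
        })
        m = tip_distance_matrix(build_taxonomy_tree(tax, ["A", "B"]))
        with pytest.raises(PhylumNotFoundError):
            phylum_distance(m, tax, "P9")

    def test_weighted_mean_of_dp_equals_D_under_all_others(self):
        tax = generate_taxonomy(40, 6, seed=9)
        m = tip_distance_matrix(build_taxonomy_tree(tax, tax.otu_ids))
        summary = distance_summary(m, tax, pair_set="all_others")
        total = sum(summary.n_pairs.values())
        weighted = sum(
            summary.per_phylum[p] * summary.n_pairs[p] for p in summary.per_phylum
        )
        assert weighted / total == pytest.approx(summary.D)


def test_newick_round_trip_tip_count():
    dendropy = pytest.importorskip("dendropy")
    tax = generate_taxonomy(15, 3, seed=5, p_unassigned=0.3)
    tree = build_taxonomy_tree(tax, tax.otu_ids)
    dt = dendropy.Tree.get(
        data=tree.to_newick(), schema="newick", preserve_underscores=True
    )
    assert len(dt.leaf_nodes()) == 15
    assert all(e.length == 1.0 for e in dt.preorder_edge_iter() if e.head_node.parent_node)
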