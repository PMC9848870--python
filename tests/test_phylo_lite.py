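"""Concatenation, distances, neighbor joining and tree queries."""

import itertools
import math
import random

import dendropy
import pandas as pd
import pytest

from mitokit.phylo_lite import (
    Supermatrix,
    concatenate,
    distance_matrix,
    export_supermatrix,
    is_monophyletic,
    neighbor_joining,
    pairwise_distance,
    read_supermatrix,
    rf_distance,
    topology_matches,
)


class TestConcatenate:
    def test_columns_sum(self):
        sm = concatenate({"g1": {"a": "ACGT", "b": "ACGA"},
                          "g2": {"a": "GG", "b": "GC"}})
        assert sm.n_columns == 6
        assert sm.partitions == {"g1": (0, 4), "g2": (4, 6)}

    def test_missing_taxon_gap_filled(self):
        sm = concatenate({"g1": {"a": "ACGT", "b": "ACGA"},
                          "g2": {"a": "GG"}}, taxa=["a", "b"])
        assert sm.sequences["b"] == "ACGA--"

    def test_unknown_taxon_is_error(self):
        with pytest.raises(ValueError):
            concatenate({"g1": {"a": "AC", "z": "AC"}}, taxa=["a"])

    def test_partition_map_tiles_columns(self, genome):
        from mitokit.annotation_io import extract_feature_sequence

        genes = {f.canonical_name: {"t1": extract_feature_sequence(genome, f)}
                 for f in genome.features}
        sm = concatenate(genes)
        spans = sorted(sm.partitions.values())
        assert spans[0][0] == 0 and spans[-1][1] == sm.n_columns
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))

    def test_ragged_gene_rejected(self):
        with pytest.raises(ValueError):
            concatenate({"g": {"a": "ACG", "b": "AC"}})


class TestDistances:
    def test_identical_zero(self):
        assert pairwise_distance("ACGT", "ACGT", "p") == 0.0

    def test_hand_counted_p(self):
        assert pairwise_distance("ACGT", "ACGA", "p") == 0.25

    def test_k2p_transversion_free_limit(self):
        # only transitions: Q=0, so d ~ -1/2 ln(1-2P)
        s1, s2 = "A" * 96 + "AAAA", "A" * 96 + "GGGG"
        p = 4 / 100
        assert pairwise_distance(s1, s2, "K2P") == \
            pytest.approx(-0.5 * math.log(1 - 2 * p), rel=1e-9)

    def test_pairwise_deletion_of_gaps(self):
        assert pairwise_distance("AC-T", "ACGT", "p") == 0.0
        assert pairwise_distance("ANGT", "ACGT", "p") == 0.0

    def test_k2p_dominates_p(self):
        rng = random.Random(0)
        for _ in range(10):
            s1 = "".join(rng.choice("ACGT") for _ in range(200))
            s2 = "".join(c if rng.random() > 0.1 else rng.choice("ACGT")
                         for c in s1)
            p = pairwise_distance(s1, s2, "p")
            k = pairwise_distance(s1, s2, "K2P")
            assert k >= p - 1e-12

    def test_matrix_symmetric_zero_diagonal(self, genome):
        seqs = {"a": "ACGTACGT", "b": "ACGAACGA", "c": "TCGAACGA"}
        d = distance_matrix(seqs, "p")
        assert (d.values == d.values.T).all()
        assert (d.values.diagonal() == 0).all()


def random_tree_and_additive_matrix(n, rng):
    """Random binary tree with integer branch lengths; its patristic
    matrix is additive by construction."""
    taxa = [f"t{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        taxon_namespace=tns, rng=rng)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = rng.randint(1, 10)
    pdm = tree.phylogenetic_distance_matrix()
    d = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for a, b in itertools.combinations(tns, 2):
        d.loc[a.label, b.label] = d.loc[b.label, a.label] = \
            pdm.patristic_distance(a, b)
    return tree, d


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # hand-built additive matrix from ((A:1,B:2):1,(C:3,D:4))
        d = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float)
        tree = neighbor_joining(d)
        assert topology_matches(tree, "((A,B),(C,D));")
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxa_star(self):
        d = pd.DataFrame([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        tree = neighbor_joining(d)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_recovery_against_patristic_oracle(self, n):
        """On additive matrices NJ must reproduce the generating tree:
        patristic distances of the NJ tree equal the input exactly."""
        rng = random.Random(100 + n)
        truth, d = random_tree_and_additive_matrix(n, rng)
        nj = neighbor_joining(d)
        assert rf_distance(nj, truth) == 0
        pdm = nj.phylogenetic_distance_matrix()
        for a, b in itertools.combinations(nj.taxon_namespace, 2):
            assert pdm.patristic_distance(a, b) == \
                pytest.approx(d.loc[a.label, b.label])

    def test_undefined_entry_is_error(self):
        d = pd.DataFrame([[0, float("nan"), 1], [float("nan"), 0, 1],
                          [1, 1, 0]], index=list("ABC"), columns=list("ABC"))
        with pytest.raises(ValueError):
            neighbor_joining(d)

    def test_deterministic_under_ties(self):
        d = pd.DataFrame(1.0, index=list("ABCD"), columns=list("ABCD"))
        for i in range(4):
            d.iloc[i, i] = 0.0
        t1 = neighbor_joining(d).as_string(schema="newick")
        t2 = neighbor_joining(d).as_string(schema="newick")
        assert t1 == t2


class TestTreeQueries:
    TREE = "((A:1,B:1):1,(C:1,D:1):1);"

    def _tree(self):
        return dendropy.Tree.get(data=self.TREE, schema="newick")

    def test_monophyly_true(self):
        assert is_monophyletic(self._tree(), {"A", "B"}, outgroup="D")

    def test_monophyly_false(self):
        assert not is_monophyletic(self._tree(), {"A", "C"}, outgroup="D")

    def test_unknown_taxon_is_error(self):
        with pytest.raises(ValueError):
            is_monophyletic(self._tree(), {"A", "Z"}, outgroup="D")

    def test_rf_distance_to_self_is_zero(self):
        assert rf_distance(self._tree(), self._tree()) == 0

    def test_study_topology_fixture(self):
        """The wagtail clade structure: flava+tschutschensis sister pair,
        alba next, cinerea basal."""
        study = dendropy.Tree.get(
            data="((((M.flava:1,M.tschutschensis:1):1,M.alba:2):1,"
                 "M.cinerea:3):1,D.indicus:4);",
            schema="newick")
        assert topology_matches(
            study, "(((M.flava,M.tschutschensis),M.alba),M.cinerea);")
        assert not topology_matches(
            study, "(((M.flava,M.alba),M.tschutschensis),M.cinerea);")
        assert is_monophyletic(
            study, {"M.flava", "M.tschutschensis"}, outgroup="D.indicus")


class TestExport:
    SM = Supermatrix(["t one", "t2"], {"t one": "ACGT-A", "t2": "ACGAAA"},
                     {"g1": (0, 4), "g2": (4, 6)})

    def test_phylip_header_and_round_trip(self, tmp_path):
        p = tmp_path / "m.phy"
        mapping = export_supermatrix(self.SM, p, "phylip")
        assert p.read_text().splitlines()[0] == "2 6"
        assert mapping["t one"] == "t_one"
        back = read_supermatrix(p, "phylip")
        assert back.sequences == {"t_one": "ACGT-A", "t2": "ACGAAA"}

    def test_nexus_charsets_match_partitions(self, tmp_path):
        p = tmp_path / "m.nex"
        export_supermatrix(self.SM, p, "nexus")
        back = read_supermatrix(p, "nexus")
        assert back.partitions == self.SM.partitions
        assert back.sequences["t_one"] == "ACGT-A"

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            Supermatrix(["a", "b"], {"a": "AC", "b": "ACG"}, {})
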