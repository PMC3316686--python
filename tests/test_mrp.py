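"""MRP coding, weighted parsimony scoring and search, strict consensus."""

import itertools

import numpy as np
import pytest

from coraledge import read_newick, write_newick
from coraledge.mrp import (
    ROOT_TAXON,
    SourceTree,
    build_supertree,
    encode_mrp,
    fitch_score,
    parsimony_search,
    strict_consensus,
)
from coraledge.synth import SyntheticStudyConfig, extract_source_trees, simulate_tree
from coraledge.tree import prune_to


def src(newick, **kw):
    return SourceTree(read_newick(newick), **kw)


class TestEncoding:
    def test_single_clade_with_missing_taxon(self):
        m = encode_mrp([src("((A,B)80,C);")], all_taxa={"A", "B", "C", "D"})
        assert m.n_characters == 1
        states = dict(zip(m.taxa, m.states[:, 0]))
        assert states == {"A": 1, "B": 1, "C": 0, "D": -1}
        assert m.weights[0] == 80.0

    def test_taxonomy_tree_unit_weights(self):
        m = encode_mrp([src("((A,B)95,(C,D)90);", provenance="taxonomic")])
        assert m.n_characters == 2
        assert list(m.weights) == [1.0, 1.0]

    def test_duplicate_sources_not_merged(self):
        m = encode_mrp([src("((A,B)80,C);"), src("((A,B)60,C);")])
        assert m.n_characters == 2
        assert sorted(m.weights) == [60.0, 80.0]
        assert np.array_equal(m.states[:, 0], m.states[:, 1])

    def test_character_count_equals_informative_nodes(self):
        # ((A,B),((C,D),E)) has 3 non-root internal nodes
        m = encode_mrp([src("((A,B)70,((C,D)60,E)50);")])
        assert m.n_characters == 3

    def test_tiny_source_warns_and_contributes_nothing(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                encode_mrp([src("(A,B);")])

    def test_empty_source_list_rejected(self):
        with pytest.raises(ValueError):
            encode_mrp([])

    def test_root_taxon_all_zero(self):
        m = encode_mrp([src("((A,B)80,C);")], add_root_taxon=True)
        i = m.taxa.index(ROOT_TAXON)
        assert np.all(m.states[i] == 0)

    def test_nexus_export_has_weights(self):
        m = encode_mrp([src("((A,B)80,C);")])
        nx = m.to_nexus()
        assert "WTSET" in nx and "80" in nx and "MISSING=?" in nx


class TestFitchScore:
    def test_hand_scored_character(self):
        m = encode_mrp([src("((A,B)80,C);")])
        assert fitch_score(read_newick("((A,B),C);"), m) == 80.0
        # one change still suffices on the alternative grouping
        assert fitch_score(read_newick("((A,C),B);"), m) == 80.0

    def test_two_changes_when_ones_split(self):
        # character A=1,B=1,C=0,D=0; tree interleaves the 1s
        m = encode_mrp([src("((A,B)80,(C,D)70);")])
        t = read_newick("((A,C),(B,D));")
        # clade {A,B} needs 2 changes, clade {C,D} needs 2 as well
        assert fitch_score(t, m) == 80.0 * 2 + 70.0 * 2

    def test_polytomies_scored_exactly(self):
        # A=1,B=1,C=0 on a star: one change (root in state 1, C flips)
        m = encode_mrp([src("((A,B)80,C);")])
        assert fitch_score(read_newick("(A,B,C);"), m) == 80.0
        # two 1s vs two 0s on a 4-star: two changes whatever the root state
        m2 = encode_mrp([src("((A,B)80,(C,D)70);")])
        assert fitch_score(read_newick("(A,B,C,D);"), m2) == 2 * 80.0 + 2 * 70.0

    def test_invariant_to_orders_and_weight_scale(self):
        sources = [src("((A,B)80,C);"), src("((B,C)40,(A,D)30);")]
        m = encode_mrp(sources)
        t = read_newick("(((A,B),C),D);")
        base = fitch_score(t, m)
        # character order
        perm = np.array([1, 2, 0])
        m2 = encode_mrp(sources)
        m2.states = m2.states[:, perm]
        m2.weights = m2.weights[perm]
        m2.character_provenance = [m.character_provenance[i] for i in perm]
        assert fitch_score(t, m2) == base
        # taxon order
        order = [3, 1, 0, 2]
        m3 = encode_mrp(sources)
        m3.taxa = [m.taxa[i] for i in order]
        m3.states = m3.states[order]
        assert fitch_score(t, m3) == base
        # weight scaling
        m4 = encode_mrp(sources)
        m4.weights = m4.weights * 2.5
        assert fitch_score(t, m4) == pytest.approx(2.5 * base)

    def test_missing_taxon_in_tree_rejected(self):
        m = encode_mrp([src("((A,B)80,C);")])
        with pytest.raises(ValueError):
            fitch_score(read_newick("((A,B),X);"), m)


def _all_unrooted_scores(matrix):
    """Brute-force oracle: score every unrooted topology on the matrix taxa
    (enumerated by stepwise leaf addition)."""
    from coraledge.mrp import _attachment_points, _insert_leaf_above, _two_leaf_base, _unrooted_key

    taxa = matrix.taxa
    trees = [_two_leaf_base(taxa[0], taxa[1])]
    for t in taxa[2:]:
        trees = [
            _insert_leaf_above(tr, p, t)
            for tr in trees
            for p in _attachment_points(tr)
        ]
    return {_unrooted_key(t): fitch_score(t, matrix) for t in trees}


class TestSearch:
    def test_branch_and_bound_matches_enumeration(self):
        sources = [src("((A,B)80,C);"), src("((B,C)40,(A,D)30);"), src("((C,E)20,D);")]
        m = encode_mrp(sources)
        oracle = _all_unrooted_scores(m)
        best = min(oracle.values())
        res = parsimony_search(m, "branch_and_bound", seed=0)
        assert res.score == best
        from coraledge.mrp import _unrooted_key

        assert {_unrooted_key(t) for t in res.trees} == {
            k for k, v in oracle.items() if v == best
        }

    def test_single_source_recovered_uniquely(self):
        source = src("(((A,B)70,C)90,(D,E)60);")
        m = encode_mrp([source], add_root_taxon=True)
        res = parsimony_search(m, "branch_and_bound", seed=1, root_taxon=ROOT_TAXON)
        assert len(res.trees) == 1
        assert res.trees[0].topology_key() == source.tree.topology_key()
        # every character changes exactly once
        assert res.score == m.weights.sum()

    def test_conflict_collapses_to_polytomy(self):
        m = encode_mrp(
            [src("((A,B)80,C);"), src("((A,C)80,B);")], add_root_taxon=True
        )
        res = parsimony_search(m, "branch_and_bound", seed=0, root_taxon=ROOT_TAXON)
        assert len(res.trees) >= 2
        cons = strict_consensus(res.trees)
        assert cons.clades() == set()  # star: no shared grouping

    def test_weight_dominance(self):
        m = encode_mrp(
            [src("((A,B)90,C);"), src("((A,C)10,B);")], add_root_taxon=True
        )
        res = parsimony_search(m, "branch_and_bound", seed=0, root_taxon=ROOT_TAXON)
        assert len(res.trees) == 1
        assert frozenset({"A", "B"}) in res.trees[0].clades()

    def test_hill_climb_finds_optimum_small(self):
        sources = [src("((A,B)80,C);"), src("((B,C)40,(A,D)30);"), src("((C,E)20,D);")]
        m = encode_mrp(sources)
        exact = parsimony_search(m, "branch_and_bound", seed=0).score
        heur = parsimony_search(m, "hill_climb", n_starts=8, seed=3)
        assert heur.score == exact
        assert heur.n_rearrangements > 0

    def test_hill_climb_respects_rearrangement_limit(self):
        cfg = SyntheticStudyConfig(
            n_species=10,
            polytomy_fraction=0.0,
            missing_data_fraction=0.0,
            n_source_trees=4,
            source_size_range=(5, 8),
            include_taxonomy_source=False,
            seed=5,
        )
        model = simulate_tree(cfg)
        m = encode_mrp(extract_source_trees(model, cfg))
        res = parsimony_search(m, "hill_climb", n_starts=3, rearrangement_limit=7, seed=0)
        assert res.n_rearrangements <= 7

    def test_guards(self):
        m = encode_mrp([src("((A,B)80,C);")])
        with pytest.raises(ValueError):
            parsimony_search(m, "hill_climb")  # 3 taxa
        m4 = encode_mrp([src("((A,B)80,(C,D)70);")])
        with pytest.raises(ValueError):
            parsimony_search(m4, "hill_climb", rearrangement_limit=0)


class TestStrictConsensus:
    def test_single_tree_identity(self):
        t = read_newick("((A,B),(C,D));")
        assert strict_consensus([t]).topology_key() == t.topology_key()

    def test_total_conflict_gives_star(self):
        cons = strict_consensus(
            [read_newick("((A,B),C);"), read_newick("((A,C),B);")]
        )
        assert cons.clades() == set()
        assert sorted(cons.leaf_labels()) == ["A", "B", "C"]

    def test_shared_clade_retained(self):
        trees = [
            read_newick("(((A,B),C),D);"),
            read_newick("(((A,B),D),C);"),
            read_newick("((A,B),(C,D));"),
        ]
        assert frozenset({"A", "B"}) in strict_consensus(trees).clades()

    def test_tip_mismatch_rejected(self):
        with pytest.raises(ValueError):
            strict_consensus([read_newick("((A,B),C);"), read_newick("((A,B),D);")])


class TestSupertreePipeline:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conflict_free_sources_recovered(self, seed):
        """With conflict-free induced-subtree sources, every source clade
        reappears as an induced clade of the searched strict consensus."""
        cfg = SyntheticStudyConfig(
            n_species=10,
            polytomy_fraction=0.0,
            missing_data_fraction=0.0,
            n_source_trees=5,
            source_size_range=(5, 8),
            include_taxonomy_source=False,
            seed=100 + seed,
        )
        model = simulate_tree(cfg)
        sources = extract_source_trees(model, cfg, conflict_rate=0.0)
        cons, res = build_supertree(sources, n_starts=5, seed=seed)
        # the consensus asserts only clades of the generating model tree
        # (restricted to the taxa sampled by at least one source)
        sampled = set().union(*(s.tree.leaf_labels() for s in sources))
        assert cons.clades() <= prune_to(
            model, sampled, include_root_path=False
        ).clades()
        # every optimal tree displays every source clade on its own taxa
        for t in res.trees:
            for s in sources:
                induced = prune_to(
                    t, s.tree.leaf_labels(), include_root_path=False
                ).clades()
                for clade in s.tree.clades():
                    assert clade in induced
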