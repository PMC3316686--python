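"""Synthetic study generator: determinism, exact counts, controlled
phylogenetic structure."""

from collections import Counter

import numpy as np
import pytest

from coraledge.edge import RedListCategory
from coraledge.signal import fritz_purvis_d
from coraledge.synth import (
    PAPER_CATEGORY_COUNTS,
    SyntheticStudyConfig,
    TraitSpec,
    extract_source_trees,
    scaled_category_counts,
    simulate_binary_traits,
    simulate_categories,
    simulate_study,
    simulate_tree,
    write_study,
)
from coraledge.tree import prune_to, read_newick, write_newick


def cfg(**kw):
    defaults = dict(
        n_species=60,
        polytomy_fraction=0.0,
        missing_data_fraction=0.0,
        seed=1,
    )
    defaults.update(kw)
    return SyntheticStudyConfig(**defaults)


class TestTreeSimulation:
    def test_clean_tree_is_binary_with_positive_lengths(self):
        t = simulate_tree(cfg())
        assert t.is_binary()
        assert t.n_leaves == 60
        assert all(
            (n.length or 0) > 0 for n in t.preorder() if n.parent is not None
        )

    def test_deterministic(self):
        a = simulate_tree(cfg(seed=9))
        b = simulate_tree(cfg(seed=9))
        assert write_newick(a) == write_newick(b)
        assert write_newick(a) != write_newick(simulate_tree(cfg(seed=10)))

    def test_polytomy_fraction_removes_internal_nodes(self):
        clean = simulate_tree(cfg(n_species=100))
        degraded = simulate_tree(cfg(n_species=100, polytomy_fraction=0.3))
        n_clean = len(clean.internal_nodes())  # 99 on a binary 100-tip tree
        n_deg = len(degraded.internal_nodes())
        removed = n_clean - n_deg
        expected = round(0.3 * (n_clean - 1))  # root is never collapsed
        assert abs(removed - expected) <= 1
        assert not degraded.is_binary()

    def test_missing_fraction_zeroes_terminals(self):
        t = simulate_tree(cfg(n_species=80, missing_data_fraction=0.25))
        zero_tips = sum(1 for l in t.leaves() if l.length == 0.0)
        assert zero_tips == 20

    def test_birth_death_guard(self):
        with pytest.raises(ValueError):
            SyntheticStudyConfig(
                n_species=10, tree_model="birth_death", birth_rate=1.0, death_rate=1.5
            )


class TestCategories:
    def test_default_census_is_the_printed_one(self):
        counts = SyntheticStudyConfig(n_species=837).category_counts()
        assert counts == PAPER_CATEGORY_COUNTS
        assert sum(counts.values()) == 837

    def test_scaled_counts_sum_exactly(self):
        for n in (10, 60, 100, 500):
            assert sum(scaled_category_counts(n).values()) == n

    def test_exact_assignment(self):
        c = cfg()
        t = simulate_tree(c)
        cats = simulate_categories(t, c)
        observed = Counter(cats.values())
        expected = {k: v for k, v in c.category_counts().items() if v > 0}
        assert dict(observed) == expected

    def test_brownian_mode_is_clumped_random_mode_is_not(self):
        c = cfg(n_species=64, seed=3)
        t = simulate_tree(c)

        def vu_indicator(cats):
            members = {RedListCategory.CR, RedListCategory.EN, RedListCategory.VU}
            from coraledge.signal import TraitVector

            return TraitVector(
                {s: 1.0 if cat in members else 0.0 for s, cat in cats.items()},
                "vu_plus",
                "binary",
            )

        d_random = np.mean(
            [
                fritz_purvis_d(
                    t,
                    vu_indicator(simulate_categories(t, cfg(n_species=64, seed=s), "none")),
                    100,
                    100,
                    seed=s,
                ).observed
                for s in range(15)
            ]
        )
        d_brown = np.mean(
            [
                fritz_purvis_d(
                    t,
                    vu_indicator(
                        simulate_categories(t, cfg(n_species=64, seed=s), "brownian")
                    ),
                    100,
                    100,
                    seed=s,
                ).observed
                for s in range(15)
            ]
        )
        assert d_random > 0.7
        assert d_brown < 0.3

    def test_count_mismatch_rejected(self):
        c = cfg(category_frequencies={"LC": 59, "CR": 1})
        t = simulate_tree(cfg())
        with pytest.raises(ValueError):
            SyntheticStudyConfig(n_species=10, category_frequencies={"LC": 3})


class TestBinaryTraits:
    def test_exact_prevalences(self):
        c = cfg(n_species=100)
        t = simulate_tree(c)
        traits = simulate_binary_traits(t, c)
        for spec in c.trait_specs:
            vec = traits[spec.name].vector(t.leaf_labels())
            assert vec.sum() == round(spec.prevalence * 100)

    def test_shared_liability_traits_overlap(self):
        c = cfg(
            n_species=80,
            trait_specs=[
                TraitSpec("a", 0.3, "clumped_brownian_threshold", "g"),
                TraitSpec("b", 0.4, "clumped_brownian_threshold", "g"),
                TraitSpec("c", 0.3, "clumped_brownian_threshold"),
            ],
        )
        t = simulate_tree(c)
        traits = simulate_binary_traits(t, c)
        a = traits["a"].vector(t.leaf_labels())
        b = traits["b"].vector(t.leaf_labels())
        # same liability, nested thresholds: every carrier of the rarer
        # trait also carries the commoner one
        assert np.all(b[a == 1] == 1)

    def test_deterministic(self):
        c = cfg(seed=5)
        t = simulate_tree(c)
        t1 = simulate_binary_traits(t, c)
        t2 = simulate_binary_traits(t, c)
        assert all(t1[k].values == t2[k].values for k in t1)


class TestSourceTrees:
    def test_conflict_free_sources_are_induced_subtrees(self):
        c = cfg(n_species=30, n_source_trees=6, source_size_range=(5, 10))
        t = simulate_tree(c)
        for s in extract_source_trees(t, c, conflict_rate=0.0):
            induced = prune_to(t, s.tree.leaf_labels(), include_root_path=False)
            assert s.tree.topology_key() == induced.topology_key()

    def test_conflict_rate_perturbs_sources(self):
        c = cfg(n_species=30, n_source_trees=20, source_size_range=(8, 12), seed=8)
        t = simulate_tree(c)
        perturbed = 0
        for s in extract_source_trees(t, c, conflict_rate=0.5):
            induced = prune_to(t, s.tree.leaf_labels(), include_root_path=False)
            perturbed += s.tree.topology_key() != induced.topology_key()
        assert 4 <= perturbed <= 16  # ~10 expected of 20

    def test_support_range_and_taxonomy_flag(self):
        c = cfg(n_species=20, n_source_trees=3, include_taxonomy_source=True)
        t = simulate_tree(c)
        sources = extract_source_trees(t, c, support_range=(100, 100))
        assert sources[0].provenance == "taxonomic"
        for s in sources:
            for n in s.tree.internal_nodes():
                if n.parent is not None:
                    assert n.support == 100.0


class TestStudyAssembly:
    def test_representation_counts_match_sources(self):
        study = simulate_study(cfg(n_species=25, n_source_trees=4, source_size_range=(5, 9)))
        manual = Counter()
        for s in study.sources:
            manual.update(s.tree.leaf_labels())
        for sp in study.tree.leaf_labels():
            assert study.representation[sp] == manual.get(sp, 0)

    def test_written_study_round_trips(self, tmp_path):
        from coraledge.mrp import read_source_trees
        from coraledge.pipeline import read_species_table, read_traits_table

        study = simulate_study(cfg(n_species=20, n_source_trees=3, source_size_range=(5, 8)))
        write_study(study, tmp_path)
        tree = read_newick(tmp_path / "supertree.nwk")
        assert tree.topology_key() == study.tree.topology_key()
        df = read_species_table(tmp_path / "species_table.tsv")
        assert len(df) == 20
        assert dict(zip(df["species"], df["category"])) == study.categories
        traits = read_traits_table(tmp_path / "traits.tsv")
        assert set(traits) == set(study.traits)
        sources = read_source_trees(tmp_path / "sources" / "manifest.tsv")
        assert len(sources) == 3
        assert (tmp_path / "manifest.yaml").exists()
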