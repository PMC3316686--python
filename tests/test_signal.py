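"""Blomberg's K, Fritz & Purvis' D, independent contrasts."""

import numpy as np
import pytest

from coraledge.signal import (
    TraitVector,
    binary_contrast_correlation,
    blomberg_k,
    fritz_purvis_d,
    independent_contrasts,
    k_randomization_test,
    simulate_brownian_tips,
    stratified_signal,
)
from coraledge.tree import read_newick, resolve_polytomies

# Six-tip reference tree with continuous traits; expected contrasts, slope
# and K values were computed independently with ape::pic and picante::Kcalc
# (R 4.3) and frozen here.
ORACLE_NEWICK = "(((A:1.2,B:0.8):0.5,(C:0.6,D:1.4):0.9):0.3,(E:2.0,F:1.1):0.7);"
ORACLE_X = dict(A=1.3, B=0.9, C=-0.2, D=0.5, E=2.1, F=-1.0)
ORACLE_Y = dict(A=2.2, B=1.1, C=0.3, D=0.8, E=3.5, F=-0.9)
ORACLE_PIC_X = [0.3400721617, 0.6923494971, 0.2828427125, 0.4949747468, 1.7606816862]
ORACLE_PIC_Y = [0.2748360693, 0.7187247160, 0.7778174593, 0.3535533906, 2.4990320707]
ORACLE_SLOPE = 1.3398201352
ORACLE_SLOPE_P = 0.0008191086
ORACLE_K_X = 0.8352988504
ORACLE_K_Y = 0.8566159868


@pytest.fixture
def oracle_tree():
    return read_newick(ORACLE_NEWICK)


def _trait(values, kind="continuous", name="t"):
    return TraitVector(values=dict(values), trait_name=name, kind=kind)


class TestBlombergK:
    def test_matches_reference_implementation(self, oracle_tree):
        assert blomberg_k(oracle_tree, _trait(ORACLE_X)) == pytest.approx(
            ORACLE_K_X, abs=1e-9
        )
        assert blomberg_k(oracle_tree, _trait(ORACLE_Y)) == pytest.approx(
            ORACLE_K_Y, abs=1e-9
        )

    def test_equal_star_tree_gives_one(self):
        star = read_newick("(A:1,B:1,C:1,D:1,E:1);")
        assert blomberg_k(star, _trait(dict(A=3.0, B=-1.0, C=0.2, D=7.0, E=1.1))) == (
            pytest.approx(1.0)
        )

    def test_affine_trait_invariance(self, oracle_tree):
        base = blomberg_k(oracle_tree, _trait(ORACLE_X))
        shifted = {k: 3.0 * v - 7.0 for k, v in ORACLE_X.items()}
        assert blomberg_k(oracle_tree, _trait(shifted)) == pytest.approx(base)

    def test_branch_scale_invariance(self, oracle_tree):
        base = blomberg_k(oracle_tree, _trait(ORACLE_X))
        scaled = oracle_tree.copy()
        for n in scaled.preorder():
            if n.length is not None:
                n.length *= 4.2
        assert blomberg_k(scaled, _trait(ORACLE_X)) == pytest.approx(base)

    def test_brownian_traits_near_one(self, yule_tree):
        ks = []
        for seed in range(40):
            t = yule_tree(48, seed=400 + seed)
            vals, labels = simulate_brownian_tips(
                t, 1, np.random.default_rng(seed)
            )
            ks.append(blomberg_k(t, _trait(dict(zip(labels, vals[:, 0])))))
        assert 0.85 < np.mean(ks) < 1.15

    def test_degenerate_inputs_rejected(self, oracle_tree):
        with pytest.raises(ValueError):
            blomberg_k(oracle_tree, _trait({k: 1.0 for k in ORACLE_X}))
        with pytest.raises(ValueError):
            blomberg_k(read_newick("((A:1,B:1):1,C:1);"), _trait(dict(A=1, B=2, C=3)))


class TestKRandomization:
    def test_deterministic_and_positive_p(self, oracle_tree):
        a = k_randomization_test(oracle_tree, _trait(ORACLE_X), 199, seed=7)
        b = k_randomization_test(oracle_tree, _trait(ORACLE_X), 199, seed=7)
        assert a.p_vs_random == b.p_vs_random
        assert 0 < a.p_vs_random <= 1
        assert a.n_replicates == 199

    def test_detects_brownian_signal(self, yule_tree):
        t = yule_tree(64, seed=11)
        vals, labels = simulate_brownian_tips(t, 1, np.random.default_rng(1))
        res = k_randomization_test(t, _trait(dict(zip(labels, vals[:, 0]))), 199, seed=0)
        assert res.p_vs_random < 0.05

    def test_low_replicate_warning(self, oracle_tree):
        with pytest.warns(UserWarning):
            k_randomization_test(oracle_tree, _trait(ORACLE_X), 50, seed=0)


class TestFritzPurvisD:
    def test_clade_indicator_is_clumped(self):
        # one half-tree carries the trait: maximally clumped
        tips_a = [f"A{i}" for i in range(16)]
        tips_b = [f"B{i}" for i in range(16)]

        def comb(tips):
            s = f"{tips[0]}:1"
            for t in tips[1:]:
                s = f"({s},{t}:1):1"
            return s

        t = read_newick(f"({comb(tips_a)},{comb(tips_b)});")
        trait = _trait(
            {**{t_: 1.0 for t_ in tips_a}, **{t_: 0.0 for t_ in tips_b}},
            kind="binary",
        )
        res = fritz_purvis_d(t, trait, 200, 200, seed=0)
        assert res.observed < 0.5
        assert res.p_vs_random < 0.01  # strongly rejects the random null

    def test_random_trait_near_one(self, yule_tree):
        ds = []
        for seed in range(30):
            t = yule_tree(48, seed=500 + seed)
            rng = np.random.default_rng(seed)
            vec = np.zeros(48)
            vec[:14] = 1.0
            trait = _trait(
                dict(zip(t.leaf_labels(), rng.permutation(vec))), kind="binary"
            )
            ds.append(fritz_purvis_d(t, trait, 100, 100, seed=seed).observed)
        assert 0.8 < np.mean(ds) < 1.2

    def test_brownian_threshold_near_zero(self, yule_tree):
        ds = []
        for seed in range(30):
            t = yule_tree(48, seed=600 + seed)
            vals, labels = simulate_brownian_tips(t, 1, np.random.default_rng(seed))
            order = np.argsort(-vals[:, 0])
            vec = np.zeros(48)
            vec[order[:14]] = 1.0
            trait = _trait(dict(zip(labels, vec)), kind="binary")
            ds.append(fritz_purvis_d(t, trait, 100, 100, seed=seed).observed)
        assert -0.2 < np.mean(ds) < 0.2

    def test_monomorphic_rejected(self, oracle_tree):
        with pytest.raises(ValueError):
            fritz_purvis_d(
                oracle_tree,
                _trait({k: 1.0 for k in ORACLE_X}, kind="binary"),
                50,
                50,
                seed=0,
            )

    def test_plus_one_rule(self, yule_tree):
        t = yule_tree(32, seed=3)
        vec = np.zeros(32)
        vec[:10] = 1.0
        trait = _trait(dict(zip(t.leaf_labels(), vec)), kind="binary")
        res = fritz_purvis_d(t, trait, 99, 99, seed=0)
        assert res.p_vs_random >= 1 / 100
        assert res.p_vs_clumped >= 1 / 100


class TestContrasts:
    def test_two_tip_contrast(self):
        t = read_newick("(A:1,B:1);")
        res = independent_contrasts(t, _trait(dict(A=4, B=2)), _trait(dict(A=1, B=1.5)))
        assert abs(res.contrasts_x[0]) == pytest.approx(2 / np.sqrt(2))
        assert res.n_contrasts == 1

    def test_matches_reference_implementation(self, oracle_tree):
        res = independent_contrasts(
            oracle_tree, _trait(ORACLE_X), _trait(ORACLE_Y)
        )
        assert sorted(np.abs(res.contrasts_x)) == pytest.approx(
            sorted(ORACLE_PIC_X), abs=1e-9
        )
        assert sorted(np.abs(res.contrasts_y)) == pytest.approx(
            sorted(ORACLE_PIC_Y), abs=1e-9
        )
        assert res.slope == pytest.approx(ORACLE_SLOPE, abs=1e-9)
        assert res.p_value == pytest.approx(ORACLE_SLOPE_P, abs=1e-9)

    def test_linear_trait_gives_exact_slope(self, oracle_tree):
        y = {k: 2.0 * v for k, v in ORACLE_X.items()}
        res = independent_contrasts(oracle_tree, _trait(ORACLE_X), _trait(y))
        assert res.slope == pytest.approx(2.0)
        assert res.contrasts_y == pytest.approx(2.0 * res.contrasts_x)

    def test_polytomy_rejected(self):
        t = read_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="bifurcating"):
            independent_contrasts(t, _trait(dict(A=1, B=2, C=3)), _trait(dict(A=1, B=2, C=3)))

    def test_binary_identity_and_complement(self, yule_tree):
        t = yule_tree(16, seed=21)
        vec = dict(zip(t.leaf_labels(), ([1.0] * 5 + [0.0] * 11)))
        x = _trait(vec, kind="binary")
        same = binary_contrast_correlation(t, x, x)
        assert same.slope == pytest.approx(1.0)
        comp = binary_contrast_correlation(
            t, x, _trait({k: 1 - v for k, v in vec.items()}, kind="binary")
        )
        assert comp.slope == pytest.approx(-1.0)

    def test_zero_length_edges_handled(self, yule_tree):
        t = yule_tree(24, seed=31, polytomy_fraction=0.3, missing_data_fraction=0.4)
        rep = resolve_polytomies(t, 1, seed=0).replicates[0]
        x = dict(zip(rep.leaf_labels(), np.arange(24.0)))
        res = independent_contrasts(rep, _trait(x), _trait(x))
        assert np.all(np.isfinite(res.contrasts_x))
        assert res.slope == pytest.approx(1.0)


class TestStratified:
    def test_whole_tree_stratum_matches_plain_run(self, yule_tree):
        t = yule_tree(32, seed=41)
        vec = np.zeros(32)
        vec[:12] = 1.0
        trait = _trait(dict(zip(t.leaf_labels(), vec)), kind="binary")
        strata = {s: "all" for s in t.leaf_labels()}
        res = stratified_signal(t, trait, strata, 99, 99, seed=5)["all"]
        plain = fritz_purvis_d(t, trait, 99, 99, seed=5)
        assert res.observed == pytest.approx(plain.observed)
        assert res.p_vs_random == plain.p_vs_random

    def test_monomorphic_stratum_skipped(self, yule_tree):
        t = yule_tree(20, seed=43)
        tips = t.leaf_labels()
        trait = _trait(
            {s: (1.0 if i < 6 else 0.0) for i, s in enumerate(tips)}, kind="binary"
        )
        strata = {s: ("mono" if i < 6 else "mixed") for i, s in enumerate(tips)}
        with pytest.warns(UserWarning, match="mono"):
            res = stratified_signal(t, trait, strata, 99, 99, seed=0)
        assert "mono" not in res

    def test_partition_covers_species(self, yule_tree):
        t = yule_tree(30, seed=44)
        tips = t.leaf_labels()
        rng = np.random.default_rng(2)
        trait = _trait(dict(zip(tips, rng.integers(0, 2, 30).astype(float))), kind="binary")
        strata = {s: ("x" if i % 2 else "y") for i, s in enumerate(tips)}
        res = stratified_signal(t, trait, strata, 99, 99, seed=0)
        analysed = sum(len([s for s in tips if strata[s] == g]) for g in res)
        assert analysed == 30
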