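"""Phylogenetic-signal permutation tests."""

import itertools

import numpy as np
import pytest

from nichevol import synth
from nichevol.signal import (
    _er_batch_loglik,
    fraction_significant,
    lambda_signal_test,
    tiptip_distance_test,
)
from nichevol import mk
from nichevol.traits import CharacterData
from nichevol.tree import PhyloTree, TreeSet, cophenetic_matrix


def balanced_tree(depth):
    """Fully balanced ultrametric tree with 2**depth tips, unit tip depth."""
    tips = [f"t{i}" for i in range(2 ** depth)]
    def build(lo, hi, length):
        if hi - lo == 1:
            return f"{tips[lo]}:{length:g}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid, length/2)},{build(mid, hi, length/2)}):{length/2:g}"
    nwk = f"({build(0, len(tips)//2, 1.0)},{build(len(tips)//2, len(tips), 1.0)});"
    return PhyloTree.from_newick(nwk)


class TestErBatchLoglik:
    def test_matches_generic_pruning(self, bd_tree20):
        rng = np.random.default_rng(8)
        k = 3
        states = rng.integers(0, k, size=(4, bd_tree20.n_tips))
        q = rng.uniform(0.05, 1.0, size=4)
        lnl = _er_batch_loglik(bd_tree20, states, q, k)
        for d in range(4):
            Q = np.full((k, k), q[d])
            np.fill_diagonal(Q, 0.0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            data = CharacterData("x", ("a", "b", "c"),
                                 {l: int(states[d, i])
                                  for i, l in enumerate(bd_tree20.labels)})
            assert lnl[d] == pytest.approx(
                mk.prune_loglik(bd_tree20, data, Q), abs=1e-8)


class TestLambdaSignalTest:
    def test_star_tree_scenario_is_never_significant(self, bd_tree20):
        rng = np.random.default_rng(0)
        data = CharacterData("x", ("a", "b"),
                             {l: int(rng.integers(2))
                              for l in bd_tree20.labels})
        res = lambda_signal_test(bd_tree20, data, scenarios=(0.0,),
                                 n_perm=99, seed=1)
        assert len(res) == 1
        # at λ=0 the likelihood is permutation-invariant, so p = 1 exactly
        assert res[0].p == pytest.approx(1.0)

    def test_clustered_character_detected(self):
        # low-rate simulation on a tall tree gives strong clustering
        hits = 0
        for rep in range(8):
            tree = synth.simulate_bd_tree(1.0, 0.0, 40, seed=300 + rep)
            tree = PhyloTree(tree.parent.copy(), tree.blen / tree.height,
                             tree.labels)
            Q = np.array([[-0.5, 0.5], [0.5, -0.5]])
            data = synth.simulate_mk(tree, Q, 0, seed=rep)
            if len(np.unique(data.state_vector(tree.labels))) < 2:
                continue
            res = lambda_signal_test(tree, data, scenarios=(1.0,),
                                     n_perm=199, seed=rep)
            hits += res[0].p <= 0.05
        assert hits >= 6

    def test_constant_character_flagged_untestable(self, bd_tree20):
        data = CharacterData("x", ("a", "b"),
                             {l: 0 for l in bd_tree20.labels})
        res = lambda_signal_test(bd_tree20, data, scenarios=(1.0,),
                                 n_perm=99, seed=0)
        assert res[0].untestable

    def test_results_per_tree_and_scenario(self, bd_tree20):
        rng = np.random.default_rng(1)
        data = CharacterData("x", ("a", "b"),
                             {l: int(rng.integers(2))
                              for l in bd_tree20.labels})
        ts = synth.simulate_posterior_set(bd_tree20, 3, jitter=0.05, seed=2)
        res = lambda_signal_test(ts, data, scenarios=(0.5, 1.0), n_perm=99,
                                 seed=3)
        assert len(res) == 6
        assert {r.tree_index for r in res} == {0, 1, 2}

    def test_minimum_permutations_enforced(self, bd_tree20):
        data = CharacterData("x", ("a", "b"),
                             {l: 0 for l in bd_tree20.labels})
        with pytest.raises(ValueError):
            lambda_signal_test(bd_tree20, data, n_perm=10)


class TestTipTipDistanceTest:
    def test_perfect_split_maximal_clustering(self):
        tree = balanced_tree(4)  # 16 tips, two root clades of 8
        states = {l: (0 if int(l[1:]) < 8 else 1) for l in tree.labels}
        data = CharacterData("x", ("a", "b"), states)
        hits = 0
        for rep in range(10):
            res = tiptip_distance_test(tree, data, n_perm=199, seed=rep)
            pooled = [r for r in res if r.label == "pooled"][0]
            hits += pooled.p <= 0.05
        assert hits >= 9

    def test_all_one_state_untestable(self, bd_tree20):
        data = CharacterData("x", ("a", "b"),
                             {l: 0 for l in bd_tree20.labels})
        res = tiptip_distance_test(bd_tree20, data, n_perm=99, seed=0)
        assert res[0].untestable
        assert res[0].p == pytest.approx(1.0)

    def test_sister_pair_statistic_and_exhaustive_p(self):
        # 6-tip balanced-ish tree; state "b" on the two sister tips t0, t1
        tree = PhyloTree.from_newick(
            "(((t0:1,t1:1):1,(t2:1,t3:1):1):1,(t4:2,t5:1.5):1);")
        data = CharacterData("x", ("a", "b"),
                             {"t0": 1, "t1": 1, "t2": 0, "t3": 0,
                              "t4": 0, "t5": 0})
        res = tiptip_distance_test(tree, data, n_perm=999, seed=5)
        b_res = [r for r in res if r.label == "b"][0]
        assert b_res.statistic == pytest.approx(2.0)  # sisters at depth 1
        # exhaustive oracle: all C(6,2)=15 placements of the two "b" labels
        d = cophenetic_matrix(tree)
        ids = {l: i for i, l in enumerate(tree.labels)}
        stats = [d[ids[a], ids[b]]
                 for a, b in itertools.combinations(tree.labels, 2)]
        exact_p = sum(s <= 2.0 + 1e-9 for s in stats) / len(stats)
        # permutation p converges to the exhaustive fraction (within MC error)
        se = np.sqrt(exact_p * (1 - exact_p) / 999)
        assert abs(b_res.p - exact_p) <= 3 * se + 2 / 999

    def test_states_with_single_tip_skipped_with_note(self, bd_tree20):
        states = {l: 0 for l in bd_tree20.labels}
        states[bd_tree20.labels[0]] = 1
        data = CharacterData("x", ("a", "b"), states)
        res = tiptip_distance_test(bd_tree20, data, n_perm=99, seed=1)
        skipped = [r for r in res if r.label == "b"][0]
        assert skipped.untestable
        assert skipped.n_tips_in_state == 1

    def test_state_relabeling_invariance(self, bd_tree20):
        rng = np.random.default_rng(12)
        states = {l: int(rng.integers(2)) for l in bd_tree20.labels}
        d1 = CharacterData("x", ("a", "b"), states)
        d2 = CharacterData("x", ("b", "a"),
                           {l: 1 - s for l, s in states.items()})
        r1 = tiptip_distance_test(bd_tree20, d1, n_perm=99, seed=7)
        r2 = tiptip_distance_test(bd_tree20, d2, n_perm=99, seed=7)
        p1 = {r.label: r.p for r in r1}
        p2 = {r.label: r.p for r in r2}
        assert p1 == p2


def test_fraction_significant_summary():
    from nichevol.signal import SignalTestResult
    mk_res = [SignalTestResult(0, 1.0, 0.0, np.empty(0), p, 99)
              for p in (0.01, 0.2, 0.04)]
    assert fraction_significant(mk_res) == pytest.approx(2 / 3)
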