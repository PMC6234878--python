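"""Mk machinery: models, propagators, pruning likelihood, ASR, fitting."""

import itertools

import numpy as np
import pytest
import scipy.linalg

from nichevol import mk, synth
from nichevol.traits import CharacterData
from nichevol.tree import PhyloTree


def random_q(k, rng, lo=0.1, hi=1.0):
    Q = rng.uniform(lo, hi, (k, k))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def brute_force_loglik(tree, data, Q, prior=None):
    """Exhaustive sum over all internal-state assignments (tiny trees only)."""
    k = Q.shape[0]
    P = {n: scipy.linalg.expm(Q * tree.blen[n]) for n in range(tree.n_nodes)}
    ts = data.state_vector(tree.labels)
    prior = np.full(k, 1.0 / k) if prior is None else prior
    n_internal = tree.n_nodes - tree.n_tips
    total = 0.0
    for assign in itertools.product(range(k), repeat=n_internal):
        st = list(ts) + list(assign)
        p = prior[st[tree.root]]
        for node in range(tree.n_nodes - 1):
            p *= P[node][st[tree.parent[node]], st[node]]
        total += p
    return np.log(total)


class TestBuildModel:
    @pytest.mark.parametrize("k,spec,expected", [
        (2, "ER", 1), (5, "ER", 1),
        (5, "SYM", 10), (3, "SYM", 3),
        (5, "ARD", 20), (2, "ARD", 2),
    ])
    def test_free_parameter_counts(self, k, spec, expected):
        assert mk.build_model(k, spec).n_params == expected

    def test_mask_shape_mismatch_rejected(self):
        mask = np.full((3, 3), mk.DIAG)
        mask[0, 1] = 0
        with pytest.raises(ValueError):
            mk.MkModel("bad", 4, mask)

    def test_custom_mask_with_absorbing_row(self):
        mask = np.array([[mk.DIAG, mk.ZERO], [0, mk.DIAG]])
        model = mk.MkModel("absorb0", 2, mask)
        Q = model.q([0.7])
        assert Q[0, 1] == 0.0
        assert Q[1, 0] == pytest.approx(0.7)
        assert np.allclose(Q.sum(axis=1), 0.0)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        rng = np.random.default_rng(0)
        Q = random_q(4, rng)
        assert np.allclose(mk.transition_probabilities(Q, 0.0), np.eye(4))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            mk.transition_probabilities(np.zeros((2, 2)), -1.0)

    @pytest.mark.parametrize("q,t", [(0.5, 1.0), (0.1, 3.0), (2.0, 0.2)])
    def test_two_state_symmetric_closed_form(self, q, t):
        Q = np.array([[-q, q], [q, -q]])
        P = mk.transition_probabilities(Q, t)
        stay = 0.5 * (1.0 + np.exp(-2.0 * q * t))
        assert P[0, 0] == pytest.approx(stay, abs=1e-10)
        assert P[0, 1] == pytest.approx(1.0 - stay, abs=1e-10)

    def test_er_long_time_reaches_uniform(self):
        model = mk.build_model(5, "ER")
        P = mk.transition_probabilities(model.q([1.0]), 50.0)
        assert np.allclose(P, 0.2, atol=1e-8)

    def test_semigroup_property(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            Q = random_q(4, rng)
            t1, t2 = rng.uniform(0.1, 2.0, 2)
            P = mk.transition_probabilities(Q, t1 + t2)
            P12 = mk.transition_probabilities(Q, t1) @ \
                mk.transition_probabilities(Q, t2)
            assert np.allclose(P, P12, atol=1e-10)

    def test_rows_stochastic(self):
        rng = np.random.default_rng(1)
        Q = random_q(5, rng)
        P = mk.transition_probabilities(Q, 1.3)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert P.min() >= 0.0

    def test_masked_absorbing_matrix_fallback(self):
        # an absorbing Q may be defective; results must still be stochastic
        model = mk.enumerate_noswitch_models(3)[0]
        Q = model.q(np.full(model.n_params, 0.4))
        P = mk.transition_probabilities(Q, 2.0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(P[0], [1.0, 0.0, 0.0], atol=1e-12)


class TestPruneLoglik:
    def test_no_change_limit_leaves_root_uncertainty(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        data = CharacterData("x", ("a", "b"), {"A": 0, "B": 0})
        Q = np.array([[-1e-12, 1e-12], [1e-12, -1e-12]])
        assert mk.prune_loglik(tree, data, Q) == pytest.approx(np.log(0.5),
                                                               abs=1e-6)

    def test_two_tip_hand_computation(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        data = CharacterData("x", ("a", "b"), {"A": 0, "B": 1})
        q = 0.5
        Q = np.array([[-q, q], [q, -q]])
        P = scipy.linalg.expm(Q)
        expected = np.log(sum(0.5 * P[r, 0] * P[r, 1] for r in range(2)))
        assert mk.prune_loglik(tree, data, Q) == pytest.approx(expected,
                                                               abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_enumeration(self, k):
        rng = np.random.default_rng(k)
        for rep in range(5):
            tree = synth.simulate_bd_tree(1.0, 0.2, 5, seed=int(rng.integers(2**31)))
            Q = random_q(k, rng)
            states = {l: int(rng.integers(k)) for l in tree.labels}
            data = CharacterData("x", tuple("abc"[:k]), states)
            ll = mk.prune_loglik(tree, data, Q)
            assert ll == pytest.approx(brute_force_loglik(tree, data, Q),
                                       abs=1e-9)

    def test_multifurcation_handled(self):
        tree = PhyloTree.from_newick("(A:1,B:1,C:1);")
        rng = np.random.default_rng(5)
        Q = random_q(2, rng)
        data = CharacterData("x", ("a", "b"), {"A": 0, "B": 1, "C": 0})
        ll = mk.prune_loglik(tree, data, Q)
        assert ll == pytest.approx(brute_force_loglik(tree, data, Q), abs=1e-9)

    def test_invariant_to_tip_relabeling(self, bd_tree20):
        rng = np.random.default_rng(9)
        Q = random_q(3, rng)
        states = {l: int(rng.integers(3)) for l in bd_tree20.labels}
        data = CharacterData("x", ("a", "b", "c"), states)
        ll = mk.prune_loglik(bd_tree20, data, Q)
        # permute the state-space labels and the data consistently
        perm = [2, 0, 1]
        Qp = Q[np.ix_(perm, perm)]
        datap = CharacterData("x", ("c", "a", "b"),
                              {l: perm.index(s) for l, s in states.items()})
        assert mk.prune_loglik(bd_tree20, datap, Qp) == pytest.approx(ll,
                                                                      abs=1e-10)

    def test_missing_tip_state_rejected(self, cherry_tree):
        data = CharacterData("x", ("a", "b"), {"A": 0})
        with pytest.raises(Exception, match="B"):
            mk.prune_loglik(cherry_tree, data, np.array([[-1.0, 1.0],
                                                         [1.0, -1.0]]))


class TestFitMk:
    def test_nesting_inequality(self, bd_tree20):
        rng = np.random.default_rng(3)
        Q = random_q(3, rng, 0.3, 0.8)
        data = synth.simulate_mk(bd_tree20, Q, 0, seed=17,
                                 states=("a", "b", "c"))
        fits = {s: mk.fit_mk(bd_tree20, data, s, n_restarts=2, seed=1)
                for s in ("ER", "SYM", "ARD")}
        assert fits["ARD"].loglik >= fits["SYM"].loglik - 1e-6
        assert fits["SYM"].loglik >= fits["ER"].loglik - 1e-6

    def test_constant_character_hits_lower_bound(self, bd_tree20):
        data = CharacterData("x", ("a", "b"),
                             {l: 0 for l in bd_tree20.labels})
        fit = mk.fit_mk(bd_tree20, data, "ER")
        assert fit.theta[0] <= 1e-7
        assert fit.loglik == pytest.approx(np.log(0.5), abs=1e-5)

    def test_er_rate_recovery(self):
        # moderate-rate simulation on a long tree recovers the rate scale
        hits = 0
        for rep in range(10):
            tree = synth.simulate_bd_tree(1.0, 0.0, 80, seed=900 + rep)
            tree = PhyloTree(tree.parent.copy(),
                             tree.blen * (10.0 / tree.height), tree.labels)
            Q = np.array([[-0.3, 0.3], [0.3, -0.3]])
            data = synth.simulate_mk(tree, Q, 0, seed=rep)
            if len(np.unique(data.state_vector(tree.labels))) < 2:
                continue
            fit = mk.fit_mk(tree, data, "ER")
            hits += 0.15 <= fit.theta[0] <= 0.6
        assert hits >= 7

    def test_aic_formula(self, bd_tree20):
        data = CharacterData("x", ("a", "b"),
                             {l: i % 2 for i, l in enumerate(bd_tree20.labels)})
        fit = mk.fit_mk(bd_tree20, data, "ARD")
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)


class TestMarginalAsr:
    def test_no_change_limit_concentrates_on_tip_state(self, bd_tree20):
        data = CharacterData("x", ("a", "b"),
                             {l: 0 for l in bd_tree20.labels})
        Q = np.array([[-1e-9, 1e-9], [1e-9, -1e-9]])
        asr = mk.marginal_asr(bd_tree20, data, Q)
        for node, p in asr.probs.items():
            assert p[0] == pytest.approx(1.0, abs=1e-6)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_tip_bayes_formula(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        data = CharacterData("x", ("a", "b"), {"A": 0, "B": 1})
        q = 0.4
        Q = np.array([[-q, q], [q, -q]])
        P = scipy.linalg.expm(Q)
        post = np.array([P[r, 0] * P[r, 1] for r in range(2)])
        post /= post.sum()
        asr = mk.marginal_asr(tree, data, Q)
        assert np.allclose(asr.probs[tree.root], post, atol=1e-10)

    @pytest.mark.parametrize("root_prior", ["uniform", "stationary"])
    def test_matches_enumeration_oracle(self, root_prior):
        rng = np.random.default_rng(31)
        k = 3
        tree = synth.simulate_bd_tree(1.0, 0.2, 5, seed=77)
        Q = random_q(k, rng)
        data = CharacterData("x", ("a", "b", "c"),
                             {l: int(rng.integers(k)) for l in tree.labels})
        prior = (np.full(k, 1 / k) if root_prior == "uniform"
                 else mk.stationary_distribution(Q))
        asr = mk.marginal_asr(tree, data, Q, root_prior=root_prior)
        # brute force: restrict the enumeration to each node state in turn
        P = {n: scipy.linalg.expm(Q * tree.blen[n])
             for n in range(tree.n_nodes)}
        ts = data.state_vector(tree.labels)
        n_internal = tree.n_nodes - tree.n_tips
        for node in range(tree.n_tips, tree.n_nodes):
            marg = np.zeros(k)
            for assign in itertools.product(range(k), repeat=n_internal):
                st = list(ts) + list(assign)
                p = prior[st[tree.root]]
                for n in range(tree.n_nodes - 1):
                    p *= P[n][st[tree.parent[n]], st[n]]
                marg[st[node]] += p
            marg /= marg.sum()
            assert np.allclose(asr.probs[node], marg, atol=1e-9)


class TestNoSwitchEnumeration:
    def test_count_formula(self):
        assert len(mk.enumerate_noswitch_models(5)) == 30
        assert len(mk.enumerate_noswitch_models(2)) == 2
        assert len(mk.enumerate_noswitch_models(3)) == 6

    def test_constrained_rows_are_zero(self):
        for model in mk.enumerate_noswitch_models(3):
            Q = model.q(np.full(model.n_params, 0.5))
            absorbing = [i for i in range(3)
                         if np.all(model.mask[i] != 0) and model.mask[i, (i + 1) % 3] == mk.ZERO]
            for i in range(3):
                row_zeroed = all(model.mask[i, j] == mk.ZERO
                                 for j in range(3) if j != i)
                if row_zeroed:
                    assert np.allclose(Q[i], 0.0)

    def test_deterministic_ordering(self):
        names = [m.name for m in mk.enumerate_noswitch_models(3)]
        assert names == ["noswitch[0]", "noswitch[1]", "noswitch[2]",
                         "noswitch[0+1]", "noswitch[0+2]", "noswitch[1+2]"]

    def test_free_cells_are_ard_on_complement(self):
        models = mk.enumerate_noswitch_models(4)
        sizes = sorted(m.n_params for m in models)
        # |S|=s leaves (4-s)*3 free rates
        expected = sorted([(4 - s) * 3 for s in (1, 2, 3)
                           for _ in range(len(list(itertools.combinations(range(4), s))))])
        assert sizes == expected

    def test_json_serialisation(self):
        model = mk.enumerate_noswitch_models(3)[0]
        import json
        doc = json.loads(model.to_json())
        assert doc["k"] == 3
        assert [0, 1] in doc["zero_cells"]


def test_stationary_distribution_irreducible():
    rng = np.random.default_rng(4)
    Q = random_q(4, rng)
    pi = mk.stationary_distribution(Q)
    assert np.allclose(pi @ Q, 0.0, atol=1e-10)
    assert pi.sum() == pytest.approx(1.0)
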