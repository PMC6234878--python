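"""MuSSE likelihood reductions, inference, MCMC, and rate comparisons."""

import numpy as np
import pytest

from nichevol import mk, sse, synth
from nichevol.sse import (
    MusseParams,
    bd_loglik,
    compare_rates,
    diversification_density,
    fit_musse,
    musse_loglik,
    musse_mcmc,
    trait_independence_test,
)
from nichevol.traits import CharacterData
from nichevol.tree import PhyloTree, TreeValidationError


class TestParams:
    def test_diversification_rate(self):
        p = MusseParams(lam=[0.3, 0.5], mu=[0.1, 0.2],
                        q=[[0.0, 0.1], [0.1, 0.0]])
        assert np.allclose(p.r, [0.2, 0.3])

    @pytest.mark.parametrize("bad", [
        dict(lam=[0.0, 0.5], mu=[0.1, 0.1], q=[[0, 0.1], [0.1, 0]]),
        dict(lam=[0.3, 0.5], mu=[-0.1, 0.1], q=[[0, 0.1], [0.1, 0]]),
        dict(lam=[0.3, 0.5], mu=[0.1, 0.1], q=[[0, 0.1], [0.1, 0]],
             rho=[1.5, 1.0]),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            MusseParams(**bad)


class TestLoglikStructure:
    def test_polytomy_rejected(self):
        tree = PhyloTree.from_newick("(A:1,B:1,C:1);")
        p = MusseParams(lam=[0.5, 0.5], mu=[0, 0], q=[[0, 0.1], [0.1, 0]])
        with pytest.raises(TreeValidationError):
            musse_loglik(tree, np.array([0, 1, 0]), p)

    def test_non_ultrametric_rejected(self):
        tree = PhyloTree.from_newick("((A:1,B:2):1,C:2);")
        p = MusseParams(lam=[0.5, 0.5], mu=[0, 0], q=[[0, 0.1], [0.1, 0]])
        with pytest.raises(TreeValidationError):
            musse_loglik(tree, np.array([0, 1, 0]), p)

    def test_sampling_fraction_changes_likelihood(self, bd_tree20, er2):
        data = synth.simulate_mk(bd_tree20, er2, 0, seed=1, states=("a", "b"))
        base = dict(lam=[0.6, 0.6], mu=[0.1, 0.1], q=[[0, 0.3], [0.3, 0]])
        full = musse_loglik(bd_tree20, data, MusseParams(**base))
        half = musse_loglik(bd_tree20, data,
                            MusseParams(**base, rho=[0.5, 0.5]))
        assert full != pytest.approx(half)


class TestClosedFormReductions:
    def test_yule_closed_form(self, bd_tree20):
        lam = 0.7
        p = MusseParams(lam=[lam], mu=[0.0], q=[[0.0]])
        ll = musse_loglik(bd_tree20, np.zeros(bd_tree20.n_tips, int), p)
        yule = ((bd_tree20.n_nodes - bd_tree20.n_tips) * np.log(lam)
                - lam * bd_tree20.total_length())
        assert ll == pytest.approx(yule, abs=1e-8)
        assert bd_loglik(bd_tree20, lam, 0.0) == pytest.approx(yule, abs=1e-12)

    def test_birth_death_closed_form(self, bd_tree20):
        p = MusseParams(lam=[0.9], mu=[0.3], q=[[0.0]])
        ll = musse_loglik(bd_tree20, np.zeros(bd_tree20.n_tips, int), p)
        assert ll == pytest.approx(bd_loglik(bd_tree20, 0.9, 0.3), abs=1e-6)

    @pytest.mark.parametrize("root_prior", ["uniform", "conditional"])
    def test_equal_rates_factorisation(self, bd_tree20, er2, root_prior):
        data = synth.simulate_mk(bd_tree20, er2, 0, seed=3, states=("a", "b"))
        lam, mu = 0.8, 0.2
        p = MusseParams(lam=[lam] * 2, mu=[mu] * 2,
                        q=[[0.0, 0.5], [0.5, 0.0]])
        root = "fitzjohn" if root_prior == "conditional" else "uniform"
        ll = musse_loglik(bd_tree20, data, p, root=root)
        expected = bd_loglik(bd_tree20, lam, mu) + mk.prune_loglik(
            bd_tree20, data, er2, root_prior=root_prior)
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_no_extinction_keeps_e_at_zero(self, bd_tree20):
        # with rho=1 and mu=0 no lineage can vanish unobserved
        from nichevol import _ssecore
        p = MusseParams(lam=[0.5, 0.8], mu=[0.0, 0.0],
                        q=[[0, 0.2], [0.2, 0]])
        cp, ci = bd_tree20.flat_children()
        y, _ = _ssecore.musse_root(
            bd_tree20.blen, cp, ci, bd_tree20.n_tips,
            np.zeros(bd_tree20.n_tips, np.int64), p.rho, p.lam, p.mu,
            p.q * (1 - np.eye(2)), 1e-9, 1e-12)
        assert np.allclose(y[:2], 0.0, atol=1e-10)

    def test_loglik_smooth_under_perturbation(self, bd_tree20, er2):
        data = synth.simulate_mk(bd_tree20, er2, 0, seed=9, states=("a", "b"))
        base = np.array([0.6, 0.8, 0.1, 0.2, 0.3, 0.4])

        def ll(v):
            p = MusseParams(lam=v[:2], mu=v[2:4],
                            q=[[0, v[4]], [v[5], 0]])
            return musse_loglik(bd_tree20, data, p)

        f0 = ll(base)
        eps = 1e-6
        for i in range(6):
            up = base.copy(); up[i] += eps
            dn = base.copy(); dn[i] -= eps
            g_central = (ll(up) - ll(dn)) / (2 * eps)
            g_forward = (ll(up) - f0) / eps
            # finite-difference gradients agree -> no discontinuities
            assert g_forward == pytest.approx(g_central, abs=1e-2, rel=1e-3)


class TestFitMusse:
    def test_fixed_mu_respected(self, bd_tree20, er2):
        data = synth.simulate_mk(bd_tree20, er2, 0, seed=2, states=("a", "b"))
        fit = fit_musse(bd_tree20, data, fix_mu=0.0, q_spec="er", seed=0,
                        n_restarts=1, maxfev=400)
        assert fit.converged
        assert np.allclose(fit.params.mu, 0.0)

    def test_tied_rates_reduce_parameter_count(self, bd_tree20, er2):
        data = synth.simulate_mk(bd_tree20, er2, 0, seed=2, states=("a", "b"))
        dep = fit_musse(bd_tree20, data, seed=0, n_restarts=1, maxfev=200)
        indep = fit_musse(bd_tree20, data, tie_lambda=True, tie_mu=True,
                          seed=0, n_restarts=1, maxfev=200)
        assert dep.n_params == 6
        assert indep.n_params == 4


class TestMcmc:
    def test_same_seed_identical_chains(self, bd_tree20, er2):
        data = synth.simulate_mk(bd_tree20, er2, 0, seed=4, states=("a", "b"))
        c1 = musse_mcmc(bd_tree20, data, n_steps=200, seed=7, q_spec="er",
                        tie_lambda=True, tie_mu=True)
        c2 = musse_mcmc(bd_tree20, data, n_steps=200, seed=7, q_spec="er",
                        tie_lambda=True, tie_mu=True)
        assert np.allclose(c1.draws, c2.draws)

    def test_prior_only_chain_recovers_prior_mean(self):
        data = CharacterData("x", ("a", "b"), {"t": 0})
        chain = musse_mcmc(None, data, n_steps=20_000, seed=1,
                           prior_mean=0.8, q_spec="er", tie_lambda=True,
                           tie_mu=True)
        draws = chain.draws
        # independent Exp(mean 0.8) marginals; MC error via effective size
        for j in range(draws.shape[1]):
            x = draws[:, j]
            se = x.std() / np.sqrt(len(x) / 50)  # conservative ESS guess
            assert abs(x.mean() - 0.8) < 4 * se + 0.02


class TestCompareRates:
    def test_separated_samples_exact_p(self):
        U, p = compare_rates([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_fully_tied_samples(self):
        U, p = compare_rates([1.0] * 5, [1.0] * 5)
        assert U == pytest.approx(12.5)
        assert p == 1.0

    def test_large_separated_samples_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 300)
        b = rng.normal(1.5, 1.0, 300)
        _, p = compare_rates(a, b)
        assert p < 0.01

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            compare_rates([1.0], [2.0, 3.0])


class TestDiversificationDensity:
    def test_pooling_concatenates_draws(self, bd_tree20, er2):
        data = synth.simulate_mk(bd_tree20, er2, 0, seed=4, states=("a", "b"))
        chains = [musse_mcmc(bd_tree20, data, n_steps=100, seed=s,
                             q_spec="er", tie_lambda=True, tie_mu=True)
                  for s in (1, 2)]
        dens = diversification_density(chains, states=("a", "b"))
        assert len(dens["a"]["draws"]) == sum(len(c) for c in chains)

    def test_zero_diversification_centred_at_zero(self):
        spec = sse._MusseSpec(2, tie_lambda=False, tie_mu=False,
                              fix_mu=None, q_spec="er")
        lam = np.abs(np.random.default_rng(0).normal(0.5, 0.05, 200))
        draws = np.column_stack([lam, lam, lam, lam, np.full(200, 0.1)])
        sample = sse.PosteriorSample(draws=draws, names=spec.names,
                                     loglik=np.zeros(200), acceptance=1.0,
                                     spec=spec)
        dens = diversification_density(sample)
        assert dens["state_0"]["mean"] == pytest.approx(0.0, abs=1e-12)


def test_trait_independence_validation(bd_tree20):
    with pytest.raises(ValueError):
        trait_independence_test(bd_tree20, [1.0], n_sims=0)
    with pytest.raises(ValueError):
        trait_independence_test(bd_tree20, [-1.0], n_sims=5)


def test_trait_independence_report_structure():
    tree = synth.simulate_bd_tree(1.0, 0.0, 25, seed=9)
    res = trait_independence_test(tree, [0.5, 2.0], n_sims=4, seed=0,
                                  maxfev=150)
    assert [r["q"] for r in res] == [0.5, 2.0]
    for r in res:
        assert 0.0 <= r["ci_low"] <= r["ci_high"] <= 1.0
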