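"""Permutation tests for phylogenetic signal in a discrete character.

Two multi-tree tests, both comparing the observed character to tip-label
randomisations:

* **λ-scenario likelihood test** — fit an equal-rates Mk model on Pagel-λ
  transformed trees; the observed maximised log-likelihood is compared to
  its permutation null.  At λ = 0 the tree is a star phylogeny, every
  permutation yields the same likelihood and the test is non-significant by
  construction.
* **Tip-to-tip distance test** — the mean patristic distance over all
  unordered same-state tip pairs (per state, and pooled) is compared to its
  permutation null; signal shows up as distances shorter than the null.

p-values use the add-one permutation estimator, ``p = (1 + #{null at least
as extreme}) / (1 + n_perm)``, which is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import PhyloTree, TreeSet, cophenetic_matrix, lambda_transform

__all__ = [
    "SignalTestResult",
    "lambda_signal_test",
    "tiptip_distance_test",
    "fraction_significant",
    "DEFAULT_LAMBDA_SCENARIOS",
]

DEFAULT_LAMBDA_SCENARIOS = (0.0, 0.25, 0.5, 0.75, 1.0)

#: numerical slack when comparing permuted to observed statistics, so exact
#: ties (e.g. the λ=0 star tree) count as "at least as extreme"
TIE_EPS = 1e-9


@dataclass
class SignalTestResult:
    """One permutation test on one tree (and one scenario or state)."""

    tree_index: int
    label: object  # λ value, state name, or "pooled"
    statistic: float
    null: np.ndarray
    p: float
    n_perm: int
    seed: object = None
    untestable: bool = False
    note: str = ""
    n_tips_in_state: int | None = None


def fraction_significant(results, alpha: float = 0.05) -> float:
    """Share of testable results with p <= alpha (cross-tree summary)."""
    usable = [r for r in results if not r.untestable]
    if not usable:
        return float("nan")
    return sum(r.p <= alpha for r in usable) / len(usable)


# ---------------------------------------------------------------------------
# Batched equal-rates pruning


def _er_batch_loglik(tree: PhyloTree, states: np.ndarray, q: np.ndarray,
                     k: int):
    """ER-Mk log-likelihood for D datasets at D rates simultaneously.

    ``states`` is (D, n_tips) integer state matrix; ``q`` a (D,) vector of
    per-cell rates.  Uses the closed-form ER propagator
    ``P(t)v = e^{-kqt} v + (1 - e^{-kqt}) * mean(v)`` and a uniform root
    prior, vectorised over the dataset axis.
    """
    D, n_tips = states.shape
    kq = k * q
    L = np.zeros((tree.n_nodes, D, k))
    rows = np.arange(D)
    for i in range(n_tips):
        L[i, rows, states[:, i]] = 1.0
    logscale = np.zeros(D)
    for node in range(tree.n_tips, tree.n_nodes):
        prod = np.ones((D, k))
        for c in tree.children[node]:
            e = np.exp(-kq * tree.blen[c])[:, None]
            v = L[c]
            prod *= e * v + (1.0 - e) * v.mean(axis=1, keepdims=True)
        m = prod.max(axis=1)
        np.clip(m, 1e-300, None, out=m)
        L[node] = prod / m[:, None]
        logscale += np.log(m)
    return logscale + np.log(L[tree.root].mean(axis=1))


def _er_batch_ml(tree: PhyloTree, states: np.ndarray, k: int,
                 lo=np.log(1e-8), hi=np.log(1e3), iters: int = 70) -> np.ndarray:
    """Per-dataset maximised ER log-likelihood (vectorised ternary search)."""
    D = states.shape[0]
    a = np.full(D, lo)
    b = np.full(D, hi)
    for _ in range(iters):
        m1 = a + (b - a) / 3.0
        m2 = b - (b - a) / 3.0
        f1 = _er_batch_loglik(tree, states, np.exp(m1), k)
        f2 = _er_batch_loglik(tree, states, np.exp(m2), k)
        better1 = f1 >= f2
        b = np.where(better1, m2, b)
        a = np.where(better1, a, m1)
    x = (a + b) / 2.0
    return _er_batch_loglik(tree, states, np.exp(x), k)


def lambda_signal_test(trees, data, scenarios=DEFAULT_LAMBDA_SCENARIOS,
                       n_perm: int = 999, seed=None) -> list:
    """λ-scenario permutation test on every tree of a set.

    For each tree and each λ: transform the tree, maximise the ER-Mk
    likelihood for the observed states and for ``n_perm`` tip-label
    permutations, and report the one-sided p for "observed fit better than
    random".  Returns a flat list of :class:`SignalTestResult`.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if isinstance(trees, PhyloTree):
        trees = TreeSet([trees])
    rng = np.random.default_rng(seed)
    results = []
    for ti, tree in enumerate(trees):
        obs = data.state_vector(tree.labels)
        constant = len(np.unique(obs)) < 2
        perm = np.empty((1 + n_perm, tree.n_tips), dtype=np.int64)
        perm[0] = obs
        for i in range(n_perm):
            perm[1 + i] = obs[rng.permutation(tree.n_tips)]
        for lam in scenarios:
            if constant:
                results.append(SignalTestResult(
                    tree_index=ti, label=lam, statistic=np.nan,
                    null=np.empty(0), p=1.0, n_perm=n_perm, seed=seed,
                    untestable=True, note="constant character"))
                continue
            tlam = lambda_transform(tree, lam)
            lnl = _er_batch_ml(tlam, perm, data.k)
            stat, null = lnl[0], lnl[1:]
            p = (1.0 + np.sum(null >= stat - TIE_EPS)) / (1.0 + n_perm)
            results.append(SignalTestResult(
                tree_index=ti, label=lam, statistic=float(stat), null=null,
                p=float(p), n_perm=n_perm, seed=seed))
    return results


# ---------------------------------------------------------------------------
# Tip-to-tip distance test


def _same_state_mean(distmat, states, k):
    """Mean same-state pair distance per state (nan when < 2 tips) + pooled."""
    per_state = np.full(k, np.nan)
    tot_sum = 0.0
    tot_n = 0
    for s in range(k):
        ix = np.flatnonzero(states == s)
        if len(ix) < 2:
            continue
        sub = distmat[np.ix_(ix, ix)]
        n_pairs = len(ix) * (len(ix) - 1) // 2
        ssum = sub.sum() / 2.0
        per_state[s] = ssum / n_pairs
        tot_sum += ssum
        tot_n += n_pairs
    pooled = tot_sum / tot_n if tot_n else np.nan
    return per_state, pooled


def tiptip_distance_test(trees, data, n_perm: int = 999, seed=None) -> list:
    """Same-state patristic-distance permutation test on every tree.

    The statistic (per state with >= 2 tips, and pooled over states) is the
    mean patristic distance over unordered same-state tip pairs; the
    one-sided p asks whether it is shorter than under tip-label permutation.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if isinstance(trees, PhyloTree):
        trees = TreeSet([trees])
    rng = np.random.default_rng(seed)
    k = data.k
    results = []
    for ti, tree in enumerate(trees):
        obs = data.state_vector(tree.labels)
        counts = np.bincount(obs, minlength=k)
        distmat = cophenetic_matrix(tree)
        if counts.max() == tree.n_tips:
            results.append(SignalTestResult(
                tree_index=ti, label="pooled",
                statistic=float(_same_state_mean(distmat, obs, k)[1]),
                null=np.empty(0), p=1.0, n_perm=n_perm, seed=seed,
                untestable=True, note="all tips share one state"))
            continue
        obs_state, obs_pooled = _same_state_mean(distmat, obs, k)
        null_state = np.empty((n_perm, k))
        null_pooled = np.empty(n_perm)
        for i in range(n_perm):
            ps = obs[rng.permutation(tree.n_tips)]
            null_state[i], null_pooled[i] = _same_state_mean(distmat, ps, k)
        for s in range(k):
            if counts[s] < 2:
                results.append(SignalTestResult(
                    tree_index=ti, label=data.states[s], statistic=np.nan,
                    null=np.empty(0), p=1.0, n_perm=n_perm, seed=seed,
                    untestable=True, note="fewer than 2 tips in state",
                    n_tips_in_state=int(counts[s])))
                continue
            p = (1.0 + np.sum(null_state[:, s] <= obs_state[s] + TIE_EPS)) \
                / (1.0 + n_perm)
            results.append(SignalTestResult(
                tree_index=ti, label=data.states[s],
                statistic=float(obs_state[s]), null=null_state[:, s],
                p=float(p), n_perm=n_perm, seed=seed,
                n_tips_in_state=int(counts[s])))
        p = (1.0 + np.sum(null_pooled <= obs_pooled + TIE_EPS)) / (1.0 + n_perm)
        results.append(SignalTestResult(
            tree_index=ti, label="pooled", statistic=float(obs_pooled),
            null=null_pooled, p=float(p), n_perm=n_perm, seed=seed,
            n_tips_in_state=int(tree.n_tips)))
    return results
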