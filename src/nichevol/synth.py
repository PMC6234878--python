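"""Synthetic data generators emulating the empirical study design.

Provides birth–death tree simulation conditioned on a tip count, forward
CTMC character simulation (with full histories retained for cross-checks),
joint state-dependent tree+character (MuSSE) simulation, posterior-sample
emulation by branch-length jitter (plus optional NNI moves), and a bundled
demo dataset at the study scale: ~100 tips, 100 trees, a five-state
substrate character with strong phylogenetic clustering and a correlated
binary generalist/specialist character.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .simmap import StochasticMap
from .traits import CharacterData, GS_STATES, PS_STATES
from .tree import PhyloTree, TreeSet

__all__ = [
    "SimConfig",
    "simulate_bd_tree",
    "simulate_mk",
    "simulate_musse",
    "simulate_posterior_set",
    "demo_dataset",
]


@dataclass
class SimConfig:
    """Record of how a synthetic artifact was generated (for regeneration)."""

    kind: str
    seed: object
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=str, sort_keys=True)


class _Lineage:
    __slots__ = ("birth", "children", "death", "state", "label")

    def __init__(self, birth, state=0):
        self.birth = birth
        self.children = None
        self.death = None
        self.state = state
        self.label = None


def _newick_of(node, end_time, counter):
    """Newick of the extant-pruned subtree, or None if wholly extinct."""
    if node.children is None:
        if node.death is not None:
            return None
        counter[0] += 1
        node.label = f"t{counter[0]}"
        return f"{node.label}:{end_time - node.birth:.12g}"
    parts = [_newick_of(c, end_time, counter) for c in node.children]
    parts = [p for p in parts if p is not None]
    if not parts:
        return None
    stop = node.death if node.death is not None else end_time
    length = stop - node.birth
    if len(parts) == 1:
        # collapse unifurcation left by a dead subtree: extend the child edge
        name, _, sub = parts[0].rpartition(":")
        return f"{name}:{float(sub) + length:.12g}"
    return f"({','.join(parts)}):{length:.12g}"


def _forward_bd(rng, lam, mu, qmat, n_tips, root_state, max_events=2_000_000):
    """One forward birth–death(-transition) attempt from a crown root.

    ``lam``/``mu`` are per-state vectors; ``qmat`` the transition rates (zero
    diagonal).  Returns ``(newick, tip_states)`` or None on full extinction.
    """
    k = len(lam)
    root = _Lineage(0.0, root_state)
    c1, c2 = _Lineage(0.0, root_state), _Lineage(0.0, root_state)
    root.children = [c1, c2]
    root.death = 0.0  # crown root has zero-length stem
    active = [c1, c2]
    t = 0.0
    for _ in range(max_events):
        if len(active) >= n_tips:
            break
        if not active:
            return None
        rates = np.array(
            [lam[x.state] + mu[x.state] + qmat[x.state].sum() for x in active]
        )
        total = rates.sum()
        t += rng.exponential(1.0 / total)
        who = rng.choice(len(active), p=rates / total)
        lin = active[who]
        s = lin.state
        r = rng.uniform(0.0, rates[who])
        if r < lam[s]:  # speciation
            a, b = _Lineage(t, s), _Lineage(t, s)
            lin.children = [a, b]
            lin.death = t
            active[who] = a
            active.append(b)
        elif r < lam[s] + mu[s]:  # extinction
            lin.death = t
            active.pop(who)
        else:  # state transition
            probs = qmat[s] / qmat[s].sum()
            lin.state = int(rng.choice(k, p=probs))
    else:
        raise RuntimeError("birth–death simulation exceeded the event budget")
    if len(active) < n_tips:
        return None
    # stop at a uniform time within the n-lineage interval (before the next
    # event), so pendant branches are strictly positive
    rates = np.array(
        [lam[x.state] + mu[x.state] + qmat[x.state].sum() for x in active]
    )
    total = rates.sum()
    if total > 0:
        t += rng.uniform() * rng.exponential(1.0 / total)
    counter = [0]
    nwk = _newick_of(root, t, counter)
    tip_states = {}

    def collect(node):
        if node.children is None:
            if node.death is None:
                tip_states[node.label] = int(node.state)
        else:
            for c in node.children:
                collect(c)

    collect(root)
    return nwk + ";", tip_states


def simulate_bd_tree(lam: float, mu: float, n_tips: int, seed=None,
                     max_attempts: int = 1000) -> PhyloTree:
    """Simulate an ultrametric binary tree with exactly ``n_tips`` extant tips.

    Forward birth–death simulation from a crown root, stopped at the moment
    the extant lineage count first reaches ``n_tips``; extinct lineages are
    pruned.  Attempts that go fully extinct are resampled.
    """
    if not lam > mu >= 0:
        raise ValueError("need lam > mu >= 0")
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed)
    z = np.zeros((1, 1))
    for _ in range(max_attempts):
        out = _forward_bd(rng, np.array([lam]), np.array([mu]), z, n_tips, 0)
        if out is not None:
            tree = PhyloTree.from_newick(out[0])
            if tree.n_tips == n_tips:
                return tree
    raise RuntimeError(f"no surviving tree in {max_attempts} attempts")


def simulate_mk(tree: PhyloTree, Q, root_state: int, seed=None, states=None,
                return_history: bool = False):
    """Evolve a discrete character forward along a tree under rate matrix Q.

    Returns a :class:`CharacterData`; with ``return_history=True`` also the
    full :class:`~nichevol.simmap.StochasticMap`-style history, which lets
    transition counts from the simulation be checked against the counter.
    """
    Q = np.asarray(Q, float)
    k = Q.shape[0]
    if states is None:
        states = tuple(f"s{i}" for i in range(k))
    if not 0 <= root_state < k:
        raise ValueError("root_state outside state space")
    rng = np.random.default_rng(seed)
    exit_rate = -np.diag(Q)
    node_states = np.empty(tree.n_nodes, dtype=np.int64)
    node_states[tree.root] = root_state
    segments = {}
    counts = np.zeros((k, k), dtype=np.int64)
    for node in range(tree.n_nodes - 2, -1, -1):  # preorder below root
        state = int(node_states[tree.parent[node]])
        t = float(tree.blen[node])
        pos = 0.0
        segs = []
        while True:
            rate = exit_rate[state]
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if pos + wait >= t:
                segs.append((state, t - pos))
                break
            pos += wait
            segs.append((state, wait))
            probs = Q[state].copy()
            probs[state] = 0.0
            probs /= probs.sum()
            nxt = int(rng.choice(k, p=probs))
            counts[state, nxt] += 1
            state = nxt
        node_states[node] = state
        segments[node] = segs
    data = CharacterData(
        name="sim", states=tuple(states),
        data={tree.labels[i]: int(node_states[i]) for i in range(tree.n_tips)},
    )
    if return_history:
        hist = StochasticMap(states=tuple(states), node_states=node_states,
                             segments=segments, counts=counts, seed=seed)
        return data, hist
    return data


def simulate_musse(params, n_tips: int, seed=None, states=None,
                   root_state: int = 0, subsample=None,
                   max_attempts: int = 1000):
    """Joint forward simulation of tree and character under a MuSSE process.

    Per-lineage events are state-dependent speciation, extinction and
    character transition.  The tree is stopped when ``n_tips`` extant
    lineages are reached and pruned to extant tips.  ``subsample`` optionally
    gives per-state retention probabilities (sampling fractions ρ).
    Returns ``(PhyloTree, CharacterData)``.
    """
    lam = np.asarray(params.lam, float)
    mu = np.asarray(params.mu, float)
    qmat = np.asarray(params.q, float).copy()
    np.fill_diagonal(qmat, 0.0)
    k = len(lam)
    if states is None:
        states = tuple(f"s{i}" for i in range(k))
    if n_tips < 10:
        raise ValueError("n_tips must be >= 10")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        out = _forward_bd(rng, lam, mu, qmat, n_tips, root_state)
        if out is None:
            continue
        nwk, tip_states = out
        tree = PhyloTree.from_newick(nwk)
        if subsample is not None:
            rho = np.asarray(subsample, float)
            keep = [l for l in tree.labels if rng.uniform() < rho[tip_states[l]]]
            if len(keep) < 3:
                continue
            tree = _prune_to(tree, keep)
            tip_states = {l: tip_states[l] for l in keep}
        data = CharacterData(name="sim", states=tuple(states), data=tip_states)
        return tree, data
    raise RuntimeError(f"no surviving simulation in {max_attempts} attempts")


def _prune_to(tree: PhyloTree, keep) -> PhyloTree:
    dtree = tree.to_dendropy()
    taxa = [t for t in dtree.taxon_namespace if t.label in set(keep)]
    dtree.retain_taxa(taxa)
    return PhyloTree.from_dendropy(dtree)


def _reultrametrize(tree: PhyloTree) -> PhyloTree:
    """Stretch pendant branches so every root-to-tip depth equals the max."""
    depths = tree.depths()
    h = depths[: tree.n_tips].max()
    blen = tree.blen.copy()
    for tip in range(tree.n_tips):
        blen[tip] = h - depths[tree.parent[tip]]
    return PhyloTree(tree.parent.copy(), blen, list(tree.labels))


def _one_nni(tree: PhyloTree, rng) -> PhyloTree:
    """One random nearest-neighbour interchange (on a dendropy clone)."""
    dtree = tree.to_dendropy()
    internal = [
        n for n in dtree.preorder_node_iter()
        if not n.is_leaf() and n.parent_node is not None
    ]
    if not internal:
        return tree
    c = internal[rng.integers(len(internal))]
    p = c.parent_node
    sibs = [x for x in p.child_nodes() if x is not c]
    s = sibs[rng.integers(len(sibs))]
    x = c.child_nodes()[rng.integers(len(c.child_nodes()))]
    p.remove_child(s)
    c.remove_child(x)
    c.add_child(s)
    p.add_child(x)
    return PhyloTree.from_dendropy(dtree)


def simulate_posterior_set(base_tree: PhyloTree, n_trees: int,
                           jitter: float = 0.1, seed=None,
                           nni_fraction: float = 0.0) -> TreeSet:
    """Emulate a posterior sample of chronograms around a base tree.

    Each tree's branch lengths are multiplied by i.i.d. lognormal noise
    (``sigma = jitter``) and the tree re-ultrametrised by adjusting pendant
    branches; ``nni_fraction`` of trees additionally receive one random NNI
    move for topological variation.  ``jitter=0, nni_fraction=0`` yields
    identical copies.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    trees = []
    for i in range(n_trees):
        t = base_tree.copy()
        touched = False
        if nni_fraction > 0 and rng.uniform() < nni_fraction:
            t = _one_nni(t, rng)
            touched = True
        if jitter > 0:
            noise = rng.lognormal(0.0, jitter, size=t.n_nodes)
            noise[t.root] = 1.0
            t = PhyloTree(t.parent.copy(), t.blen * noise, list(t.labels))
            touched = True
        trees.append(_reultrametrize(t) if touched else t)
    return TreeSet(trees, provenance="synthetic-posterior")


# ---------------------------------------------------------------------------
# Study-scale demo dataset


def demo_dataset(seed=0, n_tips: int = 100, n_trees: int = 100,
                 jitter: float = 0.08, ps_rate: float = 0.03,
                 gs_rate: float = 0.05):
    """A full synthetic bundle at the empirical study's scale.

    Returns a dict with a base ultrametric tree (~height 1), a jittered
    posterior-style tree set, a clustered five-state substrate character, a
    correlated binary strategy character, a per-species occurrence table
    consistent with both, and the :class:`SimConfig` provenance record.

    Character rates default to a few expected changes across the whole tree,
    which produces the strong phylogenetic clustering the empirical system
    shows.
    """
    rng = np.random.default_rng(seed)
    base = simulate_bd_tree(lam=6.0, mu=1.0, n_tips=n_tips,
                            seed=int(rng.integers(2**31)))
    # rescale to unit height so rates are per-tree-depth
    base = PhyloTree(base.parent.copy(), base.blen / base.height,
                     list(base.labels))
    scale = base.total_length()
    kps = len(PS_STATES)
    Qps = (np.ones((kps, kps)) - np.eye(kps)) * ps_rate * 40.0 / scale
    np.fill_diagonal(Qps, -Qps.sum(axis=1) + np.diag(Qps))
    ps = simulate_mk(base, Qps, root_state=0, states=PS_STATES,
                     seed=int(rng.integers(2**31)))
    ps.name = "PS"
    Qgs = (np.ones((2, 2)) - np.eye(2)) * gs_rate * 40.0 / scale
    np.fill_diagonal(Qgs, -Qgs.sum(axis=1) + np.diag(Qgs))
    gs = simulate_mk(base, Qgs, root_state=1, states=GS_STATES,
                     seed=int(rng.integers(2**31)))
    gs.name = "GS"
    trees = simulate_posterior_set(base, n_trees, jitter=jitter,
                                   seed=int(rng.integers(2**31)))
    rows = []
    for tip in base.labels:
        pref = ps.state_of(tip)
        counts = {s: 0 for s in PS_STATES}
        if gs.state_of(tip) == "specialist":
            counts[pref] = 98
            other = rng.choice([s for s in PS_STATES if s != pref])
            counts[other] = rng.integers(0, 3)
        else:
            counts[pref] = 60
            others = rng.choice([s for s in PS_STATES if s != pref], size=2,
                                replace=False)
            counts[others[0]] = 30
            counts[others[1]] = 10
        rows.append({"species": tip, **counts})
    occurrences = pd.DataFrame(rows).set_index("species")
    config = SimConfig(
        kind="demo_dataset", seed=seed,
        params={"n_tips": n_tips, "n_trees": n_trees, "jitter": jitter,
                "ps_rate": ps_rate, "gs_rate": gs_rate},
    )
    return {"base_tree": base, "trees": trees, "ps": ps, "gs": gs,
            "occurrences": occurrences, "config": config}
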