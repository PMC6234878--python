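"""Stochastic character mapping and transition counting.

A stochastic map is one complete character history on one tree: a sampled
state at every node plus, for every branch, an ordered list of
``(state, dwell time)`` segments.  Maps are drawn conditional on the tip data
and a rate matrix: node states are sampled from their joint conditional
distribution (pruning up-pass, then root-to-tip sampling), and branch
histories conditional on their endpoint states via uniformization
(Poissonisation with the dominating rate ``max|Q_ii|``), which is exact.
Transition counts over many maps summarise how often and in which direction
the character switched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _mkcore
from .mk import edge_probabilities, _root_prior_vector
from .tree import PhyloTree

__all__ = [
    "StochasticMap",
    "TransitionSummary",
    "sample_maps",
    "count_transitions",
]

#: below this dominating-rate × length product a branch is treated as
#: event-free (identity) rather than uniformised
TINY_BRANCH = 1e-8


@dataclass
class StochasticMap:
    """One sampled character history on one tree."""

    states: tuple
    node_states: np.ndarray  # (n_nodes,) sampled state index per node
    segments: dict  # node id -> [(state, dwell), ...] parent-end to child-end
    counts: np.ndarray  # (k, k) off-diagonal change counts
    tree_index: int = 0
    replicate: int = 0
    seed: object = None

    @property
    def n_changes(self) -> int:
        return int(self.counts.sum())


@dataclass
class TransitionSummary:
    """Cross-map transition-count summaries."""

    states: tuple
    per_map: np.ndarray  # (n_maps, k, k)
    cumulative: np.ndarray = field(init=False)
    mean: np.ndarray = field(init=False)

    def __post_init__(self):
        self.cumulative = self.per_map.sum(axis=0)
        self.mean = self.per_map.mean(axis=0)

    def direction_counts(self, i, j) -> np.ndarray:
        """Per-map counts for one direction (for histograms)."""
        i = self.states.index(i) if isinstance(i, str) else i
        j = self.states.index(j) if isinstance(j, str) else j
        return self.per_map[:, i, j]


class InfeasibleEndpointsError(RuntimeError):
    """Endpoint pair has zero probability under Q on a positive branch."""


def _sample_branch_path(rng, Q, R, Rpow, omega, t, a, b, P_ab):
    """Uniformised path on one branch conditional on endpoint states (a → b).

    Returns the list of (time, new_state) true change events.
    """
    if omega * t < TINY_BRANCH:
        if a == b:
            return []
        # dominant single-event path in the vanishing-rate limit
        return [(rng.uniform(0.0, t), b)]
    if P_ab <= 0:
        raise InfeasibleEndpointsError(
            f"P({a}->{b}; t={t}) = 0 under Q; conditioning infeasible"
        )
    # number of uniformised jumps: P(N=n | a,b) ∝ Pois(Ωt; n) · (R^n)[a,b]
    mu_t = omega * t
    u = rng.uniform()
    log_pois = -mu_t
    cum = 0.0
    n_jumps = None
    max_n = int(mu_t + 12.0 * np.sqrt(mu_t) + 60)
    for n in range(max_n + 1):
        while len(Rpow) <= n:
            Rpow.append(Rpow[-1] @ R)
        term = np.exp(log_pois) * Rpow[n][a, b] / P_ab
        cum += term
        if u <= cum:
            n_jumps = n
            break
        log_pois += np.log(mu_t) - np.log(n + 1)
    if n_jumps is None:  # numerical tail; take the truncation point
        n_jumps = max_n
    if n_jumps == 0:
        return []
    while len(Rpow) <= n_jumps:
        Rpow.append(Rpow[-1] @ R)
    times = np.sort(rng.uniform(0.0, t, size=n_jumps))
    events = []
    state = a
    for j in range(1, n_jumps + 1):
        # state after jump j, conditional on reaching b in the remaining jumps
        w = R[state] * Rpow[n_jumps - j][:, b]
        tot = w.sum()
        if tot <= 0:
            raise InfeasibleEndpointsError("zero-probability uniformised step")
        nxt = rng.choice(len(w), p=w / tot)
        if nxt != state:
            events.append((times[j - 1], int(nxt)))
            state = nxt
    return events


def sample_maps(tree: PhyloTree, data, Q, n_maps: int, seed=None,
                root_prior="uniform", tree_index: int = 0) -> list:
    """Draw ``n_maps`` stochastic maps conditional on the tip data and Q."""
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    Q = np.asarray(Q, float)
    k = Q.shape[0]
    rng = np.random.default_rng(seed)
    tipstate = data.state_vector(tree.labels)
    P = edge_probabilities(Q, tree.blen)
    child_ptr, child_idx = tree.flat_children()
    L, logscale = _mkcore.prune_partials(P, tipstate, child_ptr, child_idx,
                                         tree.n_tips)
    if not np.isfinite(logscale):
        raise ValueError("tip data impossible under Q")
    pi = _root_prior_vector(root_prior, Q, L[tree.root], k)
    omega = float(np.max(-np.diag(Q)))
    R = np.eye(k) + (Q / omega if omega > 0 else Q)
    Rpow = [np.eye(k)]

    maps = []
    for rep in range(n_maps):
        node_states = np.empty(tree.n_nodes, dtype=np.int64)
        node_states[: tree.n_tips] = tipstate
        # root draw
        w = pi * L[tree.root]
        node_states[tree.root] = rng.choice(k, p=w / w.sum())
        # preorder: parent ids exceed child ids
        for node in range(tree.n_nodes - 1, tree.n_tips - 1, -1):
            s_par = node_states[node]
            for c in tree.children[node]:
                if c < tree.n_tips:
                    continue
                w = P[c][s_par] * L[c]
                tot = w.sum()
                if tot <= 0:
                    raise InfeasibleEndpointsError(
                        f"no feasible state at node {c}"
                    )
                node_states[c] = rng.choice(k, p=w / tot)
        # branch paths
        segments = {}
        counts = np.zeros((k, k), dtype=np.int64)
        for node in range(tree.n_nodes - 1):
            a = node_states[tree.parent[node]]
            b = node_states[node]
            t = float(tree.blen[node])
            events = _sample_branch_path(
                rng, Q, R, Rpow, omega, t, int(a), int(b), float(P[node][a, b])
            )
            segs = []
            prev_t, state = 0.0, int(a)
            for ev_t, ev_s in events:
                segs.append((state, ev_t - prev_t))
                counts[state, ev_s] += 1
                prev_t, state = ev_t, ev_s
            segs.append((state, t - prev_t))
            if state != b:  # cannot happen: conditioned on endpoints
                raise InfeasibleEndpointsError("path endpoint mismatch")
            segments[node] = segs
        maps.append(
            StochasticMap(states=tuple(data.states), node_states=node_states,
                          segments=segments, counts=counts,
                          tree_index=tree_index, replicate=rep, seed=seed)
        )
    return maps


def count_transitions(maps) -> TransitionSummary:
    """Aggregate per-map transition-count matrices across maps."""
    maps = list(maps)
    if not maps:
        raise ValueError("no maps given")
    states = maps[0].states
    for m in maps:
        if m.states != states:
            raise ValueError("maps mix different state spaces")
    per_map = np.stack([m.counts for m in maps])
    return TransitionSummary(states=states, per_map=per_map)


def maps_to_events(maps) -> list:
    """Flatten maps to an event list (tree, map, branch, time, from, to)."""
    rows = []
    for m in maps:
        for node, segs in m.segments.items():
            t = 0.0
            for (state, dwell), nxt in zip(segs[:-1], segs[1:]):
                t += dwell
                rows.append({
                    "tree_index": m.tree_index, "replicate": m.replicate,
                    "branch": node, "time_on_branch": t,
                    "from_state": m.states[state], "to_state": m.states[nxt[0]],
                })
    return rows
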