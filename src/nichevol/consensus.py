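"""Ensemble ancestral-state reconstruction with per-node majority voting.

Single-method, single-model, single-tree ancestral reconstructions are
sensitive to all three choices.  The ensemble strategy here runs every cell
of a (method × model × root prior) grid on every tree of a posterior sample,
takes the point ancestral state per anchored node from each cell, and calls
the consensus state per node by majority vote, with vote margins, per-method
agreement tables, tie flags and a ledger of failed fits reported alongside.

Focal nodes are identified across topologically varying trees by MRCA
anchors (see :class:`nichevol.tree.NodeAnchor`); the fraction of trees in
which an anchor resolves monophyletically is reported with its votes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import mk, simmap
from .tree import TreeSet, resolve_anchor

__all__ = [
    "GridCell",
    "EnsembleGrid",
    "ConsensusReport",
    "default_grid",
    "run_ensemble",
    "summarize_node",
]


@dataclass(frozen=True)
class GridCell:
    method: str  # "ml" or "simmap"
    model: str  # "ER", "SYM", "ARD"
    root_prior: str = "uniform"

    @property
    def name(self) -> str:
        return f"{self.method}:{self.model}:{self.root_prior}"


@dataclass
class EnsembleGrid:
    cells: list

    def __post_init__(self):
        if not self.cells:
            raise ValueError("empty ensemble grid")
        for c in self.cells:
            if c.method not in ("ml", "simmap"):
                raise ValueError(f"unknown method {c.method!r}")

    def __len__(self):
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)


def default_grid(k: int) -> EnsembleGrid:
    """Default reconstruction grid for a k-state character.

    Multi-state: ML marginal reconstruction under {ER, SYM, ARD} × {uniform,
    stationary, fitzjohn-conditional} root priors, plus stochastic mapping
    under each model (12 cells).  Binary: SYM duplicates ER, so the model
    axis shrinks to {ER, ARD} (8 cells).  Fully configurable.
    """
    models = ["ER", "ARD"] if k == 2 else ["ER", "SYM", "ARD"]
    cells = [
        GridCell("ml", m, rp)
        for m in models
        for rp in ("uniform", "stationary", "conditional")
    ]
    cells += [GridCell("simmap", m, "uniform") for m in models]
    return EnsembleGrid(cells)


@dataclass
class ConsensusReport:
    """Vote tallies per anchored node across all grid cells and trees."""

    anchors: list
    grid: EnsembleGrid
    n_trees: int
    # anchor name -> cell name -> state name -> votes
    votes: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)  # (tree_index, cell name, reason)
    monophyly: dict = field(default_factory=dict)  # anchor name -> fraction

    def total_votes(self, anchor_name: str) -> dict:
        out: dict = {}
        for cell_votes in self.votes[anchor_name].values():
            for state, n in cell_votes.items():
                out[state] = out.get(state, 0) + n
        return out

    def to_rows(self) -> list:
        rows = []
        for a in self.votes:
            for cell, sv in self.votes[a].items():
                for state, n in sv.items():
                    rows.append({"node": a, "cell": cell, "state": state,
                                 "votes": n})
        return rows


def _cell_point_states(tree, data, cell: GridCell, anchor_nodes, seed,
                       n_maps: int, n_restarts: int):
    """Point ancestral state per anchored node for one tree × grid cell."""
    fit = mk.fit_mk(tree, data, cell.model, root_prior=cell.root_prior,
                    n_restarts=n_restarts, seed=seed)
    if not fit.converged:
        raise RuntimeError("fit failed to converge")
    Q = fit.q_matrix
    if cell.method == "ml":
        asr = mk.marginal_asr(tree, data, Q, root_prior=cell.root_prior)
        return {name: asr.point_estimate(node)
                for name, node in anchor_nodes.items()}
    maps = simmap.sample_maps(tree, data, Q, n_maps=n_maps, seed=seed,
                              root_prior=cell.root_prior)
    draws = np.stack([m.node_states for m in maps])
    out = {}
    for name, node in anchor_nodes.items():
        modal = np.bincount(draws[:, node], minlength=data.k).argmax()
        out[name] = data.states[int(modal)]
    return out


def run_ensemble(trees: TreeSet, data, grid: EnsembleGrid, anchors, seed=None,
                 n_maps: int = 25, n_restarts: int = 2) -> ConsensusReport:
    """Run every grid cell on every tree and tally per-node state votes.

    Failed fits are logged in ``report.failures`` and excluded from votes,
    so per node: total votes + failures = n_trees × n_cells.
    """
    rng = np.random.default_rng(seed)
    report = ConsensusReport(anchors=list(anchors), grid=grid,
                             n_trees=len(trees))
    for a in anchors:
        report.votes[a.name] = {c.name: {} for c in grid}
    mono = {a.name: 0 for a in anchors}
    for ti, tree in enumerate(trees):
        anchor_nodes = {}
        for a in anchors:
            node, is_mono = resolve_anchor(a, tree)
            anchor_nodes[a.name] = node
            mono[a.name] += bool(is_mono)
        for cell in grid:
            cell_seed = int(rng.integers(2**31))
            try:
                states = _cell_point_states(tree, data, cell, anchor_nodes,
                                            cell_seed, n_maps, n_restarts)
            except Exception as e:  # failures accumulate, never abort the grid
                report.failures.append((ti, cell.name, str(e)))
                continue
            for name, state in states.items():
                sv = report.votes[name][cell.name]
                sv[state] = sv.get(state, 0) + 1
    report.monophyly = {a.name: mono[a.name] / len(trees) for a in anchors}
    return report


def summarize_node(report: ConsensusReport, node_name: str):
    """Winning state, vote counts and margin for one anchored node.

    Ties are reported as ties (winner ``None``), never broken arbitrarily.
    """
    if node_name not in report.votes:
        raise KeyError(f"unknown node {node_name!r}")
    totals = report.total_votes(node_name)
    n_votes = sum(totals.values())
    if not totals:
        return {"node": node_name, "winner": None, "votes": {}, "margin": 0.0,
                "tie": False}
    best = max(totals.values())
    winners = sorted(s for s, n in totals.items() if n == best)
    tie = len(winners) > 1
    return {
        "node": node_name,
        "winner": None if tie else winners[0],
        "votes": totals,
        "margin": best / n_votes if n_votes else 0.0,
        "tie": tie,
        "monophyly_fraction": report.monophyly.get(node_name),
    }
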