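"""Evolutionary dead-end ("no-switch") model ranking across a tree set.

Every constrained rate-matrix model (one per non-empty proper subset of
states made absorbing; 30 models for a five-state character) is fitted to
every tree of a posterior sample, the models are ranked per tree by AIC
(dense ranks, 1 = best), and rank frequencies are aggregated across trees:
for how many trees a model came first, second, and so on.  The headline
summary is the set of models that rank within the top ``window`` (default
five) on a majority of trees — the states those winning masks make
non-exitable are the candidate dead-end substrates.

Fits that fail to converge are excluded from the affected tree's ranking
(and counted), not propagated as errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mk
from .tree import TreeSet

__all__ = ["RankTable", "rank_models", "top_models"]

#: AICs closer than this are treated as tied when ranking
AIC_TIE_TOL = 1e-6


@dataclass
class RankTable:
    """AICs, convergence flags, and per-tree dense ranks for a model grid."""

    model_names: list
    n_params: np.ndarray  # (M,)
    aic: np.ndarray  # (M, T)
    loglik: np.ndarray  # (M, T)
    converged: np.ndarray  # (M, T) bool
    ranks: np.ndarray  # (M, T) int; 0 where excluded
    dropped_trees: list = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.model_names)

    @property
    def n_trees(self) -> int:
        return self.aic.shape[1]

    @property
    def n_attempted(self) -> int:
        return int(self.aic.size)

    @property
    def n_failed(self) -> int:
        return int((~self.converged).sum())

    def rank_frequency(self, model) -> np.ndarray:
        """Histogram over ranks 1..M of one model's per-tree ranks."""
        m = self.model_names.index(model) if isinstance(model, str) else model
        r = self.ranks[m]
        return np.bincount(r[r > 0], minlength=self.n_models + 1)[1:]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, name in enumerate(self.model_names):
            for t in range(self.n_trees):
                rows.append({
                    "model": name, "tree_index": t,
                    "loglik": self.loglik[m, t], "n_params": int(self.n_params[m]),
                    "aic": self.aic[m, t], "rank": int(self.ranks[m, t]),
                    "converged": bool(self.converged[m, t]),
                })
        return pd.DataFrame(rows)


def _dense_ranks(aic, n_params, converged):
    """Dense AIC ranks (1 = best) over the converged models of one tree.

    Ties within ``AIC_TIE_TOL`` share a rank; ordering within the sorted
    sequence breaks exact ties toward fewer parameters, then model order.
    """
    M = len(aic)
    ranks = np.zeros(M, dtype=np.int64)
    valid = np.flatnonzero(converged & np.isfinite(aic))
    if valid.size == 0:
        return ranks, False
    order = sorted(valid, key=lambda m: (aic[m], n_params[m], m))
    rank = 1
    prev = None
    for m in order:
        if prev is not None and aic[m] - prev > AIC_TIE_TOL:
            rank += 1
        ranks[m] = rank
        prev = aic[m]
    return ranks, True


def rank_models(trees: TreeSet, data, models=None, seed=None,
                root_prior="uniform", n_restarts: int = 1,
                maxfev: int | None = 800) -> RankTable:
    """Fit every model to every tree and rank by AIC per tree.

    ``models`` defaults to the full no-switch enumeration for the
    character's state space.  Every model × tree cell is attempted;
    non-converged cells are excluded from that tree's ranking.
    """
    if models is None:
        models = mk.enumerate_noswitch_models(data.k, states=data.states)
    M, T = len(models), len(trees)
    rng = np.random.default_rng(seed)
    aic = np.full((M, T), np.inf)
    loglik = np.full((M, T), -np.inf)
    converged = np.zeros((M, T), dtype=bool)
    n_params = np.array([m.n_params for m in models])
    for t, tree in enumerate(trees):
        for m, model in enumerate(models):
            fit = mk.fit_mk(tree, data, model, root_prior=root_prior,
                            n_restarts=n_restarts,
                            seed=int(rng.integers(2**31)), maxfev=maxfev)
            converged[m, t] = fit.converged
            loglik[m, t] = fit.loglik
            aic[m, t] = fit.aic
    ranks = np.zeros((M, T), dtype=np.int64)
    dropped = []
    for t in range(T):
        ranks[:, t], ok = _dense_ranks(aic[:, t], n_params, converged[:, t])
        if not ok:
            dropped.append(t)
    return RankTable(model_names=[m.name for m in models], n_params=n_params,
                     aic=aic, loglik=loglik, converged=converged, ranks=ranks,
                     dropped_trees=dropped)


def top_models(table: RankTable, window: int = 5) -> list:
    """Models ranking within the top ``window`` on a majority of trees.

    Returns ``[(model_name, n_trees_in_window), ...]`` for every model whose
    count strictly exceeds half the non-dropped trees, best-supported first.
    """
    n_valid = table.n_trees - len(table.dropped_trees)
    out = []
    for m, name in enumerate(table.model_names):
        r = table.ranks[m]
        count = int(np.sum((r > 0) & (r <= window)))
        if count > n_valid / 2.0:
            out.append((name, count))
    out.sort(key=lambda x: (-x[1], table.model_names.index(x[0])))
    return out
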