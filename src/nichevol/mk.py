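"""Mk (continuous-time Markov) models for discrete characters on trees.

Provides rate-matrix templates with constraint masks (ER / SYM / ARD /
arbitrary custom masks, including absorbing "no-switch" scenarios), the
Felsenstein pruning likelihood (multifurcation-safe), maximum-likelihood
fitting with multi-start optimisation in log-rate space, AIC, marginal
ancestral-state reconstruction, and the exhaustive enumeration of no-switch
constraint masks (one per non-empty proper subset of states made
non-exitable, 2**k − 2 models in total).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import minimize, minimize_scalar

from . import _mkcore
from .tree import PhyloTree

__all__ = [
    "MkModel",
    "MkFit",
    "AncestralStates",
    "build_model",
    "transition_probabilities",
    "edge_probabilities",
    "stationary_distribution",
    "prune_loglik",
    "fit_mk",
    "marginal_asr",
    "enumerate_noswitch_models",
]

#: mask codes for non-free cells
DIAG = -1
ZERO = -2

#: box constraints on free rates (per unit branch length)
RATE_MIN = 1e-9
RATE_MAX = 1e3

ROOT_PRIORS = ("uniform", "stationary", "conditional")


@dataclass
class MkModel:
    """A k-state rate-matrix template: constraint mask plus free parameters.

    ``mask[i, j]`` for ``i != j`` is either a free-parameter index (>= 0;
    repeated indices tie rates) or ``ZERO`` (structurally impossible
    transition).  The diagonal is always ``DIAG`` and derived as minus the
    row sum.
    """

    name: str
    k: int
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=np.int64)
        if self.mask.shape != (self.k, self.k):
            raise ValueError(
                f"mask shape {self.mask.shape} does not match k={self.k}"
            )
        off = self.mask[~np.eye(self.k, dtype=bool)]
        if np.any(off < ZERO):
            raise ValueError("mask entries must be >= -2")
        idx = off[off >= 0]
        self._n_params = int(idx.max()) + 1 if idx.size else 0
        if self._n_params and set(range(self._n_params)) != set(idx.tolist()):
            raise ValueError("free-parameter indices must be consecutive from 0")

    @property
    def n_params(self) -> int:
        return self._n_params

    def q(self, theta) -> np.ndarray:
        """Instantiate the rate matrix for a free-parameter vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"model {self.name!r} expects {self.n_params} rates, got {theta.shape}"
            )
        if np.any(theta < 0):
            raise ValueError("rates must be >= 0")
        if not hasattr(self, "_free_cells"):
            free = np.argwhere(self.mask >= 0)
            self._free_cells = (free[:, 0], free[:, 1],
                                self.mask[free[:, 0], free[:, 1]])
        rows, cols, idx = self._free_cells
        Q = np.zeros((self.k, self.k))
        Q[rows, cols] = theta[idx]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def to_json(self) -> str:
        zero = [[int(i), int(j)] for i in range(self.k) for j in range(self.k)
                if i != j and self.mask[i, j] == ZERO]
        cells = {}
        for i in range(self.k):
            for j in range(self.k):
                if i != j and self.mask[i, j] >= 0:
                    cells.setdefault(int(self.mask[i, j]), []).append([i, j])
        return json.dumps(
            {"name": self.name, "k": self.k, "zero_cells": zero,
             "tied_cells": cells}
        )


def build_model(k: int, spec="ER", name: str | None = None) -> MkModel:
    """Build a rate-matrix template.

    ``spec`` is ``"ER"`` (1 shared rate), ``"SYM"`` (k(k−1)/2 symmetric
    rates), ``"ARD"`` (k(k−1) free rates) or a custom integer mask array.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(spec, str):
        spec_u = spec.upper()
        mask = np.full((k, k), DIAG, dtype=np.int64)
        if spec_u == "ER":
            mask[~np.eye(k, dtype=bool)] = 0
        elif spec_u == "SYM":
            p = 0
            for i in range(k):
                for j in range(i + 1, k):
                    mask[i, j] = mask[j, i] = p
                    p += 1
        elif spec_u == "ARD":
            p = 0
            for i in range(k):
                for j in range(k):
                    if i != j:
                        mask[i, j] = p
                        p += 1
        else:
            raise ValueError(f"unknown model spec {spec!r}")
        return MkModel(name or spec_u, k, mask)
    mask = np.asarray(spec, dtype=np.int64)
    return MkModel(name or "custom", k, mask)


def enumerate_noswitch_models(k: int, states=None) -> list[MkModel]:
    """All no-switch (dead-end) constraint masks for a k-state character.

    One model per non-empty proper subset S of states: every transition out
    of every state in S is fixed to zero (S absorbing) and all remaining
    off-diagonal rates are free.  Ordered by subset size, then
    lexicographically; ``2**k − 2`` models in total (30 for k = 5).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if states is not None and len(states) != k:
        raise ValueError("states length must equal k")
    models = []
    for size in range(1, k):
        for subset in itertools.combinations(range(k), size):
            mask = np.full((k, k), DIAG, dtype=np.int64)
            p = 0
            for i in range(k):
                for j in range(k):
                    if i == j:
                        continue
                    if i in subset:
                        mask[i, j] = ZERO
                    else:
                        mask[i, j] = p
                        p += 1
            if states is not None:
                tag = "+".join(states[i] for i in subset)
            else:
                tag = "+".join(str(i) for i in subset)
            models.append(MkModel(f"noswitch[{tag}]", k, mask))
    return models


# ---------------------------------------------------------------------------
# Transition probabilities


def transition_probabilities(Q, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a single branch length."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    return edge_probabilities(np.asarray(Q, float), np.array([t]))[0]


def _eig_propagator(Q):
    """Eigendecomposition of Q usable for fast exp(Qt), or None if unsafe.

    Masked (absorbing) matrices can be defective; the caller falls back to
    scaling-and-squaring in that case.
    """
    w, V = np.linalg.eig(Q)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return None
    # a near-defective eigenbasis shows up as poor reconstruction of Q
    if np.max(np.abs((V * w) @ Vinv - Q)) > 1e-10 * max(1.0, np.abs(Q).max()):
        return None
    return w, V, Vinv


def edge_probabilities(Q, lengths) -> np.ndarray:
    """exp(Q t) for every t in ``lengths`` (vectorised over branches)."""
    Q = np.asarray(Q, float)
    lengths = np.asarray(lengths, float)
    k = Q.shape[0]
    eig = _eig_propagator(Q)
    if eig is not None:
        w, V, Vinv = eig
        E = np.exp(np.multiply.outer(lengths, w))  # (B, k)
        P = np.einsum("ab,nb,bc->nac", V, E, Vinv)
        P = np.ascontiguousarray(P.real)
    else:
        P = np.empty((len(lengths), k, k))
        cache: dict[float, np.ndarray] = {}
        for n, t in enumerate(lengths):
            key = float(t)
            if key not in cache:
                cache[key] = scipy.linalg.expm(Q * key)
            P[n] = cache[key]
    np.clip(P, 0.0, 1.0, out=P)
    P[lengths == 0.0] = np.eye(k)  # exact identity, no eigen roundoff leak
    return P


def stationary_distribution(Q) -> np.ndarray:
    """Stationary distribution of Q.

    For irreducible chains this is the unique left null vector.  For
    reducible (masked/absorbing) chains the stationary set is not unique; the
    long-run distribution reached from a uniform start is returned instead.
    """
    Q = np.asarray(Q, float)
    k = Q.shape[0]
    ns = scipy.linalg.null_space(Q.T)
    if ns.shape[1] == 1:
        pi = np.abs(ns[:, 0])
        return pi / pi.sum()
    scale = np.abs(np.diag(Q)).max()
    horizon = 200.0 / scale if scale > 0 else 1.0
    P = scipy.linalg.expm(Q * horizon)
    pi = np.full(k, 1.0 / k) @ P
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Pruning likelihood


def _root_prior_vector(root_prior, Q, L_root, k):
    if isinstance(root_prior, np.ndarray):
        return root_prior
    if root_prior == "uniform":
        return np.full(k, 1.0 / k)
    if root_prior == "stationary":
        return stationary_distribution(Q)
    if root_prior == "conditional":
        s = L_root.sum()
        if s <= 0:
            return np.full(k, 1.0 / k)
        return L_root / s
    raise ValueError(f"unknown root prior {root_prior!r}")


def _tipstates(tree: PhyloTree, data) -> np.ndarray:
    return data.state_vector(tree.labels)


def prune_loglik(tree: PhyloTree, data, Q, root_prior="uniform") -> float:
    """Log-likelihood of the tip data under rate matrix Q (pruning algorithm).

    ``root_prior`` is ``"uniform"``, ``"stationary"``, ``"conditional"``
    (FitzJohn weighting by the relative root partials) or an explicit
    probability vector.  Multifurcations are handled natively.
    """
    Q = np.asarray(Q, float)
    k = Q.shape[0]
    if k != data.k:
        raise ValueError(f"Q is {k}-state but character has k={data.k}")
    tipstate = _tipstates(tree, data)
    P = edge_probabilities(Q, tree.blen)
    child_ptr, child_idx = tree.flat_children()
    L_root, logscale = _mkcore.prune_root(P, tipstate, child_ptr, child_idx,
                                          tree.n_tips)
    if not np.isfinite(logscale):
        return -np.inf
    pi = _root_prior_vector(root_prior, Q, L_root, k)
    tot = float(pi @ L_root)
    if tot <= 0:
        return -np.inf
    return float(np.log(tot) + logscale)


@dataclass
class MkFit:
    """Result of a maximum-likelihood Mk fit."""

    model: MkModel
    theta: np.ndarray
    loglik: float
    converged: bool
    root_prior: object = "uniform"
    n_restarts: int = 1

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def aic(self) -> float:
        if not self.converged or not np.isfinite(self.loglik):
            return np.inf
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def q_matrix(self) -> np.ndarray:
        return self.model.q(self.theta)


def _initial_rate(tree: PhyloTree, data) -> float:
    """Crude rate scale: observed state diversity per unit tree length."""
    total = tree.total_length()
    k_obs = max(2, int((data.counts() > 0).sum()))
    return max(k_obs / max(total, 1e-12), 10 * RATE_MIN)


def fit_mk(tree: PhyloTree, data, model, root_prior="uniform",
           n_restarts: int = 5, seed=None, maxfev: int | None = None) -> MkFit:
    """Maximum-likelihood fit of an Mk model by multi-start optimisation.

    Optimisation runs in log-rate space with box constraints
    ``[1e-9, 1e3]``; the best of ``n_restarts`` local searches is kept.
    Failures are reported through ``converged=False`` (AIC = inf), never as
    exceptions, so grid analyses can exclude them the way failed fits are
    excluded from rank summaries.
    """
    if isinstance(model, str):
        model = build_model(data.k, model)
    npar = model.n_params
    rng = np.random.default_rng(seed)
    lo, hi = np.log(RATE_MIN), np.log(RATE_MAX)

    def neg(logtheta):
        ll = prune_loglik(tree, data, model.q(np.exp(logtheta)), root_prior)
        return -ll if np.isfinite(ll) else 1e12

    if npar == 1:
        # bounded 1-D search is deterministic; restarts add nothing
        res = minimize_scalar(
            lambda x: neg(np.array([x])), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        best_x, best_f = np.array([res.x]), res.fun
    else:
        # the shared-rate optimum is a strong, cheap starting point for any
        # multi-rate mask; extra restarts jitter around it in log space
        er = fit_mk(tree, data, build_model(data.k, "ER"),
                    root_prior=root_prior, n_restarts=1)
        q0 = np.log(er.theta[0]) if er.converged \
            else np.log(_initial_rate(tree, data))
        q0 = np.clip(q0, lo + 1.0, hi - 1.0)
        best_x, best_f = None, np.inf
        for r in range(max(1, n_restarts)):
            x0 = np.full(npar, q0) if r == 0 else np.clip(
                q0 + rng.normal(0, 1.5, size=npar), lo, hi)
            res = minimize(
                neg, x0, method="L-BFGS-B", bounds=[(lo, hi)] * npar,
                options={"maxfun": maxfev or 3000, "ftol": 1e-9,
                         "gtol": 1e-6},
            )
            if res.fun < best_f:
                best_x, best_f = res.x, res.fun
    converged = best_x is not None and best_f < 1e11
    theta = np.exp(best_x) if best_x is not None else np.full(npar, np.nan)
    loglik = -best_f if converged else -np.inf
    return MkFit(model=model, theta=theta, loglik=loglik, converged=converged,
                 root_prior=root_prior, n_restarts=n_restarts)


# ---------------------------------------------------------------------------
# Marginal ancestral states


@dataclass
class AncestralStates:
    """Marginal state probabilities at internal nodes."""

    states: tuple
    probs: dict = field(default_factory=dict)  # node id -> (k,) vector

    def point_estimate(self, node: int) -> str:
        return self.states[int(np.argmax(self.probs[node]))]


def marginal_asr(tree: PhyloTree, data, Q, root_prior="uniform") -> AncestralStates:
    """Marginal ancestral-state probabilities at every internal node.

    Standard up–down (inside–outside) algorithm: the marginal at a node
    combines the pruning partial below it with the outside partial from the
    rest of the tree and the root prior.
    """
    Q = np.asarray(Q, float)
    k = Q.shape[0]
    tipstate = _tipstates(tree, data)
    P = edge_probabilities(Q, tree.blen)
    child_ptr, child_idx = tree.flat_children()
    L, logscale = _mkcore.prune_partials(P, tipstate, child_ptr, child_idx,
                                         tree.n_tips)
    if not np.isfinite(logscale):
        raise ValueError("tip data impossible under Q")
    pi = _root_prior_vector(root_prior, Q, L[tree.root], k)
    # outside pass, root downward (preorder = descending node ids)
    down = np.zeros((tree.n_nodes, k))
    down[tree.root] = pi
    for node in range(tree.n_nodes - 1, tree.n_tips - 1, -1):
        kids = tree.children[node]
        # P-projected partials of each child, for sibling products
        proj = {c: P[c] @ L[c] for c in kids}
        for c in kids:
            sib = down[node].copy()
            for s in kids:
                if s != c:
                    sib *= proj[s]
            vec = P[c].T @ sib
            tot = vec.sum()
            down[c] = vec / tot if tot > 0 else vec
    out = AncestralStates(states=tuple(data.states))
    for node in range(tree.n_tips, tree.n_nodes):
        m = down[node] * L[node]
        s = m.sum()
        if s <= 0:
            raise ValueError(f"zero marginal at node {node}")
        out.probs[node] = m / s
    return out


def fits_to_table(fits) -> "list[dict]":
    """Serialise a collection of fits to rows (model id, lnL, K, AIC, converged)."""
    return [
        {"model": f.model.name, "loglik": f.loglik, "n_params": f.n_params,
         "aic": f.aic, "converged": f.converged}
        for f in fits
    ]
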