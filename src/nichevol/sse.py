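"""State-dependent speciation–extinction (MuSSE) inference.

The MuSSE model couples a k-state character to diversification: lineages in
state *i* speciate at rate λᵢ, go extinct at rate μᵢ, and switch to state
*j* at rate qᵢⱼ.  The likelihood of an ultrametric, fully bifurcating tree
with tip states follows from integrating the standard D/E ODE system along
every branch (see :mod:`nichevol._ssecore`), with per-state sampling
fractions ρᵢ entering through the tip initial conditions
``D_i(0) = ρ_i·1[state=i]``, ``E_i(0) = 1 − ρ_i``.

Beyond the likelihood this module provides maximum-likelihood fitting,
Metropolis–Hastings MCMC with independent exponential priors,
diversification-rate (r = λ − μ) density summaries pooled over trees,
pairwise Mann–Whitney rate comparisons, and the trait-independence
calibration test: the rate at which character-dependent models are preferred
for characters simulated with no effect on diversification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from . import _ssecore
from .tree import PhyloTree, TreeValidationError

__all__ = [
    "MusseParams",
    "MusseFit",
    "PosteriorSample",
    "musse_loglik",
    "bd_loglik",
    "fit_musse",
    "musse_mcmc",
    "diversification_density",
    "compare_rates",
    "trait_independence_test",
]

#: ODE tolerances for per-branch integration (tight enough that accumulated
#: error across a few hundred branches stays below ~1e-8 in log-likelihood)
ODE_RTOL = 1e-9
ODE_ATOL = 1e-12

#: box constraints for ML fitting (per unit branch length)
SSE_RATE_MIN = 1e-8
SSE_RATE_MAX = 1e3


@dataclass
class MusseParams:
    """Per-state MuSSE parameters λᵢ, μᵢ, qᵢⱼ and sampling fractions ρᵢ."""

    lam: np.ndarray
    mu: np.ndarray
    q: np.ndarray  # (k, k), diagonal ignored
    rho: np.ndarray = None

    def __post_init__(self):
        self.lam = np.atleast_1d(np.asarray(self.lam, float))
        self.mu = np.atleast_1d(np.asarray(self.mu, float))
        self.q = np.atleast_2d(np.asarray(self.q, float))
        k = len(self.lam)
        if self.rho is None:
            self.rho = np.ones(k)
        self.rho = np.atleast_1d(np.asarray(self.rho, float))
        if not (len(self.mu) == k and self.q.shape == (k, k)
                and len(self.rho) == k):
            raise ValueError("inconsistent MuSSE parameter dimensions")
        if np.any(self.lam <= 0):
            raise ValueError("speciation rates must be > 0")
        if np.any(self.mu < 0) or np.any(self.q < 0):
            raise ValueError("extinction and transition rates must be >= 0")
        if np.any((self.rho <= 0) | (self.rho > 1)):
            raise ValueError("sampling fractions must be in (0, 1]")

    @property
    def k(self) -> int:
        return len(self.lam)

    @property
    def r(self) -> np.ndarray:
        """Net diversification rate per state, r = λ − μ."""
        return self.lam - self.mu


def _tipstates(tree: PhyloTree, data, k: int) -> np.ndarray:
    if hasattr(data, "state_vector"):
        ts = data.state_vector(tree.labels)
    else:
        ts = np.asarray(data, dtype=np.int64)
        if ts.shape != (tree.n_tips,):
            raise ValueError("tip-state array length must equal n_tips")
    if ts.size and (ts.min() < 0 or ts.max() >= k):
        raise ValueError("tip state outside parameter state space")
    return ts


def _check_tree(tree: PhyloTree):
    if not tree.is_ultrametric():
        raise TreeValidationError("MuSSE requires an ultrametric tree")
    if not tree.is_binary():
        raise TreeValidationError("MuSSE requires a fully bifurcating tree")


def musse_loglik(tree: PhyloTree, data, params: MusseParams,
                 root="fitzjohn", condition_on_survival: bool = False,
                 rtol: float = ODE_RTOL, atol: float = ODE_ATOL) -> float:
    """MuSSE log-likelihood of a tree plus tip states.

    ``root`` is ``"fitzjohn"`` (weight root D by its own relative
    magnitudes), ``"uniform"``, or an explicit weight vector.  With
    ``condition_on_survival`` the root D is divided by λᵢ(1−Eᵢ)² before
    weighting.  ``data`` may be a CharacterData or a raw integer state array
    (which permits the degenerate k = 1 pure-birth/birth–death check).
    """
    _check_tree(tree)
    k = params.k
    tipstate = _tipstates(tree, data, k)
    qmat = params.q.copy()
    np.fill_diagonal(qmat, 0.0)
    child_ptr, child_idx = tree.flat_children()
    y, logscale = _ssecore.musse_root(
        tree.blen, child_ptr, child_idx, tree.n_tips, tipstate,
        params.rho, params.lam, params.mu, qmat, rtol, atol,
    )
    if np.isnan(logscale):
        raise RuntimeError("ODE integration failed on a branch")
    if not np.isfinite(logscale):
        return -np.inf
    E = y[:k]
    D = y[k:].copy()
    if isinstance(root, str) and root == "fitzjohn":
        w = D / D.sum() if D.sum() > 0 else np.full(k, 1.0 / k)
    elif isinstance(root, str) and root == "uniform":
        w = np.full(k, 1.0 / k)
    else:
        w = np.asarray(root, float)
    if condition_on_survival:
        denom = params.lam * (1.0 - E) ** 2
        if np.any(denom <= 0):
            return -np.inf
        D = D / denom
    tot = float(w @ D)
    if tot <= 0:
        return -np.inf
    return float(np.log(tot) + logscale)


def bd_loglik(tree: PhyloTree, lam: float, mu: float) -> float:
    """Closed-form constant-rate birth–death log-likelihood (ρ = 1).

    Same conventions as :func:`musse_loglik` with no survival conditioning:
    one λ factor per internal node plus, per branch, the exact propagator
    ratio ``ln f(age_parent) − ln f(age_child)`` where
    ``f(a) = e^{-ra} r² / (λ − μ e^{-ra})²`` is the lineage-survival-weighted
    density at age ``a`` before the present (extinction probability
    accumulates from the tips, so branch factors depend on node ages, not
    branch lengths; for μ = 0 the terms telescope to ``−λ·Σ lengths``).
    Serves as the independent reference for the k = 1 / equal-rates
    reductions of the MuSSE likelihood.
    """
    if not lam > 0 or mu < 0:
        raise ValueError("need lam > 0 and mu >= 0")
    _check_tree(tree)
    r = lam - mu
    ages = tree.height - tree.depths()

    def logf(a):
        if mu == 0:
            return -lam * a
        return -r * a + 2.0 * (np.log(r) - np.log(lam - mu * np.exp(-r * a)))

    total = (tree.n_nodes - tree.n_tips) * np.log(lam)
    for node in range(tree.n_nodes - 1):
        total += logf(ages[tree.parent[node]]) - logf(ages[node])
    return float(total)


# ---------------------------------------------------------------------------
# Parameter packing for ML / MCMC


class _MusseSpec:
    """Free-parameter layout: per-state or tied λ/μ, ARD or ER q, fixed μ=0."""

    def __init__(self, k, tie_lambda=False, tie_mu=False, fix_mu=None,
                 q_spec="ard", rho=None):
        self.k = k
        self.tie_lambda = tie_lambda
        self.tie_mu = tie_mu
        self.fix_mu = fix_mu
        self.q_spec = q_spec
        self.rho = np.ones(k) if rho is None else np.asarray(rho, float)
        self.n_lam = 1 if tie_lambda else k
        self.n_mu = 0 if fix_mu is not None else (1 if tie_mu else k)
        self.n_q = 1 if q_spec == "er" else k * (k - 1)
        self.n_params = self.n_lam + self.n_mu + self.n_q

    @property
    def names(self):
        out = [f"lam_{i}" for i in range(self.n_lam)]
        out += [f"mu_{i}" for i in range(self.n_mu)]
        if self.q_spec == "er":
            out += ["q"]
        else:
            out += [f"q_{i}{j}" for i in range(self.k) for j in range(self.k)
                    if i != j]
        return out

    def unpack(self, theta) -> MusseParams:
        k = self.k
        pos = 0
        lam = np.full(k, theta[0]) if self.tie_lambda else theta[:k].copy()
        pos += self.n_lam
        if self.fix_mu is not None:
            mu = np.full(k, float(self.fix_mu))
        elif self.tie_mu:
            mu = np.full(k, theta[pos])
        else:
            mu = theta[pos:pos + k].copy()
        pos += self.n_mu
        q = np.zeros((k, k))
        if self.q_spec == "er":
            q[:] = theta[pos]
            np.fill_diagonal(q, 0.0)
        else:
            vals = theta[pos:]
            idx = 0
            for i in range(k):
                for j in range(k):
                    if i != j:
                        q[i, j] = vals[idx]
                        idx += 1
        return MusseParams(lam=lam, mu=mu, q=q, rho=self.rho.copy())


@dataclass
class MusseFit:
    """Maximum-likelihood MuSSE fit."""

    params: MusseParams
    loglik: float
    converged: bool
    n_params: int

    @property
    def aic(self) -> float:
        if not self.converged:
            return np.inf
        return 2.0 * self.n_params - 2.0 * self.loglik


def _initial_theta(tree, data, spec: _MusseSpec, rng):
    n = tree.n_tips
    lam0 = max((n - 1) / max(tree.total_length(), 1e-9), 1e-4)
    q0 = max(spec.k / max(tree.total_length(), 1e-9), 1e-4)
    x = []
    x += [lam0] * spec.n_lam
    x += [lam0 * 0.2] * spec.n_mu
    x += [q0] * spec.n_q
    return np.log(np.array(x))


def fit_musse(tree: PhyloTree, data, rho=None, seed=None, tie_lambda=False,
              tie_mu=False, fix_mu=None, q_spec="ard", root="fitzjohn",
              condition_on_survival: bool = False, n_restarts: int = 3,
              maxfev: int | None = None, x0=None) -> MusseFit:
    """Box-constrained multi-start ML fit of a MuSSE model in log space.

    ``tie_lambda`` / ``tie_mu`` share one rate across states (the
    character-independent reductions); ``fix_mu`` pins extinction (e.g. 0 for
    pure birth); ``q_spec`` is ``"ard"`` or ``"er"``.  Failures are reported
    via ``converged=False``.
    """
    k = data.k if hasattr(data, "k") else int(np.max(data)) + 1
    if rho is not None and hasattr(rho, "vector") and hasattr(data, "states"):
        rho = rho.vector(data.states)
    spec = _MusseSpec(k, tie_lambda, tie_mu, fix_mu, q_spec, rho)
    rng = np.random.default_rng(seed)
    lo, hi = np.log(SSE_RATE_MIN), np.log(SSE_RATE_MAX)

    def neg(logtheta):
        try:
            # slightly looser ODE tolerance during the search; the returned
            # optimum is re-evaluated at full precision below
            ll = musse_loglik(tree, data, spec.unpack(np.exp(logtheta)),
                              root=root,
                              condition_on_survival=condition_on_survival,
                              rtol=1e-7, atol=1e-10)
        except RuntimeError:
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    base = _initial_theta(tree, data, spec, rng) if x0 is None else np.log(x0)
    best_x, best_f = None, np.inf
    for r in range(max(1, n_restarts)):
        start = base if r == 0 else np.clip(
            base + rng.normal(0.0, 1.0, size=spec.n_params), lo, hi)
        res = minimize(
            neg, start, method="Nelder-Mead",
            bounds=[(lo, hi)] * spec.n_params,
            options={"maxfev": maxfev or 300 * spec.n_params + 500,
                     "xatol": 1e-6, "fatol": 1e-8,
                     "adaptive": spec.n_params > 6},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    converged = best_x is not None and best_f < 1e11
    params = spec.unpack(np.exp(best_x if best_x is not None
                                else np.full(spec.n_params, np.nan)))
    if converged:
        try:
            loglik = musse_loglik(tree, data, params, root=root,
                                  condition_on_survival=condition_on_survival)
        except RuntimeError:
            loglik, converged = -np.inf, False
    else:
        loglik = -np.inf
    return MusseFit(params=params, loglik=loglik, converged=converged,
                    n_params=spec.n_params)


# ---------------------------------------------------------------------------
# MCMC


@dataclass
class PosteriorSample:
    """Post-burn-in MCMC draws over MuSSE parameters."""

    draws: np.ndarray  # (n_draws, n_params) on the natural scale
    names: list
    loglik: np.ndarray
    acceptance: float
    settings: dict = field(default_factory=dict)
    spec: object = None
    tree_index: int = 0

    def __len__(self):
        return len(self.draws)

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def to_frame(self):
        """Draws as a DataFrame (tree index, iteration, parameters, lnL)."""
        import pandas as pd

        df = pd.DataFrame(self.draws, columns=self.names)
        df.insert(0, "tree_index", self.tree_index)
        df.insert(1, "iteration", np.arange(len(self.draws)))
        df["loglik"] = self.loglik
        return df

    def r_draws(self) -> np.ndarray:
        """Per-state diversification draws r = λ − μ, shape (n_draws, k)."""
        k = self.spec.k
        out = np.empty((len(self.draws), k))
        for n, theta in enumerate(self.draws):
            p = self.spec.unpack(theta)
            out[n] = p.r
        return out


def musse_mcmc(tree, data, rho=None, n_steps: int = 10_000,
               burnin_fraction: float = 0.1, seed=None, prior_mean: float = 1.0,
               tie_lambda=False, tie_mu=False, fix_mu=None, q_spec="ard",
               root="fitzjohn", condition_on_survival=False,
               tree_index: int = 0) -> PosteriorSample:
    """Metropolis–Hastings sampling of MuSSE parameters.

    Random-walk proposals on log parameters, independent Exponential
    (mean ``prior_mean``) priors on the natural scale; the proposal scale is
    adapted toward ~23% acceptance during burn-in only.  Passing
    ``tree=None`` samples the prior alone (the zero-data check).
    """
    if n_steps < 10:
        raise ValueError("n_steps must be >= 10")
    if tree is None:
        k = data.k if hasattr(data, "k") else 2
        spec = _MusseSpec(k, tie_lambda, tie_mu, fix_mu, q_spec, rho)

        def loglik_fn(theta):
            return 0.0
    else:
        k = data.k if hasattr(data, "k") else int(np.max(data)) + 1
        if rho is not None and hasattr(rho, "vector") and hasattr(data, "states"):
            rho = rho.vector(data.states)
        spec = _MusseSpec(k, tie_lambda, tie_mu, fix_mu, q_spec, rho)

        def loglik_fn(theta):
            try:
                return musse_loglik(tree, data, spec.unpack(theta), root=root,
                                    condition_on_survival=condition_on_survival)
            except RuntimeError:
                return -np.inf

    rng = np.random.default_rng(seed)
    rate = 1.0 / prior_mean

    def logpost(x):  # x = log parameters; exp prior + Jacobian
        theta = np.exp(x)
        ll = loglik_fn(theta)
        if not np.isfinite(ll):
            return -np.inf, ll
        return ll + np.sum(np.log(rate) - rate * theta + x), ll

    x = np.log(np.full(spec.n_params, prior_mean))
    lp, ll = logpost(x)
    scale = 0.5
    n_burn = int(burnin_fraction * n_steps)
    draws = np.empty((n_steps, spec.n_params))
    logliks = np.empty(n_steps)
    accepted = 0
    window_acc = 0
    for it in range(n_steps):
        prop = x + rng.normal(0.0, scale, size=spec.n_params)
        lp_new, ll_new = logpost(prop)
        if np.log(rng.uniform()) < lp_new - lp:
            x, lp, ll = prop, lp_new, ll_new
            accepted += 1
            window_acc += 1
        draws[it] = np.exp(x)
        logliks[it] = ll
        if it < n_burn and (it + 1) % 50 == 0:  # adapt during burn-in only
            acc = window_acc / 50.0
            scale *= np.exp(0.5 * (acc - 0.234))
            window_acc = 0
    acc_rate = accepted / n_steps
    return PosteriorSample(
        draws=draws[n_burn:], names=spec.names, loglik=logliks[n_burn:],
        acceptance=acc_rate, spec=spec, tree_index=tree_index,
        settings={"n_steps": n_steps, "burnin": n_burn, "seed": seed,
                  "prior_mean": prior_mean, "final_scale": scale},
    )


# ---------------------------------------------------------------------------
# Posterior summaries and comparisons


def diversification_density(samples, states=None) -> dict:
    """Pooled per-state diversification-rate (r = λ − μ) density summaries.

    ``samples`` is one PosteriorSample or a list (pooled over trees).
    Returns per state: pooled draws, mean, quantiles, and a Gaussian KDE
    evaluated on a regular grid.
    """
    if isinstance(samples, PosteriorSample):
        samples = [samples]
    if not samples:
        raise ValueError("no posterior samples given")
    k = samples[0].spec.k
    pooled = np.vstack([s.r_draws() for s in samples])
    names = list(states) if states is not None else [f"state_{i}" for i in range(k)]
    out = {}
    for i in range(k):
        d = pooled[:, i]
        entry = {
            "draws": d,
            "mean": float(d.mean()),
            "median": float(np.median(d)),
            "q025": float(np.quantile(d, 0.025)),
            "q975": float(np.quantile(d, 0.975)),
        }
        if d.std() > 0 and len(d) > 5:
            kde = stats.gaussian_kde(d)
            grid = np.linspace(d.min(), d.max(), 256)
            entry["kde"] = (grid, kde(grid))
        out[names[i]] = entry
    return out


def compare_rates(draws_i, draws_j):
    """Two-sided Mann–Whitney comparison of two rate-draw samples.

    Exact enumeration for small tie-free samples (n ≤ 8 each), tie-corrected
    normal approximation otherwise; fully tied samples give p = 1.
    Returns ``(U, p)``.
    """
    x = np.asarray(draws_i, float)
    y = np.asarray(draws_j, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Trait-independence (type-1 error) calibration


def trait_independence_test(tree: PhyloTree, q_values, n_sims: int, seed=None,
                            alpha: float = 0.05, n_restarts: int = 1,
                            maxfev: int | None = None, fix_mu=None) -> list:
    """How often do SSE models link diversification to a *neutral* character?

    For each transition rate q: simulate ``n_sims`` neutral binary characters
    on the fixed tree under symmetric Mk(q), fit a character-dependent
    (per-state λ) and a character-independent (tied λ) model, and record the
    fraction of simulations in which the dependent model is preferred by a
    likelihood-ratio test at level ``alpha``.  With ``fix_mu`` unset both
    models free per-state/tied extinction (df = 2); on a pure-birth tree pass
    ``fix_mu=0`` so the reference χ² holds exactly — a free μ whose true
    value sits on the zero boundary makes the test conservative.
    Returns one dict per q with the false-positive rate and a 95% CI.
    """
    from .synth import simulate_mk  # local import to avoid a cycle

    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    _check_tree(tree)
    rng = np.random.default_rng(seed)
    df = 1 if fix_mu is not None else 2
    crit = stats.chi2.ppf(1.0 - alpha, df)
    results = []
    for q in q_values:
        if q <= 0:
            raise ValueError("q values must be > 0")
        Q = np.array([[-q, q], [q, -q]])
        rejections = 0
        tested = 0
        for _ in range(n_sims):
            char = simulate_mk(tree, Q, root_state=int(rng.integers(2)),
                               seed=int(rng.integers(2**31)))
            if len(np.unique(char.state_vector(tree.labels))) < 2:
                # constant character: the dependent model is not identifiable
                # and no dependence can be claimed; count as non-rejection
                tested += 1
                continue
            s = int(rng.integers(2**31))
            indep = fit_musse(tree, char, tie_lambda=True,
                              tie_mu=fix_mu is None, fix_mu=fix_mu,
                              q_spec="ard", seed=s, n_restarts=n_restarts,
                              maxfev=maxfev)
            if not indep.converged:
                continue
            pieces = [np.repeat(indep.params.lam[:1], 2)]
            if fix_mu is None:
                pieces.append(np.repeat(indep.params.mu[:1], 2))
            pieces.append([indep.params.q[0, 1], indep.params.q[1, 0]])
            x0 = np.concatenate(pieces)
            dep = fit_musse(tree, char, fix_mu=fix_mu, q_spec="ard", seed=s,
                            n_restarts=n_restarts, maxfev=maxfev,
                            x0=np.clip(x0, SSE_RATE_MIN, SSE_RATE_MAX))
            if not dep.converged:
                continue
            lrt = max(0.0, 2.0 * (dep.loglik - indep.loglik))
            tested += 1
            if lrt > crit:
                rejections += 1
        ci = stats.binomtest(rejections, max(tested, 1)).proportion_ci()
        results.append({
            "q": float(q), "n_sims": n_sims, "n_tested": tested,
            "rejections": rejections,
            "false_positive_rate": rejections / tested if tested else np.nan,
            "ci_low": float(ci.low), "ci_high": float(ci.high),
        })
    return results
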