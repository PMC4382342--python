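"""Binary-state speciation-extinction (BiSSE) likelihood, ML, LRT and MCMC.

The likelihood propagates, root-ward along every branch, the coupled system

    E_i' = mu_i - (lambda_i + mu_i + q_ij) E_i + lambda_i E_i^2 + q_ij E_j
    D_i' = -(lambda_i + mu_i + q_ij) D_i + q_ij D_j + 2 lambda_i E_i D_i

where ``E_i(t)`` is the probability that a lineage in state ``i`` at time
``t`` before present leaves no sampled descendants and ``D_i`` the density
of the observed subtree.  Tips are initialized with state-specific sampling
fractions ``f_i``: ``D_i = f_i [state = i]`` (a missing state sets
``D_i = f_i`` for both states) and ``E_i = 1 - f_i``.  At internal nodes
``D_i <- D_left,i D_right,i lambda_i`` with running log-renormalization of D
to avoid underflow; at the root states are weighted by their relative D
values by default, and the likelihood is conditioned on survival of the two
crown lineages (both defaults overridable).

The default integrator is a compiled fixed-step RK4 whose step density
scales with the total rate; ``ode="scipy"`` switches to adaptive
``solve_ivp`` integration for validation work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2 as chi2_dist

from shiftscape.phylo_io import TimeTree
from shiftscape.bd_models import ModelFit
from shiftscape import _kernels

__all__ = [
    "BiSSEParams", "SamplingFractions", "MCMCSettings", "bisse_lnl",
    "bisse_ml", "lrt", "bisse_mcmc", "pool_chains", "code_binary_trait",
    "hostplant_family_counts", "compute_sampling_fractions",
]

PARAM_NAMES = ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10")


@dataclass(frozen=True)
class BiSSEParams:
    """State-specific speciation, extinction and transition rates (per My)."""

    lambda0: float
    lambda1: float
    mu0: float
    mu1: float
    q01: float
    q10: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def r0(self) -> float:
        return self.lambda0 - self.mu0

    @property
    def r1(self) -> float:
        return self.lambda1 - self.mu1

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, x) -> "BiSSEParams":
        return cls(*[float(v) for v in x])

    def constrained_equal_lambda(self) -> "BiSSEParams":
        lam = 0.5 * (self.lambda0 + self.lambda1)
        return replace(self, lambda0=lam, lambda1=lam)


@dataclass(frozen=True)
class SamplingFractions:
    """Proportion of extant species of each state present as tips."""

    f0: float = 1.0
    f1: float = 1.0

    def __post_init__(self):
        for f in (self.f0, self.f1):
            if not 0.0 < f <= 1.0:
                raise ValueError("sampling fractions must be in (0, 1]")


def compute_sampling_fractions(tree: TimeTree, traits: Mapping[str, object],
                               richness: Mapping[str, int]
                               ) -> SamplingFractions:
    """f_i = (tips in state i) / (described species whose genus is state i).

    Assumes all species of a terminal share its state; missing-state tips
    enter neither numerator nor denominator.
    """
    k = {0: 0, 1: 0}
    n = {0: 0, 1: 0}
    for lab in tree.labels:
        s = traits.get(lab, None)
        if s in (0, 1):
            k[s] += 1
            n[s] += int(richness.get(lab, 1))
    if n[0] == 0 or n[1] == 0:
        raise ValueError("need at least one tip in each state to derive "
                         "sampling fractions")
    return SamplingFractions(f0=k[0] / n[0], f1=k[1] / n[1])


# ---------------------------------------------------------------------------
# likelihood


def _tree_arrays(tree: TimeTree):
    """(post_internal, left, right, lengths) memoized on the tree."""
    cached = getattr(tree, "_bisse_arrays", None)
    if cached is not None:
        return cached
    if not tree.is_binary():
        raise ValueError("BiSSE requires a binary tree")
    post_internal = np.array([v for v in tree.postorder
                              if not tree.is_tip(v)], dtype=np.int64)
    left = np.full(tree.n_nodes, -1, dtype=np.int64)
    right = np.full(tree.n_nodes, -1, dtype=np.int64)
    for v in range(tree.n_nodes):
        if tree.children[v]:
            left[v], right[v] = tree.children[v]
    lengths = tree.lengths.astype(np.float64)
    tree._bisse_arrays = (post_internal, left, right, lengths)
    return tree._bisse_arrays


def _tip_D(tree: TimeTree, traits: Mapping[str, object],
           sampling: SamplingFractions) -> np.ndarray:
    D = np.zeros((tree.n_tips, 2))
    for i, lab in enumerate(tree.labels):
        s = traits.get(lab, None)
        if s == 0:
            D[i, 0] = sampling.f0
        elif s == 1:
            D[i, 1] = sampling.f1
        elif s is None:
            D[i, 0] = sampling.f0
            D[i, 1] = sampling.f1
        else:
            raise ValueError(f"invalid state {s!r} for tip {lab!r}")
    return D


def _steps_per_unit(params: BiSSEParams, precision: str) -> tuple[float, int]:
    rho = sum(params.as_array()) + 1e-9
    if precision == "high":
        return 8.0 * rho, 24
    if precision == "fast":
        return 2.5 * rho, 8
    raise ValueError(f"unknown precision {precision!r}")


def bisse_lnl(tree: TimeTree, traits: Mapping[str, object],
              params: BiSSEParams,
              sampling: Optional[SamplingFractions] = None,
              root: str = "obs", condition_surv: bool = True,
              ode: str = "rk4", precision: str = "high",
              root_weights: Optional[Sequence[float]] = None) -> float:
    """Log-likelihood of the tree plus tip states under BiSSE.

    ``root`` is "obs" (weight states by relative D, the default), "flat"
    (equal weights) or "given" (explicit ``root_weights``).
    """
    sampling = sampling or SamplingFractions()
    post_internal, left, right, lengths = _tree_arrays(tree)
    tipD = _tip_D(tree, traits, sampling)
    p = params
    if ode == "rk4":
        spu, mins = _steps_per_unit(params, precision)
        E, D, log_comp, n_clamped = _kernels.bisse_prune(
            post_internal, left, right, lengths, tipD,
            1.0 - sampling.f0, 1.0 - sampling.f1,
            p.lambda0, p.lambda1, p.mu0, p.mu1, p.q01, p.q10,
            spu, mins)
    elif ode == "scipy":
        E, D, log_comp, n_clamped = _prune_scipy(
            tree, post_internal, left, right, lengths, tipD, sampling, p)
    else:
        raise ValueError(f"unknown ode backend {ode!r}")
    if not math.isfinite(log_comp):
        return -math.inf

    if root == "obs":
        tot = D[0] + D[1]
        if tot <= 0:
            return -math.inf
        w = D / tot
    elif root == "flat":
        w = np.array([0.5, 0.5])
    elif root == "given":
        w = np.asarray(root_weights, dtype=float)
        if w.shape != (2,) or w.min() < 0 or not np.isclose(w.sum(), 1.0):
            raise ValueError("root_weights must be two non-negative numbers "
                             "summing to 1")
    else:
        raise ValueError(f"unknown root treatment {root!r}")

    like = float(w[0] * D[0] + w[1] * D[1])
    if like <= 0:
        return -math.inf
    out = math.log(like) + log_comp
    if condition_surv:
        lam = np.array([p.lambda0, p.lambda1])
        denom = float(np.sum(w * lam * (1.0 - E) ** 2))
        if denom <= 0:
            return -math.inf
        out -= math.log(denom)
    return out


def _prune_scipy(tree, post_internal, left, right, lengths, tipD, sampling,
                 p: BiSSEParams):
    """Adaptive-integration pruning (validation backend)."""
    from scipy.integrate import solve_ivp

    def deriv(_, y):
        E0, E1, D0, D1 = y
        return [
            p.mu0 - (p.lambda0 + p.mu0 + p.q01) * E0 + p.lambda0 * E0 ** 2
            + p.q01 * E1,
            p.mu1 - (p.lambda1 + p.mu1 + p.q10) * E1 + p.lambda1 * E1 ** 2
            + p.q10 * E0,
            -(p.lambda0 + p.mu0 + p.q01) * D0 + p.q01 * D1
            + 2 * p.lambda0 * E0 * D0,
            -(p.lambda1 + p.mu1 + p.q10) * D1 + p.q10 * D0
            + 2 * p.lambda1 * E1 * D1,
        ]

    def integrate(y0, ln):
        if ln <= 0:
            return np.asarray(y0)
        for rtol in (1e-8, 1e-10):
            sol = solve_ivp(deriv, (0.0, ln), y0, rtol=rtol, atol=1e-12,
                            method="RK45", dense_output=False)
            if sol.success:
                return sol.y[:, -1]
        raise RuntimeError("ODE integration failed at tightened tolerance")

    n = tree.n_nodes
    E = np.zeros((n, 2))
    D = np.zeros((n, 2))
    log_comp = 0.0
    n_clamped = 0
    for v in range(tree.n_tips):
        y0 = [1 - sampling.f0, 1 - sampling.f1, tipD[v, 0], tipD[v, 1]]
        y = integrate(y0, lengths[v])
        E[v], D[v] = y[:2], y[2:]
    root_node = post_internal[-1]
    for v in post_internal:
        l, r = left[v], right[v]
        e = 0.5 * (E[l] + E[r])
        d = np.array([D[l, 0] * D[r, 0] * p.lambda0,
                      D[l, 1] * D[r, 1] * p.lambda1])
        n_clamped += int((d < 0).sum())
        d = np.maximum(d, 0.0)
        s = d.sum()
        if s <= 0:
            return e, d, -math.inf, n_clamped
        d /= s
        log_comp += math.log(s)
        y = np.concatenate([e, d])
        if v != root_node and lengths[v] > 0:
            y = integrate(y, lengths[v])
        E[v], D[v] = y[:2], y[2:]
    return E[root_node], D[root_node], log_comp, n_clamped


# ---------------------------------------------------------------------------
# maximum likelihood and the LRT


def _heuristic_start(tree: TimeTree, sampling: SamplingFractions
                     ) -> BiSSEParams:
    f_bar = 0.5 * (sampling.f0 + sampling.f1)
    n_eff = max(tree.n_tips / f_bar, 3.0)
    r_hat = max(math.log(n_eff / 2.0) / tree.root_age, 1e-3)
    q0 = max(2.0 / max(tree.total_branch_length(), 1e-6), 1e-4)
    return BiSSEParams(lambda0=2.0 * r_hat, lambda1=2.0 * r_hat,
                       mu0=r_hat, mu1=r_hat, q01=q0, q10=q0)


def _pack(params: BiSSEParams, constraint: str) -> np.ndarray:
    x = np.log(np.maximum(params.as_array(), 1e-10))
    if constraint == "equal_lambda":
        lam = math.log(max(0.5 * (params.lambda0 + params.lambda1), 1e-10))
        return np.concatenate([[lam], x[2:]])
    return x


def _unpack(x: np.ndarray, constraint: str) -> BiSSEParams:
    e = np.exp(x)
    if constraint == "equal_lambda":
        return BiSSEParams(e[0], e[0], e[1], e[2], e[3], e[4])
    return BiSSEParams(*e)


def bisse_ml(tree: TimeTree, traits: Mapping[str, object],
             sampling: Optional[SamplingFractions] = None,
             constraint: str = "none", n_restarts: int = 2, seed: int = 0,
             precision: str = "high", start: Optional[BiSSEParams] = None,
             **lnl_kwargs) -> tuple[BiSSEParams, ModelFit]:
    """Bounded multi-start ML fit; k = 6 (full) or 5 (equal speciation)."""
    if constraint not in ("none", "equal_lambda"):
        raise ValueError(f"unknown constraint {constraint!r}")
    sampling = sampling or SamplingFractions()
    rng = np.random.default_rng(seed)
    s0 = start or _heuristic_start(tree, sampling)

    def nll(x):
        val = bisse_lnl(tree, traits, _unpack(x, constraint), sampling,
                        precision=precision, **lnl_kwargs)
        return -val if math.isfinite(val) else 1e12

    starts = [_pack(s0, constraint)]
    alt = replace(s0, lambda1=s0.lambda1 * 2.0, mu1=s0.mu1 * 0.5)
    starts.append(_pack(alt, constraint))
    for _ in range(n_restarts):
        jitter = rng.normal(0.0, 0.7, size=len(starts[0]))
        starts.append(starts[0] + jitter)

    lb, ub = -12.0, 4.0
    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            nll, np.clip(x0, lb + 0.5, ub - 0.5), method="L-BFGS-B",
            bounds=[(lb, ub)] * len(x0),
            options={"maxiter": 300, "ftol": 1e-11})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    params = _unpack(best.x, constraint)
    k = 5 if constraint == "equal_lambda" else 6
    fit = ModelFit(lnL=-float(best.fun), k=k, n_obs=tree.n_tips,
                   converged=converged)
    return params, fit


def lrt(full: ModelFit, constrained: ModelFit,
        tol: float = 1e-6) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (chi2, df, p).

    chi2 = 2 (lnL_full - lnL_constrained); a materially negative chi2
    signals an optimization failure upstream and raises.
    """
    if full.k <= constrained.k:
        raise ValueError("the full model must have more parameters")
    chi2 = 2.0 * (full.lnL - constrained.lnL)
    if chi2 < -tol * max(1.0, abs(full.lnL)):
        raise RuntimeError(
            f"negative LRT statistic ({chi2:.4g}): the constrained fit "
            f"beat the full fit; rerun the optimizations")
    chi2 = max(chi2, 0.0)
    df = full.k - constrained.k
    p = float(chi2_dist.sf(chi2, df))
    return chi2, df, p


# ---------------------------------------------------------------------------
# MCMC


@dataclass
class MCMCSettings:
    """Slice-sampling MCMC settings (defaults follow the study protocol:
    10000 generations, first 7500 discarded as burnin)."""

    steps: int = 10000
    burnin: int = 7500
    seed: int = 0
    prior_mean: Optional[float] = None     # None: 2 * crude net-div estimate
    slice_w: Optional[float] = None        # None: prior mean
    init: Optional[BiSSEParams] = None
    precision: str = "high"

    def __post_init__(self):
        if not 0 <= self.burnin < self.steps:
            raise ValueError("require 0 <= burnin < steps")


def bisse_mcmc(tree: TimeTree, traits: Mapping[str, object],
               sampling: Optional[SamplingFractions] = None,
               settings: Optional[MCMCSettings] = None,
               **lnl_kwargs) -> pd.DataFrame:
    """Posterior sample of the six BiSSE rates by univariate slice sampling.

    Exponential prior on each rate with a common mean (default twice a crude
    whole-tree net diversification estimate).  Returns a DataFrame with one
    row per generation: step, lnpost, the six rates and the derived r0, r1.
    The chain is fully determined by ``settings.seed``.
    """
    settings = settings or MCMCSettings()
    sampling = sampling or SamplingFractions()
    rng = np.random.default_rng(settings.seed)
    r_hat = max(math.log(max(tree.n_tips, 3) / 2.0) / tree.root_age, 1e-3)
    prior_mean = settings.prior_mean or 2.0 * r_hat
    w = settings.slice_w or prior_mean
    x = (settings.init or _heuristic_start(tree, sampling)).as_array()

    def logpost(vec):
        if np.any(vec < 0):
            return -math.inf
        ll = bisse_lnl(tree, traits, BiSSEParams.from_array(vec), sampling,
                       precision=settings.precision, **lnl_kwargs)
        if not math.isfinite(ll):
            return -math.inf
        return ll - float(np.sum(vec)) / prior_mean

    lp = logpost(x)
    if not math.isfinite(lp):
        raise RuntimeError("MCMC initial state has non-finite posterior; "
                           f"state: {x}")
    rows = np.empty((settings.steps, 8))
    for step in range(settings.steps):
        for j in range(6):
            x, lp = _slice_update(x, j, lp, logpost, w, rng)
        if not math.isfinite(lp):
            raise RuntimeError(f"chain diverged at step {step}; state: {x}")
        rows[step, 0] = lp
        rows[step, 1:7] = x
        rows[step, 7] = step
    df = pd.DataFrame(rows[:, 1:7], columns=list(PARAM_NAMES))
    df.insert(0, "step", np.arange(settings.steps))
    df.insert(1, "lnpost", rows[:, 0])
    df["r0"] = df["lambda0"] - df["mu0"]
    df["r1"] = df["lambda1"] - df["mu1"]
    df.attrs["burnin"] = settings.burnin
    return df


def _slice_update(x, j, lp, logpost, w, rng, max_steps: int = 30):
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    y = lp + math.log(rng.random())
    x0 = x[j]
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if lo <= 0:
            lo = 0.0
            break
        t = x.copy()
        t[j] = lo
        if logpost(t) < y:
            break
        lo -= w
    lo = max(lo, 0.0)
    for _ in range(max_steps):
        t = x.copy()
        t[j] = hi
        if logpost(t) < y:
            break
        hi += w
    while True:
        xj = lo + (hi - lo) * rng.random()
        t = x.copy()
        t[j] = xj
        lp_new = logpost(t)
        if lp_new >= y:
            return t, lp_new
        if xj < x0:
            lo = xj
        else:
            hi = xj
        if hi - lo < 1e-14:
            return x, lp


def pool_chains(chains: Sequence[pd.DataFrame],
                burnin: Optional[int] = None,
                tree_indices: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """Concatenate post-burnin draws from several chains.

    Provenance (the source tree index) is retained per draw in a ``tree``
    column.  All chains must share the same parameterization.
    """
    if not chains:
        raise ValueError("no chains to pool")
    cols = list(chains[0].columns)
    for c in chains[1:]:
        if list(c.columns) != cols:
            raise ValueError("chains have mismatched parameterizations")
    idx = list(tree_indices) if tree_indices is not None else list(
        range(len(chains)))
    if len(idx) != len(chains):
        raise ValueError("tree_indices length must match chains")
    parts = []
    for i, c in zip(idx, chains):
        b = burnin if burnin is not None else c.attrs.get("burnin", 0)
        part = c.iloc[b:].copy()
        part["tree"] = i
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# trait coding from hostplant records


def code_binary_trait(records: pd.DataFrame, target_family: str,
                      recode_to_zero: Sequence[str] = ()) -> dict:
    """Binary hostplant-use coding from a records table.

    A genus is state 1 iff any record links it to ``target_family``; genera
    with records but no such link are 0; genera absent from the table are
    simply absent (missing).  ``recode_to_zero`` flips listed genera to 0
    (sensitivity re-coding for dubious records).
    """
    if len(records) == 0:
        raise ValueError("empty hostplant record table")
    fam = records["plant_family"].astype(str).str.strip()
    genus = records["butterfly_genus"].astype(str).str.strip()
    users = set(genus[fam == target_family])
    out = {g: (1 if g in users else 0) for g in sorted(set(genus))}
    for g in recode_to_zero:
        if g in out:
            out[g] = 0
    return out


def hostplant_family_counts(records: pd.DataFrame) -> dict:
    """Record/genus bookkeeping: total records, genera using exactly one
    versus more than one plant family, distinct plant families."""
    genus = records["butterfly_genus"].astype(str).str.strip()
    fam = records["plant_family"].astype(str).str.strip()
    per_genus = pd.crosstab(genus, fam).gt(0).sum(axis=1)
    return {
        "n_records": int(len(records)),
        "n_genera": int(per_genus.size),
        "n_plant_families": int(fam.nunique()),
        "n_single_family": int((per_genus == 1).sum()),
        "n_multi_family": int((per_genus > 1).sum()),
    }
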