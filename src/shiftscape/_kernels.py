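"""Compiled numerical kernels (numba).

Two hot loops live here: the BiSSE pruning likelihood (fixed-step RK4 over
every branch) and the forward count-only birth-death simulator used as a
distributional oracle for the clade-size law.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _bisse_deriv(y, la0, la1, mu0, mu1, q01, q10, out):
    E0, E1, D0, D1 = y[0], y[1], y[2], y[3]
    out[0] = mu0 - (la0 + mu0 + q01) * E0 + la0 * E0 * E0 + q01 * E1
    out[1] = mu1 - (la1 + mu1 + q10) * E1 + la1 * E1 * E1 + q10 * E0
    out[2] = -(la0 + mu0 + q01) * D0 + q01 * D1 + 2.0 * la0 * E0 * D0
    out[3] = -(la1 + mu1 + q10) * D1 + q10 * D0 + 2.0 * la1 * E1 * D1


@njit(cache=False)
def _rk4_branch(y, length, n_steps, la0, la1, mu0, mu1, q01, q10):
    h = length / n_steps
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    tmp = np.empty(4)
    for _ in range(n_steps):
        _bisse_deriv(y, la0, la1, mu0, mu1, q01, q10, k1)
        for i in range(4):
            tmp[i] = y[i] + 0.5 * h * k1[i]
        _bisse_deriv(tmp, la0, la1, mu0, mu1, q01, q10, k2)
        for i in range(4):
            tmp[i] = y[i] + 0.5 * h * k2[i]
        _bisse_deriv(tmp, la0, la1, mu0, mu1, q01, q10, k3)
        for i in range(4):
            tmp[i] = y[i] + h * k3[i]
        _bisse_deriv(tmp, la0, la1, mu0, mu1, q01, q10, k4)
        for i in range(4):
            y[i] = y[i] + (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
    return y


@njit(cache=False)
def bisse_prune(post_internal, left, right, lengths, tip_D, e0_init, e1_init,
                la0, la1, mu0, mu1, q01, q10, steps_per_unit, min_steps):
    """Post-order BiSSE pruning with per-node D renormalization.

    Parameters are flat arrays indexed by node id (tips first).  Returns
    (E_root[2], D_root[2], log_comp, n_neg_clamped).
    ``post_internal`` lists internal nodes in child-before-parent order;
    ``left``/``right`` index their children; ``lengths[v]`` is the branch
    above node v.  ``tip_D`` is (n_tips, 2).
    """
    n_nodes = lengths.shape[0]
    n_tips = tip_D.shape[0]
    E = np.empty((n_nodes, 2))
    D = np.empty((n_nodes, 2))
    log_comp = 0.0
    n_clamped = 0

    y = np.empty(4)
    # tip branches
    for v in range(n_tips):
        y[0] = e0_init
        y[1] = e1_init
        y[2] = tip_D[v, 0]
        y[3] = tip_D[v, 1]
        ln = lengths[v]
        if ln > 0.0:
            ns = int(ln * steps_per_unit) + 1
            if ns < min_steps:
                ns = min_steps
            _rk4_branch(y, ln, ns, la0, la1, mu0, mu1, q01, q10)
        E[v, 0], E[v, 1] = y[0], y[1]
        D[v, 0], D[v, 1] = y[2], y[3]

    root = post_internal[post_internal.shape[0] - 1]
    for idx in range(post_internal.shape[0]):
        v = post_internal[idx]
        l = left[v]
        r = right[v]
        e0 = 0.5 * (E[l, 0] + E[r, 0])
        e1 = 0.5 * (E[l, 1] + E[r, 1])
        d0 = D[l, 0] * D[r, 0] * la0
        d1 = D[l, 1] * D[r, 1] * la1
        if d0 < 0.0:
            d0 = 0.0
            n_clamped += 1
        if d1 < 0.0:
            d1 = 0.0
            n_clamped += 1
        s = d0 + d1
        if s > 0.0:
            d0 /= s
            d1 /= s
            log_comp += np.log(s)
        else:
            return (np.array([e0, e1]), np.array([d0, d1]), -np.inf, n_clamped)
        y[0], y[1], y[2], y[3] = e0, e1, d0, d1
        ln = lengths[v]
        if v != root and ln > 0.0:
            ns = int(ln * steps_per_unit) + 1
            if ns < min_steps:
                ns = min_steps
            _rk4_branch(y, ln, ns, la0, la1, mu0, mu1, q01, q10)
        E[v, 0], E[v, 1] = y[0], y[1]
        D[v, 0], D[v, 1] = y[2], y[3]

    return (np.array([E[root, 0], E[root, 1]]),
            np.array([D[root, 0], D[root, 1]]), log_comp, n_clamped)


@njit(cache=False)
def simulate_clade_sizes(b, d, t_stop, n_reps, seed):
    """Forward linear birth-death counts N(t_stop) from one lineage, per rep."""
    np.random.seed(seed)
    out = np.empty(n_reps, dtype=np.int64)
    for rep in range(n_reps):
        n = 1
        t = 0.0
        while n > 0:
            rate = n * (b + d)
            t += np.random.exponential(1.0 / rate)
            if t >= t_stop:
                break
            if np.random.random() < b / (b + d):
                n += 1
            else:
                n -= 1
        out[rep] = n
    return out


# ---------------------------------------------------------------------------
# piecewise birth-death piece likelihood (mirrors shiftscape.bd_models math)


@njit(cache=False)
def _log_dr_scalar(b, d, t):
    r = b - d
    if abs(r) < 1e-12 * b:
        return np.log1p(b * t)
    c = b / r
    if r > 0.0:
        return r * t + np.log(c - (c - 1.0) * np.exp(-r * t))
    return np.log1p(c * np.expm1(r * t))


@njit(cache=False)
def _log_beta_scalar(b, d, t):
    r = b - d
    if abs(r) < 1e-12 * b:
        return np.log(b * t) - np.log1p(b * t)
    c = b / r
    if r > 0.0:
        num = np.log(c) + r * t + np.log(-np.expm1(-r * t))
    else:
        num = np.log(c * np.expm1(r * t))
    return num - _log_dr_scalar(b, d, t)


@njit(cache=False)
def bd_piece_lnl(branch_top, branch_bot, n_internal, tip_stem, tip_rich,
                 n_condition, root_age, b, d):
    """Piece log-likelihood: branch psi factors + b per owned branching
    event + one crown-daughter survival conditioning factor per
    ``n_condition`` + geometric richness terms."""
    r = b - d
    total = n_internal * np.log(b)
    for i in range(branch_top.shape[0]):
        s = branch_bot[i]
        t = branch_top[i]
        total += r * (t - s) + 2.0 * (_log_dr_scalar(b, d, s)
                                      - _log_dr_scalar(b, d, t))
    if n_condition > 0.0:
        total -= n_condition * (r * root_age - _log_dr_scalar(b, d, root_age))
    for i in range(tip_stem.shape[0]):
        # stem survival (1 - alpha) times conditional geometric law
        total += r * tip_stem[i] - 2.0 * _log_dr_scalar(b, d, tip_stem[i])
        if tip_rich[i] > 1:
            total += (tip_rich[i] - 1.0) * _log_beta_scalar(b, d, tip_stem[i])
    if not np.isfinite(total):
        return -1e10
    if total < -1e10:
        return -1e10
    return total


@njit(cache=False)
def _piece_nll(x0, x1, bt, bb, n_int, ts, tn, cond, ra):
    # bounds on log b, log d plus a relative-extinction guard (eps <= e^3):
    # the conditioned likelihood is only meaningful far from the d >> b
    # degeneracy, which carries no support from any real or simulated tree
    if x0 < -14.0 or x0 > 7.0 or x1 < -16.0 or x1 > 7.0 or x1 > x0 + 3.0:
        return 1e12 + x0 * x0 + x1 * x1
    return -bd_piece_lnl(bt, bb, n_int, ts, tn, cond, ra,
                         np.exp(x0), np.exp(x1))


@njit(cache=False)
def bd_fit_nm(start0, start1, bt, bb, n_int, ts, tn, cond, ra,
              maxiter, ftol):
    """Nelder-Mead over (log b, log d) for one piece; returns (x0, x1, f)."""
    xs = np.empty((3, 2))
    fs = np.empty(3)
    xs[0, 0], xs[0, 1] = start0, start1
    xs[1, 0], xs[1, 1] = start0 + 0.5, start1
    xs[2, 0], xs[2, 1] = start0, start1 + 0.5
    for i in range(3):
        fs[i] = _piece_nll(xs[i, 0], xs[i, 1], bt, bb, n_int, ts, tn, cond, ra)
    for _ in range(maxiter):
        order = np.argsort(fs)
        xs = xs[order]
        fs = fs[order]
        if fs[2] - fs[0] < ftol and (abs(xs[2, 0] - xs[0, 0])
                                     + abs(xs[2, 1] - xs[0, 1])) < 1e-9:
            break
        c0 = 0.5 * (xs[0, 0] + xs[1, 0])
        c1 = 0.5 * (xs[0, 1] + xs[1, 1])
        r0 = c0 + (c0 - xs[2, 0])
        r1 = c1 + (c1 - xs[2, 1])
        fr = _piece_nll(r0, r1, bt, bb, n_int, ts, tn, cond, ra)
        if fr < fs[0]:
            e0 = c0 + 2.0 * (c0 - xs[2, 0])
            e1 = c1 + 2.0 * (c1 - xs[2, 1])
            fe = _piece_nll(e0, e1, bt, bb, n_int, ts, tn, cond, ra)
            if fe < fr:
                xs[2, 0], xs[2, 1], fs[2] = e0, e1, fe
            else:
                xs[2, 0], xs[2, 1], fs[2] = r0, r1, fr
        elif fr < fs[1]:
            xs[2, 0], xs[2, 1], fs[2] = r0, r1, fr
        else:
            if fr < fs[2]:
                k0 = c0 + 0.5 * (r0 - c0)
                k1 = c1 + 0.5 * (r1 - c1)
            else:
                k0 = c0 + 0.5 * (xs[2, 0] - c0)
                k1 = c1 + 0.5 * (xs[2, 1] - c1)
            fk = _piece_nll(k0, k1, bt, bb, n_int, ts, tn, cond, ra)
            if fk < min(fr, fs[2]):
                xs[2, 0], xs[2, 1], fs[2] = k0, k1, fk
            else:
                for i in (1, 2):
                    xs[i, 0] = xs[0, 0] + 0.5 * (xs[i, 0] - xs[0, 0])
                    xs[i, 1] = xs[0, 1] + 0.5 * (xs[i, 1] - xs[0, 1])
                    fs[i] = _piece_nll(xs[i, 0], xs[i, 1], bt, bb, n_int,
                                       ts, tn, cond, ra)
    order = np.argsort(fs)
    return xs[order[0], 0], xs[order[0], 1], fs[order[0]]


@njit(cache=False)
def _yule_nll(x0, bt, bb, n_int, ts, tn, cond, ra):
    if x0 < -14.0 or x0 > 7.0:
        return 1e12 + x0 * x0
    return -bd_piece_lnl(bt, bb, n_int, ts, tn, cond, ra, np.exp(x0), 0.0)


@njit(cache=False)
def yule_fit_golden(bt, bb, n_int, ts, tn, cond, ra, lo, hi):
    """Golden-section minimum of the yule (d = 0) negative log-likelihood
    over log b in [lo, hi]; returns (log_b, f)."""
    invphi = 0.6180339887498949
    a, b_ = lo, hi
    c = b_ - invphi * (b_ - a)
    d_ = a + invphi * (b_ - a)
    fc = _yule_nll(c, bt, bb, n_int, ts, tn, cond, ra)
    fd = _yule_nll(d_, bt, bb, n_int, ts, tn, cond, ra)
    for _ in range(120):
        if b_ - a < 1e-11:
            break
        if fc < fd:
            b_, d_, fd = d_, c, fc
            c = b_ - invphi * (b_ - a)
            fc = _yule_nll(c, bt, bb, n_int, ts, tn, cond, ra)
        else:
            a, c, fc = c, d_, fd
            d_ = a + invphi * (b_ - a)
            fd = _yule_nll(d_, bt, bb, n_int, ts, tn, cond, ra)
    if fc < fd:
        return c, fc
    return d_, fd
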