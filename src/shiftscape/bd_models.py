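"""Constant-rate birth-death likelihoods, the unresolved-clade richness law,
and piecewise composition with AIC/AICc scoring.

Model
-----
Within a rate regime ("piece") lineages speciate at rate ``b`` and go extinct
at rate ``d`` (per lineage per My), with net diversification ``r = b - d``
and relative extinction ``epsilon = d / b``.  The resolved part of a piece is
scored with the reconstructed-process pruning density: every *internal*
branch spanning ages ``(s, t)`` (s younger) contributes a factor

    psi(s, t) = exp(r (t - s)) * ((b e^{r s} - d) / (b e^{r t} - d))^2,

every branching event owned by the piece contributes ``b``, and every
terminal lineage contributes its survival probability ``1 - alpha`` from its
stem age.  A terminal standing for an unresolved clade of ``n`` extant
species with stem age ``t`` additionally contributes the conditional
geometric clade-size law

    Pr(N = n | survival) = (1 - beta) beta^{n-1},
    beta = b (e^{r t} - 1) / (b e^{r t} - d),

which sums to one over n >= 1 and collapses to the Yule law as d -> 0.  The
product of the survival factor and the conditional law is the unconditional
Kendall probability ``(1 - alpha)(1 - beta) beta^{n-1}`` of observing ``n``
species from a stem lineage; at ``n = 1`` it equals the pendant-branch
factor ``psi(0, t)``, so for a fully resolved tree the piece likelihood is
exactly the classic (Nee et al.) branching-times birth-death likelihood up
to a labelling constant.  Pieces are independent, so a piecewise model's
likelihood decomposes over pieces.  For a whole-tree (single piece) fit an
optional conditioning on both crown lineages surviving to the present is
available (``n_condition`` on :class:`TreePiece`); multi-piece searches run
unconditioned, where every per-piece term stays bounded.

All formulas are continued through r = 0 and r < 0 (d > b); ``b e^{r t} - d``
is evaluated as ``r * (1 + (b/r) expm1(r t))``, whose second factor is
positive for every admissible parameter setting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from shiftscape.phylo_io import TimeTree, CladeKey

__all__ = [
    "PieceRates", "ModelFit", "TreePiece", "resolved_lnl", "clade_size_lnl",
    "piece_lnl", "piecewise_lnl", "fit_piece", "assign_pieces", "build_piece",
    "aic", "aicc", "geometric_alpha_beta",
]

LNL_FLOOR = -1e10      # numerical floor; contributions below this are clamped
_R_TINY = 1e-12        # |r| below this (relative to b) uses the r -> 0 limit


@dataclass(frozen=True)
class PieceRates:
    """Rates of one birth-death piece.

    ``flavor`` is "yule" (pure birth, d = 0) or "bd".  ``epsilon`` may exceed
    1 for bd pieces (d > b, negative net diversification).
    """

    b: float
    d: float = 0.0
    flavor: str = "bd"

    def __post_init__(self):
        if not (self.b > 0):
            raise ValueError(f"speciation rate must be positive, got {self.b}")
        if self.d < 0:
            raise ValueError(f"extinction rate must be >= 0, got {self.d}")
        if self.flavor not in ("yule", "bd"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if self.flavor == "yule" and self.d != 0:
            raise ValueError("yule flavor requires d = 0")

    @property
    def r(self) -> float:
        return self.b - self.d

    @property
    def epsilon(self) -> float:
        return self.d / self.b

    @property
    def n_params(self) -> int:
        return 1 if self.flavor == "yule" else 2

    def to_dict(self) -> dict:
        return {"b": self.b, "d": self.d, "r": self.r,
                "epsilon": self.epsilon, "flavor": self.flavor}


# ---------------------------------------------------------------------------
# elementary quantities


def _log_dr(b: float, d: float, t):
    """log[(b e^{r t} - d) / r], continued through r = 0; overflow-safe.

    The argument (b e^{rt} - d)/r is positive for every b > 0, d >= 0,
    t >= 0, whatever the sign of r.
    """
    r = b - d
    t = np.asarray(t, dtype=float)
    if abs(r) < _R_TINY * b:
        return np.log1p(b * t)
    c = b / r
    if r > 0:
        # Dr = c e^{rt} - (c - 1); factor out e^{rt}
        return r * t + np.log(c - (c - 1.0) * np.exp(-r * t))
    # r < 0: e^{rt} <= 1, direct evaluation cannot overflow
    return np.log1p(c * np.expm1(r * t))


def _log_beta(b: float, d: float, t):
    """log of the geometric parameter beta(t); -inf at t = 0."""
    r = b - d
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        if abs(r) < _R_TINY * b:
            return np.log(b * t) - np.log1p(b * t)
        c = b / r
        if r > 0:
            # beta = c(e^{rt} - 1)/Dr; log(e^{rt}-1) = rt + log(1 - e^{-rt})
            num = math.log(c) + r * t + np.log(-np.expm1(-r * t))
        else:
            num = np.log(c * np.expm1(r * t))
        return num - _log_dr(b, d, t)


def geometric_alpha_beta(b: float, d: float, t):
    """(alpha, beta) of the clade-size law at stem age t.

    alpha is the extinction probability of the stem lineage, beta the
    geometric parameter; alpha = beta * (d/b).
    """
    if t < 0:
        raise ValueError("stem age must be >= 0")
    beta = float(np.exp(_log_beta(b, d, t))) if t > 0 else 0.0
    beta = min(beta, 1.0 - 1e-16)
    alpha = min(beta * (d / b), 1.0 - 1e-16)   # -> 1 only in the t -> inf limit
    return alpha, beta


def _clade_size_terms(b: float, d: float, stem_age, n):
    """Vectorized log Pr(N = n | survival); arrays stem_age, n align."""
    stem_age = np.asarray(stem_age, dtype=float)
    n = np.asarray(n, dtype=np.int64)
    out = -_log_dr(b, d, stem_age)              # log(1 - beta)
    multi = n > 1
    if np.any(multi):
        lb = _log_beta(b, d, stem_age[multi])
        out = np.array(out, dtype=float)
        out[multi] = out[multi] + (n[multi] - 1) * lb
    return out


def clade_size_lnl(stem_age: float, n: int, rates: PieceRates) -> float:
    """log Pr(N(stem_age) = n | survival) under the geometric clade-size law."""
    if n < 1:
        raise ValueError("unresolved clades represent >= 1 extant species")
    if stem_age <= 0:
        raise ValueError("stem age must be positive")
    out = float(_clade_size_terms(rates.b, rates.d, [stem_age], [n])[0])
    return max(out, LNL_FLOOR) if math.isfinite(out) else LNL_FLOOR


def _log_psi(b: float, d: float, bot, top):
    """Per-branch log factor of the reconstructed-process density."""
    r = b - d
    return r * (np.asarray(top) - np.asarray(bot)) + 2.0 * (
        _log_dr(b, d, bot) - _log_dr(b, d, top))


def _log_survival(b: float, d: float, t: float) -> float:
    """log Pr(a lineage of age t has extant descendants) = log(1 - alpha)."""
    r = b - d
    return r * t - float(_log_dr(b, d, t))


# ---------------------------------------------------------------------------
# pieces


@dataclass
class TreePiece:
    """Branches, branching events and unresolved tips of one rate regime.

    ``branch_top``/``branch_bot`` are parent-end / child-end ages of the
    piece's *internal* branches (child end is a branching event; each also
    contributes one factor of ``b``, counted by ``n_internal``).
    ``tip_stem_age``/``tip_richness`` describe the piece's terminal lineages:
    each contributes its survival probability from the stem age (in
    :func:`resolved_lnl`) and its conditional clade-size probability (in
    :func:`piece_lnl`).

    ``n_condition`` counts crown-daughter survival factors charged to the
    piece: the model conditions on both root daughter lineages surviving to
    the present, and each factor is paid by the piece that owns that
    daughter's branch (so the factors still partition across pieces and the
    likelihood stays decomposable).
    """

    branch_top: np.ndarray
    branch_bot: np.ndarray
    n_internal: int
    tip_stem_age: np.ndarray
    tip_richness: np.ndarray
    n_condition: int = 0
    root_age: float = 0.0

    def __post_init__(self):
        self.branch_top = np.asarray(self.branch_top, dtype=float)
        self.branch_bot = np.asarray(self.branch_bot, dtype=float)
        self.tip_stem_age = np.asarray(self.tip_stem_age, dtype=float)
        self.tip_richness = np.asarray(self.tip_richness, dtype=np.int64)

    @property
    def n_branches(self) -> int:
        return len(self.branch_top)

    @property
    def n_tips(self) -> int:
        return len(self.tip_richness)

    def is_degenerate(self) -> bool:
        """True when there is nothing to fit (no events, no richness signal)."""
        return self.n_internal == 0 and self.n_tips == 0 and self.n_branches == 0

    def total_time(self) -> float:
        """Total lineage-time subtended by the piece (branches + stems)."""
        return float(np.sum(self.branch_top - self.branch_bot)
                     + np.sum(self.tip_stem_age))


def resolved_lnl(piece: TreePiece, rates: PieceRates) -> float:
    """Log-likelihood of the piece's resolved part: internal-branch psi
    factors, one ``b`` per owned branching event, and the survival
    probability of each terminal lineage from its stem age."""
    b, d = rates.b, rates.d
    r = b - d
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        out = float(np.sum(_log_psi(b, d, piece.branch_bot, piece.branch_top)))
        out += piece.n_internal * math.log(b)
        if piece.n_tips:
            out += float(np.sum(r * piece.tip_stem_age
                                - _log_dr(b, d, piece.tip_stem_age)))
        if piece.n_condition:
            out -= piece.n_condition * _log_survival(b, d, piece.root_age)
    if not math.isfinite(out):
        return -math.inf
    return max(out, LNL_FLOOR)


def piece_lnl(piece: TreePiece, rates: PieceRates) -> float:
    """Resolved plus unresolved-tip log-likelihood of one piece."""
    out = resolved_lnl(piece, rates)
    if piece.n_tips:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            out += float(np.sum(_clade_size_terms(
                rates.b, rates.d, piece.tip_stem_age, piece.tip_richness)))
    if not math.isfinite(out):
        return -math.inf
    return max(out, LNL_FLOOR)


# ---------------------------------------------------------------------------
# piece assignment on a tree


def assign_pieces(tree: TimeTree, shift_nodes: Sequence[int],
                  convention: str = "stem") -> np.ndarray:
    """Piece index per branch (indexed by child node); 0 is the background.

    Shift ``i`` (node ``shift_nodes[i]``) owns piece ``i + 1``.  Under the
    "stem" convention a shift claims the branch subtending its node plus the
    subtree; under "node" the subtree only.  Nested shifts carve their region
    out of the enclosing piece.
    """
    if convention not in ("stem", "node"):
        raise ValueError(f"unknown cut convention {convention!r}")
    if len(set(shift_nodes)) != len(shift_nodes):
        raise ValueError("shift nodes must be distinct")
    if tree.root in shift_nodes:
        raise ValueError("the root cannot be a shift node")
    shift_of = {int(v): i + 1 for i, v in enumerate(shift_nodes)}
    piece = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in tree.postorder[::-1]:      # preorder
        p = tree.parent[v]
        if p < 0:
            piece[v] = 0
            continue
        if convention == "stem":
            piece[v] = shift_of.get(int(v), piece[p])
        else:
            piece[v] = shift_of.get(int(p), piece[p])
    return piece


def build_piece(tree: TimeTree, richness: Mapping[str, int],
                assignment: np.ndarray, piece_id: int,
                condition_crown: bool = False) -> TreePiece:
    """Extract one piece's branch/tip data from a tree under an assignment.

    With ``condition_crown`` the piece pays one survival factor per crown
    daughter branch it owns.  This is the classic conditioning for a
    single-piece (whole tree) fit; for multi-piece models it is an
    approximation that can reward absurd d >> b rate settings in pieces
    hollowed out by nested shifts, so piecewise searches leave it off.
    """
    nodes = [v for v in range(tree.n_nodes)
             if v != tree.root and assignment[v] == piece_id]
    n_cond = sum(1 for v in tree.children[tree.root]
                 if assignment[v] == piece_id) if condition_crown else 0
    return piece_from_nodes(tree, richness, nodes, n_condition=n_cond)


def piece_from_nodes(tree: TimeTree, richness: Mapping[str, int],
                     nodes: Iterable[int], n_condition: int = 0) -> TreePiece:
    """TreePiece from an explicit branch-node set (branch = child-end node)."""
    nodes = sorted(int(v) for v in nodes)
    internal = [v for v in nodes if not tree.is_tip(v)]
    tips = [v for v in nodes if tree.is_tip(v)]
    return TreePiece(
        branch_top=np.array([float(tree.ages[tree.parent[v]])
                             for v in internal]),
        branch_bot=np.array([float(tree.ages[v]) for v in internal]),
        n_internal=len(internal),
        tip_stem_age=np.array([float(tree.ages[tree.parent[v]])
                               for v in tips]),
        tip_richness=np.array([int(richness[tree.labels[v]]) for v in tips],
                              dtype=np.int64),
        n_condition=n_condition, root_age=tree.root_age)


def piecewise_lnl(tree: TimeTree, richness: Mapping[str, int],
                  shifts: Sequence[tuple], background: PieceRates,
                  convention: str = "stem",
                  condition_crown: bool = False) -> float:
    """Total log-likelihood of a piecewise model.

    ``shifts`` is a sequence of ``(CladeKey, PieceRates)``; each shift is
    placed at the MRCA of its clade key.  The total is the sum of independent
    per-piece contributions.
    """
    if not tree.is_binary():
        raise ValueError("the birth-death likelihood requires a binary tree")
    nodes = [tree.mrca(key) for key, _ in shifts]
    assignment = assign_pieces(tree, nodes, convention)
    rates = [background] + [r for _, r in shifts]
    total = 0.0
    for pid, rt in enumerate(rates):
        total += piece_lnl(
            build_piece(tree, richness, assignment, pid, condition_crown), rt)
    return total


# ---------------------------------------------------------------------------
# information criteria


def aic(lnl: float, k: int) -> float:
    return -2.0 * lnl + 2.0 * k


def aicc(lnl: float, k: int, n_obs: int) -> float:
    """AIC with the small-sample correction; +inf when n_obs <= k + 1."""
    if n_obs <= k + 1:
        return math.inf
    return aic(lnl, k) + 2.0 * k * (k + 1) / (n_obs - k - 1)


@dataclass
class ModelFit:
    """A scored model: log-likelihood, parameter count and AIC/AICc."""

    lnL: float
    k: int
    n_obs: int
    converged: bool = True

    @property
    def AIC(self) -> float:
        return aic(self.lnL, self.k)

    @property
    def AICc(self) -> float:
        return aicc(self.lnL, self.k, self.n_obs)

    def to_dict(self) -> dict:
        return {"lnL": self.lnL, "k": self.k, "n_obs": self.n_obs,
                "AIC": self.AIC, "AICc": self.AICc, "converged": self.converged}


# ---------------------------------------------------------------------------
# maximum-likelihood fitting of one piece


def _initial_b(piece: TreePiece) -> float:
    """Crude Yule-style start: events / subtended time, floored away from 0."""
    events = piece.n_internal + max(
        int(np.sum(np.log(np.maximum(piece.tip_richness, 1)))), 0)
    total_time = float(np.sum(piece.branch_top - piece.branch_bot))
    total_time += float(np.sum(piece.tip_stem_age))
    if total_time <= 0:
        return 0.1
    return max(events, 1) / total_time


def fit_piece(piece: TreePiece, flavor: str = "bd",
              n_restarts: int = 2, seed: int = 0) -> tuple[PieceRates, float]:
    """ML rates of one piece by bounded numeric optimization.

    The yule flavor optimizes ``log b`` alone; bd optimizes ``(log b, log d)``
    so that d > b (negative net diversification) stays reachable.  Restarts
    jitter the starting point; non-convergence returns the best value found.
    """
    if piece.is_degenerate():
        raise ValueError("cannot fit a degenerate (empty) piece")
    b0 = _initial_b(piece)
    lb, ub = -14.0, 7.0

    from shiftscape import _kernels
    bt, bb = piece.branch_top, piece.branch_bot
    ts, tn = piece.tip_stem_age, piece.tip_richness
    cond, ra = float(piece.n_condition), float(piece.root_age)

    args = (bt, bb, float(piece.n_internal), ts, tn, cond, ra)

    if flavor == "yule":
        x, f = _kernels.yule_fit_golden(*args, lb, ub)
        return PieceRates(b=math.exp(x), flavor="yule"), -float(f)

    if flavor != "bd":
        raise ValueError(f"unknown flavor {flavor!r}")

    rng = np.random.default_rng(seed)
    lb0 = math.log(b0)
    starts = [
        (lb0, lb0 - 2.0),
        (lb0 + 0.7, lb0 + 0.3),       # d close to / above b
    ]
    for _ in range(n_restarts):
        starts.append((lb0 + rng.normal(0, 1.5), lb0 + rng.normal(-1, 2.0)))
    best = (math.inf, 0.0, 0.0)
    for x0, x1 in starts:
        x0 = min(max(x0, lb + 0.5), ub - 0.5)
        x1 = min(max(x1, lb + 0.5), ub - 0.5)
        r0, r1, f = _kernels.bd_fit_nm(x0, x1, *args, 600, 1e-11)
        if f < best[0]:
            best = (f, r0, r1)
    if not math.isfinite(best[0]):
        raise RuntimeError("bd piece fit failed to produce a finite likelihood")
    rates = PieceRates(b=math.exp(best[1]), d=math.exp(best[2]), flavor="bd")
    return rates, -float(best[0])
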