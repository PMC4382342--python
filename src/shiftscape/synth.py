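"""Synthetic-data generators with planted truth.

Forward Gillespie simulation of constant-rate and shifted birth-death trees,
joint tree/binary-trait (state-dependent) simulation, genus-level collapsing
with richness bookkeeping, and pseudo-posterior tree samples built by age
jitter plus local (nearest-neighbor) topology perturbation.

All generators are pure functions of their settings and a seed: the same
seed reproduces the same output byte for byte.  Trees start from two crown
lineages and are conditioned (by rejection) on both leaving extant sampled
descendants, so reconstructed root age equals the simulation's crown age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from shiftscape.phylo_io import TimeTree, TreeSample, CladeKey, clade_key, retain_tips
from shiftscape.bd_models import PieceRates

__all__ = [
    "SyntheticScenario", "simulate_bd_tree", "simulate_shifted_tree",
    "collapse_genera", "pseudo_posterior", "simulate_bisse",
]

_MAX_TRIES = 2000
_MAX_LINEAGES = 200_000


class SimulationError(RuntimeError):
    pass


@dataclass
class SyntheticScenario:
    """Settings bundle for a planted-shift recovery experiment.

    ``shifts`` is a list of ``(shift_age_My, PieceRates, clade_size)`` where
    ``clade_size`` is a minimum tip count or a ``(lo, hi)`` range; rates
    switch on the stem of a randomly chosen lineage alive at that age.
    ``tip_range`` optionally rejects whole trees outside a total tip-count
    window, keeping replicate experiments at a controlled size.
    """

    background: PieceRates
    crown_age: float
    shifts: list = field(default_factory=list)
    seed: int = 0
    tip_range: Optional[tuple] = None


# ---------------------------------------------------------------------------
# forward engine


def _forward(rng, rates_by_group, q=None, stop=("age", 50.0),
             root_group=0, shift_times=None):
    """Forward birth-death(-transition) simulation from two crown lineages.

    Returns ``None`` on total extinction, else a dict of per-lineage arrays
    plus the present time and the ids of planted lineages (one per entry of
    ``shift_times``, each ``(t_forward, new_group)``).
    """
    parent = [-1, -1]
    tb = [0.0, 0.0]
    te = [math.inf, math.inf]
    group = [root_group, root_group]
    children: list = [[], []]
    alive = {g: [] for g in range(len(rates_by_group))}
    alive[root_group] = [0, 1]
    pos = {0: 0, 1: 1}                       # lineage -> index in its alive list

    pending = sorted(shift_times or [], key=lambda s: s[0])
    planted = []
    t = 0.0
    mode, limit = stop
    t_present = limit if mode == "age" else None

    def _remove(lin):
        g = group[lin]
        lst = alive[g]
        i = pos.pop(lin)
        last = lst.pop()
        if last != lin:
            lst[i] = last
            pos[last] = i

    def _add(lin):
        g = group[lin]
        pos[lin] = len(alive[g])
        alive[g].append(lin)

    while True:
        n_alive = sum(len(v) for v in alive.values())
        if n_alive == 0:
            return None
        total = 0.0
        for g, lst in alive.items():
            b, d = rates_by_group[g]
            gr = b + d
            if q is not None:
                gr += sum(q.get((g, h), 0.0) for h in range(len(rates_by_group)))
            total += len(lst) * gr
        dt = rng.exponential(1.0 / total) if total > 0 else math.inf

        if pending and t + dt >= pending[0][0]:
            t_shift, new_group = pending.pop(0)
            if t_present is not None and t_shift >= t_present:
                raise SimulationError("shift age outside tree age")
            t = t_shift
            src = alive[root_group]
            if not src:
                return None
            lin = src[int(rng.integers(len(src)))]
            _remove(lin)
            group[lin] = new_group
            _add(lin)
            planted.append(lin)
            continue

        if mode == "age" and t + dt >= limit:
            break
        t += dt

        # choose event
        u = rng.uniform(0.0, total)
        acc = 0.0
        chosen = None
        for g, lst in alive.items():
            b, d = rates_by_group[g]
            for kind, rate in (("birth", b), ("death", d)):
                acc += len(lst) * rate
                if u < acc:
                    chosen = (g, kind, None)
                    break
            if chosen:
                break
            if q is not None:
                for h in range(len(rates_by_group)):
                    rate = q.get((g, h), 0.0)
                    acc += len(lst) * rate
                    if u < acc:
                        chosen = (g, "move", h)
                        break
            if chosen:
                break
        if chosen is None:      # float edge; treat as last category
            g = max(alive, key=lambda k: len(alive[k]))
            chosen = (g, "birth", None)
        g, kind, h = chosen
        lin = alive[g][int(rng.integers(len(alive[g])))]

        if kind == "birth":
            te[lin] = t
            _remove(lin)
            for _ in range(2):
                parent.append(lin)
                tb.append(t)
                te.append(math.inf)
                group.append(g)
                children.append([])
                children[lin].append(len(parent) - 1)
                _add(len(parent) - 1)
            if len(parent) > _MAX_LINEAGES:
                raise SimulationError("simulation exceeded lineage budget")
            if mode == "taxa" and sum(len(v) for v in alive.values()) >= limit:
                # present falls uniformly inside the next waiting interval
                total2 = 0.0
                for gg, lst in alive.items():
                    b2, d2 = rates_by_group[gg]
                    gr = b2 + d2
                    if q is not None:
                        gr += sum(q.get((gg, hh), 0.0)
                                  for hh in range(len(rates_by_group)))
                    total2 += len(lst) * gr
                dt2 = rng.exponential(1.0 / total2)
                t_present = t + rng.uniform(0.0, 1.0) * dt2
                break
        elif kind == "death":
            te[lin] = t
            _remove(lin)
        else:                   # state transition
            _remove(lin)
            group[lin] = h
            _add(lin)

    extant = [lin for lst in alive.values() for lin in lst]
    return {
        "parent": parent, "tb": tb, "te": te, "group": group,
        "children": children, "extant": sorted(extant),
        "t_present": t_present, "planted": planted,
    }


def _reconstruct(sim) -> tuple[TimeTree, dict]:
    """Extant-only reconstructed tree; returns (tree, lineage->tip label)."""
    parent, children = sim["parent"], sim["children"]
    T = sim["t_present"]
    n = len(parent)
    extant = set(sim["extant"])
    kept = [False] * n
    for lin in sorted(extant, reverse=True):
        kept[lin] = True
    for i in range(n - 1, -1, -1):
        if kept[i] and parent[i] >= 0:
            kept[parent[i]] = True

    n_kept_children = [0] * n
    for i in range(n):
        if kept[i] and parent[i] >= 0:
            n_kept_children[parent[i]] += 1
    is_tip = [kept[i] and i in extant for i in range(n)]
    is_node = [is_tip[i] or (kept[i] and n_kept_children[i] >= 2)
               for i in range(n)]
    event_time = [T if is_tip[i] else sim["te"][i] for i in range(n)]

    # nearest strictly-ancestral node lineage (parents have smaller ids)
    na = [-1] * n
    for i in range(n):
        p = parent[i]
        if p < 0:
            na[i] = -1
        else:
            na[i] = p if is_node[p] else na[p]

    tips = [i for i in range(n) if is_tip[i]]
    internals = [i for i in range(n) if is_node[i] and not is_tip[i]]
    root_children = [i for i in (0, 1) if kept[i]]
    use_virtual_root = len(root_children) == 2
    if not use_virtual_root:
        raise SimulationError("crown condition violated in reconstruction")

    width = len(str(max(len(tips), 1)))
    labels = [f"t{str(k + 1).zfill(width)}" for k in range(len(tips))]
    idx = {}
    for k, lin in enumerate(tips):
        idx[lin] = k
    for k, lin in enumerate(internals):
        idx[lin] = len(tips) + k
    root_id = len(tips) + len(internals)

    n_nodes = root_id + 1
    parent_arr = np.full(n_nodes, -1, dtype=np.int64)
    length_arr = np.zeros(n_nodes)
    for lin in tips + internals:
        a = na[lin]
        pa = root_id if a < 0 else idx[a]
        parent_arr[idx[lin]] = pa
        top_time = 0.0 if a < 0 else event_time[a]
        length_arr[idx[lin]] = event_time[lin] - top_time
    tree = TimeTree(parent_arr, length_arr, labels)
    lin_to_label = {lin: labels[idx[lin]] for lin in tips}
    return tree, lin_to_label


def _descendant_extant(sim, lin) -> list:
    out = []
    stack = [lin]
    extant = set(sim["extant"])
    while stack:
        v = stack.pop()
        if v in extant:
            out.append(v)
        stack.extend(sim["children"][v])
    return out


# ---------------------------------------------------------------------------
# public generators


def simulate_bd_tree(b: float, d: float, stop, seed: int = 0) -> TimeTree:
    """Extant-only ultrametric birth-death tree from two crown lineages.

    ``stop`` is ``("age", T)`` (crown age T, My) or ``("taxa", n)`` (stop at
    n extant tips, present drawn uniformly inside the following waiting
    interval).  Conditioned by rejection on both crown lineages surviving.
    """
    if not b > 0 or d < 0:
        raise ValueError("require b > 0 and d >= 0")
    if stop[0] == "taxa" and stop[1] < 3:
        raise ValueError("taxa stop requires >= 3 tips")
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_TRIES):
        sim = _forward(rng, [(b, d)], stop=stop)
        if sim is None or len(sim["extant"]) < 2:
            continue
        closure = _ancestor_closure(sim)
        if not (0 in closure and 1 in closure):
            continue
        try:
            tree, _ = _reconstruct(sim)
        except SimulationError:
            continue
        return tree
    raise SimulationError(f"no surviving tree in {_MAX_TRIES} tries "
                          f"(b={b}, d={d}, stop={stop})")


def _ancestor_closure(sim) -> set:
    keep = set(sim["extant"])
    parent = sim["parent"]
    for lin in list(keep):
        p = parent[lin]
        while p >= 0 and p not in keep:
            keep.add(p)
            p = parent[p]
    return keep


def simulate_shifted_tree(scenario: SyntheticScenario):
    """Tree with planted clade rate shifts; returns (tree, [truth CladeKey]).

    Each shift picks a random background lineage alive at the shift age and
    switches its whole descendant subtree to the shifted rates (stem switch).
    Rejection enforces crown survival, >= min_clade_tips surviving tips per
    planted clade, and >= 2 surviving background tips.
    """
    rng = np.random.default_rng(scenario.seed)
    bg = scenario.background
    rates = [(bg.b, bg.d)] + [(r.b, r.d) for _, r, _ in scenario.shifts]
    shift_times = [(scenario.crown_age - age, gi + 1)
                   for gi, (age, _, _) in enumerate(scenario.shifts)]
    for age, _, _ in scenario.shifts:
        if not 0 < age < scenario.crown_age:
            raise ValueError("shift ages must lie inside (0, crown_age)")
    bounds = []
    for _, _, size in scenario.shifts:
        bounds.append(size if isinstance(size, tuple) else (size, 10 ** 9))
    for _ in range(_MAX_TRIES):
        sim = _forward(rng, rates, stop=("age", scenario.crown_age),
                       shift_times=list(shift_times))
        if sim is None or len(sim["extant"]) < 2:
            continue
        if len(sim["planted"]) != len(scenario.shifts):
            continue
        if scenario.tip_range is not None and not (
                scenario.tip_range[0] <= len(sim["extant"])
                <= scenario.tip_range[1]):
            continue
        clades = [_descendant_extant(sim, lin) for lin in sim["planted"]]
        if any(not (bounds[i][0] <= len(c) <= bounds[i][1])
               for i, c in enumerate(clades)):
            continue
        n_shifted = sum(len(c) for c in clades)
        if len(sim["extant"]) - n_shifted < 2:
            continue
        try:
            tree, lin_to_label = _reconstruct(sim)
        except SimulationError:
            continue
        keys = [clade_key(lin_to_label[v] for v in c) for c in clades]
        return tree, keys
    raise SimulationError("planted-shift simulation exhausted its retry budget")


def collapse_genera(tree: TimeTree, target_genera: int,
                    max_genus_size: int = 40, seed: int = 0):
    """Collapse monophyletic tip blocks into richness-bearing terminals.

    Random internal clades of 2..max_genus_size tips are collapsed (without
    overlap) until at most ``target_genera`` terminals remain or candidates
    run out.  Returns (collapsed TimeTree, RichnessTable dict); the richness
    total always equals the original tip count.
    """
    if target_genera < 2:
        raise ValueError("target_genera must be >= 2")
    if tree.n_tips < target_genera:
        raise ValueError("tree too small for the requested collapse")
    rng = np.random.default_rng(seed)
    clades = {}
    for v in range(tree.n_tips, tree.n_nodes):
        if v == tree.root:
            continue
        tipset = tree.clade_tips(v)
        if 2 <= len(tipset) <= max_genus_size:
            clades[v] = tipset
    order = list(clades)
    rng.shuffle(order)
    taken: set = set()
    accepted = []
    n_terminals = tree.n_tips
    for v in order:
        if n_terminals <= target_genera:
            break
        tipset = clades[v]
        if taken & set(tipset):
            continue
        if n_terminals - (len(tipset) - 1) < target_genera:
            continue
        accepted.append(tipset)
        taken |= set(tipset)
        n_terminals -= len(tipset) - 1
    richness = {lab: 1 for lab in tree.labels if lab not in taken}
    keep = [lab for lab in tree.labels if lab not in taken]
    for tipset in accepted:
        rep = tipset[0]
        keep.append(rep)
        richness[rep] = len(tipset)
    collapsed = retain_tips(tree, keep)
    assert sum(richness.values()) == tree.n_tips
    return collapsed, richness


def pseudo_posterior(tree: TimeTree, n_trees: int,
                     age_jitter_sd: float = 0.0,
                     topo_rate: float = 0.0, seed: int = 0) -> TreeSample:
    """Pseudo-posterior sample: age jitter + local NNI topology noise.

    ``age_jitter_sd`` is the standard deviation of a multiplicative lognormal
    jitter on internal-node ages (ultrametricity restored top-down);
    ``topo_rate`` is the probability of a nearest-neighbor interchange at
    each eligible internal edge.  Tip sets are always preserved.  Zero noise
    yields identical copies.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trees):
        out.append(_perturb(tree, rng, age_jitter_sd, topo_rate))
    return TreeSample(out, source=f"pseudo_posterior(seed={seed})")


def _perturb(tree: TimeTree, rng, sd: float, topo_rate: float) -> TimeTree:
    if sd == 0.0 and topo_rate == 0.0:
        return TimeTree(tree.parent.copy(), tree.lengths.copy(),
                        list(tree.labels))
    parent = tree.parent.copy()
    ages = tree.ages.copy()
    children = [list(c) for c in tree.children]

    if topo_rate > 0:
        # eligible edges: (p, c) with c internal, p internal (incl. root)
        edges = [v for v in range(tree.n_tips, tree.n_nodes)
                 if v != tree.root]
        for c in edges:
            if rng.random() >= topo_rate:
                continue
            p = parent[c]
            sibs = [x for x in children[p] if x != c]
            if not sibs:
                continue
            s = sibs[int(rng.integers(len(sibs)))]
            kids = children[c]
            if not kids:
                continue
            k = kids[int(rng.integers(len(kids)))]
            # swap subtrees k <-> s
            children[c][children[c].index(k)] = s
            children[p][children[p].index(s)] = k
            parent[k], parent[s] = p, c
            # re-draw c's age inside its new valid interval
            lo = max((ages[x] for x in children[c]), default=0.0)
            hi = ages[p]
            if not lo < ages[c] < hi:
                ages[c] = lo + (hi - lo) * rng.uniform(0.05, 0.95)

    if sd > 0:
        order = _preorder(parent, children, tree.root)
        for v in order:
            if v < tree.n_tips:
                continue
            if v == tree.root:
                ages[v] = ages[v] * math.exp(rng.normal(0.0, sd))
            else:
                prop = ages[v] * math.exp(rng.normal(0.0, sd))
                hi = ages[parent[v]]
                lo = 0.0
                ages[v] = min(prop, 0.995 * hi) if prop < hi else 0.995 * hi
                ages[v] = max(ages[v], 1e-6 * hi)
        # enforce child < parent strictly after jitter (children later in order)

    # rebuild lengths from ages
    lengths = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):
        if parent[v] >= 0:
            lengths[v] = max(ages[parent[v]] - ages[v], 1e-9)
    return TimeTree(parent, lengths, list(tree.labels))


def _preorder(parent, children, root):
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(children[v])
    return order


def simulate_bisse(params, stop, root_state: int = 0, seed: int = 0,
                   sampling=(1.0, 1.0)):
    """Joint forward simulation of a tree and a binary trait under BiSSE.

    ``params`` is a :class:`shiftscape.bisse.BiSSEParams`.  Returns
    ``(TimeTree, trait dict)``; with ``sampling = (f0, f1)`` each extant tip
    in state i is retained with probability f_i (at least 2 tips kept).
    """
    rng = np.random.default_rng(seed)
    rates = [(params.lambda0, params.mu0), (params.lambda1, params.mu1)]
    q = {(0, 1): params.q01, (1, 0): params.q10}
    f0, f1 = sampling
    if not (0 < f0 <= 1 and 0 < f1 <= 1):
        raise ValueError("sampling fractions must be in (0, 1]")
    for _ in range(_MAX_TRIES):
        sim = _forward(rng, rates, q=q, stop=stop, root_group=root_state)
        if sim is None or len(sim["extant"]) < 2:
            continue
        try:
            tree, lin_to_label = _reconstruct(sim)
        except SimulationError:
            continue
        traits = {lin_to_label[lin]: sim["group"][lin]
                  for lin in sim["extant"]}
        if f0 < 1.0 or f1 < 1.0:
            keep = [lab for lab in tree.labels
                    if rng.random() < (f0 if traits[lab] == 0 else f1)]
            if len(keep) < 2:
                continue
            tree = retain_tips(tree, keep)
            traits = {lab: traits[lab] for lab in keep}
        return tree, traits
    raise SimulationError("BiSSE simulation exhausted its retry budget")
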