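"""Shift detection across a posterior tree sample.

The stepwise search is run independently on every tree of a sample; shifts
are then matched across topologically varying trees against a list of
reference clades (normally the shifts found on an MCC tree).  A shift in
tree T matches reference clade S iff its node is the MRCA of S's tips in T —
the clade itself need not be monophyletic in T, which is what lets a
reference clade present in only a fraction of trees still be recovered with
frequency near 1.  Per-clade recovery frequency (``sum_prop``), rate
dispersion statistics and a significance call at a cutoff (default 0.90)
are reported.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from shiftscape.phylo_io import TimeTree, TreeSample, CladeKey, clade_key
from shiftscape.medusa import ShiftConfig, PiecewiseShiftModel, stepwise_search

log = logging.getLogger(__name__)

__all__ = ["ShiftSummary", "MultiTreeResult", "run_over_sample",
           "match_shifts", "summarize"]


@dataclass
class ShiftSummary:
    """Cross-tree recovery and rate dispersion for one reference clade."""

    clade: CladeKey
    sum_prop: float                  # matched trees / trees analyzed
    n_trees_matched: int
    n_trees_with_clade: int          # trees where the clade is monophyletic
    n_trees: int
    matched_r: list = field(default_factory=list)
    matched_epsilon: list = field(default_factory=list)
    n_matched_monophyletic: int = 0

    @property
    def conditional_prop(self) -> float:
        """Recovery frequency among trees where the clade is monophyletic."""
        if self.n_trees_with_clade == 0:
            return math.nan
        return self.n_matched_monophyletic / self.n_trees_with_clade

    @property
    def median_r(self) -> float:
        return float(np.median(self.matched_r)) if self.matched_r else math.nan

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.matched_r)) if self.matched_r else math.nan

    @property
    def sd_r(self) -> float:
        if len(self.matched_r) < 2:
            return 0.0 if self.matched_r else math.nan
        if min(self.matched_r) == max(self.matched_r):
            return 0.0       # exactly zero for identical matched rates
        return float(np.std(self.matched_r, ddof=1))

    @property
    def median_epsilon(self) -> float:
        return (float(np.median(self.matched_epsilon))
                if self.matched_epsilon else math.nan)


@dataclass
class MultiTreeResult:
    models: list                     # Optional[PiecewiseShiftModel] per tree
    summaries: list                  # list[ShiftSummary]
    cutoff: float
    n_failures: int = 0
    unanchored: Optional[pd.DataFrame] = None

    def significant(self) -> list:
        return [s for s in self.summaries if s.sum_prop >= self.cutoff]


def _tree_hash(tree: TimeTree, config: ShiftConfig) -> str:
    payload = tree.to_newick() + "|" + json.dumps(
        {"thr": config.aicc_threshold, "max": config.max_shifts,
         "flavors": list(config.flavors), "conv": config.cut_convention,
         "n_obs": config.n_obs}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:24]


def run_over_sample(sample: TreeSample, richness: Mapping[str, int],
                    config: Optional[ShiftConfig] = None,
                    cache_dir=None,
                    max_failure_fraction: float = 0.05) -> list:
    """Independent stepwise search per tree; failures logged and excluded.

    ``cache_dir`` (optional) stores one JSON per (tree, config) so an
    interrupted run resumes where it stopped.  More than
    ``max_failure_fraction`` failed trees aborts with diagnostics.
    """
    config = config or ShiftConfig()
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    models: list = []
    failures = []
    for i, tree in enumerate(sample):
        path = cache / f"{_tree_hash(tree, config)}.json" if cache else None
        if path and path.exists():
            models.append(PiecewiseShiftModel.from_json(path.read_text()))
            continue
        try:
            model = stepwise_search(tree, richness, config)
        except Exception as e:       # per-tree failure: collect, keep going
            failures.append((i, str(e)))
            models.append(None)
            continue
        models.append(model)
        if path:
            path.write_text(model.to_json())
    if failures:
        log.warning("stepwise search failed on %d/%d trees", len(failures),
                    len(sample))
        if len(failures) > max_failure_fraction * len(sample):
            detail = "; ".join(f"tree {i}: {msg}" for i, msg in failures[:5])
            raise RuntimeError(
                f"{len(failures)}/{len(sample)} trees failed "
                f"(> {max_failure_fraction:.0%}): {detail}")
    return models


def match_shifts(sample: TreeSample, models: Sequence,
                 reference: Sequence[CladeKey]) -> list:
    """Match per-tree shifts to reference clades by the MRCA rule.

    For reference clade S and tree T, a shift in T's model matches S iff the
    shift node equals ``mrca(T, S)``.  ``sum_prop`` is matches divided by the
    number of trees analyzed (failed trees excluded); rate statistics pool
    the matching pieces' rates.
    """
    refs = [clade_key(k) for k in reference]
    analyzed = [(t, m) for t, m in zip(sample, models) if m is not None]
    n_trees = len(analyzed)
    if n_trees == 0:
        raise ValueError("no successfully analyzed trees to match against")
    out = []
    for ref in refs:
        matched_r, matched_eps = [], []
        n_matched = 0
        n_with = 0
        n_matched_mono = 0
        for tree, model in analyzed:
            node = tree.mrca(ref)
            mono = tree.clade_tips(node) == ref
            if mono:
                n_with += 1
            for s in model.shifts:
                if s.node == node:
                    n_matched += 1
                    if mono:
                        n_matched_mono += 1
                    matched_r.append(s.rates.r)
                    matched_eps.append(s.rates.epsilon)
                    break
        out.append(ShiftSummary(
            clade=ref, sum_prop=n_matched / n_trees,
            n_trees_matched=n_matched, n_trees_with_clade=n_with,
            n_trees=n_trees, matched_r=matched_r,
            matched_epsilon=matched_eps,
            n_matched_monophyletic=n_matched_mono))
    return out


def unanchored_shifts(sample: TreeSample, models: Sequence,
                      reference: Sequence[CladeKey]) -> pd.DataFrame:
    """Shifts found in sampled trees that match no reference clade.

    Aggregated by clade key; needed to see per-tree shift counts beyond the
    reference set rather than silently dropping them.
    """
    refs = {clade_key(k) for k in reference}
    ref_nodes = {}
    rows: dict = {}
    for tree, model in zip(sample, models):
        if model is None:
            continue
        ref_node_ids = {tree.mrca(r) for r in refs}
        for s in model.shifts:
            if s.node in ref_node_ids:
                continue
            rec = rows.setdefault(s.key, {"count": 0, "r": []})
            rec["count"] += 1
            rec["r"].append(s.rates.r)
    data = [{"clade": "|".join(k), "n_trees": v["count"],
             "median_r": float(np.median(v["r"]))}
            for k, v in sorted(rows.items())]
    return pd.DataFrame(data, columns=["clade", "n_trees", "median_r"])


def summarize(sample: TreeSample, models: Sequence,
              reference: Sequence[CladeKey], cutoff: float = 0.90,
              mcc_model: Optional[PiecewiseShiftModel] = None
              ) -> MultiTreeResult:
    """Full cross-tree summary: per-clade table plus rate matrix.

    The result's ``summaries`` hold one :class:`ShiftSummary` per reference
    clade; ``significant()`` applies the >= cutoff rule on ``sum_prop``.
    """
    summaries = match_shifts(sample, models, reference)
    n_failures = sum(1 for m in models if m is None)
    un = unanchored_shifts(sample, models, reference)
    return MultiTreeResult(models=list(models), summaries=summaries,
                           cutoff=cutoff, n_failures=n_failures,
                           unanchored=un)


def summary_table(result: MultiTreeResult,
                  mcc_model: Optional[PiecewiseShiftModel] = None
                  ) -> pd.DataFrame:
    """Per-reference-clade table: single-tree rate, median cross-tree rate,
    recovery probability, significance flag."""
    mcc_rate = {}
    if mcc_model is not None:
        for s in mcc_model.shifts:
            mcc_rate[s.key] = s.rates.r
    rows = []
    for i, s in enumerate(result.summaries, start=1):
        rows.append({
            "shift": i,
            "clade": "|".join(s.clade[:3]) + ("|..." if len(s.clade) > 3 else ""),
            "rate_single_tree": mcc_rate.get(s.clade, math.nan),
            "median_rate": s.median_r,
            "mean_rate": s.mean_r,
            "sd_rate": s.sd_r,
            "median_epsilon": s.median_epsilon,
            "sum_prop": s.sum_prop,
            "conditional_prop": s.conditional_prop,
            "n_trees_with_clade": s.n_trees_with_clade,
            "significant": s.sum_prop >= result.cutoff,
        })
    return pd.DataFrame(rows)


def rate_matrix(result: MultiTreeResult) -> pd.DataFrame:
    """Boxplot-ready matrix: one row per clade, matched per-tree r values."""
    data = {}
    for s in result.summaries:
        data["|".join(s.clade[:3])] = pd.Series(s.matched_r, dtype=float)
    return pd.DataFrame(data).T
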