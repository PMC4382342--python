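# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `shiftscape`. It is written for users who want to know
exactly what is being computed, and for maintainers who need to know why the
defaults are what they are.

## The piecewise birth-death model

A rooted, ultrametric, time-calibrated tree (ages in My before present) is
partitioned into *pieces*, each evolving under a constant-rate birth-death
process with speciation rate `b` and extinction rate `d` (per lineage per
My). We report the field-standard transforms net diversification
`r = b - d` and relative extinction `epsilon = d / b`. Terminal taxa may be
unresolved clades (here: genera) carrying a known extant species richness
`n >= 1`; their internal branching is not observed.

### Likelihood of one piece

Three kinds of factors multiply into a piece's likelihood:

1. **Internal branches.** A branch spanning ages `(s, t)`, `s` younger,
   contributes the reconstructed-process factor
   `psi(s, t) = e^{r(t-s)} ((b e^{rs} - d)/(b e^{rt} - d))^2`,
   the probability that a lineage at age `t` is continued by exactly the
   observed lineage at age `s` with all side branches extinct.
2. **Branching events.** Each speciation event owned by the piece
   contributes `b`. Ownership follows the branch above the event, so a
   shift on a stem branch also owns the branching event at its bottom.
3. **Terminals.** A terminal lineage with stem age `t` (the age of its
   parent node) and richness `n` contributes the unconditional Kendall
   probability of observing `n` extant species from one stem lineage,
   factored as survival times the conditional geometric clade-size law:
   `(1 - alpha) * (1 - beta) beta^{n-1}`, with
   `alpha = d(e^{rt}-1)/(b e^{rt}-d)` and
   `beta = b(e^{rt}-1)/(b e^{rt}-d)`.
   The conditional law sums to one over `n >= 1` and collapses to the Yule
   geometric `e^{-bt}(1-e^{-bt})^{n-1}` as `d -> 0`.

At `n = 1` the terminal factor equals the pendant-branch factor
`psi(0, t)`, so on a fully resolved tree the piece likelihood is exactly the
classic branching-times birth-death likelihood (Nee-style), up to the
labelled-tree orientation constant `(n-1)!`, which is the same for every
model compared on a given tree and is therefore omitted. A consequence used
as a test oracle: the ML speciation rate of a pure-birth tree is
(branching events)/(total branch length).

Two flavors are fit per piece: `yule` (`d = 0`, one parameter) and `bd`
(two parameters). The bd optimizer works on `(log b, log d)`, so `d > b`
(negative `r`, `epsilon > 1`) is reachable — multi-tree summaries of
depauperate clades genuinely produce negative median rates. A guard
`epsilon <= e^3` walls off the data-free `d >> b` ridge (see below).

### Survival conditioning

Conditioning the whole-tree likelihood on both crown lineages surviving to
the present is conventional for single constant-rate fits and is available
(`build_piece(..., condition_crown=True)`). The piecewise search, however,
runs **unconditioned**: for multi-piece models any crown-survival factor is
charged to one piece while parts of that crown lineage's subtree belong to
other pieces, and the resulting conditioned "likelihood" is unbounded above
in the `d >> b` direction (the conditioning reward `~|r| T` outruns the
piece's remaining branch penalties). Unconditioned, every factor above is a
probability or bounded density and the per-piece maximum always exists.
This choice affects absolute likelihood values slightly and model
comparison essentially not at all (the conditioning term is shared by all
candidate models of similar background rates); it is the price of exact
per-piece decomposability, which the stepwise search requires.

### AIC/AICc

`AIC = -2 lnL + 2k`, `AICc = AIC + 2k(k+1)/(n_obs - k - 1)`. The parameter
count `k` sums the per-piece rate parameters (yule 1, bd 2) plus one per
accepted breakpoint (its location); `n_obs` defaults to the number of
terminal taxa, both configurable.

## Stepwise breakpoint search

The search starts from the better (by AICc) of the two single-piece
flavors. Each step scores every admissible cut: under the default `stem`
convention a cut at node X moves X's branch plus subtree into a new piece
(the `node` convention moves the subtree only; both are implemented because
published figures mark shifts on nodes while rate regimes plausibly start
on stems). Only the donor piece and the new piece are refit; every other
piece's term is reused — refitting a piece never depends on any other
piece's rates, and a test verifies the incremental totals equal independent
full refits to 1e-8. Per-candidate flavor choice evaluates all four
donor/new flavor combinations against the total AICc.

The best candidate is accepted iff it improves AICc by **more than the
threshold** (default 7.8 units, the documented value for the ~400-terminal
study dataset this package was built around; a `{n_tips: threshold}` table
can supply size-dependent values, and a missing threshold is an explicit
error, never a silent default). The search stops when no candidate clears
the threshold or `max_shifts` (default 30) is reached. Ties are broken
deterministically: AICc, then older shift-node age, then lexicographic
clade key. An optional backward pass (off by default) re-tests the removal
of earlier shifts after each acceptance; the default is forward-only
because the incremental-addition protocol is the one being reproduced.

Per-piece fitting uses compiled optimizers (golden-section on `log b` for
yule; Nelder-Mead on `(log b, log d)` for bd, two deterministic starts plus
optional jittered restarts). Multi-start agreement is tested to 1e-6.

## Multi-tree uncertainty protocol

The stepwise search runs independently on every tree of a posterior (or
pseudo-posterior) sample; per-tree failures are logged, excluded, and more
than 5% of failures aborts the run. Results can be cached as one JSON per
(tree, configuration) hash, making 1000-tree runs resumable.

**Matching rule.** Given reference clades (normally the shifts found on an
MCC tree), a shift in sample tree T matches reference S iff the shift node
*is* the MRCA of S's tips in T. Monophyly of S in T is **not** required —
this is what lets a clade present in only a quarter of the trees still be
recovered with frequency near one, the behavior the protocol is designed to
expose. The recovery frequency `sum_prop` = matched trees / analyzed trees;
a conditional frequency (among trees where S is monophyletic) is also
reported, since the literature is ambiguous about which is meant. A shift is
*significant* when `sum_prop >= cutoff` (default 0.90). Matched pieces' `r`
and `epsilon` values are pooled into median/mean/SD summaries and a
boxplot-ready rate matrix; shifts matching no reference clade are kept in an
"unanchored" table rather than dropped.

## BiSSE

The binary-state speciation-extinction likelihood propagates, rootward
along each branch, extinction probabilities `E_i(t)` and subtree densities
`D_i(t)` for states `i in {0, 1}`:

    E_i' = mu_i - (lambda_i + mu_i + q_ij) E_i + lambda_i E_i^2 + q_ij E_j
    D_i' = -(lambda_i + mu_i + q_ij) D_i + q_ij D_j + 2 lambda_i E_i D_i

Tips initialize with state-specific sampling fractions `f_i` (the
proportion of extant species in state `i` present as tips): `D_i = f_i` for
the observed state, 0 otherwise (both set for a missing state, which
exactly marginalizes over it), `E_i = 1 - f_i`. Sampling fractions can be
derived from richness and trait tables — `f_i` = (tips in state i)/(described
species in state-i genera), assuming a genus's species share its state — or
given explicitly; a single global fraction is the special case `f_0 = f_1`.
At internal nodes `D_i <- D_left,i D_right,i lambda_i` with running log
renormalization of D against underflow. Root states are weighted by their
relative D values by default ("obs"; "flat" and explicit weights are
options because the source analyses do not state their choice), and the
likelihood is conditioned on survival of both crown lineages by dividing by
`sum_i w_i lambda_i (1 - E_i)^2` (also toggleable). With all tips in state
0 and `q = 0` this reduces exactly to the crown-conditioned constant-rate
birth-death likelihood, and with state-independent rates it factorizes into
(tree likelihood) x (two-state Markov character likelihood) — both are
test oracles.

**Integration.** The default integrator is a compiled fixed-step RK4 whose
step density scales with the total rate (minimum 24 steps per branch at
"high" precision, 8 at "fast"); cross-checks against adaptive `solve_ivp`
(rtol 1e-8 retried at 1e-10) and an independent high-resolution integrator
agree to ~1e-6 at "high" and ~1e-4 at "fast". "fast" is used inside
replicated calibration experiments where thousands of fits are needed.

**Fitting and testing.** ML fits run bounded L-BFGS-B on log-rates with
multi-start; the constrained model enforces `lambda_0 = lambda_1` (k = 5 vs
6). The LRT uses `chi2 = 2 (lnL_full - lnL_constrained)` with 1 df; a
materially negative statistic raises instead of being clamped silently,
since it signals an optimizer failure. Null simulations confirm the 1-df
chi-square calibration (KS test in the acceptance suite).

**MCMC.** A seeded univariate slice sampler (stepping-out with shrinkage)
updates the six rates in order once per generation. The prior is iid
exponential on each rate with mean twice a crude whole-tree net
diversification estimate `log(n/2)/T` — a weakly informative default in the
spirit of the implementations this protocol descends from; the defaults of
10000 generations with 7500 discarded as burnin follow the study protocol.
Chains from a tree sample are pooled post-burnin with per-draw tree
provenance, so phylogenetic uncertainty widens the pooled intervals.

**Hostplant coding.** `code_binary_trait` codes a genus 1 iff any record
links it to the target plant family (one record suffices), 0 if it has
records but none for the target, and leaves it missing otherwise; a recode
list supports flipping dubious records to 0 for sensitivity analysis.
`hostplant_family_counts` reports the records/genera/families bookkeeping,
including the genera using exactly one versus more than one plant family.

## Synthetic generators

All generators are deterministic functions of settings and a seed.

* `simulate_bd_tree` — forward Gillespie from two crown lineages, extinct
  lineages pruned, rejection until both crown lineages leave sampled
  descendants; stop at a crown age (root age is then exact) or at a tip
  count (the present is drawn uniformly inside the next waiting interval).
* `simulate_shifted_tree` — plants rate shifts by switching a uniformly
  chosen background lineage (and its descendants) to new rates at a given
  age; the surviving planted clade is returned as truth. Rejection bounds
  keep total tips and clade sizes in configured windows so replicate
  experiments run at controlled sizes.
* `collapse_genera` — collapses random non-overlapping monophyletic blocks
  of 2..`max_genus_size` tips into single richness-bearing terminals until
  a target terminal count; richness always sums to the original tip count.
* `pseudo_posterior` — emulates a Bayesian tree sample by per-replicate
  nearest-neighbor interchanges (probability `topo_rate` per eligible
  internal edge) plus multiplicative lognormal age jitter with top-down
  restoration of parent-older-than-child and ultrametricity. Zero noise
  yields byte-identical copies. This reproduces the qualitative phenomenon
  of interest — shift support collapsing with nodal uncertainty — but it is
  *not* a sample from any posterior: branch-length and topology
  perturbations are independent and locally generated, so passing recovery
  tests says nothing about amplitudes of real BEAST posteriors.
* `simulate_bisse` — joint forward simulation of branching, extinction and
  state flips; optional per-state subsampling emulates sampling fractions.

What the generators do **not** emulate: non-ultrametric noise, calibration
uncertainty that correlates node ages, gene-tree/species-tree conflict,
taxonomic error in richness assignment, and rate variation in time within a
regime. Results on synthetic data bound what the method can do under its
own assumptions, not under real-data violations of them.

## Problem sizes used in the shipped experiments

The acceptance suite and `scripts/acceptance.py` run the full experiments
at sizes chosen to make their statistical assertions sharp while keeping a
complete run in minutes on one core: clade-size law, 1e5 forward
replicates per (b, d, t) point; false-positive rate, 40 pure-birth
100-tip trees; planted-shift recovery, 30 trees of 70-150 tips with
20-45-tip planted clades (a shift counts as recovered at the planted
clade's MRCA, one node adjacent, or at Jaccard >= 0.9 tip overlap —
stem-versus-crown placement of a mid-branch regime change is ambiguous by
one node); noise response, 16-tree pseudo-posteriors at NNI rates
{0, 0.2, 0.5}; null LRT calibration, 120-150 replicates at 80 tips;
BiSSE power, 25-30 replicates at 300 tips with `lambda_1 = 2 lambda_0`;
pure-birth rate recovery, 150-200 trees of crown age 30 (where the MLE's
O(1/n) bias is far inside Monte-Carlo error).

## Numerical notes

* All birth-death quantities are computed through `log[(b e^{rt} - d)/r]`,
  continued through `r = 0` and evaluated in overflow-safe form for either
  sign of `r`; piece log-likelihood contributions are floored at -1e10.
* The tie-break ordering, candidate exclusion of already-accepted nodes,
  and per-piece fit caching make the search invariant to tip order and to
  child rotation of the input file.
* Degenerate single-terminal pieces are legal (their fit maximizes the
  richness terms alone; with richness 1 the fitted rate runs to the lower
  bound, reproducing the familiar "rate ~ 0, lnL ~ 0" terminal shifts).
* Slice-sampler stepping out is capped at 30 widths; intervals shrink to
  the current point in degenerate flat regions rather than looping.

## Known limitations

* The geometric clade-size law treats each unresolved terminal as an
  independent birth-death realization from its stem age; backbone and
  clade-size information interact only through the shared rates.
* The unconditioned search likelihood means absolute AICc values are not
  comparable to implementations that condition on survival (model
  *rankings* are, in all cases we tested).
* BiSSE inherits the model family's known sensitivity to tree size, tip
  ratio and rate asymmetry; the power experiment documents the regime
  (hundreds of tips, 2x speciation bias) where detection is reliable.
* The pseudo-posterior is a controlled noise model, not an inference
  posterior (above).
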