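# shiftscape

Diversification-rate analysis on time-calibrated phylogenies whose terminals
may stand for unresolved clades (genera) of known species richness.
`shiftscape` implements three linked analyses that, together, answer "where
did the tempo of diversification change, how sure are we given phylogenetic
uncertainty, and is a binary trait responsible?":

1. **Piecewise birth-death shift detection by stepwise AICc.** Each tree
   piece evolves at constant speciation `b` and extinction `d` (net
   diversification `r = b - d`, relative extinction `epsilon = d/b`).
   Resolved branches contribute the classic reconstructed-process
   likelihood; a terminal of richness `n` and stem age `t` contributes the
   geometric clade-size law `Pr(N = n | survival) = (1-beta) beta^{n-1}`
   with `beta = b(e^{rt}-1)/(b e^{rt}-d)`. Breakpoints are added one at a
   time, each accepted only if it improves AICc by more than a threshold
   (7.8 units for the ~400-terminal dataset this package was built around).
2. **Multi-tree uncertainty protocol.** The search runs independently over
   a sample of posterior trees; a shift in tree T matches a reference clade
   S iff its node is the MRCA of S's tips in T (monophyly not required), and
   each reference shift gets a recovery frequency `sum_prop`, rate
   dispersion statistics, and a significance call at `sum_prop >= 0.90`.
3. **Trait-dependent diversification (BiSSE)** with state-specific
   speciation, extinction and transition rates (`lambda_i, mu_i, q_ij`),
   state-specific sampling fractions for missing species, equal-speciation
   constrained fits with likelihood-ratio tests, and a seeded slice-sampling
   MCMC whose chains can be pooled across a tree sample.

A synthetic-data module plants known truth (trees with rate shifts,
genus-collapsed richness, pseudo-posterior samples, joint tree/trait
simulations) so every stage is testable without external data. See
`docs/methods.md` for the model details and design choices.

## Worked example

Simulate a tree with one planted speciation-rate shift, find it, then
re-run the search over a noisy pseudo-posterior sample:

```bash
$ shiftscape simulate shifted --seed 11 --out data
wrote 101-tip tree with 1 planted shift(s)

$ shiftscape medusa --tree data/tree.nwk --richness data/richness.csv \
      --out model.json --table shifts.csv
background: flavor=yule r=0.101623
accepted shifts: 1; AICc=588.915 (lnL=-291.334, k=3)

$ shiftscape multimedusa --trees data/posterior.nex --schema nexus \
      --richness data/richness.csv --reference model.json --out summary.csv
 shift  clade               rate_single_tree  median_rate  sd_rate  sum_prop  significant
     1  t026|t053|t054|...          0.513715     0.503868 0.104452      0.90         True
significant at sum_prop >= 0.9: 1/1
```

(The `simulate` subcommand wrote the tree, an all-ones richness table and
the planted truth `data/truth.json`; `data/posterior.nex` is a 50-tree
pseudo-posterior made with `shiftscape.synth.pseudo_posterior`.) The search
recovered the planted 23-tip clade: its piece runs at `r ~ 0.50` against a
background of `r ~ 0.10`, and the shift is recovered at the same node in
90% of the perturbed trees — significant under the 0.90 rule.

Trait-dependent rates on a jointly simulated tree + binary character
(truth: `lambda1 = 2 lambda0`):

```bash
$ shiftscape simulate bisse --seed 3 --out bdata
$ shiftscape bisse --tree bdata/tree.nwk --traits bdata/traits.csv \
      --mcmc 500 --burnin 250 --seed 4 --out chain.csv
full model:        lnL=-305.3375 AIC=622.6751
  lambda0=0.06709 lambda1=0.23055 mu0=0.00001 mu1=0.03641 r0=0.06709 r1=0.19414
equal-lambda:      lnL=-308.7674 AIC=627.5348
LRT: chi2=6.860 df=1 p=0.008816
posterior means (post-burnin): r0=0.04180 r1=0.16191
```

State-1 lineages diversify faster (`r1 ~ 0.16-0.19` versus `r0 ~ 0.04-0.07`),
and the equal-speciation model is rejected (p < 0.01) — matching the
simulated 2x speciation bias.

The same functions drive library use: `shiftscape.stepwise_search`,
`shiftscape.run_over_sample` / `match_shifts` / `summarize`,
`shiftscape.bisse_ml` / `lrt` / `bisse_mcmc` / `pool_chains`, and
`shiftscape.synth.*` for generators.

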