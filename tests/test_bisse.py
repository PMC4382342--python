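"""BiSSE likelihood, ML/LRT, MCMC, pooling and trait coding."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from shiftscape import synth
from shiftscape.bd_models import PieceRates, piece_lnl, assign_pieces, build_piece
from shiftscape.bisse import (
    BiSSEParams, SamplingFractions, MCMCSettings, bisse_lnl, bisse_ml, lrt,
    bisse_mcmc, pool_chains, code_binary_trait, hostplant_family_counts,
    compute_sampling_fractions,
)
from shiftscape.bd_models import ModelFit


@pytest.fixture(scope="module")
def bisse_data():
    params = BiSSEParams(0.12, 0.25, 0.03, 0.03, 0.02, 0.02)
    tree, traits = synth.simulate_bisse(params, ("taxa", 80), seed=5)
    return params, tree, traits


class TestLikelihood:
    def test_reduces_to_birth_death_when_state1_unreachable(self):
        """All tips state 0, q = 0, f = 1: equals the crown-conditioned
        constant-rate birth-death likelihood from the bd machinery."""
        tree = synth.simulate_bd_tree(0.15, 0.05, ("taxa", 40), seed=7)
        traits = {lab: 0 for lab in tree.labels}
        p = BiSSEParams(0.15, 0.4, 0.05, 0.2, 0.0, 0.0)
        got = bisse_lnl(tree, traits, p)
        pc = build_piece(tree, {l: 1 for l in tree.labels},
                         assign_pieces(tree, []), 0, condition_crown=True)
        want = piece_lnl(pc, PieceRates(b=0.15, d=0.05))
        assert got == pytest.approx(want, abs=1e-5)

    def test_two_tip_tree_matches_independent_integrator(self):
        """Independent fixed-step RK4 written here, plus the scipy adaptive
        backend, agree with the production kernel on a 2-tip tree."""
        tree = synth.simulate_bd_tree(0.3, 0.0, ("age", 3.0), seed=3)
        tree = type(tree).from_newick(
            "(A:2.0,B:2.0);")
        traits = {"A": 0, "B": 1}
        p = BiSSEParams(0.3, 0.5, 0.1, 0.05, 0.08, 0.04)
        f = SamplingFractions(0.9, 0.8)

        def deriv(y):
            E0, E1, D0, D1 = y
            return np.array([
                p.mu0 - (p.lambda0 + p.mu0 + p.q01) * E0
                + p.lambda0 * E0 ** 2 + p.q01 * E1,
                p.mu1 - (p.lambda1 + p.mu1 + p.q10) * E1
                + p.lambda1 * E1 ** 2 + p.q10 * E0,
                -(p.lambda0 + p.mu0 + p.q01) * D0 + p.q01 * D1
                + 2 * p.lambda0 * E0 * D0,
                -(p.lambda1 + p.mu1 + p.q10) * D1 + p.q10 * D0
                + 2 * p.lambda1 * E1 * D1])

        def rk4(y, T, n=20000):
            h = T / n
            for _ in range(n):
                k1 = deriv(y)
                k2 = deriv(y + 0.5 * h * k1)
                k3 = deriv(y + 0.5 * h * k2)
                k4 = deriv(y + h * k3)
                y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            return y

        ya = rk4(np.array([1 - f.f0, 1 - f.f1, f.f0, 0.0]), 2.0)
        yb = rk4(np.array([1 - f.f0, 1 - f.f1, 0.0, f.f1]), 2.0)
        E = 0.5 * (ya[:2] + yb[:2])
        D = np.array([ya[2] * yb[2] * p.lambda0, ya[3] * yb[3] * p.lambda1])
        w = D / D.sum()
        oracle = math.log(float(w @ D)) - math.log(
            float(np.sum(w * np.array([p.lambda0, p.lambda1]) * (1 - E) ** 2)))

        assert bisse_lnl(tree, traits, p, f) == pytest.approx(oracle, abs=1e-6)
        assert bisse_lnl(tree, traits, p, f, ode="scipy") == pytest.approx(
            oracle, abs=1e-6)

    def test_factorizes_into_tree_times_markov_character(self):
        """With state-independent rates, lnL(BiSSE) - lnL(birth-death) equals
        the pure two-state Markov character likelihood (expm pruning oracle,
        identical D-weighted root treatment)."""
        lam, mu = 0.25, 0.08
        for s in range(20):
            p = BiSSEParams(lam, lam, mu, mu, 0.07, 0.11)
            tree, traits = synth.simulate_bisse(
                BiSSEParams(lam, lam, mu, mu, 0.3, 0.3), ("taxa", 10),
                seed=800 + s)
            full = bisse_lnl(tree, traits, p)
            pc = build_piece(tree, {l: 1 for l in tree.labels},
                             assign_pieces(tree, []), 0, condition_crown=True)
            tree_part = piece_lnl(pc, PieceRates(b=lam, d=mu))

            # independent character pruning with matrix exponentials
            Q = np.array([[-p.q01, p.q01], [p.q10, -p.q10]])
            C = {}
            for i, lab in enumerate(tree.labels):
                C[i] = np.array([1.0, 0.0] if traits[lab] == 0 else [0.0, 1.0])
            for v in tree.postorder:
                if tree.children[v]:
                    acc = np.ones(2)
                    for c in tree.children[v]:
                        acc = acc * (expm(Q * tree.lengths[c]) @ C[c])
                    C[v] = acc
            root = C[tree.root]
            char = math.log(float(root @ root / root.sum()))
            assert full - tree_part == pytest.approx(char, abs=1e-5)

    def test_missing_state_tip_marginalizes(self, bisse_data):
        """A missing-state tip marginalizes over states: with flat root
        weights and no survival conditioning the likelihood is exactly the
        sum over the two forced assignments."""
        p, tree, traits = bisse_data
        kw = dict(root="flat", condition_surv=False)
        some = tree.labels[0]
        partial = dict(traits); partial[some] = None
        as0 = dict(traits); as0[some] = 0
        as1 = dict(traits); as1[some] = 1
        lm = bisse_lnl(tree, partial, p, **kw)
        l0 = bisse_lnl(tree, as0, p, **kw)
        l1 = bisse_lnl(tree, as1, p, **kw)
        assert math.exp(lm) == pytest.approx(math.exp(l0) + math.exp(l1),
                                             rel=1e-6)

    def test_extinction_probability_monotone_in_age(self):
        """E_i(t) grows with t and stays within [0, 1] across a rate grid."""
        from shiftscape._kernels import _rk4_branch
        for la, mu, q in [(0.2, 0.1, 0.05), (0.5, 0.4, 0.01),
                          (0.1, 0.0, 0.2)]:
            prev = -1.0
            for t in np.linspace(0.5, 40, 12):
                y = np.array([0.0, 0.0, 1.0, 1.0])
                _rk4_branch(y, t, max(40, int(t * 20)), la, la, mu, mu, q, q)
                assert 0.0 <= y[0] <= 1.0
                assert y[0] >= prev - 1e-12
                prev = y[0]

    def test_log_compensation_matches_unscaled_small_tree(self, bisse_data):
        """Rescaling leaves lnL unchanged where no underflow occurs: the
        scipy backend (same compensation scheme) agrees with rk4 to 1e-6 and
        both are finite and reproducible."""
        p, tree, traits = bisse_data
        a = bisse_lnl(tree, traits, p)
        b = bisse_lnl(tree, traits, p, ode="scipy")
        assert a == pytest.approx(b, abs=1e-5)
        assert a == bisse_lnl(tree, traits, p)


class TestMLAndLRT:
    def test_constrained_fit_enforces_equal_lambda(self, bisse_data):
        p, tree, traits = bisse_data
        est, fit = bisse_ml(tree, traits, constraint="equal_lambda",
                            n_restarts=0, precision="fast")
        assert est.lambda0 == est.lambda1
        assert fit.k == 5

    def test_full_fit_beats_constrained(self, bisse_data):
        p, tree, traits = bisse_data
        full_p, full = bisse_ml(tree, traits, n_restarts=0, precision="fast")
        con_p, con = bisse_ml(tree, traits, constraint="equal_lambda",
                              n_restarts=0, precision="fast")
        assert full.k == 6
        assert full.lnL >= con.lnL - 1e-6
        chi2, df, pval = lrt(full, con)
        assert df == 1
        assert chi2 >= 0
        assert 0 <= pval <= 1

    def test_lrt_identical_fits(self):
        a = ModelFit(lnL=-100.0, k=6, n_obs=50)
        b = ModelFit(lnL=-100.0, k=5, n_obs=50)
        chi2, df, p = lrt(a, b)
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_lrt_rejects_non_nested(self):
        a = ModelFit(lnL=-100.0, k=5, n_obs=50)
        b = ModelFit(lnL=-100.0, k=6, n_obs=50)
        with pytest.raises(ValueError):
            lrt(a, b)

    def test_lrt_flags_optimizer_failure(self):
        good = ModelFit(lnL=-120.0, k=6, n_obs=50)
        better_constrained = ModelFit(lnL=-100.0, k=5, n_obs=50)
        with pytest.raises(RuntimeError, match="constrained"):
            lrt(good, better_constrained)


class TestMCMC:
    def test_same_seed_identical_chains(self, bisse_data):
        p, tree, traits = bisse_data
        st = MCMCSettings(steps=60, burnin=20, seed=5, precision="fast",
                          init=p)
        c1 = bisse_mcmc(tree, traits, settings=st)
        c2 = bisse_mcmc(tree, traits, settings=st)
        assert c1.equals(c2)
        assert list(c1.columns)[:2] == ["step", "lnpost"]

    def test_burnin_validation(self):
        with pytest.raises(ValueError):
            MCMCSettings(steps=100, burnin=100)

    def test_pooling_identities(self, bisse_data):
        p, tree, traits = bisse_data
        st = MCMCSettings(steps=40, burnin=10, seed=6, precision="fast",
                          init=p)
        chain = bisse_mcmc(tree, traits, settings=st)
        pooled = pool_chains([chain] * 3)
        # quantiles unchanged when pooling copies of one chain
        for col in ("lambda0", "r1"):
            assert pooled[col].quantile(0.5) == pytest.approx(
                chain.iloc[10:][col].quantile(0.5))
        # pooled mean = draw-count-weighted mean of per-chain means
        assert pooled["lambda1"].mean() == pytest.approx(
            chain.iloc[10:]["lambda1"].mean())
        assert set(pooled["tree"]) == {0, 1, 2}

    def test_pooling_rejects_mismatched_columns(self, bisse_data):
        p, tree, traits = bisse_data
        st = MCMCSettings(steps=12, burnin=2, seed=7, precision="fast",
                          init=p)
        chain = bisse_mcmc(tree, traits, settings=st)
        with pytest.raises(ValueError, match="mismatched"):
            pool_chains([chain, chain.drop(columns=["r0"])])

    def test_pooled_interval_widens_with_tree_noise(self, bisse_data):
        """Chains from a jittered pseudo-posterior spread the posterior of
        lambda1 at least as wide as the single-tree chain."""
        p, tree, traits = bisse_data
        st = MCMCSettings(steps=50, burnin=20, seed=8, precision="fast",
                          init=p)
        single = bisse_mcmc(tree, traits, settings=st).iloc[20:]
        sample = synth.pseudo_posterior(tree, 4, age_jitter_sd=0.25,
                                        topo_rate=0.3, seed=9)
        chains = []
        for i, t in enumerate(sample):
            sti = MCMCSettings(steps=50, burnin=20, seed=8 + i,
                               precision="fast", init=p)
            chains.append(bisse_mcmc(t, traits, settings=sti))
        pooled = pool_chains(chains)
        lo_s, hi_s = single["lambda1"].quantile([0.025, 0.975])
        lo_p, hi_p = pooled["lambda1"].quantile([0.025, 0.975])
        assert (hi_p - lo_p) > 0.8 * (hi_s - lo_s)


class TestSamplingFractions:
    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            SamplingFractions(0.0, 1.0)
        with pytest.raises(ValueError):
            SamplingFractions(0.5, 1.2)

    def test_derivation_from_richness_and_traits(self, bisse_data):
        p, tree, traits = bisse_data
        richness = {lab: 2 for lab in tree.labels}
        f = compute_sampling_fractions(tree, traits, richness)
        assert f.f0 == pytest.approx(0.5)
        assert f.f1 == pytest.approx(0.5)


class TestTraitCoding:
    @pytest.fixture()
    def records(self):
        rows = [
            ("Genus_A", "Solanaceae"), ("Genus_A", "Rosaceae"),
            ("Genus_B", "Apocynaceae"), ("Genus_C", "Solanaceae"),
            ("Genus_D", "Poaceae"), ("Genus_E", "Poaceae"),
            ("Genus_E", "Rosaceae"), ("Genus_F", "Solanaceae"),
        ]
        return pd.DataFrame(rows, columns=["butterfly_genus", "plant_family"])

    def test_presence_absence_coding(self, records):
        coded = code_binary_trait(records, "Solanaceae")
        assert coded["Genus_A"] == 1       # one record among many suffices
        assert coded["Genus_B"] == 0
        assert "Genus_Z" not in coded      # absent genus stays missing

    def test_recode_list_flips_to_zero(self, records):
        coded = code_binary_trait(records, "Solanaceae",
                                  recode_to_zero=["Genus_A", "Genus_Q"])
        assert coded["Genus_A"] == 0
        assert coded["Genus_C"] == 1

    def test_empty_records_rejected(self, records):
        with pytest.raises(ValueError):
            code_binary_trait(records.iloc[:0], "Solanaceae")

    def test_single_versus_multi_family_split(self, records):
        counts = hostplant_family_counts(records)
        assert counts["n_records"] == 8
        assert counts["n_single_family"] == 4   # B, C, D, F
        assert counts["n_multi_family"] == 2    # A, E
        assert counts["n_plant_families"] == 4
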