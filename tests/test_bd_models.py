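"""Birth-death likelihood core: flavors, clade-size law, pieces, fitting."""

import math

import numpy as np
import pytest
from scipy import stats

from shiftscape import synth, _kernels
from shiftscape.bd_models import (
    PieceRates, ModelFit, TreePiece, resolved_lnl, clade_size_lnl, piece_lnl,
    piecewise_lnl, fit_piece, assign_pieces, build_piece, aicc,
    geometric_alpha_beta,
)
from tests.conftest import unit_richness


def whole_tree_piece(tree, richness=None, condition=False):
    richness = richness or unit_richness(tree)
    return build_piece(tree, richness, assign_pieces(tree, []), 0,
                       condition_crown=condition)


class TestPieceRates:
    def test_invariants(self):
        r = PieceRates(b=0.2, d=0.1)
        assert r.r == pytest.approx(0.1)
        assert r.epsilon == pytest.approx(0.5)
        with pytest.raises(ValueError):
            PieceRates(b=0.0)
        with pytest.raises(ValueError):
            PieceRates(b=0.1, d=0.1, flavor="yule")

    def test_negative_r_representable_for_bd(self):
        r = PieceRates(b=0.1, d=0.15, flavor="bd")
        assert r.r < 0
        assert r.epsilon > 1


class TestResolvedLnl:
    @pytest.mark.parametrize("b", [0.05, 0.2, 1.0])
    def test_yule_equals_bd_limit_at_d_zero(self, bd_tree_60, b):
        pc = whole_tree_piece(bd_tree_60)
        ly = resolved_lnl(pc, PieceRates(b=b, flavor="yule"))
        lb = resolved_lnl(pc, PieceRates(b=b, d=0.0, flavor="bd"))
        assert ly == pytest.approx(lb, abs=1e-9)
        # and approached smoothly from d > 0
        ld = resolved_lnl(pc, PieceRates(b=b, d=1e-12, flavor="bd"))
        assert ly == pytest.approx(ld, abs=1e-6)

    def test_yule_grid_maximum_matches_analytic_estimate(self, yule_tree_50):
        """ML of b on a fully resolved Yule tree equals branching events /
        total branch length (grid-search oracle)."""
        pc = whole_tree_piece(yule_tree_50)
        S = yule_tree_50.total_branch_length()
        analytic = (yule_tree_50.n_tips - 2) / S
        grid = np.exp(np.linspace(np.log(analytic) - 1, np.log(analytic) + 1,
                                  4001))
        vals = [piece_lnl(pc, PieceRates(b=b, flavor="yule")) for b in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(analytic, rel=1e-3)

    def test_invariant_under_tip_label_permutation(self, bd_tree_60):
        pc = whole_tree_piece(bd_tree_60)
        relabeled = type(bd_tree_60)(bd_tree_60.parent.copy(),
                                     bd_tree_60.lengths.copy(),
                                     list(reversed(bd_tree_60.labels)))
        pc2 = whole_tree_piece(relabeled)
        r = PieceRates(b=0.15, d=0.03)
        assert piece_lnl(pc, r) == pytest.approx(piece_lnl(pc2, r), abs=1e-9)

    def test_numba_kernel_matches_reference_path(self, bd_tree_60):
        pc = whole_tree_piece(bd_tree_60, condition=True)
        for b, d in [(0.1, 0.0), (0.2, 0.1), (0.1, 0.15), (0.05, 0.05)]:
            ref = piece_lnl(pc, PieceRates(b=b, d=d))
            ker = _kernels.bd_piece_lnl(
                pc.branch_top, pc.branch_bot, float(pc.n_internal),
                pc.tip_stem_age, pc.tip_richness, float(pc.n_condition),
                pc.root_age, b, d)
            assert ker == pytest.approx(ref, abs=1e-9)


class TestCladeSizeLaw:
    def test_alpha_beta_relation(self):
        for b, d, t in [(0.2, 0.1, 20.0), (0.1, 0.0, 10.0), (0.1, 0.15, 30.0)]:
            alpha, beta = geometric_alpha_beta(b, d, t)
            assert 0 <= alpha < 1
            assert 0 <= beta < 1
            assert alpha == pytest.approx(beta * d / b, abs=1e-12)

    def test_normalization(self):
        rates = PieceRates(b=0.2, d=0.1)
        total = sum(math.exp(clade_size_lnl(20.0, n, rates))
                    for n in range(1, 10 ** 6))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_yule_clade_size_matches_forward_simulation(self):
        """Monte-Carlo oracle: forward birth process frequencies."""
        b, t, n_reps = 0.1, 10.0, 100_000
        counts = _kernels.simulate_clade_sizes(b, 0.0, t, n_reps, 123)
        rates = PieceRates(b=b, flavor="yule")
        p3 = math.exp(clade_size_lnl(t, 3, rates))
        freq3 = np.mean(counts == 3)
        se = math.sqrt(p3 * (1 - p3) / n_reps)
        assert abs(freq3 - p3) < 4 * se

    def test_singleton_probability_decreases_with_age(self):
        rates = PieceRates(b=0.2, d=0.05)
        vals = [clade_size_lnl(t, 1, rates) for t in np.linspace(1, 60, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            clade_size_lnl(10.0, 0, PieceRates(b=0.1))


class TestPiecewise:
    def test_zero_shifts_equals_single_piece(self, bd_tree_60):
        rich = unit_richness(bd_tree_60)
        bg = PieceRates(b=0.12, d=0.02)
        direct = piece_lnl(whole_tree_piece(bd_tree_60, rich), bg)
        assert piecewise_lnl(bd_tree_60, rich, [], bg) == pytest.approx(
            direct, abs=1e-9)

    def test_equal_rates_reproduce_no_shift_lnl(self, bd_tree_60):
        rich = unit_richness(bd_tree_60)
        bg = PieceRates(b=0.12, d=0.02)
        node = [v for v in range(bd_tree_60.n_tips, bd_tree_60.n_nodes)
                if v != bd_tree_60.root][3]
        key = bd_tree_60.clade_tips(node)
        split = piecewise_lnl(bd_tree_60, rich, [(key, bg)], bg)
        whole = piecewise_lnl(bd_tree_60, rich, [], bg)
        assert split == pytest.approx(whole, abs=1e-9)

    def test_three_piece_total_matches_term_by_term_oracle(self, bd_tree_60):
        """Brute force: every branch and tip term computed independently."""
        tree = bd_tree_60
        rich = {lab: (i % 4) + 1 for i, lab in enumerate(tree.labels)}
        internal = [v for v in range(tree.n_tips, tree.n_nodes)
                    if v != tree.root]
        internal.sort(key=lambda v: -len(tree.clade_tips(v)))
        n1, n2 = internal[1], internal[-1]
        if tree.mrca(tree.clade_tips(n1) + tree.clade_tips(n2)) in (n1, n2):
            n2 = internal[-2]
        shifts = [(tree.clade_tips(n1), PieceRates(b=0.3, d=0.05)),
                  (tree.clade_tips(n2), PieceRates(b=0.05, d=0.01))]
        bg = PieceRates(b=0.12, d=0.02)
        total = piecewise_lnl(tree, rich, shifts, bg)

        from shiftscape.bd_models import (_log_psi, _clade_size_terms,
                                          _log_survival)
        assignment = assign_pieces(tree, [n1, n2])
        rates = [bg, shifts[0][1], shifts[1][1]]
        oracle = 0.0
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            rt = rates[assignment[v]]
            stem = float(tree.ages[tree.parent[v]])
            if tree.is_tip(v):
                oracle += _log_survival(rt.b, rt.d, stem)
                oracle += float(_clade_size_terms(
                    rt.b, rt.d, [stem], [rich[tree.labels[v]]])[0])
            else:
                oracle += float(_log_psi(rt.b, rt.d, tree.ages[v], stem))
                oracle += math.log(rt.b)
        assert total == pytest.approx(oracle, abs=1e-8)

    def test_duplicate_shift_nodes_rejected(self, bd_tree_60):
        with pytest.raises(ValueError, match="distinct"):
            assign_pieces(bd_tree_60, [5, 5])


class TestFitPiece:
    def test_multistart_stability(self, yule_tree_50):
        pc = whole_tree_piece(yule_tree_50)
        lnls = [fit_piece(pc, "bd", n_restarts=2, seed=s)[1]
                for s in range(5)]
        assert max(lnls) - min(lnls) < 1e-6

    def test_yule_recovery_within_monte_carlo_error(self):
        """Mean ML b-hat over replicates is within 3 SE of the truth."""
        b_true, reps = 0.2, 200
        ests = []
        for s in range(reps):
            tree = synth.simulate_bd_tree(b_true, 0.0, ("age", 30.0),
                                          seed=3000 + s)
            pc = whole_tree_piece(tree)
            rates, _ = fit_piece(pc, "yule")
            ests.append(rates.b)
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / math.sqrt(reps)
        assert abs(ests.mean() - b_true) < 3 * se

    def test_degenerate_single_tip_piece(self):
        pc = TreePiece(branch_top=np.array([12.0]), branch_bot=np.array([0.0]),
                       n_internal=0, tip_stem_age=np.array([12.0]),
                       tip_richness=np.array([7]))
        rates, lnl = fit_piece(pc, "yule")
        assert lnl <= 0.0
        assert lnl == pytest.approx(
            piece_lnl(pc, rates), abs=1e-9)

    def test_empty_piece_rejected(self):
        empty = TreePiece(branch_top=np.array([]), branch_bot=np.array([]),
                          n_internal=0, tip_stem_age=np.array([]),
                          tip_richness=np.array([], dtype=np.int64))
        with pytest.raises(ValueError):
            fit_piece(empty, "yule")


class TestPropertyInvariants:
    """Parameter-space invariants checked over random rate settings."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(b=st.floats(0.01, 2.0), eps=st.floats(0.0, 3.0),
           t=st.floats(0.01, 80.0))
    def test_clade_size_law_is_a_probability_law(self, b, eps, t):
        d = b * eps
        alpha, beta = geometric_alpha_beta(b, d, t)
        assert 0.0 <= alpha < 1.0
        assert 0.0 <= beta < 1.0
        assert alpha == pytest.approx(beta * eps, abs=1e-9)
        rates = PieceRates(b=b, d=d)
        partial = sum(math.exp(clade_size_lnl(t, n, rates))
                      for n in range(1, 500))
        assert partial <= 1.0 + 1e-9

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(b=st.floats(0.01, 2.0), eps=st.floats(0.0, 3.0),
           s=st.floats(0.0, 40.0), dt=st.floats(1e-3, 40.0))
    def test_branch_factor_is_a_probability(self, b, eps, s, dt):
        """psi(s, t) is the probability of a single observed continuation,
        hence in (0, 1] for every admissible rate setting."""
        from shiftscape.bd_models import _log_psi
        val = float(_log_psi(b, b * eps, s, s + dt))
        assert val <= 1e-9
        assert math.isfinite(val)


class TestInformationCriteria:
    def test_aicc_definition_and_limit(self):
        fit = ModelFit(lnL=-100.0, k=3, n_obs=50)
        assert fit.AIC == pytest.approx(206.0)
        assert fit.AICc == pytest.approx(206.0 + 2 * 3 * 4 / (50 - 4))
        assert fit.AICc >= fit.AIC
        assert aicc(-100.0, 3, 10 ** 9) == pytest.approx(206.0, abs=1e-6)

    def test_aicc_inf_when_underdetermined(self):
        assert math.isinf(aicc(-10.0, 5, 6))
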