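"""Branch-specific models: fitting, LRT machinery, OBSM search, selection."""

import numpy as np
import pytest

from retrosel.branch_models import (
    BranchPartition,
    ModelContext,
    ModelSearchResult,
    NestingError,
    aic,
    chi_square_sf,
    fit_partition,
    fix_model_test,
    free_partition,
    lrt,
    nozawa_flag,
    np_free_ratio,
    np_one_ratio,
    obsm_search,
    one_ratio_partition,
    select_final,
)
from retrosel.codon_model import BranchFit
from retrosel.synthetic_data import SimulationConfig, random_tree, simulate_alignment


class TestNpAccounting:
    def test_one_ratio_and_free_ratio_counts(self):
        # a 12-branch tree: one-ratio np 14, free-ratio np 25
        assert np_one_ratio(12) == 14
        assert np_free_ratio(12) == 25

    @pytest.mark.parametrize("n_branches", [4, 8, 12, 20])
    def test_free_from_one_ratio_relation(self, n_branches):
        assert np_free_ratio(n_branches) == 2 * np_one_ratio(n_branches) - 3

    def test_fitted_np_matches_accounting(self, one_ratio_context):
        ctx = one_ratio_context
        B = ctx.n_branches
        one = fit_partition(None, None, one_ratio_partition(ctx.tree), context=ctx)
        assert one.np == np_one_ratio(B)
        free = fit_partition(
            None, None, free_partition(ctx.tree), context=ctx, init=one
        )
        assert free.np == np_free_ratio(B)


class TestChiSquare:
    def test_df2_equals_exponential_tail(self):
        for x in (0.5, 2.0, 12.0):
            assert chi_square_sf(x, 2) == pytest.approx(np.exp(-x / 2), rel=1e-12)

    def test_printed_tail_values(self):
        assert chi_square_sf(12.00, 2) == pytest.approx(0.0025, abs=5e-5)
        assert chi_square_sf(16.62, 2) == pytest.approx(2.461e-4, rel=2e-3)
        assert chi_square_sf(5.17, 1) == pytest.approx(0.023, abs=5e-4)

    def test_zero_statistic(self):
        assert chi_square_sf(0.0, 1) == 1.0
        assert chi_square_sf(0.0, 5) == 1.0


class TestLrt:
    def test_stat_from_lnl_pair(self):
        stat, p = lrt(-1497.98, -1491.98, df=2)
        assert stat == pytest.approx(12.00, abs=1e-9)
        assert p == pytest.approx(0.0025, abs=5e-5)

    def test_equal_lnls(self):
        assert lrt(-10.0, -10.0, df=1) == (0.0, 1.0)

    def test_small_violation_clamped(self):
        stat, p = lrt(-10.0, -10.0 - 1e-8, df=1)
        assert stat == 0.0 and p == 1.0

    def test_nesting_violation_raises(self):
        with pytest.raises(NestingError):
            lrt(-10.0, -12.0, df=1)


class TestAic:
    def test_arithmetic(self):
        fit = BranchFit(
            lnL=-1000.0, np=14, kappa_hat=2.0, omega_hat={0: 0.3},
            branch_lengths_hat=np.zeros(12), counts={},
        )
        assert aic(fit) == pytest.approx(2028.0)

    def test_lower_aic_preferred_in_selection(self):
        # non-nested candidates with equal lnL: fewer parameters win
        a = _result("I", {0: 0, 1: 1, 2: 0}, lnL=-500.0)
        b = _result("II", {0: 0, 1: 1, 2: 2}, lnL=-500.0)
        assert select_final([a, b]) is a


class TestNozawaFlag:
    @pytest.mark.parametrize(
        "n_n,n_s,expected",
        [(16.0, 0.0, True), (9.0, 0.0, False), (19.5, 7.1, False),
         (10.0, 0.4, True), (10.0, 0.6, False)],
    )
    def test_rule(self, n_n, n_s, expected):
        assert nozawa_flag(n_n, n_s) is expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nozawa_flag(-1.0, 0.0)


def _result(method, mapping, lnL, B=None):
    part = BranchPartition.from_dict(mapping)
    B = B if B is not None else len(mapping)
    fit = BranchFit(
        lnL=lnL,
        np=B + 1 + part.R,
        kappa_hat=2.0,
        omega_hat={c: 0.5 for c in range(part.R)},
        branch_lengths_hat=np.zeros(B),
        counts={},
        extra={"omega_of_class": {c: 0.5 for c in range(part.R)},
               "partition": part},
    )
    return ModelSearchResult(partition=part, fit=fit, method=method,
                             trail=[{"decision": "stub"}])


class TestSelectFinal:
    def test_same_r_higher_lnl_wins(self):
        a = _result("I", {0: 0, 1: 1}, lnL=-1381.523869)
        b = _result("III", {0: 0, 1: 1}, lnL=-1380.484048)
        assert select_final([a, b]) is b

    def test_nested_lrt_prefers_larger_when_significant(self):
        # R=2 within R=3, 2*deltaL = 5.17 -> p = 0.023 < 0.05
        small = _result("I", {0: 0, 1: 1, 2: 1}, lnL=-999.367951)
        big = _result("III", {0: 0, 1: 1, 2: 2}, lnL=-999.367951 + 5.17 / 2)
        assert select_final([small, big]) is big

    def test_nested_lrt_keeps_smaller_when_not_significant(self):
        small = _result("I", {0: 0, 1: 1, 2: 1}, lnL=-1000.0)
        big = _result("III", {0: 0, 1: 1, 2: 2}, lnL=-1000.0 + 0.5)
        assert select_final([small, big]) is small

    def test_identical_results_tie_break_by_method(self):
        a = _result("I", {0: 0, 1: 1}, lnL=-100.0)
        b = _result("III", {0: 0, 1: 1}, lnL=-100.0)
        assert select_final([a, b]) is b  # method order III > II > I

    def test_empty_input(self):
        with pytest.raises(ValueError):
            select_final([])


class TestFitNesting:
    def test_lnl_monotone_in_refinement(self, one_ratio_context, one_ratio_dataset):
        ctx = one_ratio_context
        _, tree, _ = one_ratio_dataset
        one = fit_partition(None, None, one_ratio_partition(tree), context=ctx)
        # a two-class partition refining one-ratio
        mapping = {b.branch_id: 0 for b in tree.branches}
        mapping[tree.branches[0].branch_id] = 1
        two = fit_partition(
            None, None, BranchPartition.from_dict(mapping), context=ctx, init=one
        )
        free = fit_partition(
            None, None, free_partition(tree), context=ctx, init=two
        )
        assert one.lnL <= two.lnL + 1e-6
        assert two.lnL <= free.lnL + 1e-6

    def test_fixed_omega_never_beats_free(self, one_ratio_context):
        ctx = one_ratio_context
        part = one_ratio_partition(ctx.tree)
        free = fit_partition(None, None, part, context=ctx)
        pinned = fit_partition(
            None, None, part, fixed_omega={0: 1.0}, context=ctx, init=free
        )
        assert pinned.lnL <= free.lnL + 1e-6
        assert pinned.np == free.np - 1


class TestFixModelTest:
    def test_fixing_class_near_one_gives_near_zero_stat(self):
        # data simulated neutrally: pinning omega = 1 costs almost nothing
        rng = np.random.default_rng(31)
        tree = random_tree(5, rng)
        aln, _ = simulate_alignment(
            SimulationConfig(
                tree=tree, n_codons=400,
                omega_scheme={"type": "one_ratio", "omega": 1.0}, seed=8,
            )
        )
        ctx = ModelContext(aln, tree)
        part = one_ratio_partition(tree)
        stat, p, _ = fix_model_test(None, None, part, [0], context=ctx)
        assert stat < 2.0
        assert p > 0.1

    def test_unknown_class_rejected(self, one_ratio_context):
        with pytest.raises(ValueError):
            fix_model_test(
                None, None, one_ratio_partition(one_ratio_context.tree), [5],
                context=one_ratio_context,
            )


class TestObsmSearch:
    def test_trail_ends_at_final_and_lnl_non_decreasing(self, two_class_dataset):
        aln, tree, truth = two_class_dataset
        ctx = ModelContext(aln, tree)
        res = obsm_search(None, None, "I", context=ctx)
        assert res.trail[-1]["decision"] == "final"
        assert res.trail[-1]["partition"] == res.partition
        accepted = [
            e["lnL"] for e in res.trail
            if e["decision"].startswith(("one-ratio", "split"))
        ]
        assert all(b >= a - 1e-9 for a, b in zip(accepted, accepted[1:]))

    def test_isolates_planted_branch(self, two_class_dataset):
        aln, tree, truth = two_class_dataset
        ctx = ModelContext(aln, tree)
        res = obsm_search(None, None, "III", context=ctx)
        target = truth["target_branch"]
        cls = res.partition.as_dict()[target]
        assert res.fit.omega_hat[cls] > 1.0
        assert res.partition.members(cls) == [target]

    def test_unknown_method(self, one_ratio_context):
        with pytest.raises(ValueError):
            obsm_search(None, None, "IV", context=one_ratio_context)


class TestMethodINullCalibration:
    def test_false_split_rate_within_alpha_plus_margin(self):
        """Under one-ratio data, greedy splitting accepts a split in at
        most alpha + 5 percentage points of replicates (20 seeds)."""
        false_splits = 0
        for seed in range(20):
            rng = np.random.default_rng(9000 + seed)
            tree = random_tree(6, rng)
            aln, _ = simulate_alignment(
                SimulationConfig(
                    tree=tree, n_codons=300,
                    omega_scheme={"type": "one_ratio", "omega": 0.3},
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
            ctx = ModelContext(aln, tree)
            res = obsm_search(None, None, "I", context=ctx)
            false_splits += res.partition.R > 1
        assert false_splits / 20 <= 0.05 + 0.05 + 1e-9
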