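"""Behavioral statistics on constructed trial tables (no simulation)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wagernet.analysis import (
    AnalysisParams,
    bootstrap_error_counts,
    conditional_sure_map,
    dt_split,
    psychometrics,
    rate_distributions,
    reward_amount,
    reward_from_trials,
    sure_probability_projections,
    wilson_interval,
    xpattern_probabilistic,
    xpattern_simulated,
)
from conftest import make_trial_table


class TestPsychometrics:
    def test_all_correct_forced(self):
        t = make_trial_table(free_choice=np.zeros(40, dtype=bool))
        out = psychometrics(t)
        assert out.p_correct_forced.iloc[0] == 1.0
        assert np.isnan(out.p_sure.iloc[0])

    def test_sure_fraction_and_waived_accuracy(self):
        final = ["S"] * 10 + ["L"] * 25 + ["R"] * 5
        t = make_trial_table(final_choice=final,
                             correct=[c == "L" for c in final])
        out = psychometrics(t)
        assert out.p_sure.iloc[0] == pytest.approx(0.25)
        assert out.p_correct_waived.iloc[0] == pytest.approx(25 / 30)
        assert out.ci_sure_lo.iloc[0] < 0.25 < out.ci_sure_hi.iloc[0]

    def test_undecided_excluded_from_denominators(self):
        final = ["L"] * 8 + ["undecided"] * 2
        t = make_trial_table(final_choice=final,
                             free_choice=np.zeros(10, dtype=bool),
                             correct=[c == "L" for c in final])
        out = psychometrics(t)
        assert out.n_forced.iloc[0] == 8
        assert out.p_correct_forced.iloc[0] == 1.0


class TestWilson:
    def test_interval_contains_proportion(self):
        lo, hi = wilson_interval(7, 20)
        assert lo < 0.35 < hi

    def test_degenerate(self):
        assert np.isnan(wilson_interval(0, 0)[0])
        lo, hi = wilson_interval(0, 10)
        assert lo == 0.0 and hi > 0.0


class TestConditionalSureMap:
    def _table_with_rule(self, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        rl = rng.uniform(0.0, 30.0, n)
        rr = rng.uniform(0.0, 30.0, n)
        sure = np.maximum(rl, rr) < 10.0
        final = np.where(sure, "S", "L")
        return make_trial_table(rate_L=rl, rate_R=rr, final_choice=final,
                                correct=np.ones(n, dtype=bool),
                                seed=np.arange(n))

    def test_constructed_max_rule(self):
        m = conditional_sure_map(self._table_with_rule(),
                                 AnalysisParams(low_count=1))
        below = m[(m.nu_L < 9.5) & (m.nu_R < 9.5)]
        above = m[(m.nu_L > 10.5) | (m.nu_R > 10.5)]
        assert np.all(below.p_sure == 1.0)
        assert np.all(above.p_sure == 0.0)

    def test_low_count_mask_boundary(self):
        rl = np.concatenate([np.full(29, 5.3), np.full(30, 7.3)])
        t = make_trial_table(rate_L=rl, rate_R=np.full(59, 5.5),
                             final_choice=["S"] * 59,
                             correct=np.zeros(59, dtype=bool))
        m = conditional_sure_map(t).sort_values("nu_L")
        assert m.low_count_mask.tolist() == [True, False]


class TestProjections:
    def test_always_sure_flat_curves(self):
        rng = np.random.default_rng(3)
        n = 500
        t = make_trial_table(rate_L=rng.uniform(0, 30, n),
                             rate_R=rng.uniform(0, 30, n),
                             final_choice=["S"] * n)
        curves = sure_probability_projections(t)
        for curve in curves.values():
            assert np.all(curve.one_minus_p_sure == 0.0)

    def test_difference_only_rule_is_monotone_in_difference(self):
        rng = np.random.default_rng(4)
        n = 6000
        rl = rng.uniform(0, 30, n)
        rr = rng.uniform(0, 30, n)
        p_sure = 1.0 / (1.0 + np.exp((np.abs(rl - rr) - 8.0)))
        final = np.where(rng.random(n) < p_sure, "S", "L")
        t = make_trial_table(rate_L=rl, rate_R=rr, final_choice=final)
        curves = sure_probability_projections(t)
        assert curves["abs_diff"].attrs["isotonic_residual"] < 0.05


class TestDtSplit:
    def test_bimodal_split_between_clusters(self):
        rng = np.random.default_rng(5)
        dts = np.concatenate([rng.normal(250, 40, 400),
                              rng.normal(1100, 120, 300)])
        t = make_trial_table(decision_time=np.clip(dts, 1.0, None))
        split, fast, slow, no_dip = dt_split(t)
        assert 350.0 < split < 950.0  # inside the between-cluster valley
        assert not no_dip
        assert len(fast) + len(slow) == len(t)
        assert fast.decision_time.max() < split <= slow.decision_time.min()

    def test_unimodal_histogram_flagged(self):
        rng = np.random.default_rng(6)
        dts = rng.gamma(4.0, 60.0, 800)  # single left-skewed mode
        t = make_trial_table(decision_time=np.clip(dts, 1.0, None))
        _, _, _, no_dip = dt_split(t)
        assert no_dip

    def test_no_decided_trials_rejected(self):
        t = make_trial_table(decision_time=[np.nan] * 5)
        with pytest.raises(ValueError):
            dt_split(t)


class TestBootstrapErrors:
    def test_identical_sets_non_significant(self):
        rng = np.random.default_rng(7)
        correct = rng.random(300) < 0.8
        t = make_trial_table(correct=correct, seed=np.arange(300))
        boot = bootstrap_error_counts(t, t.copy(), B=2000, seed=1)
        assert boot["p_value"] > 0.05 or abs(
            boot["fast"].mean() - boot["slow"].mean()) < 2.0

    def test_doubled_error_rate_detected(self):
        rng = np.random.default_rng(8)
        fast = make_trial_table(correct=rng.random(500) < 0.9,
                                seed=np.arange(500))
        slow = make_trial_table(correct=rng.random(500) < 0.8,
                                seed=np.arange(500))
        boot = bootstrap_error_counts(fast, slow, B=2000, seed=2)
        assert boot["slow"].mean() > boot["fast"].mean()
        assert boot["p_value"] < 1e-10

    def test_empty_set_rejected(self):
        t = make_trial_table(correct=[True])
        with pytest.raises(ValueError):
            bootstrap_error_counts(t.iloc[:0], t, B=10)


class TestXPattern:
    def test_probabilistic_identities(self):
        # no sure choices: P(C|S̄) = P(C) and both conditionals vanish
        psc, pse = xpattern_probabilistic(0.7, 0.0, 0.7)
        assert psc == pytest.approx(0.0, abs=1e-12)
        assert pse == pytest.approx(0.0, abs=1e-12)
        # independence: P(C|S̄) = P(C) implies P(S|C) = P(S) = P(S|E)
        psc, pse = xpattern_probabilistic(0.7, 0.3, 0.7)
        assert psc == pytest.approx(0.3, abs=1e-12)
        assert pse == pytest.approx(0.3, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.05, 0.95), st.floats(0.0, 0.9), st.floats(0.0, 1.0))
    def test_total_probability_recovered(self, p_c, p_s, u):
        """P(S|C) P(C) + P(S|E) P(E) = P(S) to 1e-12 for any valid
        combination (P(C|S̄) chosen so both conditionals stay in
        range)."""
        # P(C|S̄) must keep P(S|C), P(S|E) within [0, 1]
        p_sbar = 1.0 - p_s
        lo = max(0.0, (p_c - p_s) / p_sbar) if p_sbar > 0 else p_c
        hi = min(1.0, p_c / p_sbar) if p_sbar > 0 else p_c
        p_cw = lo + u * (hi - lo)
        psc, pse = xpattern_probabilistic(p_c, p_s, p_cw)
        total = psc * p_c + pse * (1.0 - p_c)
        assert total == pytest.approx(p_s, abs=1e-12)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            xpattern_probabilistic(1.2, 0.1, 0.5)

    def test_simulated_conditionals(self):
        early = ["L"] * 60 + ["R"] * 40
        final = (["S"] * 10 + ["L"] * 50) + (["S"] * 20 + ["R"] * 20)
        t = make_trial_table(early_choice=early, final_choice=final)
        out = xpattern_simulated(t)
        assert out.p_sure_correct.iloc[0] == pytest.approx(10 / 60)
        assert out.p_sure_error.iloc[0] == pytest.approx(20 / 40)


class TestReward:
    def test_no_sure_choices(self):
        assert reward_amount(0.75, 0.0) == 0.75

    def test_linear_in_sure_value(self):
        base = reward_amount(0.6, 0.4, w_S=0.8)
        high = reward_amount(0.6, 0.4, w_S=1.1)
        assert high - base == pytest.approx(0.3 * 0.4)

    def test_per_trial_accumulation_matches_closed_form(self):
        final = ["S"] * 25 + ["L"] * 60 + ["R"] * 15
        t = make_trial_table(final_choice=final,
                             correct=[c == "L" for c in final])
        got = reward_from_trials(t, w_S=0.8)
        assert got == pytest.approx(0.25 * 0.8 + 0.60 * 1.0)


class TestRateDistributions:
    def test_symmetric_table_no_diagonal_asymmetry(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 30, 2000)
        b = rng.uniform(0, 30, 2000)
        t = make_trial_table(rate_L=np.concatenate([a, b]),
                             rate_R=np.concatenate([b, a]),
                             seed=np.arange(4000))
        out = rate_distributions(t)
        assert abs(out.diag_asymmetry.iloc[0]) < 0.05
        assert out.prob.sum() == pytest.approx(1.0)

    def test_early_errors_nearer_diagonal(self):
        n = 400
        rng = np.random.default_rng(10)
        rl_c = rng.uniform(15, 30, n)
        rr_c = rng.uniform(0, 8, n)
        rl_e = rng.uniform(8, 14, n)
        rr_e = rng.uniform(8, 14, n)
        t = make_trial_table(
            rate_L=np.concatenate([rl_c, rl_e]),
            rate_R=np.concatenate([rr_c, rr_e]),
            early_choice=["L"] * n + ["R"] * n,
            seed=np.arange(2 * n))
        out = rate_distributions(t, grouping=["early_correct"])
        by = out.groupby("early_correct").mean_abs_diff.first()
        assert by[False] < by[True]
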