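from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from conftest import make_segment, uniform_genome
from oracles import fisher_2x2_closed_form, wilcoxon_enumeration
from ploidyclock import (
    arm_frequency_comparison,
    call_arm_events,
    count_high_breakage,
    fisher_exact,
    wilcoxon_rank_sum,
)
from ploidyclock.cohort_stats import merge_adjacent_segments
from ploidyclock.genome import arm_intervals, chrom_lengths


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == 1.0

    def test_diagonal_table_vs_enumeration(self):
        res = fisher_exact([[10, 0], [0, 10]])
        assert res.p_value == pytest.approx(2 / 184756, rel=1e-12)
        assert res.p_value == pytest.approx(fisher_2x2_closed_form([[10, 0], [0, 10]]),
                                            rel=1e-12)

    @given(st.lists(st.integers(min_value=0, max_value=15), min_size=4, max_size=4))
    @settings(max_examples=60, deadline=None)
    def test_transpose_symmetry(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        transposed = [[a, c], [b, d]]
        assert fisher_exact(table).p_value == pytest.approx(
            fisher_exact(transposed).p_value, rel=1e-12
        )

    def test_matches_scipy_2x2(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            t = rng.integers(0, 20, size=(2, 2))
            assert fisher_exact(t).p_value == pytest.approx(
                sps.fisher_exact(t)[1], abs=1e-12
            )

    def test_odds_ratio(self):
        assert fisher_exact([[8, 2], [1, 5]]).odds_ratio == pytest.approx(20.0)
        assert fisher_exact([[8, 0], [0, 5]]).odds_ratio == np.inf

    def test_rxc_enumeration_method_recorded(self):
        res = fisher_exact([[5, 2, 3], [1, 6, 2]])
        assert res.method == "exact_enumeration"

    def test_rxc_monte_carlo_close_to_enumeration(self):
        table = [[5, 2, 3], [1, 6, 2]]
        exact = fisher_exact(table).p_value
        mc = fisher_exact(table, enumeration_cap=1)  # force Monte Carlo
        assert mc.method == "monte_carlo"
        se = np.sqrt(exact * (1 - exact) / mc.n_permutations)
        assert abs(mc.p_value - exact) <= 3 * se

    def test_large_table_uses_monte_carlo(self):
        table = [[80, 60, 40], [50, 70, 90]]  # total 390 > 200
        res = fisher_exact(table, seed=7)
        assert res.method == "monte_carlo"
        assert res.seed == 7 and res.n_permutations == 100_000

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])

    def test_3x2_against_r_convention(self):
        # 3x2 enumeration agrees with scipy's 2x2 on a collapsed sanity case
        res = fisher_exact([[10, 1], [2, 8], [3, 3]])
        assert 0.0 < res.p_value < 0.05


class TestWilcoxon:
    def test_identical_samples(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value > 0.9

    def test_extreme_separation_matches_enumeration(self):
        x, y = [1, 2, 3], [10, 11, 12]
        res = wilcoxon_rank_sum(x, y)
        assert res.method == "exact_enumeration"
        assert res.p_value == pytest.approx(wilcoxon_enumeration(x, y), abs=1e-12)
        assert res.p_value == pytest.approx(0.1)

    def test_random_cases_match_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n1, n2 = rng.integers(2, 7, size=2)
            values = rng.permutation(1000)[: n1 + n2].astype(float)
            x, y = values[:n1], values[n1:]
            assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
                wilcoxon_enumeration(x, y), abs=1e-12
            )

    def test_shift_invariance(self):
        x = [3.0, 5.0, 9.0, 11.0]
        y = [1.0, 2.0, 7.0]
        assert wilcoxon_rank_sum(x, y).p_value == wilcoxon_rank_sum(
            [v + 100 for v in x], [v + 100 for v in y]
        ).p_value

    def test_normal_approximation_with_ties(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(1, 6, 30).astype(float)
        res = wilcoxon_rank_sum(x, y)
        assert res.method == "normal_approximation"
        ref = sps.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert res.p_value == pytest.approx(ref, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestArmEvents:
    def test_whole_15q_loss_in_diploid(self):
        lengths = chrom_lengths()
        _, q_start, q_end = arm_intervals()["15q"]
        segs = [
            make_segment(chrom=c, start=1, end=lengths[c], n_major=1, n_minor=1)
            for c in lengths
            if c != "15"
        ]
        segs += [
            make_segment(chrom="15", start=1, end=q_start - 1, n_major=1, n_minor=1),
            make_segment(chrom="15", start=q_start, end=q_end, n_major=1, n_minor=0),
        ]
        events = {e.arm: e for e in call_arm_events(segs, gd=False)}
        assert events["15q"].call == "loss"
        assert events["15q"].supporting_fraction == pytest.approx(1.0)
        assert events["15p"].call == "neutral"

    def test_gd_baseline_gain(self):
        lengths = chrom_lengths()
        _, q_start, _ = arm_intervals()["19q"]
        segs = [
            make_segment(chrom=c, start=1, end=lengths[c], n_major=2, n_minor=2)
            for c in lengths
            if c != "19"
        ]
        segs += [
            make_segment(chrom="19", start=1, end=q_start - 1, n_major=3, n_minor=2),
            make_segment(chrom="19", start=q_start, end=lengths["19"], n_major=2, n_minor=2),
        ]
        events = {e.arm: e for e in call_arm_events(segs, gd=True)}
        assert events["19p"].call == "gain"
        assert events["19q"].call == "neutral"

    def test_below_half_is_neutral(self):
        lengths = chrom_lengths()
        p_len = arm_intervals()["1p"][2]
        cut = 1 + int(0.4 * p_len)
        segs = [
            make_segment(chrom="1", start=1, end=cut, n_major=1, n_minor=0),
            make_segment(chrom="1", start=cut + 1, end=lengths["1"], n_major=1, n_minor=1),
        ]
        events = {e.arm: e for e in call_arm_events(segs, gd=False)}
        assert events["1p"].call == "neutral"

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError):
            call_arm_events([make_segment(chrom="MT")], gd=False)


class TestArmFrequencyComparison:
    @staticmethod
    def _events(sample_id, lost_arms):
        from ploidyclock.cohort_stats import ArmEvent

        return [
            ArmEvent(sample_id, arm, "loss" if arm in lost_arms else "neutral", 1.0)
            for arm in arm_intervals()
        ]

    def test_bonferroni_multiplication(self):
        events = {}
        groups = {}
        rng = np.random.default_rng(0)
        for i in range(40):
            sample_id = f"S{i}"
            group = "A" if i < 20 else "B"
            lost = {"15q"} if (group == "A" and rng.random() < 0.7) else set()
            events[sample_id] = self._events(sample_id, lost)
            groups[sample_id] = group
        results = arm_frequency_comparison(events, groups)
        n_tests = len(results)
        assert n_tests == len(arm_intervals()) * 2
        for r in results:
            assert r.p_corrected == pytest.approx(min(1.0, r.result.p_value * n_tests))
            assert r.p_corrected >= r.result.p_value

    def test_single_group_rejected(self):
        events = {"S1": self._events("S1", set())}
        with pytest.raises(ValueError):
            arm_frequency_comparison(events, {"S1": "A"})


class TestHighBreakage:
    def test_one_segment_per_chromosome(self):
        assert count_high_breakage(uniform_genome((1, 1))).high_breakage_count == 0

    def test_fragmented_chromosome_counted(self):
        lengths = chrom_lengths()
        segs = [
            make_segment(chrom=c, start=1, end=lengths[c]) for c in lengths if c != "1"
        ]
        bounds = np.linspace(1, lengths["1"] + 1, 16, dtype=int)
        for i in range(15):
            # alternate states so adjacency merging keeps all 15 pieces
            state = (2, 1) if i % 2 else (1, 1)
            segs.append(
                make_segment(chrom="1", start=int(bounds[i]), end=int(bounds[i + 1]) - 1,
                             n_major=state[0], n_minor=state[1])
            )
        summary = count_high_breakage(segs, k=10)
        assert summary.breakpoints["1"] == 14
        assert summary.high_breakage_count == 1

    def test_k_boundary(self):
        segs = [
            make_segment(chrom="1", start=1, end=100, n_major=1, n_minor=1),
            make_segment(chrom="1", start=101, end=200, n_major=2, n_minor=1),
        ]
        assert count_high_breakage(segs, k=1).high_breakage_count == 1
        assert count_high_breakage(segs, k=2).high_breakage_count == 0

    def test_order_invariance(self):
        segs = [
            make_segment(chrom="1", start=101, end=200, n_major=2, n_minor=1),
            make_segment(chrom="1", start=1, end=100, n_major=1, n_minor=1),
            make_segment(chrom="2", start=1, end=50, n_major=1, n_minor=1),
        ]
        assert (
            count_high_breakage(segs).breakpoints
            == count_high_breakage(list(reversed(segs))).breakpoints
        )

    def test_split_identical_segment_merged(self):
        whole = [make_segment(chrom="1", start=1, end=1000, n_major=2, n_minor=1)]
        split = [
            make_segment(chrom="1", start=1, end=400, n_major=2, n_minor=1),
            make_segment(chrom="1", start=401, end=1000, n_major=2, n_minor=1),
        ]
        assert (
            count_high_breakage(whole).breakpoints
            == count_high_breakage(split).breakpoints
        )
        merged = merge_adjacent_segments(split)
        assert len(merged) == 1 and merged[0].end == 1000
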