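"""Selectivity classification, tuning pooling, overlap and error statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from numcrow import selectivity
from numcrow.selectivity import (
    Epoch,
    SelectivityResult,
    chance_overlap_percent,
    classify_selectivity,
    epoch_rate,
    epoch_windows,
    error_trial_comparison,
    normalize_and_pool,
    overlap_binomial_test,
    preferred_correlation,
)
from numcrow.stimgen import gen_sequential_equal_item


class TestEpochRates:
    def test_rate_is_count_over_window(self):
        spikes = np.linspace(150.0, 850.0, 8)
        assert epoch_rate(spikes, [(100.0, 900.0)]) == pytest.approx(10.0)

    def test_seq_windows_from_items(self):
        # two 400 ms items -> two windows of 400 ms each, 800 ms total
        timing = gen_sequential_equal_item(2, 400.0)
        row = pd.Series({"sample_on": 500.0, "delay_on": 2700.0})
        windows = epoch_windows(row, Epoch.SAMPLE_SEQ, timing)
        assert len(windows) == 2
        total = sum(b - a for a, b in windows)
        assert total == pytest.approx(800.0)
        # shifted 100 ms after item onsets
        assert windows[0][0] == pytest.approx(600.0)

    def test_seq_item_window_capped_at_800(self):
        timing = gen_sequential_equal_item(1, 900.0)
        row = pd.Series({"sample_on": 500.0})
        a, b = epoch_windows(row, Epoch.SAMPLE_SEQ, timing)[0]
        assert b - a == pytest.approx(800.0)

    def test_delay_window_overhangs_offset(self):
        row = pd.Series({"delay_on": 3125.0})
        (a, b) = epoch_windows(row, Epoch.DELAY)[0]
        assert a == pytest.approx(3725.0)
        assert b == pytest.approx(4225.0)  # 100 ms past the 1000 ms delay end


class TestClassification:
    def test_ground_truth_recovery(self, dataset, sel_table):
        gt = dataset.neuron_frame()
        merged = sel_table.merge(gt, on="neuron_id", suffixes=("_rec", "_true"))
        for pop, epoch in [
            ("seq_sample", "sample_seq"),
            ("sim_sample", "sample_sim"),
            ("delay_num", "delay"),
        ]:
            sub = merged[(merged["population"] == pop) & (merged["epoch"] == epoch)]
            hit = (
                sub["selective"]
                & (sub["preferred_numerosity_rec"] == sub["preferred_numerosity_true"])
            ).mean()
            assert hit >= 0.9, f"{pop} recovery {hit:.2f}"

    def test_sample_populations_are_format_specific(self, dataset, sel_table):
        gt = dataset.neuron_frame()
        merged = sel_table.merge(gt, on="neuron_id")
        seq_in_sim = merged[
            (merged["population"] == "seq_sample") & (merged["epoch"] == "sample_sim")
        ]["selective"]
        assert seq_in_sim.mean() <= 0.1

    def test_constant_rates_not_selective(self):
        rates = pd.DataFrame(
            {
                "rate": np.full(48, 6.0),
                "numerosity": np.tile([1, 2, 3, 4], 12),
                "protocol": np.repeat(["standard", "control"], 24),
                "format": "seq",
            }
        )
        res = classify_selectivity(rates, Epoch.SAMPLE_SEQ)
        assert res.p_numerosity == pytest.approx(1.0)
        assert not res.selective

    def test_delay_excludes_seq_standard_one(self, dataset):
        trials = selectivity._epoch_trials(dataset, Epoch.DELAY)
        bad = trials[
            (trials["format"] == "seq")
            & (trials["protocol"] == "standard")
            & (trials["sample_numerosity"] == 1)
        ]
        assert len(bad) == 0

    def test_venn_counts_consistent(self, sel_table):
        piv = sel_table.pivot(index="neuron_id", columns="epoch", values="selective")
        n_seq = int(piv["sample_seq"].sum())
        n_sim = int(piv["sample_sim"].sum())
        both = int((piv["sample_seq"].astype(bool) & piv["sample_sim"].astype(bool)).sum())
        assert both <= min(n_seq, n_sim)


class TestTuningCurves:
    def test_minmax_normalization(self):
        res = SelectivityResult(
            0, Epoch.SAMPLE_SEQ, True, 0.001, 0.5, 0.5, True, 2,
            np.array([2.0, 10.0, 6.0, 4.0]),
        )
        (curve,) = normalize_and_pool([res])
        np.testing.assert_allclose(curve.normalized, [0.0, 1.0, 0.5, 0.25])
        assert curve.n_neurons == 1

    def test_flat_tuning_skipped(self):
        res = SelectivityResult(
            0, Epoch.SAMPLE_SEQ, True, 0.001, 0.5, 0.5, True, 2, np.full(4, 3.0)
        )
        with pytest.warns(UserWarning):
            assert normalize_and_pool([res]) == []

    def test_pooled_curves_decline_from_peak(self, dataset, sel_table):
        gt = dataset.neuron_frame()
        results = []
        for _, row in sel_table[(sel_table["epoch"] == "delay") & sel_table["selective"]].iterrows():
            results.append(
                SelectivityResult(
                    int(row["neuron_id"]), Epoch.DELAY, True,
                    row["p_numerosity"], row["p_cofactor"], row["p_interaction"],
                    True, int(row["preferred_numerosity"]),
                    np.array([row[f"rate_n{n}"] for n in (1, 2, 3, 4)]),
                )
            )
        curves = normalize_and_pool(results)
        assert curves
        for c in curves:
            vals = c.normalized
            peak = c.preferred_numerosity - 1
            assert vals[peak] == pytest.approx(1.0)
            # monotone decline on each side of the peak
            left = vals[: peak + 1]
            right = vals[peak:]
            assert np.all(np.diff(left) >= -1e-9)
            assert np.all(np.diff(right) <= 1e-9)


class TestOverlapStatistics:
    def test_worked_example(self):
        assert chance_overlap_percent(64, 45, 376) == pytest.approx(2.04, abs=0.005)

    def test_edge_cases(self):
        assert chance_overlap_percent(0, 45, 376) == 0.0
        assert chance_overlap_percent(376, 376, 376) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            chance_overlap_percent(1, 1, 0)

    def test_symmetry_and_homogeneity(self):
        assert chance_overlap_percent(64, 45, 376) == chance_overlap_percent(45, 64, 376)
        assert chance_overlap_percent(64, 45, 376) == pytest.approx(
            chance_overlap_percent(128, 90, 752)
        )

    def test_binomial_tail_worked_example(self):
        p0 = (64 / 376) * (45 / 376)
        p = overlap_binomial_test(13, 376, p0)
        assert p == pytest.approx(0.047, abs=0.001)

    def test_binomial_tail_edges(self):
        assert overlap_binomial_test(0, 376, 0.02) == pytest.approx(1.0)
        assert overlap_binomial_test(10, 10, 0.5) == pytest.approx(0.5**10)


class TestPreferredCorrelation:
    def test_perfect_and_reversed(self, rng):
        rho, _ = preferred_correlation([1, 2, 3, 4, 1, 2], [1, 2, 3, 4, 1, 2], 200, rng)
        assert rho == pytest.approx(1.0)
        rho, _ = preferred_correlation([1, 2, 3, 4], [4, 3, 2, 1], 200, rng)
        assert rho == pytest.approx(-1.0)

    def test_matches_brute_force_ranks(self, rng):
        # tie-laden 13-pair set on a 4-level scale
        a = np.array([1, 1, 2, 2, 2, 3, 3, 3, 3, 4, 4, 1, 2])
        b = np.array([2, 1, 2, 3, 1, 3, 4, 2, 3, 4, 4, 3, 1])

        def average_ranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x), dtype=float)
            sx = x[order]
            i = 0
            while i < len(x):
                j = i
                while j < len(x) and sx[j] == sx[i]:
                    j += 1
                ranks[order[i:j]] = (i + j - 1) / 2.0 + 1.0
                i = j
            return ranks

        ra, rb = average_ranks(a), average_ranks(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        rho, p = preferred_correlation(a, b, 2000, rng)
        assert rho == pytest.approx(expected)
        assert 0.0 < p <= 1.0

    def test_too_few_pairs(self, rng):
        with pytest.raises(ValueError):
            preferred_correlation([1, 2], [2, 1], 100, rng)


class TestErrorTrials:
    def test_wilcoxon_statistic_hand_computed(self):
        # pairs (10,8), (12,9), (9,9): zero difference dropped; both remaining
        # differences positive with ranks 1 and 2 -> negative-rank sum 0
        res = stats.wilcoxon([10, 12, 9], [8, 9, 9])
        assert res.statistic == 0.0

    def test_corruption_reduces_preferred_rates(self, dataset, sel_table):
        results = []
        for _, row in sel_table[
            (sel_table["epoch"] == "sample_seq") & sel_table["selective"]
        ].iterrows():
            results.append(
                SelectivityResult(
                    int(row["neuron_id"]), Epoch.SAMPLE_SEQ, True, 0, 1, 1, True,
                    int(row["preferred_numerosity"]),
                    np.array([row[f"rate_n{n}"] for n in (1, 2, 3, 4)]),
                )
            )
        level, p, n = error_trial_comparison(dataset, results, Epoch.SAMPLE_SEQ)
        assert n >= 5
        assert level < 100.0
        assert p < 0.05
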