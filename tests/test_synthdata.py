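"""Simulator ground truth: tuning, behavior model, rate profiles, spiking."""

import math

import numpy as np
import pytest
from scipy import stats

from numcrow import stimgen
from numcrow.stimgen import Format, gen_session
from numcrow.synthdata import (
    BehaviorParams,
    NeuronSpec,
    Population,
    SimConfig,
    build_dataset,
    make_neuron_specs,
    rate_profile,
    simulate_behavior,
    simulate_choice,
    simulate_spikes,
    tuning_value,
)


class TestTuning:
    def test_peak_at_preferred(self):
        assert tuning_value(2, 2, 0.5) == pytest.approx(1.0)

    def test_log_symmetry(self):
        # preferred 2: numerosities 1 and 4 are one octave away on each side
        assert tuning_value(2, 1, 1.0) == pytest.approx(tuning_value(2, 4, 1.0))

    def test_two_octave_value(self):
        assert tuning_value(1, 4, 1.0) == pytest.approx(math.exp(-2.0))

    def test_size_effect_on_linear_scale(self):
        # fixed linear distance of 1: tuning falls off less at larger preferred
        drop_small = tuning_value(1, 2, 0.5)
        drop_large = tuning_value(3, 4, 0.5)
        assert drop_large > drop_small

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            tuning_value(2, 2, 0.0)


class TestChoiceModel:
    def test_noise_free_limit_all_correct(self, rng):
        params = BehaviorParams(weber_w=1e-6, lapse_rate=0.0)
        for sample in (1, 2, 3, 4):
            for test in (1, 2, 3, 4):
                _, correct, est = simulate_choice(sample, test, sample == test, params, rng)
                assert correct
                assert est == sample

    def test_match_probability_decreases_with_noise(self, rng):
        def p_match(w):
            params = BehaviorParams(weber_w=w, lapse_rate=0.0)
            hits = sum(
                simulate_choice(3, 3, True, params, rng)[0].value == "test1"
                for _ in range(2000)
            )
            return hits / 2000

        assert p_match(0.1) > p_match(0.5) > p_match(1.5)

    def test_size_effect_closed_form_and_simulation(self, rng):
        # Gaussian overlap on the log axis: 3 vs 4 (0.415 octaves) is harder
        # than 1 vs 2 (1 octave) at equal Weber width.
        w = 0.35
        z12 = (math.log2(2) - math.log2(1)) / 2 / w
        z34 = (math.log2(4) - math.log2(3)) / 2 / w
        assert stats.norm.cdf(z34) < stats.norm.cdf(z12)
        params = BehaviorParams(weber_w=w, lapse_rate=0.0)

        def discrimination(sample, foil):
            n = 5000
            correct = 0
            for i in range(n):
                s, f = (sample, foil) if i % 2 else (foil, sample)
                correct += simulate_choice(s, f, False, params, rng)[1]
            return correct / n

        assert discrimination(3, 4) < discrimination(1, 2)

    def test_error_rate_increases_with_weber_w(self, rng):
        rates = []
        for w in (0.2, 0.5, 1.0):
            trials = [t for t in gen_session(4, np.random.default_rng(0)).trials]
            simulate_behavior(trials, BehaviorParams(weber_w=w, lapse_rate=0.0), rng)
            rates.append(np.mean([not t.correct for t in trials]))
        assert rates[0] < rates[1] < rates[2]

    def test_param_validation(self):
        with pytest.raises(ValueError):
            BehaviorParams(weber_w=0.0)
        with pytest.raises(ValueError):
            BehaviorParams(lapse_rate=0.6)


def _spec(pop, preferred=2, baseline=5.0, gain=10.0, amp=8.0):
    return NeuronSpec(0, pop, preferred if pop not in (Population.FORMAT_ONLY, Population.NONSEL) else None,
                      baseline, gain, 0.45, amp, 100.0)


def _one_trial(fmt, rng, numerosity=2):
    session = gen_session(1, rng)
    for t in session.trials:
        if t.format is fmt and t.sample_numerosity == numerosity and t.is_match:
            t.correct = True
            t.estimated_numerosity = numerosity
            return t, session.timings.get(t.trial_id)
    raise AssertionError("condition not found")


def _mean_rate(edges, rates, t0, t1):
    total = 0.0
    for i in range(len(rates)):
        lo, hi = max(edges[i], t0), min(edges[i + 1], t1)
        if hi > lo:
            total += rates[i] * (hi - lo)
    return total / (t1 - t0)


class TestRateProfiles:
    def test_nonsel_flat(self, rng):
        cfg = SimConfig()
        trial, timing = _one_trial(Format.SEQ, rng)
        edges, rates = rate_profile(_spec(Population.NONSEL), trial, timing, cfg)
        assert np.all(rates == rates[0])

    def test_seq_neuron_silent_on_sim_trial(self, rng):
        cfg = SimConfig()
        trial, timing = _one_trial(Format.SIM, rng)
        edges, rates = rate_profile(_spec(Population.SEQ_SAMPLE), trial, timing, cfg)
        assert np.all(rates == rates[0])

    def test_seq_neuron_modulated_during_items_only(self, rng):
        cfg = SimConfig()
        trial, timing = _one_trial(Format.SEQ, rng)
        spec = _spec(Population.SEQ_SAMPLE, preferred=2)
        edges, rates = rate_profile(spec, trial, timing, cfg)
        on = timing.item_onsets(trial.sample_on) + spec.latency_ms
        mid_item = on[0] + 1.0
        idx = np.searchsorted(edges, mid_item) - 1
        assert rates[idx] == pytest.approx(spec.baseline_rate + spec.gain)
        # pre-sample is baseline
        assert rates[0] == pytest.approx(spec.baseline_rate)

    def test_delay_format_signal_decays(self, rng):
        cfg = SimConfig()
        spec = _spec(Population.DELAY_NUM, preferred=2)
        seq_trial, seq_timing = _one_trial(Format.SEQ, rng)
        sim_trial, _ = _one_trial(Format.SIM, rng)
        e1, r1 = rate_profile(spec, seq_trial, seq_timing, cfg)
        e2, r2 = rate_profile(spec, sim_trial, None, cfg)
        early_diff = _mean_rate(e1, r1, seq_trial.delay_on, seq_trial.delay_on + 50) - _mean_rate(
            e2, r2, sim_trial.delay_on, sim_trial.delay_on + 50
        )
        late_diff = _mean_rate(e1, r1, seq_trial.delay_off - 50, seq_trial.delay_off) - _mean_rate(
            e2, r2, sim_trial.delay_off - 50, sim_trial.delay_off
        )
        assert early_diff == pytest.approx(spec.format_signal_amp, rel=0.05)
        assert abs(late_diff) < 0.05 * spec.format_signal_amp

    def test_delay_numerosity_ramp(self, rng):
        cfg = SimConfig()
        spec = _spec(Population.DELAY_NUM, preferred=2)
        trial, timing = _one_trial(Format.SIM, rng)  # format component zero on SIM
        e, r = rate_profile(spec, trial, timing, cfg)
        late = _mean_rate(e, r, trial.delay_off - 50, trial.delay_off)
        assert late == pytest.approx(spec.baseline_rate + spec.gain, rel=0.05)


class TestSpikes:
    def test_zero_rate_empty(self, rng):
        times = simulate_spikes(np.array([0.0, 1000.0]), np.array([0.0]), rng)
        assert times.size == 0

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_spikes(np.array([0.0, 1000.0]), np.array([-1.0]), rng)

    def test_poisson_mean(self, rng):
        counts = [
            simulate_spikes(np.array([0.0, 1000.0]), np.array([10.0]), rng).size
            for _ in range(5000)
        ]
        assert np.mean(counts) == pytest.approx(10.0, abs=0.15)
        assert np.var(counts) == pytest.approx(10.0, rel=0.1)

    def test_times_sorted_within_bounds(self, rng):
        t = simulate_spikes(np.array([0.0, 500.0, 1500.0]), np.array([20.0, 5.0]), rng)
        assert np.all(np.diff(t) >= 0)
        assert t.min() >= 0 and t.max() <= 1500.0

    def test_isi_exponential_across_seeds(self):
        # constant-rate train: inter-spike intervals are exponential
        passed = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            t = simulate_spikes(np.array([0.0, 20000.0]), np.array([25.0]), r)
            isi = np.diff(t)
            p = stats.kstest(isi, "expon", args=(0, 1000.0 / 25.0)).pvalue
            passed += p > 0.01
        assert passed >= 95


class TestDataset:
    def test_default_population_counts(self, rng):
        specs = make_neuron_specs(SimConfig(), rng)
        assert len(specs) == 376
        by_pop = {}
        for s in specs:
            by_pop[s.population] = by_pop.get(s.population, 0) + 1
        assert by_pop[Population.SEQ_SAMPLE] == 64
        assert by_pop[Population.SIM_SAMPLE] == 45
        assert by_pop[Population.DELAY_NUM] == 37

    def test_same_seed_identical(self):
        cfg = SimConfig(
            n_seq_sample=2, n_sim_sample=2, n_delay_num=2, n_format_only=1,
            n_nonsel=1, trials_per_condition=2,
        )
        a = build_dataset(cfg, seed=9)
        b = build_dataset(cfg, seed=9)
        assert a.trials.equals(b.trials)
        for nid in a.spikes:
            for tid in a.spikes[nid]:
                np.testing.assert_array_equal(a.spikes[nid][tid], b.spikes[nid][tid])

    def test_correct_trials_per_condition_grid(self, dataset):
        correct = dataset.trials[dataset.trials["correct"]]
        counts = correct.groupby(["sample_numerosity", "format", "protocol"]).size()
        assert len(counts) == 16
        assert counts.min() >= 3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            build_dataset(SimConfig(trials_per_condition=0), seed=0)

    def test_spike_times_within_trials(self, dataset):
        ends = dataset.trials.set_index("trial_id")["trial_end"]
        nid = dataset.neurons[0].neuron_id
        for tid, times in list(dataset.spikes[nid].items())[:20]:
            if times.size:
                assert times.min() >= 0.0
                assert times.max() <= ends.loc[tid]
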