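"""Stimulus-generator constraints: timing arithmetic, dot geometry, balance."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numcrow import stimgen
from numcrow.stimgen import (
    Format,
    Protocol,
    SeqCondition,
    StimulusError,
    gen_dot_display_control,
    gen_dot_display_standard,
    gen_sequential_equal_item,
    gen_sequential_equal_variance,
    gen_sequential_standard,
    gen_session,
)


class TestSequentialStandard:
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_total_and_floor(self, n, rng):
        for _ in range(50):
            t = gen_sequential_standard(n, rng)
            assert t.total_ms == pytest.approx(2625.0, abs=1e-6)
            assert t.interleaved().min() >= 300.0
            assert len(t.item_durations_ms) == n
            assert len(t.pause_durations_ms) == n

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_durations_are_random(self, n, rng):
        first_items = [gen_sequential_standard(n, rng).item_durations_ms[0] for _ in range(200)]
        assert np.var(first_items) > 0

    def test_n1_item_plus_pause(self, rng):
        t = gen_sequential_standard(1, rng)
        assert t.item_durations_ms[0] + t.pause_durations_ms[0] == pytest.approx(2625.0)

    def test_same_seed_reproducible(self):
        a = gen_sequential_standard(3, np.random.default_rng(7))
        b = gen_sequential_standard(3, np.random.default_rng(7))
        np.testing.assert_array_equal(a.interleaved(), b.interleaved())

    @pytest.mark.parametrize("bad", [0, 5, -1])
    def test_domain_error(self, bad, rng):
        with pytest.raises(StimulusError):
            gen_sequential_standard(bad, rng)

    def test_item_onsets_cumulative(self, rng):
        t = gen_sequential_standard(3, rng)
        on = t.item_onsets(500.0)
        assert on[0] == pytest.approx(500.0)
        assert on[1] == pytest.approx(500.0 + t.item_durations_ms[0] + t.pause_durations_ms[0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(n=st.integers(1, 4), seed=st.integers(0, 2**31 - 1))
def test_standard_timing_invariants_property(n, seed):
    t = gen_sequential_standard(n, np.random.default_rng(seed))
    assert t.total_ms == pytest.approx(2625.0, abs=1e-6)
    assert t.interleaved().min() >= 300.0
    assert len(t.interleaved()) == 2 * n


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n=st.integers(1, 4),
    item_ms=st.floats(300.0, 1000.0, allow_nan=False),
)
def test_equal_item_total_is_affine_property(n, item_ms):
    t = gen_sequential_equal_item(n, item_ms)
    assert t.total_ms == pytest.approx(2 * n * item_ms)
    assert np.all(t.interleaved() == item_ms)


class TestSequentialControls:
    @pytest.mark.parametrize(
        "n,expected", [(1, 1312.5), (2, 656.25), (4, 328.125)]
    )
    def test_equal_variance_values(self, n, expected):
        t = gen_sequential_equal_variance(n)
        assert np.all(t.interleaved() == expected)
        assert t.total_ms == pytest.approx(2625.0)

    def test_equal_item_totals_affine_and_increasing(self):
        totals = [gen_sequential_equal_item(n, 300.0).total_ms for n in (1, 2, 3, 4)]
        assert totals == [600.0, 1200.0, 1800.0, 2400.0]
        assert all(b > a for a, b in zip(totals, totals[1:]))

    def test_equal_item_floor_enforced(self):
        with pytest.raises(StimulusError):
            gen_sequential_equal_item(2, 299.0)


class TestDotDisplays:
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_standard_invariants(self, n, rng):
        for _ in range(20):
            d = gen_dot_display_standard(n, rng)
            d.validate()  # inside circle, radii in range, non-overlapping
            assert d.numerosity == n

    def test_standard_deterministic_under_seed(self):
        a = gen_dot_display_standard(4, np.random.default_rng(5))
        b = gen_dot_display_standard(4, np.random.default_rng(5))
        np.testing.assert_array_equal(a.centers_mm, b.centers_mm)
        np.testing.assert_array_equal(a.radii_mm, b.radii_mm)

    def test_control_equal_area_solution(self, rng):
        ctl = gen_dot_display_control(rng)
        # target 4*pi mm^2: one dot of radius 2 for n=1, four of radius 1 for n=4
        assert ctl[1].radii_mm[0] == pytest.approx(2.0)
        assert np.allclose(ctl[4].radii_mm, 1.0)

    def test_control_area_and_density_tolerance(self):
        for seed in range(50):
            ctl = gen_dot_display_control(np.random.default_rng(seed))
            areas = np.array([ctl[n].total_area_mm2 for n in (1, 2, 3, 4)])
            assert np.max(np.abs(areas - areas.mean())) <= 0.02 * areas.mean()
            dens = np.array([ctl[n].mean_pairwise_distance_mm() for n in (2, 3, 4)])
            assert np.max(np.abs(dens - dens.mean())) <= 0.05 * dens.mean()
            for n in (1, 2, 3, 4):
                ctl[n].validate()

    def test_control_density_vacuous_for_single_dot(self, rng):
        ctl = gen_dot_display_control(rng)
        assert np.isnan(ctl[1].mean_pairwise_distance_mm())

    def test_control_infeasible_area(self, rng):
        with pytest.raises(StimulusError):
            gen_dot_display_control(rng, target_area_mm2=2.0)


class TestSession:
    def test_balanced_crossing(self, rng):
        # 4 numerosities x 2 formats x 2 protocols x 2 match types = 32 cells
        session = gen_session(4, rng)
        assert len(session.trials) == 32 * 4
        counts = {}
        for t in session.trials:
            key = (t.sample_numerosity, t.format, t.protocol, t.is_match)
            counts[key] = counts.get(key, 0) + 1
        expected_cells = set(
            itertools.product(
                (1, 2, 3, 4), tuple(Format), tuple(Protocol), (True, False)
            )
        )
        assert set(counts) == expected_cells
        assert all(v == 4 for v in counts.values())

    def test_nonmatch_structure(self, rng):
        session = gen_session(2, rng)
        n_match = sum(t.is_match for t in session.trials)
        assert n_match == len(session.trials) // 2
        for t in session.trials:
            if t.is_match:
                assert t.test1_numerosity == t.sample_numerosity
                assert t.test2_on is None
            else:
                assert t.test1_numerosity != t.sample_numerosity
                assert t.test2_on == pytest.approx(t.test1_on + 800.0)

    def test_epoch_arithmetic(self, rng):
        session = gen_session(2, rng)
        for t in session.trials:
            assert t.delay_off - t.delay_on == pytest.approx(1000.0)
            assert t.sample_on - t.pre_sample_on == pytest.approx(500.0 + t.presample_jitter_ms)
            if t.format is Format.SIM:
                assert t.sample_off - t.sample_on == pytest.approx(800.0)

    def test_presample_jitter_only_for_seq_standard_one(self, rng):
        session = gen_session(6, rng)
        for t in session.trials:
            jittered = t.presample_jitter_ms > 0
            if jittered:
                assert t.format is Format.SEQ
                assert t.protocol is Protocol.STANDARD
                assert t.sample_numerosity == 1
            assert 0.0 <= t.presample_jitter_ms <= 500.0

    def test_sequential_timings_attached(self, rng):
        session = gen_session(2, rng, seq_control=SeqCondition.EQUAL_ITEM)
        for t in session.trials:
            if t.format is Format.SEQ:
                timing = session.timings[t.trial_id]
                assert timing.numerosity == t.sample_numerosity
                assert t.sample_off - t.sample_on == pytest.approx(timing.total_ms)
                expected = (
                    SeqCondition.STANDARD
                    if t.protocol is Protocol.STANDARD
                    else SeqCondition.EQUAL_ITEM
                )
                assert timing.condition is expected
            else:
                assert t.trial_id in session.displays
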