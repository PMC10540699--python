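"""The experiment generator must reproduce every design constraint exactly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from duplescales import paradigm
from duplescales.paradigm import (ALTERABLE_SCALES, CONDITIONS, Role,
                                  TimingCondition, assign_onsets, build_scale,
                                  build_schedule, build_trial, outlier_f0,
                                  pair_initial_soas, synthesize_audio)


class TestBuildScale:
    def test_octave_endpoints(self):
        up = build_scale(300, "ascending")
        assert up[0] == pytest.approx(300) and up[-1] == pytest.approx(600)
        down = build_scale(600, "descending")
        assert down[-1] == pytest.approx(300)

    def test_fourth_tone_geometric_value(self):
        # direct evaluation of the progression: 300 * 2^(3/7)
        assert build_scale(300, "ascending")[3] == pytest.approx(
            300 * 2 ** (3 / 7), rel=1e-12)
        assert build_scale(300, "ascending")[3] == pytest.approx(403.77, abs=0.01)

    @given(f0=st.floats(300, 600), direction=st.sampled_from(
        ["ascending", "descending"]))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_geometric_progression_property(self, f0, direction):
        scale = build_scale(f0, direction)
        ratios = scale[1:] / scale[:-1]
        sign = 1 if direction == "ascending" else -1
        assert np.allclose(ratios, 2 ** (sign / 7))

    @pytest.mark.parametrize("f0", [299.0, 601.0, 0.0])
    def test_out_of_range_start_rejected(self, f0):
        with pytest.raises(ValueError):
            build_scale(f0, "ascending")


class TestOnsets:
    def test_isochronous_grid(self, rng):
        onsets = assign_onsets(TimingCondition.isochronous, rng)
        assert onsets[10] == pytest.approx(2.470)
        assert np.allclose(np.diff(onsets), 0.247)

    def test_beat_based_pair_initial_grid_and_jitter(self, rng):
        onsets = assign_onsets(TimingCondition.beat_based, rng)
        assert np.allclose(onsets[0::2], np.arange(28) * 0.494)
        gaps = onsets[1::2] - onsets[0::2]
        allowed = 0.247 * np.array([0.667, 0.834, 1.166, 1.333])
        assert all(np.any(np.isclose(g, allowed)) for g in gaps)
        # the shortest allowed within-pair gap is 247 ms x 0.667
        assert allowed.min() == pytest.approx(0.1647, abs=2e-4)

    def test_interval_based_fixed_within_pair_jittered_grid(self, rng):
        onsets = assign_onsets(TimingCondition.interval_based, rng)
        assert np.allclose(onsets[1::2] - onsets[0::2], 0.247)
        deltas = np.diff(onsets[0::2]) - 0.494
        allowed = 0.247 * np.array([-0.333, -0.166, 0.166, 0.333])
        assert all(np.any(np.isclose(d, allowed, atol=1e-9)) for d in deltas)

    def test_onsets_strictly_increasing(self, rng):
        for cond in CONDITIONS:
            onsets = assign_onsets(cond, rng)
            assert np.all(np.diff(onsets) > 0)


class TestOutlier:
    def test_outlier_magnitudes(self, rng):
        scale = build_scale(300, "ascending")
        vals = sorted({round(outlier_f0(scale, rng), 9) for _ in range(60)})
        assert vals == [pytest.approx(240.0), pytest.approx(720.0)]

    def test_outlier_outside_scale_range(self, rng):
        scale = build_scale(437.0, "descending")
        for _ in range(20):
            v = outlier_f0(scale, rng)
            assert not scale.min() <= v <= scale.max()


class TestTrialConstruction:
    @pytest.fixture(scope="class")
    def trials(self):
        rng = np.random.default_rng(5)
        return [build_trial(i, CONDITIONS[i % 3], rng, include_repetition=i % 2 == 0)
                for i in range(30)]

    def test_one_deviant_per_type_in_distinct_alterable_scales(self, trials):
        for t in trials:
            ids = [x for x in t.tones if x.role is Role.deviant_ID]
            bds = [x for x in t.tones if x.role is Role.deviant_BD]
            assert len(ids) == 1 and len(bds) == 1
            assert ids[0].position_in_scale == 7
            assert bds[0].position_in_scale == 6
            assert ids[0].scale_index != bds[0].scale_index
            assert {ids[0].scale_index, bds[0].scale_index} <= set(ALTERABLE_SCALES)

    def test_first_two_scales_unaltered(self, trials):
        for t in trials:
            assert all(x.role is Role.plain for x in t.tones[:16])

    def test_repetition_is_immediate_f0_copy(self, trials):
        for t in trials:
            reps = [k for k, x in enumerate(t.tones) if x.role is Role.repetition]
            if t.repetition_scale is None:
                assert not reps
                continue
            (k,) = reps
            assert t.tones[k].f0_hz == t.tones[k - 1].f0_hz
            assert t.tones[k].scale_index == t.tones[k - 1].scale_index

    def test_designated_standards_in_clean_scales(self, trials):
        for t in trials:
            sid = [x for x in t.tones if x.role is Role.designated_standard_ID]
            sbd = [x for x in t.tones if x.role is Role.designated_standard_BD]
            assert len(sid) == 1 and sid[0].position_in_scale == 7
            assert len(sbd) == 1 and sbd[0].position_in_scale == 6
            used = set(t.deviant_scales) | {t.repetition_scale}
            assert sid[0].scale_index not in used
            assert sbd[0].scale_index not in used
            assert sid[0].scale_index != sbd[0].scale_index

    def test_pretarget_gaps_exactly_247ms(self, trials):
        for t in trials:
            onsets = np.array([x.onset_s for x in t.tones])
            for k, x in enumerate(t.tones):
                if x.role in paradigm.TARGET_ROLES:
                    assert onsets[k] - onsets[k - 1] == pytest.approx(0.247)

    def test_level_duple_stress(self, trials):
        for t in trials:
            for x in t.tones:
                expected = -10.0 if x.position_in_scale % 2 else 0.0
                assert x.level_db == expected
                assert x.duration_s == 0.166


class TestSchedule:
    def test_block_structure(self, schedule_full):
        assert len(schedule_full.blocks) == 12
        assert all(len(b) == 20 for b in schedule_full.blocks)
        conds = schedule_full.block_conditions
        assert all(a != b for a, b in zip(conds, conds[1:]))
        for c in CONDITIONS:
            assert conds.count(c) == 4

    def test_repetition_trial_fraction(self, schedule_full):
        n_rep = sum(t.repetition_scale is not None for t in schedule_full.trials)
        assert n_rep == 120

    def test_bit_reproducible(self):
        a = build_schedule(314, n_blocks=3, trials_per_block=2)
        b = build_schedule(314, n_blocks=3, trials_per_block=2)
        for ta, tb in zip(a.trials, b.trials):
            assert [x.onset_s for x in ta.tones] == [x.onset_s for x in tb.tones]
            assert [x.f0_hz for x in ta.tones] == [x.f0_hz for x in tb.tones]

    def test_beat_pair_soa_excluding_overrides(self, schedule_full):
        soas = np.concatenate([
            pair_initial_soas(t) for t in
            schedule_full.trials_for(TimingCondition.beat_based)])
        assert np.allclose(soas, 0.494, atol=1e-12)

    def test_deviant_scale_distribution_uniform(self):
        # Monte-Carlo against a uniform oracle over scales 2..6
        rng = np.random.default_rng(0)
        counts = np.zeros(5)
        n = 1500
        for i in range(n):
            t = build_trial(0, TimingCondition.isochronous, rng, False)
            counts[t.deviant_scales[0] - 2] += 1
        assert stats.chisquare(counts).pvalue > 0.001


class TestAudio:
    def test_empty_trial_is_silence(self, schedule_small):
        t = schedule_small.trials[0]
        empty = paradigm.TrialSpec(0, t.direction, t.condition,
                                   t.scale_start_f0s, tones=[])
        wave = synthesize_audio(empty, 16000)
        assert len(wave) == 16000 and not wave.any()

    def test_level_scaling_rms_ratio(self, schedule_small):
        fs = 16000
        trial = schedule_small.trials[0]
        wave = synthesize_audio(trial, fs)
        n_tone = int(0.166 * fs)
        rms = []
        for tone in trial.tones[:2]:     # a stressed and an unstressed tone
            i0 = int(round(tone.onset_s * fs))
            seg = wave[i0:i0 + int(0.14 * fs)]   # avoid overlap with next tone
            rms.append(np.sqrt(np.mean(seg ** 2)))
        assert rms[1] / rms[0] == pytest.approx(10 ** (-10 / 20), rel=0.05)

    def test_waveform_length_matches_event_table(self, schedule_small):
        fs = 16000
        trial = schedule_small.trials[1]
        wave = synthesize_audio(trial, fs)
        assert len(wave) == int(round(trial.duration_s * fs))

    def test_low_sample_rate_rejected(self, schedule_small):
        with pytest.raises(ValueError):
            synthesize_audio(schedule_small.trials[0], 4000)
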