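import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from murmurkit.io import VALVES, AudioSignal
from murmurkit.augment import (
    OP_KINDS,
    AugmentOp,
    AugmentPlan,
    add_gaussian_noise,
    apply_plan,
    make_augmented_copies,
    make_plan,
    pitch_shift,
    time_shift,
    time_warp,
)

from conftest import RATE, sine


def dominant_freq(signal: AudioSignal) -> float:
    spectrum = np.abs(np.fft.rfft(signal.samples * np.hanning(len(signal.samples))))
    freqs = np.fft.rfftfreq(len(signal.samples), 1.0 / signal.rate)
    return freqs[np.argmax(spectrum)]


class TestGaussianNoise:
    def test_zero_factor_is_identity(self):
        sig = sine(100.0)
        out = add_gaussian_noise(sig, 0.0, seed=3)
        np.testing.assert_array_equal(out.samples, sig.samples)

    def test_noise_std_matches_factor(self):
        silence = AudioSignal(np.zeros(200_000), RATE)
        out = add_gaussian_noise(silence, 0.1, seed=7)
        assert 0.095 <= out.samples.std() <= 0.105

    def test_same_seed_reproducible(self):
        sig = sine(100.0)
        a = add_gaussian_noise(sig, 0.05, seed=11)
        b = add_gaussian_noise(sig, 0.05, seed=11)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            add_gaussian_noise(sine(100.0), -0.1, seed=0)


class TestPitchShift:
    def test_identity_factor_near_lossless(self):
        sig = sine(100.0)
        out = pitch_shift(sig, 1.0)
        err = np.sqrt(np.mean((out.samples - sig.samples) ** 2))
        assert err / np.sqrt(np.mean(sig.samples**2)) < 0.05

    @pytest.mark.parametrize("alpha,expected", [(2.0, 200.0), (0.5, 50.0)])
    def test_frequency_scaled(self, alpha, expected):
        out = pitch_shift(sine(100.0, duration=4.0), alpha)
        assert abs(dominant_freq(out) - expected) <= 2.0

    def test_duration_exactly_preserved(self):
        sig = sine(100.0, duration=3.3)
        out = pitch_shift(sig, 1.17)
        assert len(out.samples) == len(sig.samples)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            pitch_shift(sine(100.0), 0.0)


class TestTimeShift:
    def test_zero_offset_identity(self):
        sig = sine(100.0)
        np.testing.assert_array_equal(time_shift(sig, 0).samples, sig.samples)

    def test_full_length_offset_identity(self):
        sig = sine(100.0)
        np.testing.assert_array_equal(time_shift(sig, len(sig.samples)).samples, sig.samples)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(offset=st.integers(min_value=0, max_value=10_000))
    def test_multiset_preserved(self, offset):
        rng = np.random.default_rng(0)
        sig = AudioSignal(rng.standard_normal(4000), RATE)
        out = time_shift(sig, offset)
        np.testing.assert_array_equal(np.sort(out.samples), np.sort(sig.samples))


class TestTimeWarp:
    def test_identity_rate_near_lossless(self):
        sig = sine(100.0)
        out = time_warp(sig, 1.0)
        n = min(len(out.samples), len(sig.samples))
        err = np.sqrt(np.mean((out.samples[:n] - sig.samples[:n]) ** 2))
        assert err / np.sqrt(np.mean(sig.samples**2)) < 0.05

    @pytest.mark.parametrize("rate,factor", [(2.0, 0.5), (0.5, 2.0)])
    def test_duration_rescaled_pitch_kept(self, rate, factor):
        sig = sine(100.0, duration=4.0)
        out = time_warp(sig, rate)
        assert abs(len(out.samples) - factor * len(sig.samples)) <= 256  # one hop
        assert abs(dominant_freq(out) - 100.0) <= 2.0

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            time_warp(sine(100.0), -1.0)


class TestMakePlan:
    def test_depth_ten_default(self):
        plan = make_plan(depth=10, seed=0, n_samples=8000)
        assert len(plan.ops) == 10

    def test_same_seed_same_plan(self):
        a = make_plan(depth=10, seed=5, n_samples=8000)
        b = make_plan(depth=10, seed=5, n_samples=8000)
        assert [(o.kind, o.params) for o in a.ops] == [(o.kind, o.params) for o in b.ops]

    def test_kinds_uniform(self):
        counts = dict.fromkeys(OP_KINDS, 0)
        for seed in range(10_000):
            plan = make_plan(depth=1, seed=seed, n_samples=8000)
            counts[plan.ops[0].kind] += 1
        for kind in OP_KINDS:
            assert abs(counts[kind] / 10_000 - 0.25) <= 0.02


class TestApplyPlan:
    def test_empty_plan_unchanged(self, four_identical_sines):
        out = apply_plan(four_identical_sines, AugmentPlan(ops=[], seed=0))
        for v in VALVES:
            np.testing.assert_array_equal(
                out.channels[v].samples, four_identical_sines.channels[v].samples)

    def test_shift_coherent_across_channels(self, four_identical_sines):
        plan = AugmentPlan(ops=[AugmentOp("shift", {"offset": 777})], seed=0)
        out = apply_plan(four_identical_sines, plan)
        expected = np.roll(four_identical_sines.channels["AV"].samples, 777)
        for v in VALVES:
            np.testing.assert_array_equal(out.channels[v].samples, expected)

    def test_pitch_coherent_on_identical_channels(self, four_identical_sines):
        plan = AugmentPlan(ops=[AugmentOp("pitch", {"alpha": 2.0})], seed=0)
        out = apply_plan(four_identical_sines, plan)
        ref = out.channels["AV"].samples
        for v in VALVES:
            np.testing.assert_array_equal(out.channels[v].samples, ref)

    def test_structural_op_equals_individual_application(self, four_identical_sines):
        """Coherence: apply_plan's channel k equals the op applied to channel k alone."""
        plan = AugmentPlan(ops=[AugmentOp("warp", {"rate": 1.1})], seed=0)
        out = apply_plan(four_identical_sines, plan)
        solo = time_warp(four_identical_sines.channels["PV"], 1.1)
        n = four_identical_sines.n_samples
        from murmurkit.sync import loop_to_length
        solo = loop_to_length(solo, n / RATE)
        np.testing.assert_allclose(out.channels["PV"].samples, solo.samples)

    def test_label_and_shapes_preserved(self, beat_group):
        plan = make_plan(depth=4, seed=9, n_samples=beat_group.n_samples)
        out = apply_plan(beat_group, plan)
        assert out.label == beat_group.label
        assert out.n_samples == beat_group.n_samples
        assert out.rate == beat_group.rate
        assert out.provenance == "augmented"


class TestMakeAugmentedCopies:
    def test_zero_copies(self, beat_group):
        assert make_augmented_copies(beat_group, n_copies=0) == []

    def test_three_copies_distinct_lineages_same_label(self, four_identical_sines):
        copies = make_augmented_copies(four_identical_sines, n_copies=3, depth=2, seed=1)
        assert len(copies) == 3
        assert len({c.lineage for c in copies}) == 3
        assert all(c.label == four_identical_sines.label for c in copies)

    def test_original_untouched_and_deterministic(self, four_identical_sines):
        before = four_identical_sines.channels["AV"].samples.copy()
        a = make_augmented_copies(four_identical_sines, n_copies=2, depth=3, seed=4)
        np.testing.assert_array_equal(four_identical_sines.channels["AV"].samples, before)
        b = make_augmented_copies(four_identical_sines, n_copies=2, depth=3, seed=4)
        for ca, cb in zip(a, b):
            for v in VALVES:
                np.testing.assert_array_equal(ca.channels[v].samples, cb.channels[v].samples)

    def test_file_count_bookkeeping(self, four_identical_sines):
        """1 original + 3 copies = 4 groups = 16 audio files per patient."""
        copies = make_augmented_copies(four_identical_sines, n_copies=3, depth=1, seed=0)
        total_files = 4 * (1 + len(copies))
        assert total_files == 16
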