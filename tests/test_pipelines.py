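"""Modality converters, noise injection, and the synthetic generator."""

import numpy as np
import pytest

from stp.errors import ContractError
from stp.pipelines import (EventStream, NoiseSpec, add_background_noise,
                           events_to_st, frames_to_diff, tokens_to_st,
                           volume_to_st)
from stp.synthetic import gen_synthetic_motion, motion_frames


def stream(records, h=6, w=6):
    arr = np.array(records, dtype=float)
    return EventStream(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], h_s=h, w_s=w)


class TestEventsToST:
    def test_single_event_lands_on_its_pixel(self):
        st = events_to_st(stream([(2, 3, 0.1, 1)]), window=1.0, t_steps=2)
        assert st.shape == (1, 2, 2, 6, 6)
        assert st[0, 0, 0, 3, 2] == 1.0
        assert st.sum() == 1.0

    def test_counts_accumulate_and_binarise(self):
        ev = stream([(1, 1, 0.2, 0), (1, 1, 0.7, 0)])
        st = events_to_st(ev, window=1.0, t_steps=1)
        assert st[0, 0, 1, 1, 1] == 2.0  # OFF polarity -> channel 1
        st_bin = events_to_st(ev, window=1.0, t_steps=1, binary=True)
        assert st_bin[0, 0, 1, 1, 1] == 1.0

    def test_empty_stream_is_all_zeros(self):
        ev = EventStream(np.array([]), np.array([]), np.array([]),
                         np.array([]), h_s=4, w_s=4)
        assert not events_to_st(ev, window=1.0, t_steps=3).any()

    def test_out_of_bounds_events_rejected_and_logged(self, caplog):
        ev = stream([(9, 0, 0.1, 1), (1, 1, 0.1, 1)])
        with caplog.at_level("WARNING", logger="stp.pipelines"):
            st = events_to_st(ev, window=1.0, t_steps=1)
        assert st.sum() == 1.0
        assert "rejected 1" in caplog.text

    def test_event_count_conservation(self, rng):
        """Non-binary binning conserves every in-bounds event inside the
        covered windows."""
        n = 500
        ev = EventStream(rng.integers(0, 8, n), rng.integers(0, 8, n),
                         rng.uniform(0, 5, n), rng.integers(0, 2, n),
                         h_s=8, w_s=8)
        st = events_to_st(ev, window=1.0, t_steps=5)
        assert st.sum() == n

    def test_integer_binning_subsamples(self):
        # sensor 6x6 -> output 3x3: pixel (4,5) falls in bin (2,2)
        st = events_to_st(stream([(5, 4, 0.1, 1)]), window=1.0, t_steps=1,
                          out_hw=(3, 3))
        assert st.shape[-2:] == (3, 3)
        assert st[0, 0, 0, 2, 2] == 1.0

    def test_invalid_window_rejected(self):
        with pytest.raises(ContractError):
            events_to_st(stream([(0, 0, 0.0, 1)]), window=0.0, t_steps=1)


class TestFramesToDiff:
    def test_constant_sequence_is_background(self):
        frames = np.ones((4, 5, 5))
        assert not frames_to_diff(frames, threshold=0.1).any()

    def test_rising_pixel_marks_enhancement_only(self):
        frames = np.zeros((2, 3, 3))
        frames[1, 1, 1] = 0.4  # rise of 2x threshold
        st = frames_to_diff(frames, threshold=0.2)
        assert st.shape == (1, 1, 2, 3, 3)
        assert st[0, 0, 0, 1, 1] == 1.0 and st[0, 0, 1, 1, 1] == 0.0

    def test_reversed_sequence_swaps_channels(self, rng):
        frames = rng.normal(size=(6, 4, 4))
        fwd = frames_to_diff(frames, 0.1)
        rev = frames_to_diff(frames[::-1], 0.1)
        np.testing.assert_array_equal(fwd[0, :, 0], rev[0, ::-1, 1])
        np.testing.assert_array_equal(fwd[0, :, 1], rev[0, ::-1, 0])

    def test_needs_two_frames(self):
        with pytest.raises(ContractError):
            frames_to_diff(np.zeros((1, 3, 3)), 0.1)


class TestVolumeToST:
    def test_gray_normalization_endpoints_and_midpoint(self):
        vol = np.array([[[-1200.0, 600.0], [-300.0, 1000.0]]])
        st = volume_to_st(vol)
        assert st.shape == (1, 1, 1, 2, 2)
        got = st[0, 0, 0]
        assert got[0, 0] == 0.0
        assert got[0, 1] == 255.0
        assert got[1, 0] == pytest.approx(127.5)
        assert got[1, 1] == 255.0  # clamped above range

    def test_empty_volume_rejected(self):
        with pytest.raises(ContractError):
            volume_to_st(np.zeros((0, 2, 2)))


class TestTokensToST:
    def test_empty_sequence_is_all_pad(self):
        assert not tokens_to_st([], vocab_size=10, pad_len=8).any()

    def test_exact_length_unchanged(self):
        toks = np.arange(1, 9)
        np.testing.assert_array_equal(
            tokens_to_st(toks, vocab_size=10, pad_len=8)[0], toks)

    def test_overflow_truncates_tail(self):
        toks = np.arange(12) % 9 + 1
        out = tokens_to_st(toks, vocab_size=10, pad_len=8)
        np.testing.assert_array_equal(out[0], toks[:8])

    def test_id_overflow_rejected(self):
        with pytest.raises(ContractError):
            tokens_to_st([3, 10], vocab_size=10, pad_len=4)


class TestBackgroundNoise:
    def test_zero_ratio_is_identity(self, rng):
        x = rng.random((1, 3, 2, 5, 5))
        np.testing.assert_array_equal(
            add_background_noise(x, NoiseSpec(0.0)), x)

    def test_full_ratio_saturates(self):
        x = np.zeros((1, 2, 2, 4, 4))
        assert add_background_noise(x, NoiseSpec(1.0)).all()

    def test_exact_forced_pixel_count(self):
        """ratio 0.25 on a 40x40 frame forces exactly 400 pixels per channel
        per frame, hence at most n*C*T changed pixels per sample."""
        x = np.zeros((1, 3, 2, 40, 40))
        out = add_background_noise(x, NoiseSpec(0.25, seed=5))
        per_frame = out.reshape(6, -1).sum(axis=1)
        assert (per_frame == 400).all()
        assert (out != x).sum() <= 400 * 2 * 3

    def test_deterministic_per_seed(self):
        x = np.zeros((1, 2, 2, 8, 8))
        a = add_background_noise(x, NoiseSpec(0.3, seed=9))
        b = add_background_noise(x, NoiseSpec(0.3, seed=9))
        np.testing.assert_array_equal(a, b)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ContractError):
            NoiseSpec(1.5)


class TestSyntheticMotion:
    def test_same_seed_bit_identical(self):
        a = gen_synthetic_motion(n_samples=12, seed=4)
        b = gen_synthetic_motion(n_samples=12, seed=4)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_time_reversed_left_is_a_right_sample(self):
        """Opposite directions are exact time reversals of each other."""
        t, hw = 10, (12, 12)
        for s in (0, 3, 11):
            left = motion_frames("left", s, t, hw)
            right = motion_frames("right", (s - (t - 1)) % hw[1], t, hw)
            np.testing.assert_array_equal(left[::-1], right)
        up = motion_frames("up", 5, t, hw)
        down = motion_frames("down", (5 - (t - 1)) % hw[0], t, hw)
        np.testing.assert_array_equal(up[::-1], down)

    def test_events_confined_to_programmed_trajectory(self):
        """Binned events are nonzero only where the bar mask changes."""
        ds = gen_synthetic_motion(classes=("right",), n_samples=3, seed=2,
                                  t_steps=8, hw=(10, 10))
        for n in range(3):
            frames = motion_frames("right", int(ds.meta["starts"][n]), 8,
                                   (10, 10))
            prev = np.zeros((10, 10))
            for t in range(8):
                changed = frames[t] != prev
                active = ds.x[n, t].sum(axis=0) > 0
                assert not active[~changed].any()
                prev = frames[t]

    def test_labels_balanced_and_classes_respected(self):
        ds = gen_synthetic_motion(classes=("left", "right"), n_samples=10,
                                  seed=0)
        counts = np.bincount(ds.y)
        assert counts.tolist() == [5, 5]

    def test_frames_emission_shape(self):
        ds = gen_synthetic_motion(n_samples=4, seed=1, emit="frames",
                                  t_steps=6, hw=(8, 9))
        assert ds.x.shape == (4, 6, 1, 8, 9)

    def test_unknown_class_rejected(self):
        with pytest.raises(ContractError):
            gen_synthetic_motion(classes=("diagonal",), n_samples=2)


class TestFrameDir:
    def test_load_frame_dir_reads_sorted_grayscale(self, tmp_path):
        import imageio.v3 as iio

        from stp.pipelines import load_frame_dir

        rng = np.random.default_rng(0)
        for k in range(3):
            iio.imwrite(tmp_path / f"f{k}.png",
                        rng.integers(0, 255, (4, 5), dtype=np.uint8))
        frames = load_frame_dir(tmp_path)
        assert frames.shape == (3, 4, 5)

    def test_empty_dir_rejected(self, tmp_path):
        from stp.pipelines import load_frame_dir

        with pytest.raises(ContractError):
            load_frame_dir(tmp_path)
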