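"""Window queue, grid geometry, spatial filter and RMS features."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from myodecode import (
    FeatureFrame,
    GridLayout,
    SpatialKernel,
    WindowQueue,
    extract_features,
    from_grid,
    pad_grid,
    rms_features,
    spatial_filter,
    to_grid,
)
from myodecode.preprocess import SPATIAL_KERNEL_WEIGHTS


def brute_force_filter(grid: np.ndarray) -> np.ndarray:
    """Independent per-electrode loop oracle: pad, correlate, crop."""
    padded = pad_grid(grid)
    out = np.zeros_like(np.asarray(grid, dtype=float))
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            acc = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    acc += SPATIAL_KERNEL_WEIGHTS[dr + 1, dc + 1] \
                        * padded[1 + r + dr, 1 + c + dc]
            out[r, c] = acc
    return out


class TestQueue:
    def test_block_emitted_only_when_full(self, short_recording):
        _, windows = short_recording
        q = WindowQueue()
        for i in range(19):
            assert q.push(windows[i]) is None
        block = q.push(windows[19])
        assert block.shape == (32, 360)

    def test_sliding_queue_emits_n_minus_19_blocks(self, short_recording):
        _, windows = short_recording
        q = WindowQueue()
        blocks = [b for w in windows[:130] if (b := q.push(w)) is not None]
        assert len(blocks) == 130 - 19 == 111

    def test_block_concatenates_in_arrival_order(self, short_recording):
        _, windows = short_recording
        q = WindowQueue()
        for w in windows[:20]:
            block = q.push(w)
        np.testing.assert_array_equal(block[:, :18], windows[0])
        np.testing.assert_array_equal(block[:, -18:], windows[19])

    def test_wrong_shape_rejected_with_diagnostic(self):
        q = WindowQueue()
        with pytest.raises(ValueError, match="31, 18"):
            q.push(np.zeros((31, 18)))


class TestGrid:
    def test_roundtrip_is_identity(self, rng):
        x = rng.normal(size=(32, 7))
        np.testing.assert_array_equal(from_grid(to_grid(x)), x)

    def test_documented_channel_positions(self):
        x = np.arange(32)
        g = to_grid(x)
        assert g[0, 0] == 0      # channel 0 -> row 0, col 0
        assert g[0, 1] == 16     # channel 16 -> row 0, col 1
        assert g[15, 0] == 15
        layout = GridLayout()
        assert layout.position_of(17) == (1, 1)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_grid(np.zeros(33))

    def test_pad_wraps_rows_and_zeroes_columns(self, rng):
        g = rng.normal(size=(16, 2))
        p = pad_grid(g)
        assert p.shape == (18, 4)
        np.testing.assert_array_equal(p[0, 1:3], g[15, :])
        np.testing.assert_array_equal(p[17, 1:3], g[0, :])
        assert np.all(p[:, 0] == 0) and np.all(p[:, 3] == 0)


class TestSpatialFilter:
    def test_matches_bruteforce_loop_exactly_on_integer_grids(self, rng):
        for _ in range(100):
            g = rng.integers(-32768, 32768, size=(16, 2)).astype(float)
            np.testing.assert_array_equal(spatial_filter(g), brute_force_filter(g))

    def test_constant_field_response(self):
        g = np.full((16, 2), 8.0)
        np.testing.assert_allclose(spatial_filter(g), 0.875 * 8.0)

    def test_single_electrode_impulse_response(self):
        v, r = 16.0, 5
        g = np.zeros((16, 2))
        g[r, 0] = v
        out = spatial_filter(g)
        expected = np.zeros((16, 2))
        expected[r, 0] = 0.125 * v
        expected[(r - 1) % 16, 0] = 0.25 * v
        expected[(r + 1) % 16, 0] = 0.25 * v
        expected[r, 1] = 0.25 * v
        np.testing.assert_array_equal(out, expected)

    def test_all_zero_block_stays_zero(self):
        assert np.all(spatial_filter(np.zeros((16, 2, 5))) == 0)

    @given(a=st.floats(-3, 3), b=st.floats(-3, 3))
    def test_linearity(self, a, b):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(16, 2, 4))
        Y = rng.normal(size=(16, 2, 4))
        np.testing.assert_allclose(
            spatial_filter(a * X + b * Y),
            a * spatial_filter(X) + b * spatial_filter(Y), atol=1e-9)

    def test_custom_kernel_path_agrees_with_default(self, rng):
        g = rng.normal(size=(16, 2, 3))
        k = SpatialKernel(weights=SPATIAL_KERNEL_WEIGHTS.copy())
        np.testing.assert_allclose(spatial_filter(g, k), spatial_filter(g),
                                   atol=1e-12)


class TestRmsFeatures:
    def test_sine_rms_is_amplitude_over_sqrt2(self):
        A = 1000.0
        t = np.arange(360)
        block = np.zeros((32, 360))
        block[4] = A * np.sin(2 * np.pi * 10 * t / 360)  # whole periods
        frame = rms_features(block, label_states=np.zeros((3, 9)))
        assert abs(frame.rms[4] - A / np.sqrt(2)) / (A / np.sqrt(2)) < 0.01
        assert np.all(frame.rms[:4] == 0)

    def test_zero_block_gives_32_zeros(self):
        frame = rms_features(np.zeros((16, 2, 360)), np.zeros((2, 9)))
        assert frame.rms.shape == (32,)
        assert np.all(frame.rms == 0)

    def test_constant_guide_label_is_exact_mean(self):
        states = np.full((8, 9), 0.6)
        frame = rms_features(np.zeros((32, 360)), states)
        np.testing.assert_array_equal(frame.label_state, np.full(9, 0.6))

    def test_empty_span_carries_last_state_and_flags(self):
        last = np.full(9, 0.3)
        with pytest.warns(UserWarning, match="carrying last known state"):
            frame = rms_features(np.zeros((32, 360)), np.zeros((0, 9)),
                                 last_state=last)
        assert frame.stale_label
        np.testing.assert_array_equal(frame.label_state, last)

    def test_rms_scales_linearly_with_block(self, rng):
        block = rng.normal(size=(32, 360))
        f1 = rms_features(block, np.zeros((1, 9)))
        f3 = rms_features(3.0 * block, np.zeros((1, 9)))
        np.testing.assert_allclose(f3.rms, 3.0 * f1.rms, rtol=1e-12)

    def test_negative_rms_rejected(self):
        with pytest.raises(ValueError):
            FeatureFrame(rms=-np.ones(32), label_state=np.zeros(9), t_end=0.0)


class TestBatchExtraction:
    def test_throughput_is_n_minus_19(self, short_recording):
        traj, windows = short_recording
        frames = extract_features(windows, traj.t, traj.states)
        assert len(frames) == windows.shape[0] - 19

    def test_batch_equals_streaming_pipeline(self, short_recording):
        """The vectorised batch path reproduces the per-push queue path."""
        traj, windows = short_recording
        sub = windows[:60]
        batch = extract_features(sub, traj.t, traj.states)
        q = WindowQueue()
        streamed = []
        for w in sub:
            block = q.push(w)
            if block is not None:
                filt = spatial_filter(to_grid(block.astype(float)))
                streamed.append(np.sqrt(np.mean(from_grid(filt) ** 2, axis=1)))
        assert len(batch) == len(streamed)
        for f, r in zip(batch, streamed):
            np.testing.assert_allclose(f.rms, r, rtol=1e-10)

    def test_feature_vector_length_is_32(self, short_recording):
        traj, windows = short_recording
        frame = extract_features(windows[:20], traj.t, traj.states)[0]
        assert frame.rms.shape == (32,)
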