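import numpy as np
import pytest
from skimage.filters import threshold_otsu as skimage_otsu

from irmspread import (DegenerateHistogramError, IRMSequence,
                       OtsuInteractionSegmenter, accumulate_transitions,
                       interaction_area_trace, interaction_mask,
                       pooled_otsu_threshold)


def _seq(frames, interval=1.0):
    return IRMSequence(np.asarray(frames), frame_interval=interval)


def exhaustive_otsu_8bit(values):
    """Independent oracle: try every candidate threshold 1..255, maximise
    between-class variance of the strict-< split, smallest threshold wins."""
    values = np.asarray(values).ravel().astype(np.float64)
    best_t, best_v = None, -np.inf
    for t in range(1, 256):
        lo = values[values < t]
        hi = values[values >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / values.size, hi.size / values.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


class TestPooledOtsu:
    def test_perfectly_bimodal(self):
        frames = np.concatenate([np.zeros(100), np.full(100, 255)])
        seq = _seq(frames.reshape(2, 10, 10).astype(np.uint8))
        thr = pooled_otsu_threshold(seq)
        mask = interaction_mask(seq, threshold=thr)
        assert 0 < thr <= 255
        # foreground is exactly the dark class
        np.testing.assert_array_equal(mask.mask, seq.frames == 0)

    def test_constant_stack_errors(self):
        with pytest.raises(DegenerateHistogramError):
            pooled_otsu_threshold(_seq(np.full((3, 4, 4), 9, dtype=np.uint8)))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        frames = rng.integers(0, 256, size=(4, 8, 8), dtype=np.uint8)
        thr = pooled_otsu_threshold(_seq(frames))
        assert thr == exhaustive_otsu_8bit(frames)

    def test_threshold_within_pooled_range(self, rng):
        frames = rng.integers(50, 150, size=(3, 6, 6), dtype=np.uint8)
        thr = pooled_otsu_threshold(_seq(frames))
        assert frames.min() < thr <= frames.max()

    def test_float_input_agrees_with_skimage(self, rng):
        # independent cross-check: same histogram resolution, so the two
        # thresholds must land within one bin of each other (we return the
        # bin edge, the reference the bin centre)
        values = np.concatenate([rng.normal(60, 2, 2000),
                                 rng.normal(100, 2, 3000)])
        frames = values.reshape(5, 10, 100)
        thr = pooled_otsu_threshold(_seq(frames))
        ref = skimage_otsu(values, nbins=256)
        bin_width = (values.max() - values.min()) / 256
        assert abs(thr - ref) <= bin_width

    def test_pooled_not_per_frame(self):
        # one global threshold: a frame darker overall than another still
        # uses the same cut
        frames = np.stack([np.full((4, 4), 10.0), np.full((4, 4), 200.0)])
        seq = _seq(frames)
        mask = interaction_mask(seq)
        assert mask.mask[0].all() and not mask.mask[1].any()


class TestInteractionMask:
    def test_threshold_below_min_all_false(self, rng):
        frames = rng.integers(10, 100, (3, 4, 4))
        assert not interaction_mask(_seq(frames), threshold=5).mask.any()

    def test_threshold_above_max_all_true(self, rng):
        frames = rng.integers(10, 100, (3, 4, 4))
        assert interaction_mask(_seq(frames), threshold=1000).mask.all()

    def test_strict_comparison_at_threshold(self):
        frames = np.array([[[5.0, 4.9]], [[5.1, 5.0]]])
        mask = interaction_mask(_seq(frames), threshold=5.0)
        np.testing.assert_array_equal(mask.mask,
                                      [[[False, True]], [[False, False]]])

    def test_matches_elementwise_oracle(self, rng):
        frames = rng.normal(size=(4, 5, 5))
        thr = 0.3
        mask = interaction_mask(_seq(frames), threshold=thr).mask
        for t in range(4):
            for i in range(5):
                for j in range(5):
                    assert mask[t, i, j] == (frames[t, i, j] < thr)

    def test_nonfinite_threshold_rejected(self, rng):
        with pytest.raises(ValueError, match="finite"):
            interaction_mask(_seq(rng.normal(size=(2, 3, 3))), threshold=np.inf)

    def test_unfitted_segmenter_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            OtsuInteractionSegmenter().transform(np.zeros((2, 3, 3)))

    def test_sklearn_params_roundtrip(self):
        seg = OtsuInteractionSegmenter()
        assert "roi" in seg.get_params()
        seg.set_params(roi=None)


class TestAreaTrace:
    def test_all_false_zero_curve(self):
        mask = interaction_mask(_seq(np.ones((3, 4, 4))), threshold=0.0)
        np.testing.assert_array_equal(interaction_area_trace(mask), [0, 0, 0])

    def test_constant_k_pixels(self, rng):
        frames = np.ones((5, 6, 6))
        frames[:, 0, :3] = -1.0  # 3 interacting pixels every frame
        mask = interaction_mask(_seq(frames), threshold=0.0)
        np.testing.assert_array_equal(interaction_area_trace(mask), [3] * 5)

    def test_matches_popcount_oracle(self, rng):
        m = rng.random((6, 5, 5)) < 0.4
        mask = interaction_mask(_seq(np.where(m, -1.0, 1.0)), threshold=0.0)
        trace = interaction_area_trace(mask)
        for t in range(6):
            assert trace[t] == int(m[t].sum())


def brute_force_transitions(history):
    """Loop oracle: count True -> False steps."""
    n = 0
    for a, b in zip(history[:-1], history[1:]):
        if a and not b:
            n += 1
    return n


class TestTransitions:
    def _mask_from(self, histories):
        """(P, T) boolean pixel histories -> InteractionMask of shape (T, P, 1)."""
        arr = np.asarray(histories, dtype=bool).T[:, :, None]
        return interaction_mask(_seq(np.where(arr, -1.0, 1.0)), threshold=0.0)

    def test_always_interacting_zero(self):
        mask = self._mask_from([[True] * 6])
        assert accumulate_transitions(mask).counts[0, 0] == 0

    def test_fbfb_pattern_counts_two(self):
        mask = self._mask_from([[True, False, True, False]])
        assert accumulate_transitions(mask).counts[0, 0] == 2

    def test_matches_brute_force(self, rng):
        histories = rng.random((50, 30)) < 0.5
        mask = self._mask_from(histories)
        counts = accumulate_transitions(mask).counts[:, 0]
        for p in range(50):
            assert counts[p] == brute_force_transitions(histories[p])

    def test_cumulative_monotone(self, rng):
        histories = rng.random((20, 40)) < 0.5
        mask = self._mask_from(histories)
        prev = np.zeros(20, dtype=int)
        for t in range(40):
            cur = accumulate_transitions(mask, up_to_frame=t).counts[:, 0]
            assert np.all(cur >= prev)
            prev = cur

    def test_updown_parity(self, rng):
        # drops and rises along one pixel history differ by at most 1
        histories = rng.random((30, 25)) < 0.5
        mask = self._mask_from(histories)
        drops = accumulate_transitions(mask).counts[:, 0]
        for p in range(30):
            h = histories[p]
            rises = sum(1 for a, b in zip(h[:-1], h[1:]) if (not a) and b)
            assert abs(int(drops[p]) - rises) <= 1

    def test_bad_frame_index(self, rng):
        mask = self._mask_from([[True, False, True]])
        with pytest.raises(ValueError, match="up_to_frame"):
            accumulate_transitions(mask, up_to_frame=3)
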