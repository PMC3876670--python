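"""Histogram equalization family: oracles, hand-derived values, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mammopyr.clahe import (
    ClaheParams,
    GrayHistogram,
    apply_clahe,
    apply_he,
    clip_histogram,
    compute_histogram,
    equalization_map,
    equalize_band,
)
from mammopyr.errors import DegenerateInputError, ParameterError
from oracles import histogram_oracle


class TestHistogram:
    def test_constant_image_single_bin(self):
        h = compute_histogram(np.full((5, 5), 0.5), L=8)
        assert h.counts.sum() == 25
        assert h.counts[4] == 25  # 0.5 falls in bin floor(0.5*8)=4

    def test_one_pixel_per_bin(self):
        img = np.array([[0.0, 1 / 3], [2 / 3, 1.0]])
        h = compute_histogram(img, L=4)
        np.testing.assert_array_equal(h.counts, [1, 1, 1, 1])

    def test_matches_tally_oracle(self, rng):
        img = rng.random((8, 8))
        h = compute_histogram(img, L=16)
        np.testing.assert_array_equal(h.counts, histogram_oracle(img, 16))

    def test_rejects_tiny_L(self, small_image):
        with pytest.raises(ParameterError):
            compute_histogram(small_image, L=1)


class TestEqualizationMap:
    def test_uniform_histogram_is_near_identity(self):
        L = 8
        tf = equalization_map(GrayHistogram(np.full(L, 10.0), 80.0, L))
        # s_k = (L-1)*(k+1)/L, within one quantization step of the identity
        np.testing.assert_allclose(tf.mapping, (L - 1) * (np.arange(L) + 1) / L)
        assert np.all(np.diff(tf.mapping) >= 0)

    def test_all_mass_at_zero_maps_to_full_range(self):
        tf = equalization_map(GrayHistogram(np.array([4.0, 0, 0]), 4.0, 3))
        assert tf.mapping[0] == 2.0

    def test_hand_derived_cumsum(self):
        tf = equalization_map(GrayHistogram(np.array([2.0, 1.0, 1.0]), 4.0, 3))
        np.testing.assert_allclose(tf.mapping, [1.0, 1.5, 2.0])

    def test_empty_histogram_rejected(self):
        with pytest.raises(DegenerateInputError):
            equalization_map(GrayHistogram(np.zeros(4), 0.0, 4))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=0, max_value=100), min_size=2, max_size=64))
    def test_mapping_always_monotone(self, counts):
        counts = np.array(counts, dtype=float)
        if counts.sum() == 0:
            counts[0] = 1
        tf = equalization_map(GrayHistogram(counts, counts.sum(), len(counts)))
        assert np.all(np.diff(tf.mapping) >= -1e-12)
        assert np.isclose(tf.mapping[-1], len(counts) - 1)


class TestClipHistogram:
    def test_below_ceiling_unchanged(self):
        h = GrayHistogram(np.array([2.0, 3.0, 2.0, 1.0]), 8.0, 4)
        np.testing.assert_array_equal(clip_histogram(h, 2.0).counts, h.counts)

    def test_maximal_limiting_flattens(self):
        h = GrayHistogram(np.array([16.0, 0, 0, 0]), 16.0, 4)
        out = clip_histogram(h, 1.0)
        assert out.counts.sum() == pytest.approx(16.0)
        assert out.counts.max() - out.counts.min() < h.n / h.L  # near-uniform

    def test_hand_iterated_redistribution(self):
        # ceiling 4; pass 1: [4,0,0,0]+1 -> [5,1,1,1]; pass 2: [4,1,1,1]+0.25
        h = GrayHistogram(np.array([8.0, 0, 0, 0]), 8.0, 4)
        out = clip_histogram(h, 2.0)
        np.testing.assert_allclose(out.counts, [4.25, 1.25, 1.25, 1.25])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=32),
        st.floats(min_value=1.0, max_value=10.0),
    )
    def test_count_conservation(self, counts, clip):
        counts = np.array(counts, dtype=float)
        h = GrayHistogram(counts, counts.sum(), len(counts))
        out = clip_histogram(h, clip)
        assert abs(out.counts.sum() - counts.sum()) < 1.0

    def test_rejects_sub_unit_clip(self):
        h = GrayHistogram(np.ones(4), 4.0, 4)
        with pytest.raises(ParameterError):
            clip_histogram(h, 0.5)


class TestHE:
    def test_constant_maps_to_constant(self):
        out = apply_he(np.full((6, 6), 0.3), L=16)
        assert np.ptp(out) == 0.0

    def test_two_valued_image_pushed_to_mid_and_max(self):
        # half zeros, half ones: cumsum = [0.5, ..., 0.5, 1.0]
        img = np.concatenate([np.zeros(8), np.ones(8)]).reshape(4, 4)
        out = apply_he(img, L=4)
        assert set(np.round(np.unique(out), 6)) == {0.5, 1.0}

    def test_flattens_coarse_histogram(self, rng):
        """Equalization spreads a skewed intensity distribution over the range."""
        img = rng.beta(2, 8, size=(32, 32))  # mass concentrated near 0
        out = apply_he(img, L=64)
        var_in = np.var(histogram_oracle(img, 8))
        var_out = np.var(histogram_oracle(out, 8))
        assert var_out < var_in


class TestClahe:
    def test_constant_image_stays_constant(self):
        out = apply_clahe(np.full((16, 16), 0.4), ClaheParams(tiles=(2, 2), n_bins=32))
        assert np.ptp(out) == 0.0

    def test_degenerates_to_he(self, rng):
        img = rng.random((20, 24))
        params = ClaheParams(tiles=(1, 1), clip_limit=1e6, n_bins=64)
        np.testing.assert_array_equal(
            apply_clahe(img, params), apply_he(img, L=64)
        )

    def test_matches_independent_per_pixel_reference(self, rng):
        """Two-texture image against a straightforward reimplementation."""
        img = np.concatenate(
            [0.2 + 0.1 * rng.random((32, 16)), 0.6 + 0.3 * rng.random((32, 16))],
            axis=1,
        )
        params = ClaheParams(tiles=(2, 2), clip_limit=2.0, n_bins=32)
        got = apply_clahe(img, params)
        expected = _clahe_reference(img, params)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_loosely_agrees_with_skimage(self, rng):
        """Independent library cross-check: outputs strongly correlated."""
        skimage = pytest.importorskip("skimage")
        from skimage import exposure

        img = rng.random((64, 64))
        ours = apply_clahe(img, ClaheParams(tiles=(8, 8), clip_limit=2.5, n_bins=256))
        theirs = exposure.equalize_adapthist(img, kernel_size=8, clip_limit=0.01)
        assert np.corrcoef(ours.ravel(), theirs.ravel())[0, 1] > 0.9

    def test_oversized_tile_grid_rejected(self, rng):
        with pytest.raises(ParameterError):
            apply_clahe(rng.random((8, 8)), ClaheParams(tiles=(8, 8)))

    def test_deterministic(self, rng):
        img = rng.random((32, 32))
        params = ClaheParams(tiles=(4, 4))
        np.testing.assert_array_equal(apply_clahe(img, params), apply_clahe(img, params))


def _clahe_reference(img, params):
    """Straightforward per-pixel reimplementation of clip + bilinear blend."""
    h, w = img.shape
    rows, cols = params.tiles
    L = params.n_bins
    re = np.round(np.linspace(0, h, rows + 1)).astype(int)
    ce = np.round(np.linspace(0, w, cols + 1)).astype(int)
    maps = {}
    for i in range(rows):
        for j in range(cols):
            tile = img[re[i]:re[i + 1], ce[j]:ce[j + 1]]
            hist = compute_histogram(tile, L)
            hist = clip_histogram(hist, params.clip_limit)
            maps[i, j] = equalization_map(hist).mapping
    rc = (re[:-1] + re[1:] - 1) / 2.0
    cc = (ce[:-1] + ce[1:] - 1) / 2.0
    out = np.zeros_like(img)
    for y in range(h):
        for x in range(w):
            py = np.interp(y, rc, np.arange(rows))
            px = np.interp(x, cc, np.arange(cols))
            i0, j0 = int(np.floor(py)), int(np.floor(px))
            wy, wx = py - i0, px - j0
            i1, j1 = min(i0 + 1, rows - 1), min(j0 + 1, cols - 1)
            b = min(int(img[y, x] * L), L - 1)
            s = ((1 - wy) * (1 - wx) * maps[i0, j0][b]
                 + (1 - wy) * wx * maps[i0, j1][b]
                 + wy * (1 - wx) * maps[i1, j0][b]
                 + wy * wx * maps[i1, j1][b])
            out[y, x] = s / (L - 1)
    return out


class TestEqualizeBand:
    def test_zero_band_passes_through(self):
        band = np.zeros((16, 16))
        np.testing.assert_array_equal(
            equalize_band(band, ClaheParams(tiles=(2, 2)), 0.5), band
        )

    def test_reduces_to_affine_wrapped_he(self, rng):
        band = rng.standard_normal((24, 24))
        params = ClaheParams(tiles=(1, 1), clip_limit=1e6, n_bins=64)
        got = equalize_band(band, params, smooth_sigma=0.0)
        lo, hi = band.min(), band.max()
        expected = apply_he((band - lo) / (hi - lo), L=64) * (hi - lo) + lo
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_impulses_rise_relative_to_background(self, rng):
        """Sparse bright impulses on weak noise keep their prominence."""
        band = 0.01 * rng.standard_normal((64, 64))
        peaks = [(10, 12), (30, 44), (52, 20)]
        for y, x in peaks:
            band[y, x] += 1.0
        out = equalize_band(band, ClaheParams(tiles=(2, 2), clip_limit=4.0), 0.5)

        def prominence(a):
            peak = np.mean([a[y, x] for y, x in peaks])
            return peak - np.median(a)

        assert prominence(out) > 0
        assert out.min() >= band.min() - 1e-9 and out.max() <= band.max() + 1e-9
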