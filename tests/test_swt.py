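"""Undecimated Haar transform: window algebra, inversion, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wfsan.swt import (
    WaveletBands,
    iswt2_level1,
    merge_bands,
    split_bands,
    subband_stats,
    swt2_level1,
)


def oracle_swt(img):
    """Brute-force reference: slide a 2x2 window with periodic wrap and
    apply the signed half-sum algebra at every position."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    planes = {k: np.zeros((h, w)) for k in "AHVD"}
    for i in range(h):
        for j in range(w):
            a = img[i, j]
            b = img[i, (j + 1) % w]
            c = img[(i + 1) % h, j]
            d = img[(i + 1) % h, (j + 1) % w]
            planes["A"][i, j] = 0.5 * (a + b + c + d)
            planes["H"][i, j] = 0.5 * (a + b - c - d)
            planes["V"][i, j] = 0.5 * (a - b + c - d)
            planes["D"][i, j] = 0.5 * (a - b - c + d)
    return planes


class TestDecomposition:
    def test_worked_2x2_example(self):
        bands = swt2_level1([[100.0, 50.0], [30.0, 20.0]])
        assert bands.A[0, 0] == 100.0
        assert bands.H[0, 0] == 50.0
        assert bands.V[0, 0] == 30.0
        assert bands.D[0, 0] == 20.0

    def test_constant_image_has_zero_details(self):
        bands = swt2_level1(np.full((5, 7), 42.0))
        assert np.allclose(bands.A, 84.0)
        for plane in (bands.H, bands.V, bands.D):
            assert np.allclose(plane, 0.0)

    @pytest.mark.parametrize("shape", [(2, 2), (3, 5), (8, 8), (7, 4)])
    def test_matches_sliding_window_oracle(self, rng, shape):
        img = rng.integers(0, 256, size=shape).astype(float)
        bands = swt2_level1(img)
        ref = oracle_swt(img)
        for name in "AHVD":
            np.testing.assert_allclose(getattr(bands, name), ref[name], atol=1e-12)

    def test_exhaustive_corner_blocks(self):
        # all 16 binary 2x2 corner images at the 8-bit extremes
        for bits in range(16):
            img = np.array(
                [[255.0 * (bits >> 3 & 1), 255.0 * (bits >> 2 & 1)],
                 [255.0 * (bits >> 1 & 1), 255.0 * (bits & 1)]]
            )
            bands = swt2_level1(img)
            ref = oracle_swt(img)
            for name in "AHVD":
                np.testing.assert_array_equal(getattr(bands, name), ref[name])

    def test_matches_pywavelets(self, rng):
        pywt = pytest.importorskip("pywt")
        img = rng.integers(0, 256, size=(16, 16)).astype(float)
        ((ca, (ch, cv, cd)),) = pywt.swt2(img, "haar", level=1)
        bands = swt2_level1(img)
        np.testing.assert_allclose(bands.A, ca, atol=1e-10)
        np.testing.assert_allclose(bands.H, ch, atol=1e-10)
        np.testing.assert_allclose(bands.V, cv, atol=1e-10)
        np.testing.assert_allclose(bands.D, cd, atol=1e-10)

    def test_rejects_degenerate_images(self):
        with pytest.raises(ValueError):
            swt2_level1(np.ones((1, 8)))
        with pytest.raises(ValueError):
            swt2_level1(np.ones(5))

    @settings(deadline=None, max_examples=25)
    @given(
        alpha=st.floats(-3, 3, allow_nan=False),
        beta=st.floats(-3, 3, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_linearity(self, alpha, beta, seed):
        r = np.random.default_rng(seed)
        x = r.random((6, 6)) * 255
        y = r.random((6, 6)) * 255
        lhs = swt2_level1(alpha * x + beta * y)
        bx, by = swt2_level1(x), swt2_level1(y)
        for name in "AHVD":
            np.testing.assert_allclose(
                getattr(lhs, name),
                alpha * getattr(bx, name) + beta * getattr(by, name),
                atol=1e-8,
            )


class TestInverse:
    def test_constant_bands_invert_to_constant(self):
        bands = WaveletBands(np.full((4, 4), 10.0), np.zeros((4, 4)),
                             np.zeros((4, 4)), np.zeros((4, 4)))
        np.testing.assert_allclose(iswt2_level1(bands), 5.0)

    def test_zero_bands_invert_to_zero(self):
        z = np.zeros((3, 3))
        np.testing.assert_array_equal(iswt2_level1(WaveletBands(z, z, z, z)), 0.0)

    def test_round_trip_random_images(self, rng):
        for _ in range(50):
            h, w = rng.integers(2, 40, size=2)
            img = rng.random((h, w)) * 255
            rec = iswt2_level1(swt2_level1(img))
            assert np.abs(rec - img).max() <= 1e-8

    def test_round_trip_odd_sizes(self, rng):
        img = rng.random((5, 9)) * 255
        np.testing.assert_allclose(iswt2_level1(swt2_level1(img)), img, atol=1e-8)

    def test_mismatched_plane_shapes_rejected(self):
        with pytest.raises(ValueError):
            WaveletBands(np.zeros((4, 4)), np.zeros((4, 4)),
                         np.zeros((4, 4)), np.zeros((8, 8)))


class TestSplitMerge:
    def test_split_orders_channels(self, random_image):
        bands = swt2_level1(random_image)
        approx, details = split_bands(bands)
        assert approx.shape == (1,) + bands.shape
        assert details.shape == (3,) + bands.shape
        np.testing.assert_array_equal(approx[0], bands.A)
        np.testing.assert_array_equal(details[0], bands.H)
        np.testing.assert_array_equal(details[1], bands.V)
        np.testing.assert_array_equal(details[2], bands.D)

    def test_merge_inverts_split(self, random_image):
        bands = swt2_level1(random_image)
        rebuilt = merge_bands(*split_bands(bands))
        for name in "AHVD":
            np.testing.assert_array_equal(getattr(rebuilt, name), getattr(bands, name))

    def test_merge_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            merge_bands(np.zeros((4, 4)), np.zeros((2, 4, 4)))
        with pytest.raises(ValueError):
            merge_bands(np.zeros((4, 4)), np.zeros((3, 8, 8)))


class TestStats:
    def test_approx_mean_doubles_image_mean(self, rng):
        for _ in range(10):
            img = rng.random((rng.integers(2, 30), rng.integers(2, 30))) * 255
            st_ = subband_stats(swt2_level1(img))
            assert abs(st_["A"]["mean"] - 2 * img.mean()) < 1e-9

    def test_detail_means_are_zero(self, rng):
        img = rng.integers(0, 256, size=(17, 23)).astype(float)
        st_ = subband_stats(swt2_level1(img))
        for name in "HVD":
            assert abs(st_[name]["mean"]) < 1e-9

    def test_detail_sums_are_zero(self, rng):
        img = rng.random((12, 12)) * 255
        bands = swt2_level1(img)
        for plane in (bands.H, bands.V, bands.D):
            assert abs(plane.sum()) < 1e-6

    def test_constant_image_zero_std(self):
        st_ = subband_stats(swt2_level1(np.full((6, 6), 7.0)))
        for name in "AHVD":
            assert st_[name]["std"] == 0.0

    def test_range_bounds_8bit(self, rng):
        img = rng.integers(0, 256, size=(16, 16)).astype(float)
        bands = swt2_level1(img)
        assert bands.A.min() >= 0.0 and bands.A.max() <= 510.0
        for plane in (bands.H, bands.V, bands.D):
            assert np.abs(plane).max() <= 255.0
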