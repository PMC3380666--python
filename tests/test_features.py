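import numpy as np
import pytest

from gaborseg.features import (FeatureLayout, PixelFeatureMatrix, assemble_features,
                               destandardize, rgb_to_luv, standardize)
from gaborseg.gabor import GaborParams, filter_bank_response
from gaborseg.io import FundusImage


def reference_luv(rgb8):
    """Textbook CIE route, coded independently: sRGB → linear → XYZ (D65) → L*u*v*."""
    rgb = np.asarray(rgb8, dtype=float) / 255.0
    lin = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    M = np.array([[0.4124564, 0.3575761, 0.1804375],
                  [0.2126729, 0.7151522, 0.0721750],
                  [0.0193339, 0.1191920, 0.9503041]])
    X, Y, Z = M @ lin
    Xn, Yn, Zn = M @ np.ones(3)          # white point of the sRGB primaries
    eps, kappa = 216 / 24389, 24389 / 27
    yr = Y / Yn
    L = 116 * yr ** (1 / 3) - 16 if yr > eps else kappa * yr
    denom = X + 15 * Y + 3 * Z
    un_prime = 4 * Xn / (Xn + 15 * Yn + 3 * Zn)
    vn_prime = 9 * Yn / (Xn + 15 * Yn + 3 * Zn)
    if denom == 0:
        return np.array([L, 0.0, 0.0])
    u_prime, v_prime = 4 * X / denom, 9 * Y / denom
    return np.array([L, 13 * L * (u_prime - un_prime), 13 * L * (v_prime - vn_prime)])


def stack_for(channel, n_scales=4):
    return filter_bank_response(channel, GaborParams(sigmas=(3., 5., 7., 9.)[:n_scales]))


class TestRgbToLuv:
    def test_black_and_white_anchors(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        luv = rgb_to_luv(FundusImage(pixels=img))
        np.testing.assert_allclose(luv[0, 0], [0, 0, 0], atol=1e-6)
        img[:] = 255
        luv = rgb_to_luv(FundusImage(pixels=img))
        assert luv[0, 0, 0] == pytest.approx(100, abs=0.01)
        assert abs(luv[0, 0, 1]) <= 0.5 and abs(luv[0, 0, 2]) <= 0.5

    @pytest.mark.parametrize("rgb", [(255, 0, 0), (0, 128, 255), (40, 200, 90),
                                     (17, 17, 17)])
    def test_against_independent_cie_oracle(self, rgb):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        img[:] = rgb
        got = rgb_to_luv(FundusImage(pixels=img))[0, 0]
        np.testing.assert_allclose(got, reference_luv(rgb), atol=0.01)


class TestAssemble:
    def test_default_layout_is_15d(self):
        assert FeatureLayout().dim == 15
        rng = np.random.default_rng(0)
        stack = stack_for(rng.uniform(size=(32, 32)))
        luv = rng.uniform(size=(32, 32, 3))
        fm = assemble_features(stack, luv, [(5, 5), (10, 20)])
        assert fm.features.shape == (2, 15)

    def test_constant_image(self):
        stack = stack_for(np.full((32, 32), 0.4))
        luv = np.tile(np.array([50.0, 10.0, -20.0]), (32, 32, 1))
        fm = assemble_features(stack, luv, [(8, 8), (16, 16), (20, 4)])
        np.testing.assert_allclose(fm.features[:, :4], 0, atol=1e-8)   # Gabor ≈ 0
        np.testing.assert_allclose(fm.features[:, 4:13], 50.0)         # all L equal
        np.testing.assert_allclose(fm.features[:, 13], 10.0)
        np.testing.assert_allclose(fm.features[:, 14], -20.0)

    def test_single_pixel_against_hand_concatenation(self):
        rng = np.random.default_rng(1)
        stack = stack_for(rng.uniform(size=(32, 32)))
        luv = rng.normal(size=(32, 32, 3))
        r, c = 13, 17
        row = assemble_features(stack, luv, [(r, c)]).features[0]
        expected = [stack.max_maps[s, r, c] for s in range(4)]
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                expected.append(luv[r + dr, c + dc, 0])   # window L*, row-major
        expected += [luv[r, c, 1], luv[r, c, 2]]
        np.testing.assert_allclose(row, expected, rtol=0, atol=0)

    def test_border_pixels_use_reflection(self):
        rng = np.random.default_rng(2)
        stack = stack_for(rng.uniform(size=(32, 32)))
        luv = rng.normal(size=(32, 32, 3))
        row = assemble_features(stack, luv, [(0, 0)]).features[0]
        # reflected window: L*[|dr|, |dc|]
        assert row[4] == luv[1, 1, 0] and row[8] == luv[0, 0, 0]

    def test_pixel_outside_image_named(self):
        stack = stack_for(np.zeros((32, 32)))
        with pytest.raises(IndexError, match=r"\(40, 2\)"):
            assemble_features(stack, np.zeros((32, 32, 3)), [(2, 2), (40, 2)])

    def test_permutation_consistency(self):
        rng = np.random.default_rng(3)
        stack = stack_for(rng.uniform(size=(32, 32)))
        luv = rng.normal(size=(32, 32, 3))
        pixels = rng.integers(2, 30, size=(20, 2))
        perm = rng.permutation(20)
        a = assemble_features(stack, luv, pixels).features
        b = assemble_features(stack, luv, pixels[perm]).features
        np.testing.assert_array_equal(a[perm], b)

    def test_translation_property(self):
        # shifting image content and pixel list together leaves rows unchanged
        rng = np.random.default_rng(4)
        base = rng.uniform(size=(48, 48))
        luv = rng.normal(size=(48, 48, 3))
        shifted = np.roll(base, (5, 3), axis=(0, 1))
        luv_shifted = np.roll(luv, (5, 3), axis=(0, 1))
        p = GaborParams(sigmas=(3.0,), orientations_deg=(0, 90))
        layout = FeatureLayout(n_gabor=1)
        a = assemble_features(filter_bank_response(base, p), luv, [(24, 24)], layout)
        b = assemble_features(filter_bank_response(shifted, p), luv_shifted,
                              [(29, 27)], layout)
        np.testing.assert_allclose(a.features, b.features, atol=1e-10)


class TestStandardize:
    def _matrix(self, X):
        n = X.shape[0]
        return PixelFeatureMatrix(features=X, coords=np.zeros((n, 2), dtype=int),
                                  image_ids=np.array(["i"] * n), layout=None)

    def test_fit_gives_zero_mean_unit_sd(self):
        X = np.random.default_rng(0).normal(2, 5, size=(200, 6))
        out, stats = standardize(self._matrix(X), "fit")
        np.testing.assert_allclose(out.features.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(out.features.std(axis=0), 1, atol=1e-6)

    def test_constant_column_passes_through_centred(self):
        X = np.random.default_rng(1).normal(size=(50, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            out, _ = standardize(self._matrix(X), "fit")
        np.testing.assert_allclose(out.features[:, 1], 0.0)

    def test_round_trip_with_train_stats(self):
        rng = np.random.default_rng(2)
        train = self._matrix(rng.normal(size=(100, 4)))
        test = self._matrix(rng.normal(size=(30, 4)))
        _, stats = standardize(train, "fit")
        std_test, _ = standardize(test, stats)
        back = destandardize(std_test)
        np.testing.assert_allclose(back.features, test.features, atol=1e-10)

    def test_stats_dim_mismatch(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="dimensionality"):
            standardize(self._matrix(X), (np.zeros(5), np.ones(5)))

    def test_window_must_be_odd(self):
        with pytest.raises(ValueError, match="odd"):
            FeatureLayout(window=4)
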