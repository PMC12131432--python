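"""Masked smoothing, quartile statistics, and the redness/ARTIX scores."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from artix.colorimetry import (
    artix_score,
    channel_stats,
    masked_gaussian_smooth,
    redness_score,
)
from artix.fingers import segment_fingers
from artix.types import ChannelStats, FingerRegion, RegionTooSmallError


def _rect_region(shape, y0, y1, x0, x1, finger="index", hand="right"):
    m = np.zeros(shape, dtype=bool)
    m[y0:y1, x0:x1] = True
    sk = np.array([[x0, y1], [x0, y0]], dtype=float)
    return FingerRegion(finger=finger, hand=hand, mask=m, skeleton=sk)


def _stats(median_r, q1_r, q3_r):
    fill = {"G": 100.0, "B": 100.0}
    return ChannelStats(median={"R": median_r, **fill},
                        q1={"R": q1_r, **fill}, q3={"R": q3_r, **fill}, n_pixels=100)


def brute_force_quantile(values, q):
    """Independent linear-interpolation quantile (sort + index arithmetic)."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestMaskedSmoothing:
    def test_constant_region_unchanged_any_sigma(self):
        img = np.full((40, 40, 3), 100.0)
        reg = _rect_region((40, 40), 5, 25, 5, 25)
        for sigma in (0.5, 2.0, 5.0):
            out = masked_gaussian_smooth(img, reg, sigma)
            assert np.allclose(out[reg.mask], 100.0)

    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 255, (30, 30, 3))
        reg = _rect_region((30, 30), 3, 20, 3, 20)
        out = masked_gaussian_smooth(img, reg, 0)
        assert np.array_equal(out[reg.mask], img[reg.mask])

    def test_outlier_is_damped_not_propagated(self):
        img = np.full((40, 40, 3), 100.0)
        img[10, 10, :] = 255.0
        reg = _rect_region((40, 40), 5, 25, 5, 25)
        out = masked_gaussian_smooth(img, reg, 2.0)
        red = out[..., 0][reg.mask]
        assert red.max() < 255.0
        assert np.median(red) == pytest.approx(100.0, abs=0.5)

    def test_background_does_not_bleed_into_region(self):
        # region borders a bright background; mask-normalized smoothing must
        # ignore it entirely
        img = np.full((40, 40, 3), 255.0)
        img[5:25, 5:25, :] = 100.0
        reg = _rect_region((40, 40), 5, 25, 5, 25)
        out = masked_gaussian_smooth(img, reg, 3.0)
        assert np.allclose(out[reg.mask], 100.0)

    def test_empty_region_raises(self):
        reg = _rect_region((20, 20), 5, 5, 5, 5)
        with pytest.raises(RegionTooSmallError):
            masked_gaussian_smooth(np.zeros((20, 20, 3)), reg, 1.0)


class TestChannelStats:
    def test_five_value_quartiles(self):
        img = np.zeros((5, 5, 3))
        img[0, :5, :] = np.array([10, 20, 30, 40, 50])[:, None]
        reg = _rect_region((5, 5), 0, 1, 0, 5)
        st_ = channel_stats(img, reg, min_pixels=5)
        assert st_.median["R"] == 30 and st_.q1["R"] == 20 and st_.q3["R"] == 40

    def test_constant_region_collapses_quartiles(self):
        img = np.full((30, 30, 3), 128.0)
        reg = _rect_region((30, 30), 0, 10, 0, 10)
        st_ = channel_stats(img, reg)
        assert st_.median["R"] == st_.q1["R"] == st_.q3["R"] == 128

    def test_region_below_minimum_rejected(self):
        img = np.zeros((20, 20, 3))
        reg = _rect_region((20, 20), 0, 2, 0, 5)  # 10 px < default 25
        with pytest.raises(RegionTooSmallError):
            channel_stats(img, reg)

    @given(st.lists(st.floats(0, 255, allow_nan=False, width=32), min_size=25, max_size=60))
    def test_quantiles_match_brute_force_oracle(self, values):
        arr = np.array(values, dtype=float)
        img = np.zeros((1, arr.size, 3))
        img[0, :, 0] = arr
        reg = _rect_region((1, arr.size), 0, 1, 0, arr.size)
        st_ = channel_stats(img, reg, min_pixels=1)
        for q, got in ((0.25, st_.q1["R"]), (0.5, st_.median["R"]), (0.75, st_.q3["R"])):
            assert got == pytest.approx(brute_force_quantile(arr, q), abs=1e-9)


class TestRednessScore:
    @pytest.mark.parametrize("med,q1,q3,expected", [
        (200, 180, 220, 400),   # median + midhinge
        (255, 255, 255, 510),   # formula maximum, all-white region
        (128, 128, 128, 256),   # mid-gray
    ])
    def test_formula_arithmetic(self, med, q1, q3, expected):
        assert redness_score(_stats(med, q1, q3)) == pytest.approx(expected)


class TestArtixScore:
    def _uniform_frame(self, reds, size=64):
        """8 rectangular scoring regions with given red values on one image."""
        img = np.zeros((size, size, 3))
        regions = []
        fingers = ["index", "middle", "ring", "pinky"]
        for i, r in enumerate(reds):
            hand = "left" if i < 4 else "right"
            x0 = 8 * i
            img[:, x0:x0 + 7, 0] = r
            regions.append(_rect_region((size, size), 0, 8, x0, x0 + 7,
                                        finger=fingers[i % 4], hand=hand))
        return img, regions

    def test_mean_identity(self):
        img, regions = self._uniform_frame([200.0] * 8)
        assert artix_score(img, regions).value == pytest.approx(400.0)

    def test_mean_of_mixed_fingers(self):
        img, regions = self._uniform_frame([150.0] * 4 + [200.0] * 4)
        assert artix_score(img, regions).value == pytest.approx(350.0)

    def test_small_fingers_skipped_with_warning_then_error(self):
        img, regions = self._uniform_frame([200.0] * 8)
        regions[0].mask[:, :] = False
        regions[0].mask[0, 0] = True  # 1 px, below minimum
        with pytest.warns(RuntimeWarning, match="skipped"):
            score = artix_score(img, regions)
        assert score.value == pytest.approx(400.0)
        for reg in regions[1:3]:
            reg.mask[:, :] = False
            reg.mask[0, 0] = True
        with pytest.raises(RegionTooSmallError):
            artix_score(img, regions)

    def test_permutation_invariance(self):
        img, regions = self._uniform_frame(np.linspace(120, 220, 8))
        a = artix_score(img, regions).value
        b = artix_score(img, regions[::-1]).value
        assert a == pytest.approx(b)

    def test_raising_red_in_one_finger_never_decreases_score(self):
        img, regions = self._uniform_frame(np.linspace(120, 220, 8))
        base = artix_score(img, regions).value
        img2 = img.copy()
        img2[..., 0][regions[3].mask] += 20.0
        assert artix_score(img2, regions).value >= base

    def test_thumb_recolour_leaves_score_unchanged(self, default_hand):
        h = default_hand
        regions = segment_fingers(h.mask, h.landmarks)
        before = artix_score(h.image, regions)
        recoloured = h.image.copy()
        recoloured[regions[0].mask] = (0, 0, 255)  # pure blue thumb
        after = artix_score(recoloured, regions)
        assert after.value == before.value
        assert after.per_finger == before.per_finger

    def test_salt_and_pepper_outliers_barely_move_redness(self):
        rng = np.random.default_rng(8)
        img = np.full((64, 64, 3), 150.0)
        reg = _rect_region((64, 64), 4, 60, 4, 60)
        n = reg.mask.sum()
        ys, xs = np.nonzero(reg.mask)
        pick = rng.choice(n, size=int(0.01 * n), replace=False)
        noisy = img.copy()
        noisy[ys[pick], xs[pick], :] = rng.choice([0.0, 255.0], size=(pick.size, 1))
        sm_clean = masked_gaussian_smooth(img, reg, 2.0)
        sm_noisy = masked_gaussian_smooth(noisy, reg, 2.0)
        r_clean = redness_score(channel_stats(sm_clean, reg))
        r_noisy = redness_score(channel_stats(sm_noisy, reg))
        assert abs(r_noisy - r_clean) < 2.0
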