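"""Masked colour statistics and the ARTIX redness score.

Inside each finger region the RGB channels are Gaussian-smoothed with a
mask-normalized kernel (background pixels carry zero weight, so region
borders do not bleed background into the statistics), summarized by
linear-interpolation quartiles, and condensed into a per-finger redness:

    redness = median_R + (Q1_R + Q3_R) / 2

i.e. the median plus the midhinge of the smoothed red channel.  Green and
blue quartiles are always computed and reported; an optional penalty weight
folds them into the score (default 0).  The ARTIX value of an assessment is
the arithmetic mean of redness over the eight non-thumb digits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fingers import scoring_regions
from .types import ArtixScore, ChannelStats, FingerRegion, RegionTooSmallError

FORMULA_VERSION = "redness-v1-median-midhinge"

#: Fewer pixels than this and quartiles are considered unreliable.
MIN_REGION_PIXELS = 25


@dataclass
class RednessWeights:
    """Configurable weights of the redness formula."""

    median_r: float = 1.0
    midhinge_r: float = 1.0
    green_blue_penalty: float = 0.0


def masked_gaussian_smooth(image: np.ndarray, region: FingerRegion, sigma: float) -> np.ndarray:
    """Per-channel Gaussian smoothing normalized over the region mask.

    Returns an ``(H, W, 3)`` float array valid inside the region (zero
    elsewhere).  ``sigma = 0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    m = region.mask
    if not m.any():
        raise RegionTooSmallError("empty region")
    img = np.asarray(image, dtype=float)
    out = np.zeros_like(img)
    if sigma == 0:
        out[m] = img[m]
        return out
    weight = ndimage.gaussian_filter(m.astype(float), sigma)
    for c in range(3):
        num = ndimage.gaussian_filter(np.where(m, img[..., c], 0.0), sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            ch = num / weight
        out[..., c][m] = ch[m]
    return out


def channel_stats(smoothed: np.ndarray, region: FingerRegion,
                  min_pixels: int = MIN_REGION_PIXELS) -> ChannelStats:
    """Median and quartiles (linear-interpolation) per channel in the region."""
    m = region.mask
    n = int(m.sum())
    if n < min_pixels:
        raise RegionTooSmallError(f"region {region.finger_id} has {n} px < {min_pixels}")
    med, q1, q3 = {}, {}, {}
    for i, c in enumerate("RGB"):
        vals = np.asarray(smoothed, dtype=float)[..., i][m]
        q1[c], med[c], q3[c] = np.quantile(vals, [0.25, 0.5, 0.75])
    return ChannelStats(median=med, q1=q1, q3=q3, n_pixels=n)


def redness_score(stats: ChannelStats, weights: RednessWeights | None = None) -> float:
    """Redness of one finger from its smoothed red-channel quartiles."""
    w = weights or RednessWeights()
    value = w.median_r * stats.median["R"] + w.midhinge_r * (stats.q1["R"] + stats.q3["R"]) / 2.0
    if w.green_blue_penalty:
        value -= w.green_blue_penalty * (stats.median["G"] + stats.median["B"]) / 2.0
    return float(value)


def artix_score(image: np.ndarray, regions, sigma: float = 2.0,
                min_pixels: int = MIN_REGION_PIXELS,
                weights: RednessWeights | None = None,
                timepoint_label: str | None = None) -> ArtixScore:
    """Mean redness over the non-thumb regions of an assessment.

    Fingers whose region is below the pixel minimum are skipped with a
    warning as long as at most two of the scoring digits are lost (six of
    eight for a two-hand frame); more failures raise
    :class:`RegionTooSmallError`.
    """
    scoring = scoring_regions(regions)
    per_finger, failed = {}, []
    for reg in scoring:
        try:
            sm = masked_gaussian_smooth(image, reg, sigma)
            st = channel_stats(sm, reg, min_pixels=min_pixels)
            per_finger[reg.finger_id] = redness_score(st, weights)
        except RegionTooSmallError:
            failed.append(reg.finger_id)
    min_valid = max(1, len(scoring) - 2)
    if len(per_finger) < min_valid:
        raise RegionTooSmallError(
            f"only {len(per_finger)} of {len(scoring)} scoring fingers usable")
    if failed:
        warnings.warn(f"fingers skipped as too small: {', '.join(failed)}",
                      RuntimeWarning, stacklevel=2)
    value = float(np.mean(list(per_finger.values())))
    return ArtixScore(value=value, per_finger=per_finger,
                      timepoint_label=timepoint_label, formula_version=FORMULA_VERSION)
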