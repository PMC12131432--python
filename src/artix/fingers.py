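"""Landmark-driven finger extraction from a hand mask.

Each digit's skeleton is the MCP->TIP polyline through its landmark chain.  A
mask pixel joins digit *d* when (a) its projection onto *d*'s proximal axis
lies distal to the MCP and (b) its distance to the skeleton is at most the
digit's half-width estimate (half the distance to the nearest adjacent MCP).
Pixels eligible for several digits go to the nearest skeleton; exact ties to
the lower finger index (thumb < index < middle < ring < pinky).
"""

from __future__ import annotations

import numpy as np

from .types import (
    FINGER_MCP,
    FINGER_SKELETON,
    FINGERS,
    FingerRegion,
    HandLandmarkSet,
    LandmarkMisalignmentError,
)


def rescale_landmarks(lms: HandLandmarkSet, mask_shape, source_shape=None) -> HandLandmarkSet:
    """Map landmarks onto the pixel grid of ``mask_shape`` (``(H, W)``).

    Normalized coordinates map as ``x_px = x * (W - 1)``, ``y_px = y * (H - 1)``.
    Pixel coordinates from a ``source_shape`` grid are scaled by the per-axis
    shape ratio; with ``source_shape`` omitted or equal to ``mask_shape`` the
    operation is the identity, so it is idempotent.
    """
    h, w = int(mask_shape[0]), int(mask_shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("mask shape must be positive")
    pts = lms.points.copy()
    if lms.normalized:
        if pts.min() < 0.0 or pts.max() > 1.0:
            raise ValueError("normalized landmarks must lie in [0, 1]")
        pts[:, 0] *= (w - 1)
        pts[:, 1] *= (h - 1)
    elif source_shape is not None:
        sh, sw = int(source_shape[0]), int(source_shape[1])
        if sh <= 0 or sw <= 0:
            raise ValueError("source shape must be positive")
        pts[:, 0] *= w / sw
        pts[:, 1] *= h / sh
    return HandLandmarkSet(pts, handedness=lms.handedness, normalized=False)


def _polyline_segments(pts: np.ndarray):
    return [(pts[i], pts[i + 1]) for i in range(len(pts) - 1)]


def _dist_to_segment(px, py, a, b):
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.hypot(px - a[0], py - a[1])
    t = np.clip(((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom, 0.0, 1.0)
    return np.hypot(px - (a[0] + t * ab[0]), py - (a[1] + t * ab[1]))


def segment_fingers(mask: np.ndarray, lms: HandLandmarkSet,
                    half_width_scale: float = 0.5) -> list:
    """Partition the digit area of ``mask`` into five :class:`FingerRegion`.

    ``lms`` must be in pixel coordinates of the mask grid (normalized sets
    are rescaled first).  Raises :class:`LandmarkMisalignmentError` when no
    landmark falls inside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if lms.normalized:
        lms = rescale_landmarks(lms, mask.shape)
    pts = lms.points

    ix = np.clip(np.rint(pts[:, 0]).astype(int), 0, w - 1)
    iy = np.clip(np.rint(pts[:, 1]).astype(int), 0, h - 1)
    if not mask[iy, ix].any():
        raise LandmarkMisalignmentError("all landmarks fall outside the hand mask")

    mcps = {f: pts[FINGER_MCP[f]] for f in FINGERS}
    half_width = {}
    for i, f in enumerate(FINGERS):
        neigh = []
        if i > 0:
            neigh.append(np.linalg.norm(mcps[f] - mcps[FINGERS[i - 1]]))
        if i < len(FINGERS) - 1:
            neigh.append(np.linalg.norm(mcps[f] - mcps[FINGERS[i + 1]]))
        half_width[f] = half_width_scale * min(neigh)

    ys, xs = np.nonzero(mask)
    px = xs.astype(float)
    py = ys.astype(float)

    dist = np.full((len(FINGERS), px.size), np.inf)
    for i, f in enumerate(FINGERS):
        chain = pts[list(FINGER_SKELETON[f])]
        u = chain[1] - chain[0]
        nu = np.linalg.norm(u)
        if nu == 0:
            continue
        u = u / nu
        proj = (px - chain[0][0]) * u[0] + (py - chain[0][1]) * u[1]
        d = np.full(px.size, np.inf)
        for a, b in _polyline_segments(chain):
            np.minimum(d, _dist_to_segment(px, py, a, b), out=d)
        eligible = (proj >= 0.0) & (d <= half_width[f])
        dist[i, eligible] = d[eligible]

    assigned = np.argmin(dist, axis=0)          # exact ties -> lower finger index
    valid = np.isfinite(dist[assigned, np.arange(px.size)])

    regions = []
    for i, f in enumerate(FINGERS):
        m = np.zeros((h, w), dtype=bool)
        sel = valid & (assigned == i)
        m[ys[sel], xs[sel]] = True
        regions.append(FingerRegion(finger=f, hand=lms.handedness, mask=m,
                                    skeleton=pts[list(FINGER_SKELETON[f])]))
    return regions


def scoring_regions(regions) -> list:
    """The non-thumb regions that enter the ARTIX score (8 for two hands)."""
    out = [r for r in regions if not r.is_thumb]
    if not out:
        raise ValueError("no non-thumb regions to score")
    return out
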