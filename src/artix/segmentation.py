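"""Hand segmentation: classical fallback, trainable model, and IoU validation.

Two interchangeable paths produce a binary hand mask from an RGB photograph:

* :func:`segment_hand_classical` — deterministic chroma thresholding against
  the background palette estimated from the frame border, followed by
  morphological cleanup.  No training required.
* :func:`train_segmenter` / :func:`segment_hand_model` — a seeded pixelwise
  classifier (small MLP on raw and Gaussian-smoothed colour features) trained
  on (image, mask) pairs, thresholded at 0.5 probability and cleaned up the
  same way.  The model sits behind a minimal interface so a heavier
  encoder-decoder can be swapped in without touching callers.

Overlap between predicted and reference masks is measured as
intersection-over-union (:func:`mask_overlap`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology, transform
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .types import NoHandFoundError

DEFAULT_SIDE = 512


@dataclass
class ResizeResult:
    """A square-resized image plus the factors mapping source x/y to it."""

    image: np.ndarray
    scale_x: float
    scale_y: float


def resize_square(image: np.ndarray, side: int = DEFAULT_SIDE) -> ResizeResult:
    """Bilinearly resize to ``side x side``, recording per-axis scale factors.

    ``scale_x = side / W`` and ``scale_y = side / H`` map source pixel
    coordinates onto the resized grid (used to carry landmarks along).
    """
    if side < 64:
        raise ValueError(f"side must be >= 64, got {side}")
    image = np.asarray(image)
    h, w = image.shape[:2]
    if (h, w) == (side, side):
        return ResizeResult(image.copy(), 1.0, 1.0)
    out = transform.resize(image, (side, side), order=1, preserve_range=True,
                           anti_aliasing=False)
    if np.issubdtype(image.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(image.dtype)
    return ResizeResult(out, side / w, side / h)


def _cleanup(fg: np.ndarray, closing_radius: int = 3, max_components: int = 2,
             min_area: int = 64) -> np.ndarray:
    """Morphological closing, then keep the largest components."""
    if closing_radius > 0:
        fg = morphology.closing(fg, morphology.disk(closing_radius))
    labels, n = ndimage.label(fg)
    if n == 0:
        return np.zeros_like(fg, dtype=bool)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = 1 + np.argsort(areas)[::-1][:max_components]
    keep = [k for k in keep if areas[k - 1] >= min_area]
    return np.isin(labels, keep)


def estimate_background_rgb(image: np.ndarray, border: int = 8) -> np.ndarray:
    """Median colour of the frame border, the insulated-surface palette."""
    img = np.asarray(image, dtype=float)
    strips = np.concatenate([
        img[:border].reshape(-1, 3), img[-border:].reshape(-1, 3),
        img[:, :border].reshape(-1, 3), img[:, -border:].reshape(-1, 3),
    ])
    return np.median(strips, axis=0)


def segment_hand_classical(image: np.ndarray, threshold: float = 60.0,
                           background_rgb=None, closing_radius: int = 3) -> np.ndarray:
    """Threshold on RGB distance to the background palette, then clean up.

    Deterministic; raises :class:`NoHandFoundError` when nothing survives
    cleanup (e.g. an all-background frame).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    bg = np.asarray(background_rgb, float) if background_rgb is not None \
        else estimate_background_rgb(img)
    dist = np.linalg.norm(img - bg, axis=2)
    mask = _cleanup(dist > threshold, closing_radius=closing_radius)
    if not mask.any():
        raise NoHandFoundError("no hand found after cleanup")
    return mask


def mask_overlap(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection-over-union of two binary masks (1.0 when both empty)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    union = np.logical_or(pred, truth).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, truth).sum() / union)


def _pixel_features(image: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Per-pixel feature stack: raw RGB plus Gaussian-smoothed RGB."""
    img = np.asarray(image, dtype=float) / 255.0
    smooth = np.stack([ndimage.gaussian_filter(img[..., c], sigma) for c in range(3)], axis=-1)
    return np.concatenate([img, smooth], axis=-1).reshape(-1, 6)


@dataclass
class SegmenterModel:
    """A trained pixelwise hand/background classifier with its val metrics."""

    classifier: MLPClassifier
    sigma: float = 2.0
    closing_radius: int = 3
    val_iou: float = float("nan")
    val_ious: list = field(default_factory=list)
    converged: bool = True


def train_segmenter(train_set, val_set, epochs: int = 200, seed: int = 0,
                    pixels_per_image: int = 1500, hidden: int = 16) -> SegmenterModel:
    """Fit the pixelwise segmenter on (image, mask) pairs.

    A balanced subsample of ``pixels_per_image`` pixels per training image is
    drawn with a seeded generator; validation reports mean IoU over
    ``val_set`` with the full post-processing applied.  Training and
    validation sets must be disjoint (caller's responsibility) and the val
    set non-empty.
    """
    train_set, val_set = list(train_set), list(val_set)
    if not train_set:
        raise ValueError("empty training set")
    if not val_set:
        raise ValueError("empty validation set")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for image, mask in train_set:
        feats = _pixel_features(image)
        lab = np.asarray(mask, dtype=bool).ravel()
        for value in (True, False):
            idx = np.flatnonzero(lab == value)
            take = min(pixels_per_image // 2, idx.size)
            pick = rng.choice(idx, size=take, replace=False)
            xs.append(feats[pick])
            ys.append(lab[pick])
    X = np.concatenate(xs)
    y = np.concatenate(ys)

    clf = MLPClassifier(hidden_layer_sizes=(hidden,), max_iter=int(epochs),
                        random_state=int(seed), tol=1e-6)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(X, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn("segmenter training did not converge; metrics still reported",
                          RuntimeWarning, stacklevel=2)

    model = SegmenterModel(classifier=clf, converged=converged)
    ious = []
    for image, mask in val_set:
        try:
            pred = segment_hand_model(model, image)
        except NoHandFoundError:
            pred = np.zeros(np.asarray(mask).shape, dtype=bool)
        ious.append(mask_overlap(pred, mask))
    model.val_ious = ious
    model.val_iou = float(np.mean(ious))
    return model


def segment_hand_model(model: SegmenterModel, image: np.ndarray) -> np.ndarray:
    """Predict a hand mask with the trained segmenter (0.5 threshold + cleanup)."""
    feats = _pixel_features(image, sigma=model.sigma)
    proba = model.classifier.predict_proba(feats)[:, list(model.classifier.classes_).index(True)]
    fg = (proba >= 0.5).reshape(np.asarray(image).shape[:2])
    mask = _cleanup(fg, closing_radius=model.closing_radius)
    if not mask.any():
        raise NoHandFoundError("no hand found after cleanup")
    return mask
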