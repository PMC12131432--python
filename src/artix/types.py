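"""Shared data structures for the ARTIX pipeline.

Coordinate convention, used everywhere: images are ``(H, W, 3)`` uint8 arrays
with the origin at the top-left pixel; a point is an ``(x, y)`` pair where
``x`` indexes columns and ``y`` indexes rows, both 0-based, sampled at pixel
centres.  Masks are boolean ``(H, W)`` arrays on the same grid as their image.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Digit order used throughout; index into this tuple is the "finger index"
#: used for deterministic tie-breaking.
FINGERS = ("thumb", "index", "middle", "ring", "pinky")

#: Digits that contribute to the ARTIX score (thumbs are excluded).
SCORING_FINGERS = ("index", "middle", "ring", "pinky")

HANDS = ("left", "right")

#: 21-point hand landmark convention: wrist, then four joints per digit
#: (CMC/MCP/IP/TIP for the thumb, MCP/PIP/DIP/TIP for the others).
LANDMARK_NAMES = (
    "wrist",
    "thumb_cmc", "thumb_mcp", "thumb_ip", "thumb_tip",
    "index_mcp", "index_pip", "index_dip", "index_tip",
    "middle_mcp", "middle_pip", "middle_dip", "middle_tip",
    "ring_mcp", "ring_pip", "ring_dip", "ring_tip",
    "pinky_mcp", "pinky_pip", "pinky_dip", "pinky_tip",
)

#: Landmark indices of each digit's chain, proximal to distal.
FINGER_LANDMARKS = {
    "thumb": (1, 2, 3, 4),
    "index": (5, 6, 7, 8),
    "middle": (9, 10, 11, 12),
    "ring": (13, 14, 15, 16),
    "pinky": (17, 18, 19, 20),
}

#: Landmark indices of the skeleton polyline used for finger segmentation
#: (MCP -> TIP; the thumb CMC lies inside the palm and is excluded).
FINGER_SKELETON = {
    "thumb": (2, 3, 4),
    "index": (5, 6, 7, 8),
    "middle": (9, 10, 11, 12),
    "ring": (13, 14, 15, 16),
    "pinky": (17, 18, 19, 20),
}

#: Landmark index of each digit's MCP joint (base of the free digit).
FINGER_MCP = {"thumb": 2, "index": 5, "middle": 9, "ring": 13, "pinky": 17}


class PipelineError(RuntimeError):
    """Base class for recoverable pipeline failures."""


class NoHandFoundError(PipelineError):
    """Segmentation produced an empty mask after cleanup."""


class LandmarkMisalignmentError(PipelineError):
    """All landmarks fall outside the hand mask."""


class RegionTooSmallError(PipelineError):
    """A finger region holds fewer pixels than the statistics minimum."""


class MissingTimepointError(PipelineError):
    """A session lacks the basal or 10-minute assessment."""


class CollinearityError(PipelineError):
    """Perfectly collinear predictors passed to the regression."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        super().__init__(f"collinear predictors: {', '.join(self.offenders)}")


@dataclass
class HandLandmarkSet:
    """21 named anatomical points for one hand.

    ``points`` is a ``(21, 2)`` float array of ``(x, y)`` coordinates, either
    normalized to ``[0, 1]`` (``normalized=True``) or in pixels of a stated
    grid.
    """

    points: np.ndarray
    handedness: str = "right"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (21, 2):
            raise ValueError(f"expected (21, 2) landmark array, got {self.points.shape}")
        if self.handedness not in HANDS:
            raise ValueError(f"handedness must be one of {HANDS}")

    def point(self, name: str) -> np.ndarray:
        return self.points[LANDMARK_NAMES.index(name)]

    def copy(self) -> "HandLandmarkSet":
        return HandLandmarkSet(self.points.copy(), self.handedness, self.normalized)


@dataclass
class FingerRegion:
    """One digit's pixel mask plus its skeleton polyline (MCP -> TIP)."""

    finger: str
    hand: str
    mask: np.ndarray
    skeleton: np.ndarray

    def __post_init__(self) -> None:
        if self.finger not in FINGERS:
            raise ValueError(f"unknown finger {self.finger!r}")
        if self.hand not in HANDS:
            raise ValueError(f"unknown hand {self.hand!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        self.skeleton = np.asarray(self.skeleton, dtype=float)

    @property
    def finger_id(self) -> str:
        return f"{self.hand}:{self.finger}"

    @property
    def is_thumb(self) -> bool:
        return self.finger == "thumb"

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ChannelStats:
    """Quartile summary of the smoothed colour channels inside one region.

    Keys of the per-channel dicts are ``"R"``, ``"G"``, ``"B"``.
    """

    median: dict
    q1: dict
    q3: dict
    n_pixels: int

    def __post_init__(self) -> None:
        for c in "RGB":
            if not (self.q1[c] <= self.median[c] <= self.q3[c]):
                raise ValueError(f"quartile ordering violated for channel {c}")


@dataclass
class ArtixScore:
    """Per-assessment redness aggregate over the eight non-thumb digits."""

    value: float
    per_finger: dict
    timepoint_label: Optional[str] = None
    formula_version: str = ""


@dataclass(frozen=True)
class TimepointSchedule:
    """Ordered assessment labels with post-immersion minute offsets.

    The basal assessment has no minute offset (``None``).
    """

    labels: tuple
    minutes: tuple

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.minutes):
            raise ValueError("labels and minutes differ in length")

    def __len__(self) -> int:
        return len(self.labels)

    def post_immersion(self):
        return [(l, m) for l, m in zip(self.labels, self.minutes) if m is not None]


@dataclass
class SubjectParams:
    """Generative parameters of one subject's cold-challenge response.

    Redness is on the ARTIX score scale (arbitrary units, roughly 300-410 for
    realistic skin); temperature in degrees Celsius.  The rewarming curve is
    mono-exponential: ``value(t) = basal * (ceiling - (ceiling - (1 - drop))
    * exp(-rate * t))`` for post-immersion minutes ``t``.
    """

    group: str = "HC"
    season: str = "MayJul"
    basal_redness: float = 375.0
    drop_fraction: float = 0.02
    recovery_rate: float = 0.55
    recovery_ceiling_fraction: float = 1.025
    noise_sd: float = 8.0
    basal_temp_C: float = 30.8
    thermal_drop_fraction: float = 0.19
    thermal_recovery_rate: float = 0.33
    thermal_ceiling_fraction: float = 1.03
    thermal_noise_sd: float = 1.2
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("drop_fraction", "thermal_drop_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class ChallengeSession:
    """One subject's 7-timepoint series of ARTIX and thermal values."""

    subject_id: str
    group: str
    season: str
    covariates: dict = field(default_factory=dict)
    artix: dict = field(default_factory=dict)
    thermal: dict = field(default_factory=dict)
    per_finger_artix: dict = field(default_factory=dict)
    per_finger_thermal: dict = field(default_factory=dict)


@dataclass
class HandSpec:
    """Geometry and appearance of one synthetic hand.

    Lengths/widths/centre default to values proportional to ``image_size``
    when left as ``None``; digit order is thumb..pinky.
    """

    image_size: int = 512
    handedness: str = "right"
    palm_center: Optional[tuple] = None
    palm_radius: Optional[float] = None
    finger_lengths: Optional[tuple] = None
    finger_widths: Optional[tuple] = None
    base_rgb: tuple = (198, 134, 122)
    background_rgb: tuple = (18, 18, 22)
    noise_sd: float = 8.0
    seed: int = 0

    def resolved(self, rng=None) -> "HandSpec":
        """Return a copy with all geometric defaults made explicit.

        With ``rng`` given, defaulted fields get mild per-hand jitter
        (anatomical variation between subjects); explicitly set fields are
        never touched.
        """
        def u(lo, hi):
            return rng.uniform(lo, hi) if rng is not None else 1.0

        s = float(self.image_size)
        out = dataclasses.replace(self)
        if out.palm_radius is None:
            out.palm_radius = 0.17 * s * u(0.95, 1.05)
        r = out.palm_radius
        if out.palm_center is None:
            out.palm_center = (0.5 * s + s * (u(0.988, 1.012) - 1.0),
                               0.62 * s + s * (u(0.988, 1.012) - 1.0))
        if out.finger_lengths is None:
            out.finger_lengths = tuple(r * f * u(0.93, 1.05)
                                       for f in (1.05, 1.45, 1.60, 1.45, 1.10))
        if out.finger_widths is None:
            out.finger_widths = tuple(r * f * u(0.93, 1.0)
                                      for f in (0.34, 0.28, 0.28, 0.26, 0.24))
        return out
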