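"""Synthetic hands, cold-challenge sessions and cohorts.

This module generates every input the downstream pipeline consumes, with
pixel-exact ground truth:

* :func:`generate_synthetic_hand` draws a hand (filled palm ellipse plus five
  capsule-shaped digits) on a dark insulated background, returning the image,
  the exact hand mask, a labelled digit partition and the 21-point landmark
  set.
* :func:`simulate_challenge_session` produces a subject's 7-timepoint series
  of ARTIX-scale redness and finger temperature, following a mono-exponential
  rewarming model after a standardized cold immersion.
* :func:`generate_cohort` samples an RP/HC cohort with clinical covariates
  and writes a session manifest, optionally rendering per-assessment
  photographs and thermal frames to disk.

All randomness flows through :class:`numpy.random.Generator` objects seeded
from explicit integer seeds, so every artefact is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from .types import (
    FINGER_LANDMARKS,
    FINGERS,
    LANDMARK_NAMES,
    SCORING_FINGERS,
    ChallengeSession,
    HandLandmarkSet,
    HandSpec,
    SubjectParams,
    TimepointSchedule,
)

# Digit axis directions in degrees from vertical (up); positive rotates
# toward image right.  Right hand; the left hand mirrors the sign.
_FINGER_ANGLES_RIGHT = {"thumb": -72.0, "index": -30.0, "middle": -6.0, "ring": 16.0, "pinky": 40.0}

#: Integer label of each digit in the ground-truth digit map (0 = not a digit).
DIGIT_LABELS = {name: i + 1 for i, name in enumerate(FINGERS)}


@dataclass
class SyntheticHand:
    """A rendered hand with its exact ground truth."""

    image: np.ndarray            # (H, W, 3) uint8
    mask: np.ndarray             # (H, W) bool, palm plus digits
    digit_labels: np.ndarray     # (H, W) uint8, values of DIGIT_LABELS
    landmarks: HandLandmarkSet   # pixel coordinates
    spec: HandSpec

    def digit_mask(self, finger: str) -> np.ndarray:
        return self.digit_labels == DIGIT_LABELS[finger]


def _unit(theta_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    return np.array([math.sin(t), -math.cos(t)])


def _segment_distance(px: np.ndarray, py: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from grid points to the segment ``a``-``b``."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.hypot(px - a[0], py - a[1])
    t = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(px - (a[0] + t * ab[0]), py - (a[1] + t * ab[1]))


def _polyline_distance(px, py, pts) -> np.ndarray:
    d = np.full(px.shape, np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        np.minimum(d, _segment_distance(px, py, np.asarray(a, float), np.asarray(b, float)), out=d)
    return d


def _hand_geometry(spec: HandSpec):
    """Base points, axis directions and landmark coordinates for a spec."""
    spec = spec.resolved()
    cx, cy = spec.palm_center
    a = spec.palm_radius              # palm semi-axis along x
    b = 0.9 * spec.palm_radius        # along y
    sign = 1.0 if spec.handedness == "right" else -1.0

    bases, dirs = {}, {}
    for finger in FINGERS:
        theta = sign * _FINGER_ANGLES_RIGHT[finger]
        d = _unit(theta)
        bases[finger] = np.array([cx + a * d[0], cy + b * d[1]])
        dirs[finger] = d

    pts = np.zeros((21, 2))
    pts[0] = (cx, cy + 0.92 * b)                      # wrist
    for i, finger in enumerate(FINGERS):
        L = spec.finger_lengths[i]
        base, d = bases[finger], dirs[finger]
        if finger == "thumb":
            cmc = np.array([cx, cy]) + 0.55 * (base - np.array([cx, cy]))
            chain = [cmc, base, base + 0.50 * L * d, base + 0.90 * L * d]
        else:
            chain = [base, base + 0.38 * L * d, base + 0.68 * L * d, base + 0.92 * L * d]
        for j, p in zip(FINGER_LANDMARKS[finger], chain):
            pts[j] = p
    return spec, bases, dirs, pts, (a, b)


def synthesize_hand(spec: HandSpec, finger_rgb: Optional[dict] = None) -> SyntheticHand:
    """Render one hand with pixel-exact ground truth.

    ``finger_rgb`` optionally overrides the fill colour of individual digits
    (keyed by finger name), which is how cold-challenge frames encode
    per-finger redness.  Defaulted geometry fields receive seed-derived
    anatomical jitter, so different seeds give differently shaped hands.
    """
    geom_rng = np.random.default_rng((int(spec.seed) * 2654435761 + 97) % (2**31))
    spec = spec.resolved(geom_rng)
    spec, bases, dirs, pts, (a, b) = _hand_geometry(spec)
    size = int(spec.image_size)
    if size < 128:
        raise ValueError(f"image_size must be >= 128, got {size}")

    # geometry must fit in the frame with a 2-px margin
    lo, hi = 2.0, size - 3.0
    for i, finger in enumerate(FINGERS):
        tip = bases[finger] + spec.finger_lengths[i] * dirs[finger]
        half = 0.5 * spec.finger_widths[i]
        if not (lo <= tip[0] - half and tip[0] + half <= hi and lo <= tip[1] - half and tip[1] + half <= hi):
            raise ValueError(f"finger {finger!r} overflows the frame")
    cx, cy = spec.palm_center
    if not (lo <= cx - a and cx + a <= hi and lo <= cy - b and cy + b <= hi):
        raise ValueError("palm overflows the frame")

    yy, xx = np.mgrid[0:size, 0:size]
    px, py = xx.astype(float), yy.astype(float)
    palm = ((px - cx) / a) ** 2 + ((py - cy) / b) ** 2 <= 1.0

    capsules, axis_dist = {}, {}
    for i, finger in enumerate(FINGERS):
        tip = bases[finger] + spec.finger_lengths[i] * dirs[finger]
        d = _segment_distance(px, py, bases[finger], tip)
        capsules[finger] = d <= 0.5 * spec.finger_widths[i]
        axis_dist[finger] = d

    mask = palm.copy()
    for m in capsules.values():
        mask |= m

    # digit partition: capsule pixels outside the palm; any overlap between
    # capsules goes to the nearest axis, ties to the lower finger index
    digit_labels = np.zeros((size, size), dtype=np.uint8)
    stack = np.stack([np.where(capsules[f], axis_dist[f], np.inf) for f in FINGERS])
    any_digit = ~palm & np.isfinite(stack).any(axis=0)
    winner = np.argmin(stack, axis=0)
    digit_labels[any_digit] = (winner + 1)[any_digit]

    rng = np.random.default_rng(spec.seed)
    img = np.empty((size, size, 3), dtype=float)
    img[:] = np.asarray(spec.background_rgb, float)
    img[mask] = np.asarray(spec.base_rgb, float)
    if finger_rgb:
        for finger, rgb in finger_rgb.items():
            img[digit_labels == DIGIT_LABELS[finger]] = np.asarray(rgb, float)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    lms = HandLandmarkSet(pts, handedness=spec.handedness, normalized=False)
    return SyntheticHand(image=image, mask=mask, digit_labels=digit_labels, landmarks=lms, spec=spec)


def generate_synthetic_hand(spec: HandSpec):
    """Return ``(image, mask, landmarks)`` for a spec (see :func:`synthesize_hand`)."""
    h = synthesize_hand(spec)
    return h.image, h.mask, h.landmarks


# ---------------------------------------------------------------------------
# Cold-challenge simulation
# ---------------------------------------------------------------------------

def rewarming_value(basal: float, drop: float, rate: float, ceiling: float, t: float) -> float:
    """Mono-exponential rewarming toward ``ceiling * basal``.

    ``t`` is minutes after immersion; ``t = 0`` gives ``basal * (1 - drop)``.
    """
    decay = 1.0 if t <= 0 else math.exp(-rate * t)
    return basal * (ceiling - (ceiling - (1.0 - drop)) * decay)


def simulate_challenge_session(
    params: SubjectParams,
    schedule: TimepointSchedule,
    seed: int = 0,
    subject_id: str = "S000",
    finger_jitter_sd: float = 0.0,
) -> ChallengeSession:
    """Simulate one subject's 7-timepoint ARTIX and thermal series.

    Measurement noise (``params.noise_sd`` / ``params.thermal_noise_sd``) is
    i.i.d. Gaussian per assessment; ``finger_jitter_sd`` adds optional
    per-digit scatter around the assessment mean.  The reported value of an
    assessment is the mean of its eight non-thumb digit values.
    """
    rng = np.random.default_rng(seed)
    finger_ids = [f"{h}:{f}" for h in ("left", "right") for f in SCORING_FINGERS]
    sess = ChallengeSession(
        subject_id=subject_id, group=params.group, season=params.season,
        covariates=dict(params.covariates),
    )
    for label, minutes in zip(schedule.labels, schedule.minutes):
        if minutes is None:
            mean_a = params.basal_redness
            mean_t = params.basal_temp_C
        else:
            mean_a = rewarming_value(
                params.basal_redness, params.drop_fraction,
                params.recovery_rate, params.recovery_ceiling_fraction, minutes)
            mean_t = rewarming_value(
                params.basal_temp_C, params.thermal_drop_fraction,
                params.thermal_recovery_rate, params.thermal_ceiling_fraction, minutes)
        mean_a += rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
        mean_t += rng.normal(0.0, params.thermal_noise_sd) if params.thermal_noise_sd > 0 else 0.0
        jit_a = rng.normal(0.0, finger_jitter_sd, 8) if finger_jitter_sd > 0 else np.zeros(8)
        jit_t = rng.normal(0.0, 0.25 * finger_jitter_sd, 8) if finger_jitter_sd > 0 else np.zeros(8)
        pf_a = {fid: mean_a + j for fid, j in zip(finger_ids, jit_a)}
        pf_t = {fid: mean_t + j for fid, j in zip(finger_ids, jit_t)}
        sess.per_finger_artix[label] = pf_a
        sess.per_finger_thermal[label] = pf_t
        sess.artix[label] = float(np.mean(list(pf_a.values())))
        sess.thermal[label] = float(np.mean(list(pf_t.values())))
    return sess


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def _d(**kw):
    return field(default_factory=lambda: dict(kw))


@dataclass
class CohortConfig:
    """Population parameters of the synthetic RP/HC cohort.

    Location parameters follow the reported group contrasts of a standardized
    cold challenge (lower basal redness and slower, lower-ceiling rewarming
    in RP than HC; colder basal values from September to December); kinetics
    are artifact choices since no quantitative rewarming constants are
    published.  Covariate prevalences mirror a typical secondary-RP clinic
    cohort.  Effects are additive shifts on basal values.
    """

    # ARTIX-scale redness
    artix_basal_mean: dict = _d(RP=341.0, HC=394.0)
    artix_basal_sd: float = 22.0
    artix_drop: dict = _d(RP=0.03, HC=0.02)
    artix_rate: dict = _d(RP=0.35, HC=0.55)
    artix_ceiling: dict = _d(RP=1.015, HC=1.025)
    artix_noise_sd: float = 8.0
    # finger temperature, degrees C
    thermal_basal_mean: dict = _d(RP=27.9, HC=30.8)
    thermal_basal_sd: dict = _d(RP=2.2, HC=2.6)
    thermal_drop: dict = _d(RP=0.17, HC=0.19)
    thermal_rate: dict = _d(RP=0.28, HC=0.33)
    thermal_ceiling: dict = _d(RP=0.98, HC=1.03)
    thermal_noise_sd: float = 1.2
    # season: additive shift for September-December assessments
    p_sepdec: float = 0.5
    season_shift_artix: float = -25.0
    season_shift_temp: float = -2.0
    # covariate marginals
    p_female: dict = _d(RP=0.911, HC=0.864)
    age_mean: dict = _d(RP=52.2, HC=45.7)
    age_sd: dict = _d(RP=16.7, HC=13.5)
    p_vasoactive: dict = _d(RP=0.555, HC=0.0)
    p_aca: dict = _d(RP=0.422, HC=0.0)
    nvc_probs: dict = _d(early=0.133, active=0.066, late=0.111, nonspecific=0.155, none=0.535)
    skin_probs: dict = _d(lcSSc=0.311, dcSSc=0.111, none=0.578)
    p_du: dict = _d(RP=0.155, HC=0.0)
    # additive covariate effects on basal redness (score units)
    effect_male: float = 12.0
    effect_vasoactive: float = 14.0
    effect_aca: float = 20.0
    effect_nvc_late: float = -12.0
    effect_dcssc: float = -10.0
    thermal_effect_male: float = 3.0
    # mild between-subject kinetic scatter
    rate_log_sd: float = 0.15
    ceiling_sd: float = 0.008

    def expected_basal_artix(self, group: str, include_season: bool = True) -> float:
        """Population expectation of basal ARTIX under these marginals."""
        g = group
        e = self.artix_basal_mean[g]
        e += (1.0 - self.p_female[g]) * self.effect_male
        e += self.p_vasoactive[g] * self.effect_vasoactive
        e += self.p_aca[g] * self.effect_aca
        if g == "RP":
            e += self.nvc_probs["late"] * self.effect_nvc_late
            e += self.skin_probs["dcSSc"] * self.effect_dcssc
        if include_season:
            e += self.p_sepdec * self.season_shift_artix
        return e

    def expected_group_effect(self) -> float:
        """Expected HC - RP difference in basal ARTIX (season cancels)."""
        return self.expected_basal_artix("HC") - self.expected_basal_artix("RP")

    def sample_subject(self, group: str, rng: np.random.Generator,
                       season: Optional[str] = None) -> SubjectParams:
        g = group
        if season is None:
            season = "SepDec" if rng.random() < self.p_sepdec else "MayJul"
        male = rng.random() >= self.p_female[g]
        cov = {
            "sex": "M" if male else "F",
            "age": float(np.clip(rng.normal(self.age_mean[g], self.age_sd[g]), 18.0, 90.0)),
            "vasoactive_therapy": bool(rng.random() < self.p_vasoactive[g]),
            "ACA": bool(rng.random() < self.p_aca[g]),
            "NVC_pattern": "none",
            "skin_subset": "none",
            "DU_history": bool(rng.random() < self.p_du[g]),
        }
        if g == "RP":
            nvc_names = list(self.nvc_probs)
            cov["NVC_pattern"] = str(rng.choice(nvc_names, p=[self.nvc_probs[k] for k in nvc_names]))
            skin_names = list(self.skin_probs)
            cov["skin_subset"] = str(rng.choice(skin_names, p=[self.skin_probs[k] for k in skin_names]))

        basal = self.artix_basal_mean[g] + rng.normal(0.0, self.artix_basal_sd)
        basal += self.effect_male * male
        basal += self.effect_vasoactive * cov["vasoactive_therapy"]
        basal += self.effect_aca * cov["ACA"]
        basal += self.effect_nvc_late * (cov["NVC_pattern"] == "late")
        basal += self.effect_dcssc * (cov["skin_subset"] == "dcSSc")
        temp = self.thermal_basal_mean[g] + rng.normal(0.0, self.thermal_basal_sd[g])
        temp += self.thermal_effect_male * male
        if season == "SepDec":
            basal += self.season_shift_artix
            temp += self.season_shift_temp

        return SubjectParams(
            group=g, season=season,
            basal_redness=float(basal),
            drop_fraction=float(np.clip(self.artix_drop[g] + rng.normal(0.0, self.ceiling_sd), 0.0, 1.0)),
            recovery_rate=float(self.artix_rate[g] * rng.lognormal(0.0, self.rate_log_sd)),
            recovery_ceiling_fraction=float(self.artix_ceiling[g] + rng.normal(0.0, self.ceiling_sd)),
            noise_sd=self.artix_noise_sd,
            basal_temp_C=float(temp),
            thermal_drop_fraction=float(np.clip(self.thermal_drop[g] + rng.normal(0.0, self.ceiling_sd), 0.0, 1.0)),
            thermal_recovery_rate=float(self.thermal_rate[g] * rng.lognormal(0.0, self.rate_log_sd)),
            thermal_ceiling_fraction=float(self.thermal_ceiling[g] + rng.normal(0.0, self.ceiling_sd)),
            thermal_noise_sd=self.thermal_noise_sd,
            covariates=cov,
        )


MANIFEST_COLUMNS = [
    "subject_id", "group", "season", "sex", "age", "vasoactive_therapy", "ACA",
    "NVC_pattern", "skin_subset", "DU_history", "timepoint_label", "minutes",
    "image_path", "thermal_path",
]


def render_session_frame(session: ChallengeSession, label: str, image_size: int = 512,
                         seed: int = 0, noise_sd: float = 8.0,
                         thermal_background_C: float = 21.0):
    """Render one assessment as a two-hand photograph plus thermal frame.

    The left hand occupies the left half of the frame, the right hand the
    right half.  Scoring digits are filled with an RGB whose red channel is
    half the digit's redness value (the default redness formula of a uniform
    region is twice its red intensity); thumbs and palm keep the base skin
    colour.  The thermal frame carries each digit's temperature on the same
    pixel grid.  Returns ``(image, thermal, landmarks_by_hand, hands_by_side)``.
    """
    pf_a = session.per_finger_artix[label]
    pf_t = session.per_finger_thermal[label]
    halves, lms_by_hand = {}, {}
    thermal = np.full((image_size, 2 * image_size), float(thermal_background_C))
    image = np.empty((image_size, 2 * image_size, 3), dtype=np.uint8)
    for k, hand in enumerate(("left", "right")):
        spec = HandSpec(image_size=image_size, handedness=hand,
                        noise_sd=noise_sd, seed=(seed * 7919 + k) % (2**31))
        finger_rgb = {}
        for f in SCORING_FINGERS:
            r = np.clip(pf_a[f"{hand}:{f}"] / 2.0, 0.0, 255.0)
            finger_rgb[f] = (r, 134.0, 122.0)
        h = synthesize_hand(spec, finger_rgb=finger_rgb)
        halves[hand] = h
        off = 0 if hand == "left" else image_size
        image[:, off:off + image_size] = h.image
        t_half = np.full((image_size, image_size), float(thermal_background_C))
        basal_t = float(np.mean(list(pf_t.values())))
        t_half[h.mask] = basal_t
        for f in SCORING_FINGERS:
            t_half[h.digit_mask(f)] = pf_t[f"{hand}:{f}"]
        thermal[:, off:off + image_size] = t_half
        lms = h.landmarks.copy()
        lms.points[:, 0] += off
        lms_by_hand[hand] = lms
    rng = np.random.default_rng((seed * 104729 + 13) % (2**31))
    thermal += rng.normal(0.0, 0.05, thermal.shape)
    return image, thermal, lms_by_hand, halves


def generate_cohort(
    n_rp: int,
    n_hc: int,
    seed: int,
    out_dir: Optional[str] = None,
    mode: str = "fast",
    image_size: int = 512,
    config: Optional[CohortConfig] = None,
    schedule: Optional[TimepointSchedule] = None,
):
    """Sample an RP/HC cohort and its cold-challenge sessions.

    ``mode="fast"`` emits per-finger redness/temperature values directly in
    the manifest (statistics-scale simulations); ``mode="images"`` also
    renders per-assessment photographs (PNG), thermal frames (headerless CSV
    of degrees C) and a landmark CSV under ``out_dir``.

    Returns ``(manifest, sessions)``; the manifest has one row per scheduled
    assessment (subjects x 7).
    """
    if n_rp < 1 or n_hc < 1:
        raise ValueError("need at least one subject per group")
    if mode not in ("fast", "images"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "images" and out_dir is None:
        raise ValueError("mode='images' requires out_dir")
    from .challenge import protocol_schedule
    schedule = schedule or protocol_schedule()
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "thermal").mkdir(parents=True, exist_ok=True)

    rows, lm_rows, sessions = [], [], []
    subjects = [("RP", i) for i in range(n_rp)] + [("HC", i) for i in range(n_hc)]
    for group, i in subjects:
        sid = f"{group}{i + 1:03d}"
        params = config.sample_subject(group, rng)
        sess_seed = int(rng.integers(0, 2**31))
        sess = simulate_challenge_session(params, schedule, seed=sess_seed,
                                          subject_id=sid, finger_jitter_sd=2.0)
        sessions.append(sess)
        for label, minutes in zip(schedule.labels, schedule.minutes):
            img_path, th_path = "", ""
            if mode == "images":
                frame_seed = int(rng.integers(0, 2**31))
                image, thermal, lms_by_hand, _ = render_session_frame(
                    sess, label, image_size=image_size, seed=frame_seed)
                img_path = f"images/{sid}_{label}.png"
                th_path = f"thermal/{sid}_{label}.csv"
                Image.fromarray(image).save(out / img_path)
                np.savetxt(out / th_path, thermal, fmt="%.3f", delimiter=",")
                for hand, lms in lms_by_hand.items():
                    for j, (x, y) in enumerate(lms.points):
                        lm_rows.append({
                            "subject_id": sid, "timepoint_label": label, "hand": hand,
                            "point_index": j, "point_name": LANDMARK_NAMES[j],
                            "x": x, "y": y, "normalized_flag": 0,
                        })
            row = {
                "subject_id": sid, "group": group, "season": params.season,
                "sex": params.covariates["sex"], "age": round(params.covariates["age"], 1),
                "vasoactive_therapy": int(params.covariates["vasoactive_therapy"]),
                "ACA": int(params.covariates["ACA"]),
                "NVC_pattern": params.covariates["NVC_pattern"],
                "skin_subset": params.covariates["skin_subset"],
                "DU_history": int(params.covariates["DU_history"]),
                "timepoint_label": label,
                "minutes": "" if minutes is None else minutes,
                "image_path": img_path, "thermal_path": th_path,
            }
            if mode == "fast":
                row["artix"] = sess.artix[label]
                row["thermal_C"] = sess.thermal[label]
            rows.append(row)

    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
        if lm_rows:
            pd.DataFrame(lm_rows).to_csv(out / "landmarks.csv", index=False)
    return manifest, sessions
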