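"""The standardized cold-challenge session model.

A session is a basal assessment followed by imaging immediately after a
one-minute 15 degC water immersion and every 2 minutes up to minute 10 —
seven assessments in total.  Thermography is aggregated exactly as the
reference protocol prescribes: the mean temperature of each of the eight
non-thumb digits (second to fifth finger, both hands), then the mean of
those eight values, one thermal value per subject per timepoint.

A subject "returned to baseline" when the 10-minute value meets or exceeds
the basal value (subjects who overshoot count as returned).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import ChallengeSession, FingerRegion, MissingTimepointError, TimepointSchedule

TIMEPOINT_LABELS = ("basal", "0min", "2min", "4min", "6min", "8min", "10min")
TIMEPOINT_MINUTES = (None, 0, 2, 4, 6, 8, 10)


def protocol_schedule() -> TimepointSchedule:
    """The 7-assessment protocol: basal, then 0/2/4/6/8/10 min post-immersion."""
    return TimepointSchedule(labels=TIMEPOINT_LABELS, minutes=TIMEPOINT_MINUTES)


def thermal_finger_mean(frame: np.ndarray, region: FingerRegion) -> float:
    """Mean temperature (degC) of the frame inside one finger region."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != region.mask.shape:
        raise ValueError(f"region grid {region.mask.shape} does not match frame {frame.shape}")
    if not region.mask.any():
        raise ValueError("empty region")
    return float(frame[region.mask].mean())


def subject_thermal_value(finger_means) -> float:
    """Mean of the eight per-finger temperatures (II-V digits, both hands)."""
    vals = np.asarray(list(finger_means), dtype=float)
    if vals.size != 8:
        raise ValueError(f"expected exactly 8 finger means, got {vals.size}")
    return float(vals.mean())


def returned_to_baseline(session: ChallengeSession, measure: str = "artix") -> bool:
    """True iff the 10-minute value meets or exceeds the basal value."""
    series = _series(session, measure)
    if "basal" not in series or "10min" not in series:
        raise MissingTimepointError(
            f"{session.subject_id}: basal and 10min required for {measure}")
    return bool(series["10min"] >= series["basal"])


def _series(session: ChallengeSession, measure: str) -> dict:
    if measure == "artix":
        return session.artix
    if measure == "thermal":
        return session.thermal
    raise ValueError(f"unknown measure {measure!r}")


def cohort_return_table(sessions, measure: str = "artix") -> pd.DataFrame:
    """Returned / not-returned counts and proportions per group.

    Rows indexed by group (``RP``, ``HC``); a missing group yields a partial
    table with a warning.
    """
    rows = {}
    for group in ("RP", "HC"):
        sub = [s for s in sessions if s.group == group]
        if not sub:
            warnings.warn(f"group {group} absent; partial return table", RuntimeWarning,
                          stacklevel=2)
            continue
        returned = sum(returned_to_baseline(s, measure) for s in sub)
        rows[group] = {
            "n": len(sub),
            "returned": returned,
            "not_returned": len(sub) - returned,
            "proportion_pct": 100.0 * returned / len(sub),
        }
    if not rows:
        raise ValueError("no sessions supplied")
    return pd.DataFrame.from_dict(rows, orient="index")


def sessions_to_dataframe(sessions) -> pd.DataFrame:
    """Session-level long table (one row per subject and timepoint)."""
    rows = []
    minutes = dict(zip(TIMEPOINT_LABELS, TIMEPOINT_MINUTES))
    for s in sessions:
        try:
            ret_a = returned_to_baseline(s, "artix")
            ret_t = returned_to_baseline(s, "thermal")
        except MissingTimepointError:
            ret_a = ret_t = None
        for label in TIMEPOINT_LABELS:
            if label not in s.artix and label not in s.thermal:
                continue
            rows.append({
                "subject_id": s.subject_id, "group": s.group, "season": s.season,
                "timepoint_label": label,
                "minutes": minutes.get(label),
                "artix": s.artix.get(label, np.nan),
                "thermal_C": s.thermal.get(label, np.nan),
                "returned_to_baseline_artix": ret_a,
                "returned_to_baseline_thermal": ret_t,
            })
    return pd.DataFrame(rows)


def sessions_from_dataframe(df: pd.DataFrame) -> list:
    """Rebuild :class:`ChallengeSession` objects from a session-level table.

    Requires columns ``subject_id, group, season, timepoint_label`` and at
    least one of ``artix`` / ``thermal_C``.
    """
    sessions = []
    for sid, sub in df.groupby("subject_id", sort=False):
        first = sub.iloc[0]
        sess = ChallengeSession(subject_id=str(sid), group=str(first["group"]),
                                season=str(first["season"]))
        for _, row in sub.iterrows():
            label = str(row["timepoint_label"])
            if "artix" in sub.columns and pd.notna(row.get("artix")):
                sess.artix[label] = float(row["artix"])
            if "thermal_C" in sub.columns and pd.notna(row.get("thermal_C")):
                sess.thermal[label] = float(row["thermal_C"])
        sessions.append(sess)
    return sessions
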