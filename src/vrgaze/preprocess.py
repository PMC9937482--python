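"""Raw eye+head streams -> synchronized world-frame gaze series.

The head quaternion stream (~70 Hz) is slerp-interpolated to the eye
timestamps (250 Hz); the world gaze direction is then the head rotation
applied to the eye-in-head direction, and the head point is the head rotation
applied to the world forward axis.  Timestamps are trial-relative milliseconds
and intervals are half-open [start, end).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import sphere
from .sphere import FORWARD

__all__ = ["interpolate_head", "project_to_world", "build_gaze_series"]

GAZE_COLUMNS = ["t", "eye_lon", "eye_lat", "eih_lon", "eih_lat",
                "head_lon", "head_lat"]


def interpolate_head(head_t, head_q, eye_t) -> np.ndarray:
    """Slerp head quaternions onto the eye timestamps.

    Outside the recorded head span the first/last orientation is held
    constant, but only up to one median head-frame period of extrapolation;
    beyond that the streams are considered unsynchronized and an error is
    raised.  A single-frame head stream yields a constant orientation.
    """
    head_t = np.asarray(head_t, dtype=float)
    head_q = np.asarray(head_q, dtype=float)
    eye_t = np.asarray(eye_t, dtype=float)
    if head_t.size == 0:
        raise ValueError("empty head stream")
    if np.any(np.diff(head_t) <= 0):
        raise ValueError("head timestamps must be strictly increasing")
    if head_t.size == 1:
        return np.tile(head_q[0], (eye_t.size, 1))

    frame = float(np.median(np.diff(head_t)))
    if eye_t.min() < head_t[0] - frame or eye_t.max() > head_t[-1] + frame:
        raise ValueError(
            "eye timestamps extend more than one head frame beyond the head stream")

    idx = np.searchsorted(head_t, eye_t, side="right") - 1
    idx = np.clip(idx, 0, head_t.size - 2)
    t0 = head_t[idx]
    t1 = head_t[idx + 1]
    u = np.clip((eye_t - t0) / (t1 - t0), 0.0, 1.0)  # clip = constant hold at ends
    return sphere.slerp(head_q[idx], head_q[idx + 1], u)


def project_to_world(eye_in_head, head_q):
    """World-frame eye point and head point for one or many samples.

    Returns ``(eye_lon, eye_lat, head_lon, head_lat)`` in degrees: the eye
    point is the head rotation applied to the eye-in-head vector, the head
    point is the head rotation applied to the forward axis.
    """
    eye_world = sphere.quat_rotate(head_q, eye_in_head)
    head_world = sphere.quat_rotate(head_q, FORWARD)
    eye_lon, eye_lat = sphere.vec_to_sph(eye_world)
    head_lon, head_lat = sphere.vec_to_sph(head_world)
    return eye_lon, eye_lat, head_lon, head_lat


def build_gaze_series(raw) -> pd.DataFrame:
    """One row per eye sample: world eye point, eye-in-head point, head point.

    The eye-in-head coordinates are kept alongside the world projections for
    the head-centered spatial analyses.
    """
    q = interpolate_head(raw.head_t, raw.head_q, raw.eye_t)
    eye_lon, eye_lat, head_lon, head_lat = project_to_world(raw.eye_vec, q)
    eih_lon, eih_lat = sphere.vec_to_sph(raw.eye_vec)
    return pd.DataFrame({
        "t": raw.eye_t,
        "eye_lon": eye_lon,
        "eye_lat": eye_lat,
        "eih_lon": eih_lon,
        "eih_lat": eih_lat,
        "head_lon": head_lon,
        "head_lat": head_lat,
    })
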