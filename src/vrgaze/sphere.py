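"""Spherical coordinate frames, great-circle geometry and quaternion algebra.

Everything downstream (fixation detection, heatmaps, cross-recurrence) measures
angles on the stimulus sphere, so all distance computations here are
great-circle central angles in degrees, never differences of projected
coordinates.

Frame convention
----------------
Longitude 0 / latitude 0 is the world "forward" direction (where the trial-start
fixation cross sits); longitude increases eastward, latitude increases toward
the north pole.  The unit-vector embedding is

    v = (cos(lat) cos(lon), cos(lat) sin(lon), sin(lat))

so ``forward = (1, 0, 0)``, ``east = (0, 1, 0)`` and ``up = (0, 0, 1)``.
At the poles the longitude is conventionally 0.

Quaternions are stored as ``(w, x, y, z)`` arrays, unit norm, canonicalized to
``w >= 0`` (q and -q encode the same rotation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateMeanError",
    "SpherePoint",
    "FORWARD",
    "UP",
    "EAST",
    "wrap_longitude",
    "sph_to_vec",
    "vec_to_sph",
    "angular_distance",
    "spherical_mean",
    "geodesic_point",
    "quat_identity",
    "quat_normalize",
    "quat_canonical",
    "quat_conjugate",
    "quat_multiply",
    "quat_rotate",
    "quat_from_axis_angle",
    "quat_between",
    "quat_angle",
    "slerp",
]

FORWARD = np.array([1.0, 0.0, 0.0])
EAST = np.array([0.0, 1.0, 0.0])
UP = np.array([0.0, 0.0, 1.0])

_POLE_EPS = 1e-12


class DegenerateMeanError(ValueError):
    """Raised when a spherical mean is undefined (resultant vector ~ 0)."""


def wrap_longitude(lon):
    """Wrap longitudes (degrees) into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class SpherePoint:
    """A location on the stimulus sphere (longitude, latitude, degrees).

    Longitude wraps modulo 360 into [-180, 180); latitude is clamped to
    [-90, 90]; at the poles the longitude is set to 0.
    """

    lon: float
    lat: float

    def __post_init__(self):
        lat = float(np.clip(self.lat, -90.0, 90.0))
        lon = float(wrap_longitude(self.lon)) if abs(lat) < 90.0 else 0.0
        object.__setattr__(self, "lon", lon)
        object.__setattr__(self, "lat", lat)

    def to_unit_vector(self) -> np.ndarray:
        return sph_to_vec(self.lon, self.lat)

    @staticmethod
    def from_unit_vector(v) -> "SpherePoint":
        lon, lat = vec_to_sph(v)
        return SpherePoint(float(lon), float(lat))


def sph_to_vec(lon, lat) -> np.ndarray:
    """Longitude/latitude (degrees) -> unit vector(s), shape (..., 3)."""
    lon = np.deg2rad(np.asarray(lon, dtype=float))
    lat = np.deg2rad(np.asarray(lat, dtype=float))
    cl = np.cos(lat)
    return np.stack([cl * np.cos(lon), cl * np.sin(lon), np.sin(lat)], axis=-1)


def vec_to_sph(v):
    """Unit vector(s) (..., 3) -> (longitude, latitude) in degrees."""
    v = np.asarray(v, dtype=float)
    z = np.clip(v[..., 2], -1.0, 1.0)
    lat = np.rad2deg(np.arcsin(z))
    lon = np.rad2deg(np.arctan2(v[..., 1], v[..., 0]))
    # longitude undefined at the poles: fix it at 0 by convention
    at_pole = np.hypot(v[..., 0], v[..., 1]) < _POLE_EPS
    lon = np.where(at_pole, 0.0, wrap_longitude(lon))
    return lon, lat


def angular_distance(lon1, lat1, lon2, lat2):
    """Great-circle central angle between points, in degrees, in [0, 180].

    Uses the atan2 form, which stays accurate for near-coincident and
    near-antipodal pairs.
    """
    a = sph_to_vec(lon1, lat1)
    b = sph_to_vec(lon2, lat2)
    cross = np.cross(a, b)
    sin = np.sqrt(np.sum(cross * cross, axis=-1))
    cos = np.sum(a * b, axis=-1)
    return np.rad2deg(np.arctan2(sin, cos))


def _vec_angular_distance(a, b):
    """Great-circle angle (degrees) between unit vectors, broadcasting."""
    cross = np.cross(a, b)
    sin = np.sqrt(np.sum(cross * cross, axis=-1))
    cos = np.sum(a * b, axis=-1)
    return np.rad2deg(np.arctan2(sin, cos))


def spherical_mean(lon, lat, weights=None):
    """(Weighted) spherical mean: normalized vector resultant, as (lon, lat).

    Raises
    ------
    DegenerateMeanError
        If the resultant vector norm is below 1e-9 (e.g. antipodal points),
        where the mean direction is undefined.
    """
    v = np.atleast_2d(sph_to_vec(lon, lat))
    if v.shape[0] == 0:
        raise DegenerateMeanError("spherical mean of an empty point set")
    if weights is None:
        m = v.mean(axis=0)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        tot = w.sum()
        if tot <= 0:
            raise DegenerateMeanError("all weights zero")
        m = (w[:, None] * v).sum(axis=0) / tot
    n = np.linalg.norm(m)
    if n <= 1e-9:
        raise DegenerateMeanError("resultant vector ~ 0: mean direction undefined")
    mlon, mlat = vec_to_sph(m / n)
    return float(mlon), float(mlat)


def geodesic_point(v0, v1, t):
    """Point(s) at fraction ``t`` along the great circle from v0 to v1.

    ``t`` may be a scalar or an array; v0, v1 are unit vectors.  For
    near-coincident endpoints, falls back to normalized linear interpolation.
    """
    v0 = np.asarray(v0, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    t = np.asarray(t, dtype=float)[..., None]
    dot = np.clip(np.sum(v0 * v1, axis=-1, keepdims=True), -1.0, 1.0)
    theta = np.arccos(dot)
    sin = np.sin(theta)
    small = sin < 1e-9
    safe_sin = np.where(small, 1.0, sin)
    w0 = np.where(small, 1.0 - t, np.sin((1.0 - t) * theta) / safe_sin)
    w1 = np.where(small, t, np.sin(t * theta) / safe_sin)
    out = w0 * v0 + w1 * v1
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# quaternions, (w, x, y, z)
# ---------------------------------------------------------------------------

def quat_identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_normalize(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def quat_canonical(q) -> np.ndarray:
    """Flip sign so that w >= 0 (q and -q are the same rotation)."""
    q = np.asarray(q, dtype=float)
    return np.where(q[..., 0:1] < 0, -q, q)


def quat_conjugate(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def quat_multiply(a, b) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w1, x1, y1, z1 = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    w2, x2, y2, z2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_rotate(q, v) -> np.ndarray:
    """Rotate vector(s) v by unit quaternion(s) q (broadcasting)."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., 0:1]
    u = q[..., 1:4]
    t = 2.0 * np.cross(u, v)
    return v + w * t + np.cross(u, t)


def quat_from_axis_angle(axis, angle_deg) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    half = np.deg2rad(np.asarray(angle_deg, dtype=float)) / 2.0
    return np.concatenate(
        [np.cos(half)[..., None], np.sin(half)[..., None] * axis], axis=-1
    )


def quat_between(a, b) -> np.ndarray:
    """Minimal (roll-free) rotation taking unit vector a to unit vector b.

    Vectorized over leading dimensions; the antipodal case picks an arbitrary
    perpendicular axis for the 180-degree rotation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = np.broadcast_arrays(a, b)
    dot = np.sum(a * b, axis=-1)
    xyz = np.cross(a, b)
    w = 1.0 + dot
    q = np.concatenate([w[..., None], xyz], axis=-1)
    anti = w < 1e-12
    if np.any(anti):
        q = np.array(q, copy=True)
        # any axis perpendicular to a works; cross with the least-aligned basis axis
        aa = np.atleast_2d(a)[np.atleast_1d(anti)]
        helper = np.zeros_like(aa)
        helper[np.arange(aa.shape[0]), np.argmin(np.abs(aa), axis=-1)] = 1.0
        axis = np.cross(aa, helper)
        axis /= np.linalg.norm(axis, axis=-1, keepdims=True)
        repl = np.concatenate([np.zeros(aa.shape[:-1] + (1,)), axis], axis=-1)
        if q.ndim == 1:
            q = repl[0]
        else:
            q[anti] = repl
    return quat_canonical(quat_normalize(q))


def quat_angle(q0, q1):
    """Rotation angle (degrees) between two unit quaternions, in [0, 180].

    Uses the relative rotation's atan2 form, accurate for tiny angles.
    """
    d = quat_multiply(quat_conjugate(np.asarray(q0, dtype=float)),
                      np.asarray(q1, dtype=float))
    vec = np.linalg.norm(d[..., 1:], axis=-1)
    return np.rad2deg(2.0 * np.arctan2(vec, np.abs(d[..., 0])))


def slerp(q0, q1, t) -> np.ndarray:
    """Spherical linear interpolation along the shorter arc.

    ``t`` broadcasts against the leading dimensions of q0/q1; t=0 returns q0
    and t=1 returns q1 (up to sign canonicalization and unit normalization).
    Near-parallel quaternions fall back to normalized linear interpolation.
    """
    q0 = np.asarray(q0, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    t = np.asarray(t, dtype=float)[..., None]
    dot = np.sum(q0 * q1, axis=-1, keepdims=True)
    q1 = np.where(dot < 0, -q1, q1)  # shorter arc
    dot = np.clip(np.abs(dot), -1.0, 1.0)
    theta = np.arccos(dot)
    sin = np.sin(theta)
    small = sin < 1e-9
    safe_sin = np.where(small, 1.0, sin)
    w0 = np.where(small, 1.0 - t, np.sin((1.0 - t) * theta) / safe_sin)
    w1 = np.where(small, t, np.sin(t * theta) / safe_sin)
    return quat_normalize(w0 * q0 + w1 * q1)
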