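"""Spherical I-DT fixation detection and per-trial movement measures.

Fixations are periods of stable eye points: a sliding window is accepted when
its dispersion -- the maximum pairwise great-circle distance among the window's
samples -- stays at or below ``max_dispersion`` (default 3 degrees) for at
least ``min_duration`` (default 80 ms), then extended sample-by-sample while
the dispersion holds.  All thresholds act on angular distance on the sphere,
never on projected longitude/latitude ranges, which keeps the detector
rotation-invariant and pole-safe.

Head fixations are the spherical mean of the head point over an eye fixation's
time span.  Saccade amplitudes / head shifts are angular distances between
successive (head) fixation centroids; the exploration tendency is the mean
great-circle distance of each centroid from the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sphere

__all__ = [
    "detect_fixations_idt",
    "head_fixations",
    "saccade_amplitudes",
    "head_shifts",
    "exploration_tendency",
    "trial_measures",
    "TrialMeasures",
]

FIXATION_COLUMNS = ["index", "start_ms", "end_ms", "dur_ms", "lon", "lat"]


def _max_angle_to(v, window):
    """Largest great-circle angle (deg) from vector v to any vector in window."""
    d = sphere._vec_angular_distance(window, v)
    return float(np.max(d))


def _pairwise_max_angle(window):
    g = np.clip(window @ window.T, -1.0, 1.0)
    return float(np.rad2deg(np.arccos(np.min(g))))


def detect_fixations_idt(t, lon, lat, max_dispersion=3.0, min_duration=80.0
                         ) -> pd.DataFrame:
    """Dispersion-threshold fixation detection on the sphere.

    Parameters
    ----------
    t : array of ms, strictly increasing
    lon, lat : eye point coordinates, degrees
    max_dispersion : maximum pairwise great-circle distance within a fixation
    min_duration : minimum spanned duration, ms

    Returns
    -------
    DataFrame with columns ``index, start_ms, end_ms, dur_ms, lon, lat`` where
    the centroid is the spherical mean of the window samples.  The minimum
    duration is tested on the inclusive sample span ``t[j] - t[i]``; the
    reported end is half-open (one sample period past the last sample).
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise ValueError("empty sample series")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if max_dispersion <= 0 or min_duration <= 0:
        raise ValueError("thresholds must be positive")

    vecs = sphere.sph_to_vec(lon, lat)
    n = t.size
    dt = float(np.median(np.diff(t))) if n > 1 else 0.0

    rows = []
    start = 0
    while start < n:
        # initial window spanning min_duration
        end0 = int(np.searchsorted(t, t[start] + min_duration, side="left"))
        if end0 >= n:
            if t[n - 1] - t[start] < min_duration:
                break
            end0 = n - 1
        window = vecs[start : end0 + 1]
        disp = _pairwise_max_angle(window)
        if disp > max_dispersion:
            start += 1
            continue
        j = end0
        while j + 1 < n:
            d_new = _max_angle_to(vecs[j + 1], vecs[start : j + 1])
            if max(disp, d_new) > max_dispersion:
                break
            disp = max(disp, d_new)
            j += 1
        clon, clat = sphere.spherical_mean(
            np.asarray(lon)[start : j + 1], np.asarray(lat)[start : j + 1])
        end_ms = t[j] + dt
        rows.append((len(rows) + 1, t[start], end_ms, end_ms - t[start],
                     clon, clat))
        start = j + 1

    return pd.DataFrame(rows, columns=FIXATION_COLUMNS)


def head_fixations(fixations: pd.DataFrame, gaze: pd.DataFrame) -> pd.DataFrame:
    """Paired head fixation per eye fixation: spherical mean of the head point
    over samples with ``t`` in [start, end)."""
    t = gaze["t"].to_numpy()
    hlon = gaze["head_lon"].to_numpy()
    hlat = gaze["head_lat"].to_numpy()
    rows = []
    for idx, start, end in zip(fixations["index"], fixations["start_ms"],
                               fixations["end_ms"]):
        sel = (t >= start) & (t < end)
        if not np.any(sel):
            raise ValueError(f"fixation {idx} spans no samples")
        clon, clat = sphere.spherical_mean(hlon[sel], hlat[sel])
        rows.append((idx, clon, clat))
    return pd.DataFrame(rows, columns=["index", "head_lon", "head_lat"])


def saccade_amplitudes(lon, lat) -> np.ndarray:
    """Angular distances between successive fixation centroids (degrees)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size < 2:
        return np.empty(0)
    return np.asarray(
        sphere.angular_distance(lon[:-1], lat[:-1], lon[1:], lat[1:]))


def head_shifts(head_lon, head_lat) -> np.ndarray:
    """Angular distances between successive head-fixation centroids."""
    return saccade_amplitudes(head_lon, head_lat)


def exploration_tendency(lon, lat) -> float:
    """Mean great-circle distance of each centroid from the first; 0 if < 2."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size == 0:
        raise ValueError("need at least one centroid")
    if lon.size == 1:
        return 0.0
    d = sphere.angular_distance(lon[1:], lat[1:], lon[0], lat[0])
    return float(np.mean(d))


@dataclass
class TrialMeasures:
    """Per-trial movement summary (fixation counts, durations, exploration)."""

    n_fixations: int
    mean_fixation_duration: float  # ms; nan when no fixations
    exploration_eye: float  # degrees; nan when no fixations
    exploration_head: float
    saccade_amplitudes: np.ndarray
    head_shifts: np.ndarray


def trial_measures(fixations: pd.DataFrame,
                   head_fix: pd.DataFrame | None = None) -> TrialMeasures:
    """All per-trial measures; zero-fixation trials yield nan means."""
    n = len(fixations)
    if n == 0:
        return TrialMeasures(0, np.nan, np.nan, np.nan,
                             np.empty(0), np.empty(0))
    lon = fixations["lon"].to_numpy()
    lat = fixations["lat"].to_numpy()
    if head_fix is not None and len(head_fix):
        hlon = head_fix["head_lon"].to_numpy()
        hlat = head_fix["head_lat"].to_numpy()
        expl_head = exploration_tendency(hlon, hlat)
        shifts = head_shifts(hlon, hlat)
    else:
        expl_head = np.nan
        shifts = np.empty(0)
    return TrialMeasures(
        n_fixations=n,
        mean_fixation_duration=float(fixations["dur_ms"].mean()),
        exploration_eye=exploration_tendency(lon, lat),
        exploration_head=expl_head,
        saccade_amplitudes=saccade_amplitudes(lon, lat),
        head_shifts=shifts,
    )
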