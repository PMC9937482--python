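"""Cross-recurrence analysis (CRA) of spherical fixation sequences.

Two equal-length sequences E (encoding) and R (recognition) define a binary
N x N matrix with r_ij = 1 iff the great-circle distance between e_i and r_j
is at or below the recurrence radius.  Nine measures summarize its structure:

==========  =================================================================
REC         percentage of recurrent points out of N^2
DET         percentage of recurrent points on diagonal lines (length >= 2)
vLAM, vTT   percentage of points on vertical lines (consecutive encoding
            indices i at a fixed recognition index j) and their mean length
hLAM, hTT   same for horizontal lines (consecutive j at fixed i)
CORM        center of recurrence mass, 100 * sum((j - i) r_ij) /
            ((N - 1) sum(r_ij)); positive = primacy (recognition dwells on
            locations fixated early in encoding), negative = recency
CLUST       percentage of points in 8-connected clusters of size >= 8
ENT         Shannon entropy (nats) of the diagonal line-length distribution
==========  =================================================================

Measures that are undefined (no recurrences, no qualifying lines) are
reported as nan and excluded from aggregation, never coerced to 0.  The
recurrence radius is calibrated by bisection so that the mean REC over a set
of sequence pairs reaches a target percentage (7% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage

from . import sphere

__all__ = [
    "CRAMeasures",
    "adjust_lengths",
    "distance_matrix",
    "recurrence_matrix",
    "rec_percent",
    "det_percent",
    "laminarity_vertical",
    "laminarity_horizontal",
    "corm_percent",
    "clust_percent",
    "diagonal_entropy",
    "compute_all",
    "calibrate_radius",
]

MEASURE_NAMES = ["rec", "det", "hlam", "htt", "vlam", "vtt", "corm", "clust",
                 "ent"]


@dataclass
class CRAMeasures:
    """The nine recurrence statistics of one sequence pair (nan = undefined)."""

    rec: float
    det: float
    hlam: float
    htt: float
    vlam: float
    vtt: float
    corm: float
    clust: float
    ent: float
    n: int
    radius: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def adjust_lengths(seq_e, seq_r):
    """Truncate both (lon, lat) sequences to the shorter length, keeping the
    leading fixations (temporal alignment from trial onset)."""
    (lon_e, lat_e), (lon_r, lat_r) = seq_e, seq_r
    lon_e = np.asarray(lon_e, dtype=float)
    lat_e = np.asarray(lat_e, dtype=float)
    lon_r = np.asarray(lon_r, dtype=float)
    lat_r = np.asarray(lat_r, dtype=float)
    if lon_e.size == 0 or lon_r.size == 0:
        raise ValueError("cannot adjust an empty sequence")
    n = min(lon_e.size, lon_r.size)
    if n < 2:
        warnings.warn("adjusted length < 2: most CRA measures will be degenerate")
    return (lon_e[:n], lat_e[:n]), (lon_r[:n], lat_r[:n])


def distance_matrix(seq_e, seq_r) -> np.ndarray:
    """Great-circle distances (deg), rows = encoding i, cols = recognition j."""
    ve = np.atleast_2d(sphere.sph_to_vec(*seq_e))
    vr = np.atleast_2d(sphere.sph_to_vec(*seq_r))
    # atan2 form: exactly 0 for identical samples, accurate near 0 and 180
    return sphere._vec_angular_distance(ve[:, None, :], vr[None, :, :])


def recurrence_matrix(seq_e, seq_r, radius) -> np.ndarray:
    """Binary matrix: r_ij = 1 iff distance(e_i, r_j) <= radius (ties count)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    return distance_matrix(seq_e, seq_r) <= radius + 1e-12


def rec_percent(r) -> float:
    r = np.asarray(r, dtype=bool)
    return 100.0 * r.sum() / r.size


def _run_lengths(x) -> list:
    """Lengths of True runs in a 1-d boolean array."""
    x = np.asarray(x, dtype=bool)
    if x.size == 0:
        return []
    padded = np.concatenate([[False], x, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(ends - starts)


def _diagonal_runs(r, min_line) -> list:
    """Lengths >= min_line of runs along diagonals parallel to the main one."""
    r = np.asarray(r, dtype=bool)
    n, m = r.shape
    out = []
    for k in range(-(n - 1), m):
        out.extend(L for L in _run_lengths(np.diagonal(r, k)) if L >= min_line)
    return out


def det_percent(r, min_line=2) -> float:
    """Percent of recurrent points on diagonal runs of length >= min_line."""
    r = np.asarray(r, dtype=bool)
    total = r.sum()
    if total == 0:
        return float("nan")
    on_lines = sum(_diagonal_runs(r, min_line))
    return 100.0 * on_lines / total


def _line_measures(r, axis, min_line):
    """(lam percent, tt mean length) for runs along the given axis."""
    r = np.asarray(r, dtype=bool)
    total = r.sum()
    if total == 0:
        return float("nan"), float("nan")
    runs = []
    lines = r.T if axis == 0 else r  # axis 0: walk down each column
    for line in lines:
        runs.extend(L for L in _run_lengths(line) if L >= min_line)
    lam = 100.0 * sum(runs) / total
    tt = float(np.mean(runs)) if runs else float("nan")
    return lam, tt


def laminarity_vertical(r, min_line=2):
    """Vertical lines: consecutive encoding indices i at a fixed recognition
    index j.  Returns (vLAM percent, vTT mean length)."""
    return _line_measures(r, axis=0, min_line=min_line)


def laminarity_horizontal(r, min_line=2):
    """Horizontal lines: consecutive recognition indices j at a fixed i."""
    return _line_measures(r, axis=1, min_line=min_line)


def corm_percent(r) -> float:
    """Center of recurrence mass; +100 at the extreme primacy corner."""
    r = np.asarray(r, dtype=bool)
    total = r.sum()
    if total == 0:
        return float("nan")
    n = r.shape[0]
    if n < 2:
        return 0.0
    i, j = np.nonzero(r)
    return 100.0 * float((j - i).sum()) / ((n - 1) * total)


def clust_percent(r, min_cluster=8) -> float:
    """Percent of recurrent points in 8-connected components of size >=
    min_cluster (lines included)."""
    r = np.asarray(r, dtype=bool)
    total = r.sum()
    if total == 0:
        return float("nan")
    labels, n_comp = ndimage.label(r, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())[1:]
    return 100.0 * sizes[sizes >= min_cluster].sum() / total


def diagonal_entropy(r, min_line=2) -> float:
    """Shannon entropy (nats) of the diagonal run-length distribution."""
    runs = _diagonal_runs(np.asarray(r, dtype=bool), min_line)
    if not runs:
        return float("nan")
    _, counts = np.unique(runs, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def compute_all(seq_e, seq_r, radius, min_line=2, min_cluster=8) -> CRAMeasures:
    """Adjust lengths, build the recurrence matrix, compute all nine measures."""
    seq_e, seq_r = adjust_lengths(seq_e, seq_r)
    r = recurrence_matrix(seq_e, seq_r, radius)
    hlam, htt = laminarity_horizontal(r, min_line)
    vlam, vtt = laminarity_vertical(r, min_line)
    return CRAMeasures(
        rec=rec_percent(r),
        det=det_percent(r, min_line),
        hlam=hlam,
        htt=htt,
        vlam=vlam,
        vtt=vtt,
        corm=corm_percent(r),
        clust=clust_percent(r, min_cluster),
        ent=diagonal_entropy(r, min_line),
        n=r.shape[0],
        radius=float(radius),
    )


def recurrence_points(r):
    """Coordinate list (i, j) of recurrent points, for diagram export."""
    i, j = np.nonzero(np.asarray(r, dtype=bool))
    return np.column_stack([i, j])


def calibrate_radius(pairs, target_rec=7.0, tol=0.01, max_iter=64) -> float:
    """Smallest radius whose mean REC over all pairs reaches ``target_rec``.

    Mean REC is a nondecreasing step function of the radius; bisection on
    [0, 180] converges to the jump location.  With many pairs the step sizes
    are tiny and the mean REC at the returned radius sits within ``tol``
    percentage points above the target; a coarse set of matrices can jump
    further, which triggers a warning.

    Raises
    ------
    ValueError
        If no pairs are given, the target is outside (0, 100), or the target
        is unreachable (below the granularity floor of the matrices).
    """
    if not 0.0 < target_rec < 100.0:
        raise ValueError("target recurrence must be in (0, 100)")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one sequence pair")
    dists = []
    for seq_e, seq_r in pairs:
        seq_e, seq_r = adjust_lengths(seq_e, seq_r)
        dists.append(distance_matrix(seq_e, seq_r).ravel())

    def mean_rec(radius):
        return float(np.mean([100.0 * np.mean(d <= radius + 1e-12)
                              for d in dists]))

    if mean_rec(0.0) >= target_rec:
        return 0.0
    if mean_rec(180.0) < target_rec:  # pragma: no cover - cannot happen
        raise ValueError("target recurrence unreachable at any radius")
    lo, hi = 0.0, 180.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if mean_rec(mid) >= target_rec:
            hi = mid
        else:
            lo = mid
    achieved = mean_rec(hi)
    if achieved - target_rec > max(tol, 0.5):
        warnings.warn(
            f"mean recurrence jumps from below {target_rec}% to "
            f"{achieved:.2f}% at radius {hi:.3f} deg (coarse matrices)")
    return float(hi)
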