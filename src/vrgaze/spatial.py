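"""Spatial statistics of eye/head points on the sphere.

Covers per-trial longitude/latitude spreads (with circular recentering of
longitudes), angular-Gaussian heatmaps on an equirectangular grid, the
latitude-weighted heatmap correlation, and the same-scene vs different-scene
contrast used to separate image-driven from incidental similarity.

The equirectangular projection stretches area by 1/cos(latitude), so the
heatmap correlation weights each cell by cos(latitude of its center), the
exact inverse of that distortion; the smoothing kernel itself is isotropic in
*angular* distance, so a point near a pole spreads over many longitude
columns instead of pinching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import sphere

__all__ = [
    "Heatmap",
    "trial_spread",
    "spread_statistics",
    "make_heatmap",
    "weighted_correlation",
    "ContrastResult",
    "same_vs_different_contrast",
]


@dataclass
class Heatmap:
    """Normalized equirectangular density grid.

    Rows run from latitude +90 down to -90, columns from longitude -180 to
    +180, ``resolution`` degrees per cell; the grid sums to 1 unless the map
    was built from an empty point set (``uniform_fallback``).
    """

    grid: np.ndarray
    resolution: float = 1.0
    uniform_fallback: bool = False

    def __post_init__(self):
        expected = (int(round(180 / self.resolution)),
                    int(round(360 / self.resolution)))
        if self.grid.shape != expected:
            raise ValueError(f"grid shape {self.grid.shape} != {expected}")
        if np.any(self.grid < 0):
            raise ValueError("heatmap cells must be nonnegative")

    @property
    def lat_centers(self) -> np.ndarray:
        r = self.resolution
        return 90.0 - r / 2.0 - r * np.arange(self.grid.shape[0])

    @property
    def lon_centers(self) -> np.ndarray:
        r = self.resolution
        return -180.0 + r / 2.0 + r * np.arange(self.grid.shape[1])

    def save_txt(self, path):
        """Plain-text export with a 3-line header (resolution, norm, row order)."""
        header = (f"resolution_deg={self.resolution}\n"
                  f"normalization=sum_to_one uniform_fallback={self.uniform_fallback}\n"
                  "rows=lat +90..-90, cols=lon -180..+180")
        np.savetxt(path, self.grid, header=header)

    @classmethod
    def load_txt(cls, path):
        with open(path) as fh:
            first = fh.readline()
        res = float(first.strip().lstrip("#").strip().split("=", 1)[1])
        return cls(grid=np.loadtxt(path), resolution=res)


def trial_spread(lon, lat):
    """(sd_longitude, sd_latitude) of one trial's points, degrees.

    Longitudes are rotated so their circular mean sits at 0, wrapped to
    [-180, 180), then given an ordinary sample SD; latitudes are linear.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size < 2:
        raise ValueError("need at least two points for a spread")
    center = np.rad2deg(stats.circmean(np.deg2rad(lon), high=np.pi, low=-np.pi))
    lon_c = sphere.wrap_longitude(lon - center)
    return float(np.std(lon_c, ddof=1)), float(np.std(lat, ddof=1))


def spread_statistics(points: pd.DataFrame, lon_col="lon", lat_col="lat",
                      group_cols=("participant", "scene", "phase"),
                      phase_col="phase"):
    """Per-trial spreads and their across-trial medians per phase.

    ``points`` holds one row per point (fixation centroid) with trial-grouping
    columns.  Trials with fewer than two points are skipped with a warning.

    Returns
    -------
    (per_trial, medians) : per-trial DataFrame with sd_lon/sd_lat, and a
    DataFrame indexed by phase with the median of each.
    """
    rows = []
    skipped = 0
    for key, grp in points.groupby(list(group_cols), sort=True):
        if len(grp) < 2:
            skipped += 1
            continue
        sd_lon, sd_lat = trial_spread(grp[lon_col].to_numpy(),
                                      grp[lat_col].to_numpy())
        rows.append(dict(zip(group_cols, key)) | {"sd_lon": sd_lon,
                                                  "sd_lat": sd_lat})
    if skipped:
        warnings.warn(f"skipped {skipped} trial(s) with < 2 points")
    per_trial = pd.DataFrame(rows)
    medians = per_trial.groupby(phase_col)[["sd_lon", "sd_lat"]].median()
    return per_trial, medians


def make_heatmap(lon, lat, sigma=4.0, resolution=1.0) -> Heatmap:
    """Angular-Gaussian heatmap: each point deposits exp(-d^2 / 2 sigma^2)
    over cell centers, with d the great-circle distance, truncated at 3 sigma.

    An empty point set yields a uniform map flagged ``uniform_fallback``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    n_lat = int(round(180 / resolution))
    n_lon = int(round(360 / resolution))
    grid = np.zeros((n_lat, n_lon))
    if lon.size == 0:
        warnings.warn("empty point set: returning a uniform heatmap")
        grid[:] = 1.0 / grid.size
        return Heatmap(grid=grid, resolution=resolution, uniform_fallback=True)

    lat_centers = 90.0 - resolution / 2.0 - resolution * np.arange(n_lat)
    lon_centers = -180.0 + resolution / 2.0 + resolution * np.arange(n_lon)
    lon_g, lat_g = np.meshgrid(lon_centers, lat_centers)
    cell_vecs = sphere.sph_to_vec(lon_g, lat_g)
    cut = 3.0 * sigma
    cos_cut = np.cos(np.deg2rad(cut))
    for plon, plat in zip(lon, lat):
        rows = np.abs(lat_centers - plat) <= cut  # |dlat| <= great-circle dist
        v = sphere.sph_to_vec(plon, plat)
        cosd = np.clip(cell_vecs[rows] @ v, -1.0, 1.0)
        d = np.rad2deg(np.arccos(cosd))
        k = np.where(cosd >= cos_cut, np.exp(-(d ** 2) / (2.0 * sigma ** 2)), 0.0)
        grid[rows] += k
    total = grid.sum()
    if total <= 0:
        grid[:] = 1.0 / grid.size
        return Heatmap(grid=grid, resolution=resolution, uniform_fallback=True)
    return Heatmap(grid=grid / total, resolution=resolution)


def weighted_correlation(h1: Heatmap, h2: Heatmap) -> float:
    """Latitude-weighted Pearson correlation of two heatmaps.

    Cell weight = cos(latitude of cell center), the inverse of the
    equirectangular area stretching.  Returns nan (with a warning) when a map
    has zero weighted variance.
    """
    if h1.grid.shape != h2.grid.shape or h1.resolution != h2.resolution:
        raise ValueError("heatmaps must share grid geometry")
    w = np.cos(np.deg2rad(h1.lat_centers))[:, None] * np.ones_like(h1.grid)
    w = w / w.sum()
    a = h1.grid
    b = h2.grid
    ma = (w * a).sum()
    mb = (w * b).sum()
    va = (w * (a - ma) ** 2).sum()
    vb = (w * (b - mb) ** 2).sum()
    if va <= 0 or vb <= 0:
        warnings.warn("zero-variance heatmap: correlation undefined")
        return float("nan")
    cov = (w * (a - ma) * (b - mb)).sum()
    return float(cov / np.sqrt(va * vb))


@dataclass
class ContrastResult:
    """Same-pair vs different-pair heatmap correlation contrast."""

    mean_same: float
    mean_different: float
    t_stat: float
    p_value: float
    n: int
    r_same: np.ndarray = field(repr=False, default=None)
    r_different: np.ndarray = field(repr=False, default=None)
    different_partner: dict = field(repr=False, default=None)


def _derangement(keys, rng):
    """Seeded permutation of keys with no fixed points."""
    n = len(keys)
    if n < 2:
        raise ValueError("need at least 2 scenes for a different-scene pairing")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return {keys[i]: keys[perm[i]] for i in range(n)}


def same_vs_different_contrast(maps_a: dict, maps_b: dict, seed=0
                               ) -> ContrastResult:
    """Compare mean correlation over same-scene pairs with seeded random
    different-scene pairs, paired t across scenes.

    ``maps_a`` and ``maps_b`` map scene id -> Heatmap for the two sides of
    the comparison (encoding vs recognition of one modality, or eye vs head
    within one phase); only scenes present in both are used.
    """
    keys = sorted(set(maps_a) & set(maps_b))
    if len(keys) < 2:
        raise ValueError("need at least 2 scenes present on both sides")
    rng = np.random.default_rng(seed)
    partner = _derangement(keys, rng)
    r_same = np.array([weighted_correlation(maps_a[k], maps_b[k]) for k in keys])
    r_diff = np.array(
        [weighted_correlation(maps_a[k], maps_b[partner[k]]) for k in keys])
    diff = r_same - r_diff
    if np.allclose(diff, diff[0]):
        # degenerate (e.g. identical maps everywhere): t undefined
        t_stat, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
    else:
        t_stat, p = stats.ttest_rel(r_same, r_diff)
    return ContrastResult(
        mean_same=float(np.mean(r_same)),
        mean_different=float(np.mean(r_diff)),
        t_stat=float(t_stat),
        p_value=float(p),
        n=len(keys),
        r_same=r_same,
        r_different=r_diff,
        different_partner=partner,
    )
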