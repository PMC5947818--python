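"""Stationary/transition segmentation, place clustering and home inference.

A grid sample is *transitioning* when any of three 10-minute moving averages
of instantaneous speed — centred, backward, forward — exceeds a threshold
``d`` (default 1.5 km/h). Stationary samples are clustered into recurrent
places with K-means++ run for increasing K, accepting the largest K whose
cluster centres all stay at least ``l`` (default 0.4 km) apart. The home is
the modal overnight (02:00-07:00) location across days, and traces are
recentred so that home sits at the origin.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .preprocess import GRID_STEP_S, GridTrace

SPEED_THRESHOLD_KMH = 1.5
CLUSTER_SEPARATION_KM = 0.4
HOME_BIN_KM = 0.01
NIGHT_WINDOW = (2, 7)  # [02:00, 07:00) local


@dataclasses.dataclass
class StationaryMask:
    """Per-grid-sample transition flags and the speed window means behind them."""

    transitioning: np.ndarray  # bool; False wherever the sample is missing
    cen: np.ndarray
    back: np.ndarray
    fwd: np.ndarray

    @property
    def stationary(self) -> np.ndarray:
        return ~self.transitioning


def segment_stationary(grid: GridTrace, d: float = SPEED_THRESHOLD_KMH) -> StationaryMask:
    """Split grid samples into stationary and transitioning points.

    Instantaneous speed is attributed to the interval between adjacent
    non-missing grid slots; a window mean averages the interval speeds whose
    midpoints fall inside it (centred: t +- 5 min; backward: [t - 10 min, t];
    forward: [t, t + 10 min]). Samples next to missing runs use whatever
    window content exists; samples with empty windows count as stationary.
    """
    n = len(grid)
    valid = grid.valid
    # Interval speeds between grid-adjacent valid slot pairs.
    pair_ok = valid[:-1] & valid[1:] if n > 1 else np.zeros(0, dtype=bool)
    dist = np.hypot(np.diff(grid.x), np.diff(grid.y))
    step_h = GRID_STEP_S / 3600.0
    sp = np.where(pair_ok, dist / step_h, np.nan)

    # Pad the interval-speed array so every window is two shifted slices;
    # interval j sits at spn[j + 2].
    spn = np.concatenate([np.full(2, np.nan), sp, np.full(2, np.nan)])

    def window_mean(j0: int, j1: int) -> np.ndarray:
        stack = np.vstack([spn[j0 + 2 : j0 + 2 + n], spn[j1 + 2 : j1 + 2 + n]])
        cnt = np.sum(~np.isnan(stack), axis=0)
        total = np.nansum(stack, axis=0)
        return np.where(cnt > 0, total / np.maximum(cnt, 1), 0.0)

    cen = window_mean(-1, 0)
    back = window_mean(-2, -1)
    fwd = window_mean(0, 1)
    transitioning = ((cen > d) | (back > d) | (fwd > d)) & valid
    return StationaryMask(transitioning, cen, back, fwd)


@dataclasses.dataclass
class PlaceClusterSet:
    """Accepted place clustering of stationary samples."""

    k: int
    centers: np.ndarray  # (k, 2)
    labels: np.ndarray  # stationary-sample -> cluster index
    separation_km: float

    def home_cluster(self, max_dist: float | None = None) -> int | None:
        """Index of the cluster nearest the origin, or None if too far.

        The trace is home-recentred before clustering, so the home cluster is
        the one whose centre lies within ``max_dist`` (default: the
        separation threshold) of (0, 0).
        """
        if max_dist is None:
            max_dist = self.separation_km
        dist = np.hypot(self.centers[:, 0], self.centers[:, 1])
        i = int(np.argmin(dist))
        return i if dist[i] <= max_dist else None


def cluster_stationary(
    points: np.ndarray,
    l: float = CLUSTER_SEPARATION_KM,
    seed: int = 0,
    n_init: int = 1,
    max_k: int = 20,
) -> PlaceClusterSet:
    """Cluster stationary coordinates with incrementally grown K-means++.

    K starts at 1 and is incremented while the minimum pairwise Euclidean
    distance between fitted centres stays at or above ``l``; the largest
    conforming fit is returned. Deterministic for a fixed seed.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        raise ValueError("cannot cluster zero stationary points")
    n_distinct = len(np.unique(points, axis=0))
    best = PlaceClusterSet(1, points.mean(axis=0, keepdims=True), np.zeros(len(points), int), l)
    k = 2
    while k <= min(max_k, n_distinct):
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed).fit(points)
        centers = km.cluster_centers_
        dists = np.hypot(
            centers[:, None, 0] - centers[None, :, 0],
            centers[:, None, 1] - centers[None, :, 1],
        )
        min_sep = dists[np.triu_indices(k, 1)].min()
        if min_sep < l:
            break
        best = PlaceClusterSet(k, centers, km.labels_, l)
        k += 1
    return best


def _bin_key(x: float, y: float) -> tuple[int, int]:
    return (int(round(x / HOME_BIN_KM)), int(round(y / HOME_BIN_KM)))


def infer_home(grid: GridTrace, tz: str = "UTC"):
    """Infer the home location and recentre the trace on it.

    For each day the modal overnight (02:00-07:00 local) coordinate is found
    (coordinates binned to 0.01 km for mode counting); the global home is the
    modal daily candidate. Ties break to the earliest occurrence. Returns
    ``(home_xy, recentered_grid)``.
    """
    local = grid.times.tz_convert(tz)
    night = (local.hour >= NIGHT_WINDOW[0]) & (local.hour < NIGHT_WINDOW[1]) & grid.valid
    if not night.any():
        raise ValueError("home undeterminable: no overnight samples")

    idx = np.flatnonzero(night)
    dates = local[idx].date
    day_candidates: list[tuple[int, int]] = []
    bin_coords: dict[tuple[int, int], list[tuple[float, float]]] = {}
    for day in pd.unique(pd.Series(dates)):
        sel = idx[dates == day]
        counts: dict[tuple[int, int], int] = {}
        for i in sel:
            key = _bin_key(grid.x[i], grid.y[i])
            counts[key] = counts.get(key, 0) + 1
            bin_coords.setdefault(key, []).append((grid.x[i], grid.y[i]))
        # max count; ties break to the earliest-seen bin (dict preserves order)
        day_candidates.append(max(counts, key=lambda k: counts[k]))

    counts = {}
    for key in day_candidates:
        counts[key] = counts.get(key, 0) + 1
    home_key = max(counts, key=lambda k: counts[k])
    home = np.mean(np.asarray(bin_coords[home_key], dtype=float), axis=0)
    recentered = GridTrace(grid.participant_id, grid.times, grid.x - home[0], grid.y - home[1])
    return home, recentered
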