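"""Cleaning of raw location traces.

Smartphone location streams interleave accurate fixes with bursts of
low-accuracy fixes that share one exact coordinate far from the true path,
and contain long missing stretches. Cleaning proceeds in three stages:

1. :func:`filter_highspeed` — drop fixes implying physically implausible
   speeds (> 100 km/h to a temporal neighbour), removing whole repeated
   artifact coordinates;
2. :func:`downsample` — reduce the uneven stream to 12 samples/hour on a
   5-minute grid using an hourly stationarity test and a median filter;
3. :func:`impute_gaps` — fill short (or overnight) missing runs whose
   flanking positions agree to within 500 m.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import Trace

GRID_STEP_S = 300  # 12 samples per hour


@dataclasses.dataclass
class PreprocessParams:
    """Cleaning thresholds.

    Attributes
    ----------
    v_max_kmh
        Speed above which a fix is considered an artifact candidate.
    stationary_sd_km
        Per-axis SD below which an hour epoch is treated as stationary and
        collapsed to its mean coordinate.
    median_win_min
        Width of the median-filter window used for moving epochs.
    impute_radius_km
        Maximum distance between the two flanks of a missing run for it to
        be imputable.
    impute_max_h_day, impute_max_h_night
        Maximum imputable run length for runs starting at any time, and for
        runs starting at or after ``night_start_hour``.
    burst_min_count
        Number of identical flagged coordinates that qualifies a location as
        a repeated-artifact burst.
    tz
        Timezone in which clock-time rules (hour epochs, 9 pm clause,
        overnight windows, weeks) are interpreted.
    """

    v_max_kmh: float = 100.0
    epoch_h: float = 1.0
    grid_per_h: int = 12
    stationary_sd_km: float = 0.01
    median_win_min: float = 5.0
    impute_radius_km: float = 0.5
    impute_max_h_day: float = 2.0
    impute_max_h_night: float = 12.0
    night_start_hour: float = 21.0
    burst_min_count: int = 3
    tz: str = "UTC"

    def __post_init__(self) -> None:
        for name in (
            "v_max_kmh",
            "epoch_h",
            "grid_per_h",
            "stationary_sd_km",
            "median_win_min",
            "impute_radius_km",
            "impute_max_h_day",
            "impute_max_h_night",
            "burst_min_count",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass
class GridTrace:
    """A trace resampled onto a regular 5-minute grid; NaN marks missing."""

    participant_id: str
    times: pd.DatetimeIndex
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.x)

    def to_trace(self) -> Trace:
        """Drop missing samples and return a plain Trace."""
        m = self.valid
        return Trace(self.participant_id, self.times[m], self.x[m], self.y[m])


def speeds_kmh(trace: Trace) -> np.ndarray:
    """Instantaneous speed between consecutive fixes (length ``n - 1``)."""
    dt_h = np.diff(trace.times.asi8) / 1e9 / 3600.0
    dist = np.hypot(np.diff(trace.x), np.diff(trace.y))
    return dist / dt_h


def filter_highspeed(trace: Trace, params: PreprocessParams | None = None):
    """Remove implausible-speed artifact fixes.

    A fix is *flagged* when the speed from its previous fix or to its next
    fix exceeds ``v_max_kmh``. Exact coordinates carrying at least
    ``burst_min_count`` fixes, at least one of which is flagged, are repeated
    artifact locations: every fix at such a coordinate is removed. A second
    pass then removes any remaining fix whose every adjacent speed still
    exceeds the threshold (a lone off-path spike); fixes that are fast on one
    side only — typically true fixes adjacent to a removed burst — are kept.

    Returns ``(kept, removed)`` where ``removed`` is a boolean mask over the
    input fixes.
    """
    params = params or PreprocessParams()
    n = len(trace)
    removed = np.zeros(n, dtype=bool)
    if n < 2:
        return trace, removed

    sp = speeds_kmh(trace)
    fast = sp > params.v_max_kmh
    flagged = np.zeros(n, dtype=bool)
    flagged[1:] |= fast
    flagged[:-1] |= fast

    coords = trace.x + 1j * trace.y
    uniq, inverse, counts = np.unique(coords, return_inverse=True, return_counts=True)
    coord_flagged = np.zeros(len(uniq), dtype=bool)
    np.logical_or.at(coord_flagged, inverse, flagged)
    burst_coord = coord_flagged & (counts >= params.burst_min_count)
    removed |= burst_coord[inverse]

    kept_idx = np.flatnonzero(~removed)
    if len(kept_idx) >= 2:
        sub = trace.subset(~removed)
        sp2 = speeds_kmh(sub) > params.v_max_kmh
        left = np.concatenate([[True], sp2])
        right = np.concatenate([sp2, [True]])
        spike = left & right
        if len(kept_idx) == 1:
            spike[:] = False
        removed[kept_idx[spike]] = True

    return trace.subset(~removed), removed


def downsample(trace: Trace, params: PreprocessParams | None = None) -> GridTrace:
    """Resample a filtered trace to 12 samples/hour on a 5-minute grid.

    Time is split into one-hour epochs aligned to clock hours (in
    ``params.tz``). If the per-axis SD of the fixes within an epoch is below
    ``stationary_sd_km`` on both axes, the participant is taken to be
    stationary and all 12 grid samples of the epoch receive the epoch mean.
    Otherwise each grid point receives the coordinate-wise median of the raw
    fixes within +-2.5 min; windows holding no fix stay missing.
    """
    params = params or PreprocessParams()
    if len(trace) == 0:
        return GridTrace(trace.participant_id, pd.DatetimeIndex([], tz="UTC"), np.array([]), np.array([]))

    local = trace.times.tz_convert(params.tz)
    start = local[0].floor("h")
    end = local[-1].floor("h") + pd.Timedelta(hours=1)
    grid = pd.date_range(start, end, freq=f"{GRID_STEP_S}s", inclusive="left", tz=params.tz)
    n_grid = len(grid)

    sec = (local.asi8 - grid.asi8[0]) / 1e9
    slot = np.floor((sec + GRID_STEP_S / 2) / GRID_STEP_S).astype(int)
    slot = np.clip(slot, 0, n_grid - 1)

    gx = np.full(n_grid, np.nan)
    gy = np.full(n_grid, np.nan)

    df = pd.DataFrame({"slot": slot, "x": trace.x, "y": trace.y})
    med = df.groupby("slot").median()
    gx[med.index.to_numpy()] = med["x"].to_numpy()
    gy[med.index.to_numpy()] = med["y"].to_numpy()

    # Hourly stationarity test overrides the slot medians of its epoch.
    epoch = np.floor(sec / 3600).astype(int)
    edf = pd.DataFrame({"epoch": epoch, "x": trace.x, "y": trace.y})
    stats = edf.groupby("epoch").agg(
        sx=("x", lambda v: np.std(v, ddof=0)),
        sy=("y", lambda v: np.std(v, ddof=0)),
        mx=("x", "mean"),
        my=("y", "mean"),
    )
    per_h = params.grid_per_h
    for e, row in stats.iterrows():
        if row["sx"] < params.stationary_sd_km and row["sy"] < params.stationary_sd_km:
            lo, hi = int(e) * per_h, min((int(e) + 1) * per_h, n_grid)
            gx[lo:hi] = row["mx"]
            gy[lo:hi] = row["my"]

    return GridTrace(trace.participant_id, grid.tz_convert("UTC"), gx, gy)


def _missing_runs(valid: np.ndarray):
    """Maximal runs of invalid samples as (start, stop) half-open pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[True], valid, [True]]).astype(int)))
    return list(zip(idx[::2], idx[1::2]))


def impute_gaps(grid: GridTrace, params: PreprocessParams | None = None) -> GridTrace:
    """Fill eligible missing runs with the mean of their flanking samples.

    A run is imputable iff its two flanking samples lie within
    ``impute_radius_km`` of each other and either (a) the run lasts at most
    ``impute_max_h_day`` hours, or (b) it lasts at most ``impute_max_h_night``
    hours and its first missing slot falls at or after ``night_start_hour``
    local clock time (runs crossing midnight qualify by their start time).
    Leading/trailing runs without two flanks are never filled.
    """
    params = params or PreprocessParams()
    x = grid.x.copy()
    y = grid.y.copy()
    valid = grid.valid
    local = grid.times.tz_convert(params.tz)
    for lo, hi in _missing_runs(valid):
        if lo == 0 or hi == len(x):
            continue
        xl, yl = x[lo - 1], y[lo - 1]
        xr, yr = x[hi], y[hi]
        if np.hypot(xl - xr, yl - yr) > params.impute_radius_km:
            continue
        run_h = (hi - lo) * GRID_STEP_S / 3600.0
        start = local[lo]
        start_hour = start.hour + start.minute / 60.0
        if run_h <= params.impute_max_h_day or (
            run_h <= params.impute_max_h_night and start_hour >= params.night_start_hour
        ):
            x[lo:hi] = (xl + xr) / 2.0
            y[lo:hi] = (yl + yr) / 2.0
    return GridTrace(grid.participant_id, grid.times, x, y)


def preprocess(trace: Trace, params: PreprocessParams | None = None) -> GridTrace:
    """filter -> downsample -> impute, returning the cleaned grid trace."""
    params = params or PreprocessParams()
    filtered, _ = filter_highspeed(trace, params)
    return impute_gaps(downsample(filtered, params), params)
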