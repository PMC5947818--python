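"""The ten weekly mobility features, computed over five data subsets.

Features (per calendar week, Monday 00:00 local to Sunday 24:00):

========  ==========================================================
ENT       entropy of cluster-occupancy proportions, -sum p_i ln p_i
NENT      ENT / ln N, scaled to [0, 1]
LV        ln of the summed coordinate variances, ln(var_y + var_x)
HS        % of recorded time assigned to the home cluster
TT        % of recorded time spent transitioning between places
TD        total Euclidean path length over consecutive samples (km)
NC        number of place clusters extracted in the week
DM        ln of mean Lomb-Scargle power of x and y in the 23.5-24.5 h
          wavelength band
DMN       DM on per-axis zero-mean unit-variance coordinates
DMD       DM on the zero-mean unit-variance distance-from-home series
========  ==========================================================

Subsets: the full week (``base``); Monday-Friday (``weekday``);
Saturday-Sunday (``weekend``); the element-wise median over ten constituent
subsets (``median``); and the week with unusually-far-travelled days removed
(``optimized``). This yields 50 values per week.

Natural logarithms are used throughout. Occupancy proportions are computed
over stationary grid samples only; transition time is carried separately by
TT.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lombscargle
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .places import (
    CLUSTER_SEPARATION_KM,
    SPEED_THRESHOLD_KMH,
    GridTrace,
    StationaryMask,
    cluster_stationary,
    segment_stationary,
)
from .preprocess import GRID_STEP_S

FEATURE_NAMES = ("ENT", "NENT", "LV", "HS", "TT", "TD", "NC", "DM", "DMN", "DMD")
SUBSET_NAMES = ("base", "weekday", "weekend", "median", "optimized")
FEATURE_COLUMNS = tuple(f"{f}_{s}" for s in SUBSET_NAMES for f in FEATURE_NAMES)

#: variance / spectral-power floor keeping the log features finite
LOG_FLOOR = 1e-10

#: default grid over which the daily-exclusion multiplier alpha is optimized
ALPHA_GRID = tuple(np.arange(0.0, 3.25, 0.25))

SLOTS_PER_DAY = 24 * 3600 // GRID_STEP_S  # 288
SLOTS_PER_WEEK = 7 * SLOTS_PER_DAY


@dataclasses.dataclass
class SpectralConfig:
    """Lomb-Scargle band settings for the diurnal-movement features."""

    band_h: tuple[float, float] = (23.5, 24.5)
    n_freq: int = 25


def entropy(p: Sequence[float]) -> tuple[float, float]:
    """Entropy and normalized entropy of an occupancy distribution.

    ``p`` is renormalised to sum to one; ``0 * ln 0`` counts as zero. NENT is
    ENT / ln N for N >= 2 and 0 for a single cluster; rounding noise is
    clipped so NENT always lies in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty occupancy vector")
    if np.any(p < 0):
        raise ValueError("occupancy proportions must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("occupancy proportions must have positive mass")
    p = p / total
    nz = p[p > 0]
    ent = float(-np.sum(nz * np.log(nz)))
    n = p.size
    nent = float(np.clip(ent / np.log(n), 0.0, 1.0)) if n >= 2 else 0.0
    return ent, nent


def location_variance(x: np.ndarray, y: np.ndarray) -> float:
    """ln(var(y) + var(x)) with a 1e-10 km^2 floor; NaN below two samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        return np.nan
    return float(np.log(max(np.var(x) + np.var(y), LOG_FLOOR)))


def total_distance(x: np.ndarray, y: np.ndarray, valid: np.ndarray) -> float:
    """Sum of Euclidean distances over grid-adjacent valid sample pairs.

    Segments spanning a missing run contribute nothing. NaN when fewer than
    two valid samples exist; a single valid point yields 0 by the convention
    that no movement was recorded.
    """
    valid = np.asarray(valid, bool)
    if valid.sum() == 0:
        return np.nan
    if valid.sum() == 1:
        return 0.0
    pair = valid[:-1] & valid[1:]
    dx = np.diff(x)[pair]
    dy = np.diff(y)[pair]
    return float(np.hypot(dx, dy).sum())


def lomb_band_power(
    t_h: np.ndarray, signal: np.ndarray, config: SpectralConfig | None = None
) -> float:
    """Mean Lomb-Scargle PSD in the configured wavelength band.

    The signal is mean-centred (the periodogram should not respond to DC
    offset) and evaluated at ``n_freq`` frequencies evenly spaced in
    frequency between 1/24.5 and 1/23.5 cycles per hour.
    """
    config = config or SpectralConfig()
    t_h = np.asarray(t_h, float)
    signal = np.asarray(signal, float)
    if t_h.size < 2:
        return np.nan
    freqs = np.linspace(1.0 / config.band_h[1], 1.0 / config.band_h[0], config.n_freq)
    sig = signal - signal.mean()
    if np.all(sig == 0):
        return 0.0
    psd = lombscargle(t_h, sig, 2.0 * np.pi * freqs)
    return float(psd.mean())


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = np.std(v)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def diurnal_movement(
    t_h: np.ndarray, x: np.ndarray, y: np.ndarray, config: SpectralConfig | None = None
) -> tuple[float, float, float]:
    """DM, DMN and DMD for one (sub)week of unevenly available samples.

    ``t_h`` are sample times in hours, ``x``/``y`` km from home. DM sums the
    band power of the raw coordinates (sensitive to travel direction and
    scale); DMN standardizes each axis first; DMD uses the standardized
    Euclidean distance-from-home series, which is rotation invariant.
    """
    config = config or SpectralConfig()
    if len(t_h) < 2:
        return np.nan, np.nan, np.nan
    ex = lomb_band_power(t_h, x, config)
    ey = lomb_band_power(t_h, y, config)
    dm = float(np.log(max(ex + ey, LOG_FLOOR)))
    exn = lomb_band_power(t_h, _standardize(np.asarray(x, float)), config)
    eyn = lomb_band_power(t_h, _standardize(np.asarray(y, float)), config)
    dmn = float(np.log(max(exn + eyn, LOG_FLOOR)))
    dist = np.hypot(x, y)
    ed = lomb_band_power(t_h, _standardize(dist), config)
    dmd = float(np.log(max(ed, LOG_FLOOR)))
    return dm, dmn, dmd


@dataclasses.dataclass
class WeekData:
    """One calendar week of a home-recentred grid trace.

    Arrays span the full Monday-00:00-to-Sunday-24:00 local week (2016
    slots); samples outside the trace, or missing, are NaN.
    """

    participant_id: str
    iso_year: int
    iso_week: int
    week_start: pd.Timestamp  # local Monday 00:00
    x: np.ndarray
    y: np.ndarray
    transitioning: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.x)

    @property
    def day_index(self) -> np.ndarray:
        return np.arange(SLOTS_PER_WEEK) // SLOTS_PER_DAY

    @property
    def hours(self) -> np.ndarray:
        return np.arange(SLOTS_PER_WEEK) * (GRID_STEP_S / 3600.0)

    def sufficient(self, min_day_fraction: float = 0.5, min_days: int = 4) -> bool:
        """At least ``min_days`` days with >= ``min_day_fraction`` slots recorded."""
        per_day = self.valid.reshape(7, SLOTS_PER_DAY).mean(axis=1)
        return int((per_day >= min_day_fraction).sum()) >= min_days


def split_weeks(grid: GridTrace, mask: StationaryMask, tz: str = "UTC") -> list[WeekData]:
    """Cut a recentred grid trace into aligned calendar weeks."""
    if len(grid) == 0:
        return []
    local = grid.times.tz_convert(tz)
    week_start_first = (local[0] - pd.Timedelta(days=local[0].weekday())).floor("D")
    offsets = ((local.asi8 - week_start_first.value) / 1e9 / GRID_STEP_S).astype(int)
    week_idx = offsets // SLOTS_PER_WEEK
    slot_in_week = offsets % SLOTS_PER_WEEK
    weeks = []
    for w in np.unique(week_idx):
        sel = week_idx == w
        start = week_start_first + pd.Timedelta(days=7 * int(w))
        x = np.full(SLOTS_PER_WEEK, np.nan)
        y = np.full(SLOTS_PER_WEEK, np.nan)
        trans = np.zeros(SLOTS_PER_WEEK, dtype=bool)
        x[slot_in_week[sel]] = grid.x[sel]
        y[slot_in_week[sel]] = grid.y[sel]
        trans[slot_in_week[sel]] = mask.transitioning[sel]
        iso = start.isocalendar()
        weeks.append(
            WeekData(grid.participant_id, int(iso.year), int(iso.week), start, x, y, trans)
        )
    return weeks


def _stable_seed(*parts) -> int:
    return zlib.crc32("|".join(str(p) for p in parts).encode()) % (2**31 - 1)


def _features_for_days(
    week: WeekData,
    days: frozenset,
    spectral: SpectralConfig,
    l: float,
    seed: int,
) -> dict[str, float]:
    """All ten features on the union of the given calendar days."""
    in_days = np.isin(week.day_index, list(days))
    valid = in_days & week.valid
    nv = int(valid.sum())
    out = {f: np.nan for f in FEATURE_NAMES}
    if nv == 0:
        return out

    x, y = week.x, week.y
    out["LV"] = location_variance(x[valid], y[valid])
    # restrict path segments to the selected days
    sel_valid = valid.copy()
    out["TD"] = total_distance(
        np.where(sel_valid, x, np.nan), np.where(sel_valid, y, np.nan), sel_valid
    )

    trans = week.transitioning & valid
    stat = valid & ~week.transitioning
    out["TT"] = 100.0 * trans.sum() / nv

    if stat.any():
        pts = np.column_stack([x[stat], y[stat]])
        clusters = cluster_stationary(pts, l=l, seed=seed)
        counts = np.bincount(clusters.labels, minlength=clusters.k).astype(float)
        ent, nent = entropy(counts)
        out["ENT"], out["NENT"], out["NC"] = ent, nent, float(clusters.k)
        home = clusters.home_cluster()
        out["HS"] = 100.0 * (clusters.labels == home).sum() / nv if home is not None else 0.0
    else:
        out["HS"] = 0.0

    t_h = week.hours[valid]
    out["DM"], out["DMN"], out["DMD"] = diurnal_movement(t_h, x[valid], y[valid], spectral)
    return out


def max_home_distance_per_day(week: WeekData) -> np.ndarray:
    """d_i: the day's maximum Euclidean distance from home; NaN if unrecorded."""
    dist = np.hypot(week.x, week.y).reshape(7, SLOTS_PER_DAY)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN days
        return np.nanmax(dist, axis=1)


def excluded_days(week: WeekData, alpha: float) -> frozenset:
    """Days violating d_i > median(D) + alpha * SD(D); none below 2 recorded days."""
    d = max_home_distance_per_day(week)
    recorded = ~np.isnan(d)
    if recorded.sum() < 2:
        return frozenset()
    dd = d[recorded]
    threshold = np.median(dd) + alpha * np.std(dd, ddof=1)
    return frozenset(int(i) for i in np.flatnonzero(recorded & (d > threshold)))


def week_features(
    week: WeekData,
    alpha: float | Mapping[str, float] = 1.0,
    spectral: SpectralConfig | None = None,
    l: float = CLUSTER_SEPARATION_KM,
    seed: int = 0,
    alpha_grid: Sequence[float] | None = None,
):
    """The 50-value feature row for one week.

    ``alpha`` sets the daily-exclusion multiplier for the ``optimized``
    subset, either one value for all features or a per-feature mapping. When
    ``alpha_grid`` is given, a second dict maps every grid alpha to the ten
    exclusion-subset feature values (used for fold-confined alpha
    optimization).
    """
    spectral = spectral or SpectralConfig()
    cache: dict[frozenset, dict[str, float]] = {}

    def feats(days: frozenset) -> dict[str, float]:
        if days not in cache:
            cache[days] = _features_for_days(week, days, spectral, l, seed)
        return cache[days]

    all_days = frozenset(range(7))
    base = feats(all_days)
    weekday = feats(frozenset(range(5)))
    weekend = feats(frozenset({5, 6}))
    loo = [feats(all_days - {d}) for d in range(7)]
    constituents = [base, weekday, weekend, *loo]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN medians
        median = {
            f: float(np.nanmedian([c[f] for c in constituents])) for f in FEATURE_NAMES
        }

    def opt_for(a: float) -> dict[str, float]:
        return feats(all_days - excluded_days(week, a))

    if isinstance(alpha, Mapping):
        optimized = {f: opt_for(float(alpha[f]))[f] for f in FEATURE_NAMES}
    else:
        optimized = opt_for(float(alpha))

    row = {}
    for sname, sdict in zip(SUBSET_NAMES, (base, weekday, weekend, median, optimized)):
        for f in FEATURE_NAMES:
            row[f"{f}_{sname}"] = sdict[f]

    if alpha_grid is not None:
        grid_out = {float(a): opt_for(float(a)) for a in alpha_grid}
        return row, grid_out
    return row


def extract_feature_table(
    weeks: Sequence[WeekData],
    alpha: float | Mapping[str, float] = 1.0,
    spectral: SpectralConfig | None = None,
    l: float = CLUSTER_SEPARATION_KM,
    seed: int = 0,
    alpha_grid: Sequence[float] | None = None,
    min_day_fraction: float = 0.5,
    min_days: int = 4,
):
    """Feature table over sufficient weeks; insufficient weeks are dropped.

    Returns a DataFrame indexed by ``(participant, iso_year, iso_week)`` with
    the 50 ``<FEAT>_<subset>`` columns; with ``alpha_grid`` set, also a
    second DataFrame of exclusion-subset features per grid alpha (columns
    ``<FEAT>_opt@<alpha>``), row-aligned with the first.
    """
    rows, grid_rows, index, dropped = [], [], [], 0
    for week in weeks:
        if not week.sufficient(min_day_fraction, min_days):
            dropped += 1
            continue
        wseed = _stable_seed(seed, week.participant_id, week.iso_year, week.iso_week)
        if alpha_grid is not None:
            row, grid_out = week_features(week, alpha, spectral, l, wseed, alpha_grid)
            grid_rows.append(
                {
                    f"{f}_opt@{a:g}": grid_out[float(a)][f]
                    for a in alpha_grid
                    for f in FEATURE_NAMES
                }
            )
        else:
            row = week_features(week, alpha, spectral, l, wseed)
        rows.append(row)
        index.append((week.participant_id, week.iso_year, week.iso_week))

    idx = pd.MultiIndex.from_tuples(index, names=["participant", "iso_year", "iso_week"])
    table = pd.DataFrame(rows, index=idx, columns=list(FEATURE_COLUMNS))
    table.attrs["n_dropped_insufficient"] = dropped
    if alpha_grid is not None:
        grid_table = pd.DataFrame(grid_rows, index=idx)
        return table, grid_table
    return table


def optimize_alpha(
    feature_by_alpha: np.ndarray,
    labels: np.ndarray,
    grid: Sequence[float] = ALPHA_GRID,
    seed: int = 0,
    n_splits: int = 3,
) -> float:
    """Choose the exclusion multiplier maximizing single-feature accuracy.

    ``feature_by_alpha`` has one column per grid value (training weeks only:
    fold-confined optimization avoids test-label leakage). Each column is
    scored by stratified K-fold accuracy of a one-feature logistic-regression
    classifier; ties break to the smallest alpha. Degenerate labels fall back
    to the grid midpoint with a warning.
    """
    feature_by_alpha = np.asarray(feature_by_alpha, float)
    labels = np.asarray(labels).astype(int)
    grid = np.asarray(grid, float)
    if feature_by_alpha.shape[1] != len(grid):
        raise ValueError("one feature column per grid alpha required")
    if len(grid) == 1:
        return float(grid[0])
    if len(np.unique(labels)) < 2:
        warnings.warn("degenerate labels: returning alpha grid midpoint")
        return float(grid[len(grid) // 2])

    scores = np.full(len(grid), -np.inf)
    for j in range(len(grid)):
        col = feature_by_alpha[:, j]
        ok = ~np.isnan(col)
        Xj, yj = col[ok, None], labels[ok]
        if len(np.unique(yj)) < 2 or np.min(np.bincount(yj)) < n_splits:
            continue
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        accs = []
        for tr, te in skf.split(Xj, yj):
            clf = LogisticRegression().fit(Xj[tr], yj[tr])
            accs.append(np.mean(clf.predict(Xj[te]) == yj[te]))
        scores[j] = np.mean(accs)
    if np.all(~np.isfinite(scores)):
        warnings.warn("no alpha could be scored: returning alpha grid midpoint")
        return float(grid[len(grid) // 2])
    return float(grid[int(np.argmax(scores))])
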