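"""The ten mobility features, data subsets and alpha-based day exclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_week
from geomood.features import (
    ALPHA_GRID,
    FEATURE_COLUMNS,
    SLOTS_PER_DAY,
    SLOTS_PER_WEEK,
    SpectralConfig,
    diurnal_movement,
    entropy,
    excluded_days,
    lomb_band_power,
    location_variance,
    optimize_alpha,
    total_distance,
    week_features,
)


class TestEntropy:
    def test_single_cluster_certainty(self):
        assert entropy([1.0]) == (0.0, 0.0)

    def test_uniform_two_clusters(self):
        ent, nent = entropy([0.5, 0.5])
        assert ent == pytest.approx(np.log(2), abs=1e-12)
        assert nent == pytest.approx(1.0, abs=1e-12)

    def test_direct_summation_oracle(self):
        p = [0.5, 0.3, 0.2]
        expected = -sum(v * np.log(v) for v in p)  # ~1.0297
        ent, _ = entropy(p)
        assert ent == pytest.approx(expected, rel=1e-12)
        assert ent == pytest.approx(1.0297, abs=5e-5)

    def test_uniform_equals_log_n(self):
        for n in range(2, 21):
            ent, nent = entropy(np.full(n, 1.0 / n))
            assert ent == pytest.approx(np.log(n), abs=1e-12)
            assert nent == pytest.approx(1.0, abs=1e-12)

    @given(
        st.lists(st.floats(1e-9, 1.0), min_size=2, max_size=20),
    )
    @settings(max_examples=1000, deadline=None)
    def test_normalized_entropy_bounded(self, weights):
        _, nent = entropy(weights)
        assert 0.0 <= nent <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            entropy([])


class TestLocationVariance:
    def test_identical_samples_hit_floor(self):
        assert location_variance(np.zeros(10), np.zeros(10)) == pytest.approx(np.log(1e-10))

    def test_unit_total_variance_gives_zero(self):
        x = np.array([-1.0, 1.0])  # var 1 with ddof=0... var=1
        y = np.zeros(2)
        assert location_variance(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariant(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 2, 50), rng.normal(0, 2, 50)
        assert location_variance(x, y) == pytest.approx(location_variance(x + 7, y - 3))

    def test_single_sample_missing(self):
        assert np.isnan(location_variance(np.array([1.0]), np.array([1.0])))


class TestTotalDistance:
    def test_single_point_zero(self):
        valid = np.array([True])
        assert total_distance(np.array([1.0]), np.array([1.0]), valid) == 0.0

    def test_square_path(self):
        x = np.array([0, 1, 1, 0, 0], float)
        y = np.array([0, 0, 1, 1, 0], float)
        assert total_distance(x, y, np.ones(5, bool)) == pytest.approx(4.0)

    def test_duplicate_sample_no_change(self):
        x = np.array([0, 1, 1, 1, 0], float)
        y = np.array([0, 0, 0, 1, 1], float)
        assert total_distance(x, y, np.ones(5, bool)) == pytest.approx(3.0)

    def test_segment_over_missing_run_skipped(self):
        x = np.array([0, np.nan, 10.0])
        valid = ~np.isnan(x)
        assert total_distance(x, np.zeros(3), valid) == 0.0


def lomb_oracle(t, x, freqs_cyc):
    """Brute-force classical least-squares periodogram."""
    out = []
    for f in freqs_cyc:
        w = 2 * np.pi * f
        tau = np.arctan2(np.sum(np.sin(2 * w * t)), np.sum(np.cos(2 * w * t))) / (2 * w)
        c = np.cos(w * (t - tau))
        s = np.sin(w * (t - tau))
        out.append(0.5 * ((x @ c) ** 2 / (c @ c) + (x @ s) ** 2 / (s @ s)))
    return np.asarray(out)


class TestDiurnalMovement:
    def _uneven_times(self, n=90, span_h=96.0, seed=0):
        rng = np.random.default_rng(seed)
        return np.sort(rng.uniform(0, span_h, n))

    def test_band_power_matches_bruteforce(self):
        t = self._uneven_times()
        rng = np.random.default_rng(1)
        x = np.sin(2 * np.pi * t / 24.0) + 0.3 * rng.normal(size=len(t))
        cfg = SpectralConfig()
        freqs = np.linspace(1 / 24.5, 1 / 23.5, cfg.n_freq)
        expected = lomb_oracle(t, x - x.mean(), freqs).mean()
        assert lomb_band_power(t, x, cfg) == pytest.approx(expected, rel=1e-9)

    def test_24h_rhythm_beats_12h_rhythm(self):
        t = self._uneven_times()
        sig24 = np.sin(2 * np.pi * t / 24.0)
        sig12 = np.sin(2 * np.pi * t / 12.0)
        x = np.zeros(len(t))
        _, _, dmd24 = diurnal_movement(t, sig24 + 5.0, x + 0.0)
        _, _, dmd12 = diurnal_movement(t, sig12 + 5.0, x + 0.0)
        assert dmd24 > dmd12

    def test_dmd_rotation_invariant_dmn_not(self):
        """Travel direction must not move the distance-from-home feature, but
        it does move the per-axis-normalized one: a due-east commute and the
        same commute rotated 45 degrees split their power across axes
        differently once each axis is scaled to unit variance (the axis sum
        of raw powers, DM, is a rotation-invariant quadratic form)."""
        t = self._uneven_times()
        r = 2.0 + np.sin(2 * np.pi * t / 24.0)
        x, y = r, np.zeros(len(t))  # travel due east of home
        theta = np.deg2rad(45.0)
        xr = x * np.cos(theta) - y * np.sin(theta)
        yr = x * np.sin(theta) + y * np.cos(theta)
        dm1, dmn1, dmd1 = diurnal_movement(t, x, y)
        dm2, dmn2, dmd2 = diurnal_movement(t, xr, yr)
        assert dmd2 == pytest.approx(dmd1, rel=1e-9)
        assert abs(dmn2 - dmn1) == pytest.approx(np.log(2), rel=1e-6)
        assert dm2 == pytest.approx(dm1, rel=1e-9)  # regression: invariant sum

    def test_scaling_shifts_dm_only(self):
        t = self._uneven_times()
        x = 2.0 + np.sin(2 * np.pi * t / 24.0)
        y = 1.0 + 0.5 * np.cos(2 * np.pi * t / 24.0)
        dm1, dmn1, dmd1 = diurnal_movement(t, x, y)
        dm2, dmn2, dmd2 = diurnal_movement(t, 10 * x, 10 * y)
        assert dmn2 == pytest.approx(dmn1, rel=1e-9)
        assert dmd2 == pytest.approx(dmd1, rel=1e-9)
        assert dm2 == pytest.approx(dm1 + np.log(100), rel=1e-6)

    def test_constant_signal_floors(self):
        t = self._uneven_times()
        dm, dmn, dmd = diurnal_movement(t, np.full(len(t), 3.0), np.full(len(t), 1.0))
        assert dm == pytest.approx(np.log(1e-10))


def _home_and_place_week(away_slots_per_day=96, place=(2.0, 0.0)):
    """Week at home except ``away_slots_per_day`` midday slots at ``place``."""
    day = np.zeros((SLOTS_PER_DAY, 2))
    lo = SLOTS_PER_DAY // 2 - away_slots_per_day // 2
    day[lo : lo + away_slots_per_day] = place
    week = np.tile(day, (7, 1))
    return make_week(week[:, 0], week[:, 1])


class TestWeekFeatures:
    def test_week_entirely_at_home(self):
        week = make_week(np.zeros(SLOTS_PER_WEEK), np.zeros(SLOTS_PER_WEEK))
        row = week_features(week)
        assert row["HS_base"] == pytest.approx(100.0)
        assert row["TT_base"] == pytest.approx(0.0)
        assert row["NC_base"] == 1.0
        assert row["ENT_base"] == pytest.approx(0.0)

    def test_home_stay_fraction_counts_slots(self):
        # 18 of 24 h at home each day -> HS = 75%
        week = _home_and_place_week(away_slots_per_day=SLOTS_PER_DAY // 4)
        row = week_features(week)
        assert row["HS_base"] == pytest.approx(75.0)
        assert row["NC_base"] == 2.0

    def test_week_away_from_home_has_zero_hs(self):
        week = make_week(np.full(SLOTS_PER_WEEK, 5.0), np.zeros(SLOTS_PER_WEEK))
        row = week_features(week)
        assert row["HS_base"] == 0.0

    def test_occupancy_partition_sums_to_100(self):
        rng = np.random.default_rng(0)
        x = np.where(rng.random(SLOTS_PER_WEEK) < 0.6, 0.0, 3.0)
        trans = rng.random(SLOTS_PER_WEEK) < 0.1
        week = make_week(x, np.zeros(SLOTS_PER_WEEK), transitioning=trans)
        row = week_features(week)
        valid = week.valid
        stat = valid & ~week.transitioning
        # share of stationary time not in the home cluster
        from geomood.places import cluster_stationary

        pts = np.column_stack([week.x[stat], week.y[stat]])
        clusters = cluster_stationary(pts, seed=0)
        home = clusters.home_cluster()
        non_home = 100.0 * (clusters.labels != home).sum() / valid.sum()
        assert row["HS_base"] + non_home + row["TT_base"] == pytest.approx(100.0, abs=1e-9)

    def test_empty_weekend_yields_missing_weekend_columns(self):
        x = np.zeros(SLOTS_PER_WEEK)
        x[5 * SLOTS_PER_DAY :] = np.nan
        week = make_week(x, x.copy())
        row = week_features(week)
        assert np.isnan(row["HS_weekend"])
        assert not np.isnan(row["HS_weekday"])

    def test_median_subset_of_identical_days(self):
        week = _home_and_place_week()
        row = week_features(week)
        # intensive features are identical on every constituent subset
        for f in ("HS", "TT", "NC", "ENT", "LV"):
            assert row[f"{f}_median"] == pytest.approx(row[f"{f}_base"], rel=1e-9)
        # TD scales with the number of days kept: oracle = direct median over
        # the ten constituents {base, weekday, weekend, 7 leave-one-day-out}
        per_day = row["TD_base"] / 7
        constituents = [7, 5, 2] + [6] * 7
        expected = np.median([n * per_day for n in constituents])
        assert row["TD_median"] == pytest.approx(expected, rel=1e-9)

    def test_feature_row_has_50_deterministic_values(self):
        week = _home_and_place_week()
        r1 = week_features(week, seed=5)
        r2 = week_features(week, seed=5)
        assert set(r1) == set(FEATURE_COLUMNS)
        assert len(r1) == 50
        for k in r1:
            assert (np.isnan(r1[k]) and np.isnan(r2[k])) or r1[k] == r2[k]


class TestDailyExclusion:
    def _week_with_day_distances(self, dists):
        day = np.zeros((SLOTS_PER_DAY, 2))
        week = np.tile(day, (7, 1))
        x = week[:, 0].copy()
        for i, d in enumerate(dists):
            x[i * SLOTS_PER_DAY + 144] = d  # one midday sample at distance d
        return make_week(x, np.zeros(SLOTS_PER_WEEK))

    def test_worked_example(self):
        # D = {1,1,1,1,1,1,20}, alpha = 1: median 1, sd ~7.18, threshold ~8.18
        week = self._week_with_day_distances([1, 1, 1, 1, 1, 1, 20])
        d = [1, 1, 1, 1, 1, 1, 20]
        assert np.std(d, ddof=1) == pytest.approx(7.1813, abs=1e-4)
        assert excluded_days(week, 1.0) == frozenset({6})

    def test_equal_days_never_excluded(self):
        week = self._week_with_day_distances([2] * 7)
        for a in (0.0, 0.5, 2.0):
            assert excluded_days(week, a) == frozenset()

    def test_huge_alpha_recovers_base(self):
        week = self._week_with_day_distances([1, 2, 3, 4, 5, 6, 40])
        assert excluded_days(week, 1e9) == frozenset()
        row = week_features(week, alpha=1e9)
        assert row["TD_optimized"] == pytest.approx(row["TD_base"])


class TestOptimizeAlpha:
    def test_uninformative_feature_ties_to_smallest_alpha(self):
        rng = np.random.default_rng(0)
        fba = np.tile(rng.normal(0, 1, (40, 1)), (1, len(ALPHA_GRID)))
        labels = np.arange(40) % 2
        assert optimize_alpha(fba, labels, ALPHA_GRID, seed=0) == ALPHA_GRID[0]

    def test_single_value_grid(self):
        fba = np.zeros((10, 1))
        assert optimize_alpha(fba, np.arange(10) % 2, [0.75]) == 0.75

    def test_degenerate_labels_fall_back_to_midpoint(self):
        fba = np.zeros((10, len(ALPHA_GRID)))
        with pytest.warns(UserWarning):
            a = optimize_alpha(fba, np.zeros(10), ALPHA_GRID)
        assert a == ALPHA_GRID[len(ALPHA_GRID) // 2]

    def test_outlier_corruption_prefers_excluding_alpha(self):
        # feature separates classes only once the corrupt column is avoided:
        # small alphas exclude the outlier day -> informative; large alphas
        # keep it -> noise. The chosen alpha must sit below the cutover.
        rng = np.random.default_rng(1)
        n = 60
        labels = (np.arange(n) % 2).astype(int)
        informative = np.where(labels == 1, 2.0, -2.0) + rng.normal(0, 0.3, n)
        noise = rng.normal(0, 1, n)
        cut = 6  # alphas below index 6 exclude the corrupt day
        fba = np.empty((n, len(ALPHA_GRID)))
        for j in range(len(ALPHA_GRID)):
            fba[:, j] = informative if j < cut else noise
        chosen = optimize_alpha(fba, labels, ALPHA_GRID, seed=0)
        assert chosen < ALPHA_GRID[cut]


class TestAlphaGridExtraction:
    def test_per_feature_alpha_mapping(self):
        week = TestDailyExclusion()._week_with_day_distances([1, 1, 1, 1, 1, 1, 20])
        alpha = {f: (0.5 if f == "TD" else 1e9) for f in
                 ("ENT", "NENT", "LV", "HS", "TT", "TD", "NC", "DM", "DMN", "DMD")}
        row = week_features(week, alpha=alpha)
        # TD excludes the outlier day; the others keep the full week
        assert row["LV_optimized"] == pytest.approx(row["LV_base"])
        assert row["TD_optimized"] < row["TD_base"] or np.isnan(row["TD_base"])

    def test_alpha_grid_table_shape(self):
        week = TestDailyExclusion()._week_with_day_distances([1, 2, 1, 2, 1, 2, 30])
        from geomood.features import extract_feature_table

        table, grid = extract_feature_table([week], alpha_grid=[0.0, 1.0, 2.0])
        assert table.shape == (1, 50)
        assert grid.shape == (1, 30)
        assert "TD_opt@1" in grid.columns
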