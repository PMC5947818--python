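"""Shared fixtures: small hand-built traces and the seeded default cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from geomood.features import SLOTS_PER_DAY, SLOTS_PER_WEEK, WeekData
from geomood.io import Trace
from geomood.pipeline import PipelineParams, extract_cohort, labeled_arrays
from geomood.synthetic import SyntheticConfig, generate_cohort

COHORT_SEED = 1


def make_trace(seconds, x, y, pid="t", start="2025-01-06 00:00:00") -> Trace:
    """Trace from offsets in seconds relative to a Monday-midnight start."""
    t0 = pd.Timestamp(start, tz="UTC")
    times = t0 + pd.to_timedelta(np.asarray(seconds, float), unit="s")
    return Trace(pid, times, np.asarray(x, float), np.asarray(y, float))


def make_week(x, y, transitioning=None, pid="w") -> WeekData:
    """WeekData directly from per-slot arrays (NaN = missing)."""
    x = np.asarray(x, float)
    assert len(x) == SLOTS_PER_WEEK
    y = np.asarray(y, float)
    if transitioning is None:
        transitioning = np.zeros(SLOTS_PER_WEEK, dtype=bool)
    start = pd.Timestamp("2025-01-06 00:00:00", tz="UTC")
    iso = start.isocalendar()
    return WeekData(pid, int(iso.year), int(iso.week), start, x, y, np.asarray(transitioning, bool))


def full_week_at(points_per_day) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) arrays for a week where every day repeats the given per-slot
    day pattern (a list of (x, y) of length SLOTS_PER_DAY)."""
    day = np.asarray(points_per_day, float)
    assert day.shape == (SLOTS_PER_DAY, 2)
    week = np.tile(day, (7, 1))
    return week[:, 0], week[:, 1]


@pytest.fixture(scope="session")
def default_cohort():
    """The default strong-effect synthetic cohort (20 participants x 10 weeks)."""
    return generate_cohort(SyntheticConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    """Feature table and labels for the default cohort (one shared run)."""
    traces = {pid: rec.trace for pid, rec in default_cohort.participants.items()}
    qids = {pid: rec.qids for pid, rec in default_cohort.participants.items()}
    table, labels = extract_cohort(traces, qids, PipelineParams(seed=COHORT_SEED))
    return table, labels


@pytest.fixture(scope="session")
def cohort_xy(cohort_features):
    """Model-ready arrays over the default five-feature set."""
    table, labels = cohort_features
    cols = ["HS_base", "NC_base", "ENT_base", "TT_base", "DMD_base"]
    X, y, groups = labeled_arrays(table, labels, cols)
    return X, y, groups
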