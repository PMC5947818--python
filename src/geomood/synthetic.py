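"""Seeded synthetic cohorts of location traces and weekly QIDS responses.

No raw geolocation/mood dataset of this kind is publicly deposited, so the
package ships a generator that emulates the statistical structure the
analysis assumes:

* each participant has a home (at the local origin) and a pool of recurrent
  places within a 10 km disc;
* weekly mood follows a two-state Markov chain; depressed weeks (QIDS >= 11)
  raise the probability of staying home, shrink the set of visited places
  and widen departure-time jitter — the behavioral directions that make
  home-stay, place-count and routine-regularity features informative;
* days follow a diurnal routine: home overnight (00:00-07:00), up to three
  excursions in morning/afternoon/evening blocks, straight-line travel at a
  constant speed;
* fixes are emitted at uneven ~2 min intervals with small coordinate noise;
  artifact bursts insert short runs of one identical coordinate displaced
  ~10 km off-path at a 10 s spacing, and gaps delete contiguous stretches;
* one QIDS response is emitted inside every week, so week labeling recovers
  the true mood state exactly.

A ground-truth ledger (true scores, states, per-week home-stay fraction and
place counts, injected-fix masks, gap intervals) gives every pipeline stage
an oracle. The effect sizes are the package's own choices — the kind of
strong, clearly-directional contrast a validation cohort is built to show —
and are documented as such.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import QidsResponse, Trace

COHORT_START = pd.Timestamp("2025-01-06 00:00:00", tz="UTC")  # a Monday

BLOCKS_H = ((8.0, 12.0), (13.0, 17.0), (18.0, 21.0))  # local excursion windows


@dataclasses.dataclass
class MoodProcess:
    baseline_qids_mean: float = 5.0
    depressed_qids_mean: float = 16.0
    qids_sd: float = 2.0
    depressed_week_fraction: float = 0.3
    persistence: float = 0.6  # P(depressed -> depressed)


@dataclasses.dataclass
class BehaviorEffects:
    home_stay_well: float = 0.55
    home_stay_depressed: float = 0.9
    places_per_week_well: int = 4
    places_per_week_depressed: int = 1
    departure_jitter_well_h: float = 0.5
    departure_jitter_depressed_h: float = 1.5
    participant_sd: float = 0.06  # random effect on the home-stay probabilities


@dataclasses.dataclass
class Sampling:
    mean_interval_s: float = 120.0
    jitter_s: float = 30.0
    noise_km: float = 0.002


@dataclasses.dataclass
class Artifacts:
    burst_rate_per_day: float = 2.0
    burst_len: int = 5
    burst_offset_km: float = 10.0
    burst_spacing_s: float = 10.0


@dataclasses.dataclass
class Gaps:
    rate_per_week: float = 1.0
    min_h: float = 1.0
    max_h: float = 8.0


@dataclasses.dataclass
class SyntheticConfig:
    n_participants: int = 20
    weeks_per_participant: int = 10
    places_per_participant: int = 6
    mood: MoodProcess = dataclasses.field(default_factory=MoodProcess)
    behavior: BehaviorEffects = dataclasses.field(default_factory=BehaviorEffects)
    sampling: Sampling = dataclasses.field(default_factory=Sampling)
    artifacts: Artifacts = dataclasses.field(default_factory=Artifacts)
    gaps: Gaps = dataclasses.field(default_factory=Gaps)
    travel_speed_kmh: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.weeks_per_participant <= 0:
            raise ValueError("participant and week counts must be positive")
        if self.places_per_participant <= 0:
            raise ValueError("places_per_participant must be positive")
        m, b = self.mood, self.behavior
        if not 0 <= m.depressed_week_fraction <= 1:
            raise ValueError("depressed_week_fraction must be in [0, 1]")
        if not (m.depressed_qids_mean >= 11 > m.baseline_qids_mean):
            raise ValueError("depressed mean must be >= 11 and baseline mean < 11")
        for frac in (b.home_stay_well, b.home_stay_depressed):
            if not 0 <= frac <= 1:
                raise ValueError("home-stay fractions must be in [0, 1]")
        for rate in (self.artifacts.burst_rate_per_day, self.gaps.rate_per_week):
            if rate < 0:
                raise ValueError("rates must be nonnegative")


@dataclasses.dataclass
class ParticipantRecord:
    trace: Trace  # emitted trace: true fixes + artifact bursts, after gaps
    qids: list[QidsResponse]
    injected: np.ndarray  # bool per trace fix: True for artifact-burst fixes
    gap_intervals: list[tuple[pd.Timestamp, pd.Timestamp]]
    places: np.ndarray  # (n_places, 2) km; home is (0, 0)

    @property
    def clean_trace(self) -> Trace:
        return self.trace.subset(~self.injected)


@dataclasses.dataclass
class Cohort:
    participants: dict[str, ParticipantRecord]
    truth: pd.DataFrame  # per participant-week ground truth
    config: SyntheticConfig


def _mood_chain(n_weeks: int, mood: MoodProcess, rng: np.random.Generator) -> np.ndarray:
    frac = mood.depressed_week_fraction
    if frac == 0:
        return np.zeros(n_weeks, dtype=bool)
    if frac == 1:
        return np.ones(n_weeks, dtype=bool)
    p_dd = mood.persistence
    p_wd = min(frac * (1 - p_dd) / (1 - frac), 1.0)
    states = np.zeros(n_weeks, dtype=bool)
    states[0] = rng.random() < frac
    for w in range(1, n_weeks):
        p = p_dd if states[w - 1] else p_wd
        states[w] = rng.random() < p
    return states


def _sample_places(n: int, rng: np.random.Generator) -> np.ndarray:
    """Places uniform in a 1.5-10 km annulus around home, mutually >= 1 km apart."""
    places: list[np.ndarray] = []
    while len(places) < n:
        r = rng.uniform(1.5, 10.0)
        theta = rng.uniform(0, 2 * np.pi)
        p = np.array([r * np.cos(theta), r * np.sin(theta)])
        if all(np.hypot(*(p - q)) >= 1.0 for q in places):
            places.append(p)
    return np.asarray(places)


def _day_schedule(
    day_h: float,
    active_places: np.ndarray,
    home_stay_p: float,
    jitter_h: float,
    speed_kmh: float,
    rng: np.random.Generator,
):
    """Knots (t_h, x, y) for one day, plus the time spent away from home.

    The participant is home overnight; each of the three daytime blocks is
    either spent at home or as a home-to-place-and-back excursion with a
    jittered departure time.
    """
    knots: list[tuple[float, float, float]] = []
    away_h = 0.0
    cursor = day_h + 7.0  # guaranteed home until 07:00
    for b0, b1 in BLOCKS_H:
        if rng.random() >= 1.0 - home_stay_p:
            continue
        place = active_places[rng.integers(len(active_places))]
        travel = np.hypot(place[0], place[1]) / speed_kmh
        dep = day_h + b0 + rng.normal(0.0, jitter_h)
        dep = float(np.clip(dep, cursor + 0.1, day_h + b1 - 2 * travel - 0.5))
        if dep <= cursor:
            continue
        leave = float(np.clip(day_h + b1 - travel, dep + travel + 0.25, day_h + 21.5))
        back = leave + travel
        knots += [
            (dep, 0.0, 0.0),
            (dep + travel, place[0], place[1]),
            (leave, place[0], place[1]),
            (back, 0.0, 0.0),
        ]
        away_h += back - dep
        cursor = back
    return knots, away_h


def _generate_participant(
    pid: str, config: SyntheticConfig, rng: np.random.Generator
):
    n_weeks = config.weeks_per_participant
    b = config.behavior
    places = _sample_places(config.places_per_participant, rng)

    hs_well = float(np.clip(rng.normal(b.home_stay_well, b.participant_sd), 0.05, 0.85))
    hs_dep = float(
        np.clip(rng.normal(b.home_stay_depressed, b.participant_sd), hs_well + 0.05, 0.98)
    )
    extra_places = int(rng.integers(-1, 2))  # participant-level habit variation

    states = _mood_chain(n_weeks, config.mood, rng)

    knots: list[tuple[float, float, float]] = [(0.0, 0.0, 0.0)]
    truth_rows = []
    qids: list[QidsResponse] = []
    for w in range(n_weeks):
        depressed = bool(states[w])
        if depressed:
            hs_p, jitter = hs_dep, b.departure_jitter_depressed_h
            n_active = max(b.places_per_week_depressed, 1)
        else:
            hs_p, jitter = hs_well, b.departure_jitter_well_h
            n_active = max(b.places_per_week_well + extra_places, 2)
        n_active = min(n_active, len(places))
        active = places[rng.choice(len(places), n_active, replace=False)]

        away_week_h = 0.0
        for d in range(7):
            day_h = (w * 7 + d) * 24.0
            day_knots, away_h = _day_schedule(
                day_h, active, hs_p, jitter, config.travel_speed_kmh, rng
            )
            knots += day_knots
            away_week_h += away_h

        if depressed:
            score = int(round(np.clip(rng.normal(config.mood.depressed_qids_mean,
                                                 config.mood.qids_sd), 11, 27)))
        else:
            score = int(round(np.clip(rng.normal(config.mood.baseline_qids_mean,
                                                 config.mood.qids_sd), 0, 10)))
        t_resp = COHORT_START + pd.Timedelta(days=w * 7 + rng.uniform(2.0, 6.5))
        qids.append(QidsResponse(t_resp, score))

        week_start = COHORT_START + pd.Timedelta(days=7 * w)
        iso = week_start.isocalendar()
        truth_rows.append(
            {
                "participant": pid,
                "iso_year": int(iso.year),
                "iso_week": int(iso.week),
                "qids": score,
                "depressed": depressed,
                "home_stay_frac": 1.0 - away_week_h / (7 * 24.0),
                "n_places_active": int(n_active),
            }
        )

    span_h = n_weeks * 7 * 24.0
    knots.append((span_h, 0.0, 0.0))
    kt = np.array([k[0] for k in knots])
    kx = np.array([k[1] for k in knots])
    ky = np.array([k[2] for k in knots])
    order = np.argsort(kt, kind="stable")
    kt, kx, ky = kt[order], kx[order], ky[order]

    s = config.sampling
    n_est = int(span_h * 3600 / s.mean_interval_s * 1.2) + 10
    intervals = np.clip(rng.normal(s.mean_interval_s, s.jitter_s, n_est), 10.0, None)
    t_s = np.cumsum(intervals)
    t_s = t_s[t_s < span_h * 3600 - 1]
    x = np.interp(t_s / 3600.0, kt, kx) + rng.normal(0, s.noise_km, len(t_s))
    y = np.interp(t_s / 3600.0, kt, ky) + rng.normal(0, s.noise_km, len(t_s))
    t_ms = (t_s * 1000).astype(np.int64)  # intervals >= 10 s, so strictly increasing
    times = COHORT_START + pd.to_timedelta(t_ms, unit="ms")
    trace = Trace(pid, times, x, y)

    truth = pd.DataFrame(truth_rows)
    return trace, qids, places, truth


def inject_artifacts(
    trace: Trace, config: SyntheticConfig, rng: np.random.Generator | None = None
):
    """Insert same-coordinate artifact bursts into a clean trace.

    Each burst places ``burst_len`` fixes at one identical coordinate
    displaced at least ``burst_offset_km`` from the concurrent true path, at
    ``burst_spacing_s`` spacing (well above the base sample rate). Returns
    the augmented trace and a boolean mask marking injected fixes.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    a = config.artifacts
    n = len(trace)
    if n < 2 or a.burst_rate_per_day <= 0:
        return trace, np.zeros(n, dtype=bool)
    t0 = trace.times.asi8 / 1e9
    span_s = t0[-1] - t0[0]
    n_bursts = rng.poisson(a.burst_rate_per_day * span_s / 86400.0)

    # keep bursts well separated so they never sandwich a true fix together
    burst_len_s = a.burst_len * a.burst_spacing_s
    starts: list[float] = []
    for _ in range(n_bursts):
        for _attempt in range(50):
            c = rng.uniform(t0[0] + 60, t0[-1] - 60 - burst_len_s)
            if all(abs(c - o) > burst_len_s + 600 for o in starts):
                starts.append(c)
                break

    new_t, new_x, new_y = [], [], []
    for c in starts:
        px = np.interp(c, t0, trace.x)
        py = np.interp(c, t0, trace.y)
        theta = rng.uniform(0, 2 * np.pi)
        r = a.burst_offset_km * (1.0 + rng.uniform(0.0, 0.5))
        bx, by = px + r * np.cos(theta), py + r * np.sin(theta)
        for i in range(a.burst_len):
            new_t.append(c + i * a.burst_spacing_s)
            new_x.append(bx)
            new_y.append(by)

    if not new_t:
        return trace, np.zeros(n, dtype=bool)
    t_ms = np.concatenate([(t0 * 1000).round().astype(np.int64),
                           (np.asarray(new_t) * 1000).round().astype(np.int64)])
    x = np.concatenate([trace.x, new_x])
    y = np.concatenate([trace.y, new_y])
    injected = np.concatenate([np.zeros(n, bool), np.ones(len(new_t), bool)])
    # resolve exact timestamp collisions deterministically
    order = np.lexsort((injected, t_ms))
    t_ms, x, y, injected = t_ms[order], x[order], y[order], injected[order]
    while len(np.unique(t_ms)) != len(t_ms):
        dup = np.concatenate([[False], np.diff(t_ms) == 0])
        t_ms[dup] += 1
        order = np.argsort(t_ms, kind="stable")
        t_ms, x, y, injected = t_ms[order], x[order], y[order], injected[order]
    epoch_ms = pd.Timestamp("1970-01-01", tz="UTC")
    times = epoch_ms + pd.to_timedelta(t_ms, unit="ms")
    return Trace(trace.participant_id, times, x, y), injected


def _apply_gaps(trace: Trace, injected: np.ndarray, config: SyntheticConfig,
                rng: np.random.Generator):
    g = config.gaps
    if g.rate_per_week <= 0 or len(trace) == 0:
        return trace, injected, []
    t0 = trace.times.asi8 / 1e9
    span_w = (t0[-1] - t0[0]) / (7 * 86400.0)
    n_gaps = rng.poisson(g.rate_per_week * span_w)
    keep = np.ones(len(trace), dtype=bool)
    intervals = []
    for _ in range(n_gaps):
        start = rng.uniform(t0[0], t0[-1])
        length = rng.uniform(g.min_h, g.max_h) * 3600.0
        keep &= ~((t0 >= start) & (t0 < start + length))
        s = pd.Timestamp(start, unit="s", tz="UTC")
        intervals.append((s, s + pd.Timedelta(seconds=length)))
    return trace.subset(keep), injected[keep], intervals


def generate_cohort(config: SyntheticConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    participants: dict[str, ParticipantRecord] = {}
    truth_frames = []
    for i in range(config.n_participants):
        pid = f"p{i:02d}"
        trace, qids, places, truth = _generate_participant(pid, config, rng)
        trace, injected = inject_artifacts(trace, config, rng)
        trace, injected, gap_intervals = _apply_gaps(trace, injected, config, rng)
        participants[pid] = ParticipantRecord(trace, qids, injected, gap_intervals, places)
        truth_frames.append(truth)
    truth = pd.concat(truth_frames, ignore_index=True).set_index(
        ["participant", "iso_year", "iso_week"]
    )
    return Cohort(participants, truth, config)
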