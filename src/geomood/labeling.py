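"""Weekly QIDS labels and the moderate-depression dichotomy.

Each calendar week receives a QIDS-SR16 score from the surrounding
questionnaire responses: a single response within 3.5 days of the week is
used directly; otherwise two or more responses within 7 days are linearly
interpolated and averaged over the week's seven day-midpoints. A week is
*depressed* when its score reaches 11, the accepted clinical threshold for
moderate depression.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import QidsResponse

QIDS_DEPRESSION_THRESHOLD = 11.0
NARROW_WINDOW_D = 3.5
WIDE_WINDOW_D = 7.0


@dataclasses.dataclass
class WeekLabel:
    participant_id: str
    iso_year: int
    iso_week: int
    score: float | None
    depressed: bool | None
    provenance: str  # "single-response" | "interpolated" | "unlabeled"


def binarize(score: float) -> bool:
    """True iff the score meets the moderate-depression threshold (>= 11)."""
    return bool(score >= QIDS_DEPRESSION_THRESHOLD)


def label_week(
    responses: Sequence[QidsResponse],
    week_start: pd.Timestamp,
    participant_id: str = "",
) -> WeekLabel:
    """Label the week starting at ``week_start`` (a local Monday 00:00).

    Exactly one response within +-3.5 d of the week is used as-is; with two
    or more responses within +-7 d, the piecewise-linear interpolant between
    responses (held constant beyond the first/last response) is evaluated at
    the seven local-noon day midpoints and averaged. Otherwise the week is
    unlabeled.
    """
    iso = week_start.isocalendar()
    week_end = week_start + pd.Timedelta(days=7)
    t = np.array([r.t.value for r in responses], dtype=float) / 1e9
    scores = np.array([r.score for r in responses], dtype=float)
    order = np.argsort(t, kind="stable")
    t, scores = t[order], scores[order]

    start_s = week_start.value / 1e9
    end_s = week_end.value / 1e9
    day_s = 86400.0
    in_narrow = (t >= start_s - NARROW_WINDOW_D * day_s) & (t <= end_s + NARROW_WINDOW_D * day_s)
    in_wide = (t >= start_s - WIDE_WINDOW_D * day_s) & (t <= end_s + WIDE_WINDOW_D * day_s)

    if in_narrow.sum() == 1:
        score = float(scores[in_narrow][0])
        provenance = "single-response"
    elif in_wide.sum() >= 2:
        tw, sw = t[in_wide], scores[in_wide]
        midpoints = start_s + (np.arange(7) + 0.5) * day_s
        score = float(np.mean(np.interp(midpoints, tw, sw)))
        provenance = "interpolated"
    else:
        return WeekLabel(participant_id, int(iso.year), int(iso.week), None, None, "unlabeled")
    return WeekLabel(
        participant_id, int(iso.year), int(iso.week), score, binarize(score), provenance
    )


def label_weeks(
    responses: Sequence[QidsResponse],
    week_starts: Sequence[pd.Timestamp],
    participant_id: str = "",
) -> pd.DataFrame:
    """Label many weeks; returns a DataFrame indexed like the feature table."""
    labels = [label_week(responses, ws, participant_id) for ws in week_starts]
    idx = pd.MultiIndex.from_tuples(
        [(l.participant_id, l.iso_year, l.iso_week) for l in labels],
        names=["participant", "iso_year", "iso_week"],
    )
    return pd.DataFrame(
        {
            "score": [l.score for l in labels],
            "depressed": [l.depressed for l in labels],
            "provenance": [l.provenance for l in labels],
        },
        index=idx,
    )
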