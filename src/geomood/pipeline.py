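"""End-to-end orchestration: traces -> cleaned grids -> weekly features -> labels.

`analyze_trace` runs one participant through cleaning, home inference,
segmentation and week splitting; `extract_cohort` assembles the labeled
50-column feature table for a whole cohort. `run_pipeline` drives the staged
file-based workflow used by the command-line interface, skipping stages
whose outputs are newer than their inputs and recording per-stage counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import features as feats
from .io import QidsResponse, Trace, read_qids_csv, read_trace_csv, write_qids_csv, write_trace_csv
from .labeling import label_weeks
from .places import (
    CLUSTER_SEPARATION_KM,
    SPEED_THRESHOLD_KMH,
    infer_home,
    segment_stationary,
)
from .preprocess import PreprocessParams, preprocess
from .synthetic import Cohort, SyntheticConfig, generate_cohort

log = logging.getLogger("geomood")


@dataclasses.dataclass
class PipelineParams:
    """All stage parameters of the analysis pipeline, with the reference
    defaults (100 km/h speed filter, 12 samples/h, 1.5 km/h stationarity
    threshold, 0.4 km cluster separation, QIDS >= 11 dichotomy)."""

    preprocess: PreprocessParams = dataclasses.field(default_factory=PreprocessParams)
    speed_threshold_kmh: float = SPEED_THRESHOLD_KMH
    cluster_separation_km: float = CLUSTER_SEPARATION_KM
    spectral: feats.SpectralConfig = dataclasses.field(default_factory=feats.SpectralConfig)
    alpha: float | Mapping[str, float] = 1.0
    min_day_fraction: float = 0.5
    min_days: int = 4
    tz: str = "UTC"
    seed: int = 0


def analyze_trace(trace: Trace, params: PipelineParams | None = None):
    """Clean one trace and return its home-recentred weekly data.

    Returns ``(weeks, home, grid, mask)``: the list of
    :class:`~geomood.features.WeekData`, the inferred home coordinate, the
    recentred grid trace and its stationarity mask.
    """
    params = params or PipelineParams()
    grid = preprocess(trace, params.preprocess)
    home, recentered = infer_home(grid, params.tz)
    mask = segment_stationary(recentered, params.speed_threshold_kmh)
    weeks = feats.split_weeks(recentered, mask, params.tz)
    return weeks, home, recentered, mask


def extract_cohort(
    traces: Mapping[str, Trace],
    qids: Mapping[str, Sequence[QidsResponse]] | None = None,
    params: PipelineParams | None = None,
    alpha_grid: Sequence[float] | None = None,
):
    """Feature table (and labels) for a cohort of traces.

    Returns ``(table, labels)`` where ``labels`` is None when no QIDS series
    are given; with ``alpha_grid`` set, returns ``(table, grid_table,
    labels)``.
    """
    params = params or PipelineParams()
    all_weeks = []
    week_starts: dict[str, list[pd.Timestamp]] = {}
    for pid, trace in traces.items():
        if trace.participant_id != pid:  # the mapping key is authoritative
            trace = dataclasses.replace(trace, participant_id=pid)
        weeks, _, _, _ = analyze_trace(trace, params)
        all_weeks.extend(weeks)
        week_starts[pid] = [w.week_start for w in weeks]
        log.info("%s: %d weeks", pid, len(weeks))

    result = feats.extract_feature_table(
        all_weeks,
        alpha=params.alpha,
        spectral=params.spectral,
        seed=params.seed,
        alpha_grid=alpha_grid,
        min_day_fraction=params.min_day_fraction,
        min_days=params.min_days,
    )
    table = result[0] if alpha_grid is not None else result

    labels = None
    if qids is not None:
        frames = [
            label_weeks(qids[pid], week_starts[pid], pid)
            for pid in traces
            if pid in qids
        ]
        labels = pd.concat(frames)
        labels = labels.loc[labels.index.intersection(table.index)].reindex(table.index)

    if alpha_grid is not None:
        return table, result[1], labels
    return table, labels


def labeled_arrays(table: pd.DataFrame, labels: pd.DataFrame, columns: Sequence[str]):
    """Aligned (X, y, groups) for modeling: labeled weeks without missing
    values in the chosen columns."""
    ok = labels["depressed"].notna().to_numpy() & ~table[list(columns)].isna().any(axis=1).to_numpy()
    X = table.loc[ok, list(columns)].to_numpy(dtype=float)
    y = labels.loc[ok, "depressed"].to_numpy().astype(int)
    groups = table.index.get_level_values("participant").to_numpy()[ok]
    return X, y, groups


# ---------------------------------------------------------------------------
# staged file-based workflow


def simulate_to_dir(config: SyntheticConfig, outdir: Path) -> Cohort:
    """Write per-participant trace and QIDS CSVs plus the truth ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    for pid, rec in cohort.participants.items():
        write_trace_csv(rec.trace, outdir / f"{pid}_trace.csv")
        write_qids_csv(rec.qids, outdir / f"{pid}_qids.csv")
    truth = cohort.truth.reset_index().to_dict(orient="records")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
    return cohort


def _stage_fresh(inputs: list[Path], outputs: list[Path]) -> bool:
    if not outputs or not all(o.exists() for o in outputs):
        return False
    newest_in = max((i.stat().st_mtime for i in inputs), default=0.0)
    return min(o.stat().st_mtime for o in outputs) >= newest_in


def run_pipeline(
    outdir: Path,
    synthetic: SyntheticConfig | None = None,
    params: PipelineParams | None = None,
    feature_columns: Sequence[str] | None = None,
    m_equalize: int = 100,
    force: bool = False,
) -> dict:
    """simulate -> features/labels -> evaluate, with stage skipping.

    Stage outputs live under ``outdir``; a stage reruns only when its outputs
    are missing or older than its inputs (or ``force``). The resolved
    configuration is written beside the outputs and the report returned (and
    stored as ``report.json``).
    """
    from .evaluation import CVConfig, qda_factory, run_cv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synthetic = synthetic or SyntheticConfig()
    params = params or PipelineParams()

    config_path = outdir / "config.json"
    config_path.write_text(
        json.dumps(
            {
                "synthetic": dataclasses.asdict(synthetic),
                "pipeline": {
                    "preprocess": dataclasses.asdict(params.preprocess),
                    "speed_threshold_kmh": params.speed_threshold_kmh,
                    "cluster_separation_km": params.cluster_separation_km,
                    "alpha": params.alpha if not isinstance(params.alpha, Mapping) else dict(params.alpha),
                    "tz": params.tz,
                    "seed": params.seed,
                },
                "m_equalize": m_equalize,
            },
            indent=1,
        )
    )

    counts: dict[str, int] = {}
    trace_files = sorted(outdir.glob("p*_trace.csv"))
    if force or not trace_files:
        log.info("stage simulate")
        simulate_to_dir(synthetic, outdir)
        trace_files = sorted(outdir.glob("p*_trace.csv"))
    else:
        log.info("stage simulate: outputs present, skipped")
    counts["participants"] = len(trace_files)

    features_path = outdir / "features.csv"
    labels_path = outdir / "labels.csv"
    if force or not _stage_fresh(trace_files, [features_path, labels_path]):
        log.info("stage featurize")
        try:
            traces = {f.stem.removesuffix("_trace"): read_trace_csv(f, reference=(0.0, 0.0))
                      for f in trace_files}
            qids = {
                f.stem.removesuffix("_qids"): read_qids_csv(f)
                for f in sorted(outdir.glob("p*_qids.csv"))
            }
            table, labels = extract_cohort(traces, qids, params)
        except Exception as exc:
            raise RuntimeError(f"stage featurize failed: {exc}") from exc
        table.to_csv(features_path)
        labels.to_csv(labels_path)
    else:
        log.info("stage featurize: outputs fresh, skipped")
        idx = ["participant", "iso_year", "iso_week"]
        table = pd.read_csv(features_path).set_index(idx)
        labels = pd.read_csv(labels_path).set_index(idx)
    counts["weeks"] = len(table)
    counts["dropped_insufficient"] = int(table.attrs.get("n_dropped_insufficient", 0))

    cols = list(feature_columns) if feature_columns else ["HS_base", "NC_base", "ENT_base",
                                                          "TT_base", "DMD_base"]
    X, y, groups = labeled_arrays(table, labels, cols)
    counts["labeled_weeks"] = len(y)
    cv = run_cv(X, y, groups, qda_factory(), CVConfig(m_equalize=m_equalize, seed=params.seed))
    counts["skipped_folds"] = cv.n_skipped_folds

    report = {
        "features": cols,
        "counts": counts,
        "metrics": {k: {"median": cv.median(k), "iqr": cv.iqr(k)} for k in cv.metrics},
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
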