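"""End-to-end orchestration: fit → scheme → classify → validate → season → condition.

The pipeline consumes a capture-record CSV, fits the healing regressions
from cord-remnant-anchored recapture histories, derives the wound-class
scheme, labels every event, validates predicted vs actual time at liberty
on recaptures outside the training set, back-calculates the parturition
season, and compares morphometrics across classes. Every stage logs the
records it excludes, because each has an explicit exclusion rule. Outputs
are CSVs plus one JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import condition as cond
from . import season as seas
from .classify import DEFAULT_BOUNDARIES, classify_cohort, derive_scheme
from .core import build_histories, events_to_frame, read_captures, DEFAULT_DATE_FORMAT
from .regression import assemble_training_pairs, closure_age, fit_wound_models
from .simulate import SEASON_MONTHS
from .validation import summarize_validation, validate_cohort

logger = logging.getLogger(__name__)

#: Keys (and scalar types) every pipeline summary must provide; the shipped
#: docs/summary.schema.json mirrors this table.
SUMMARY_SCHEMA: dict[str, type] = {
    "a0": float, "a1": float, "b0": float, "b1": float,
    "crit_area_cm2": float, "crit_perimeter_cm": float,
    "closure_day": int,
    "n_events": int, "n_sharks": int,
    "class_counts": dict,
    "validation": dict,
    "month_histogram": dict,
    "seasonality": dict,
}


class StageError(RuntimeError):
    """A pipeline stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    input_path: str | Path
    output_dir: str | Path
    boundaries: tuple[float, float, float] = DEFAULT_BOUNDARIES
    season_months: tuple[int, ...] = SEASON_MONTHS
    date_format: str = DEFAULT_DATE_FORMAT
    response: str = "k"


def validate_summary(summary: dict) -> None:
    """Check a summary against the shipped schema; raises on violation."""
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in summary:
            raise ValueError(f"summary missing key {key!r}")
        value = summary[key]
        if typ is float and not isinstance(value, (int, float)):
            raise ValueError(f"summary key {key!r} must be numeric")
        if typ in (int, dict) and not isinstance(value, typ):
            raise ValueError(f"summary key {key!r} must be {typ.__name__}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; writes CSV outputs and returns the JSON summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        events = read_captures(config.input_path, config.date_format)
        histories = build_histories(events)
    except Exception as exc:
        raise StageError("read", exc) from exc

    try:
        pairs = assemble_training_pairs(histories)
        fit = fit_wound_models(pairs)
        training_ids = sorted(pairs["shark_id"].unique())
        closure = closure_age(fit)
    except Exception as exc:
        raise StageError("fit", exc) from exc

    try:
        scheme = derive_scheme(fit, config.boundaries)
        labeled = classify_cohort(events, scheme)
        frame = labeled.frame
        frame_out = frame.copy()
        frame_out["date"] = [d.strftime(config.date_format) for d in frame_out["date"]]
        frame_out.to_csv(out / "labeled.csv", index=False)
    except Exception as exc:
        raise StageError("classify", exc) from exc

    try:
        records, excluded = validate_cohort(histories, fit, training_ids)
        val_frame = pd.DataFrame(
            [
                {
                    "shark_id": r.shark_id,
                    "initial_date": r.initial_date.strftime(config.date_format),
                    "recapture_date": r.recapture_date.strftime(config.date_format),
                    "tal": r.tal,
                    "ptal": r.ptal,
                    "abs_diff": r.abs_diff,
                }
                for r in records
            ]
        )
        val_frame.to_csv(out / "validation.csv", index=False)
        val_summary = (
            summarize_validation(records) if len(records) >= 2 else None
        )
    except Exception as exc:
        raise StageError("validate", exc) from exc

    try:
        estimates, skipped = seas.backcalculate(frame, scheme)
        hist = seas.month_distribution(estimates)
        hist.to_csv(out / "births_by_month.csv", index=False)
        counts, outside = seas.season_month_counts(estimates, config.season_months)
        season_test = (
            seas.seasonality_test(counts) if counts.sum() > 0 else None
        )
    except Exception as exc:
        raise StageError("parturition", exc) from exc

    try:
        records_cond = cond.condition_records(frame)
        comparison = None
        group_sizes = records_cond.groupby("uwc").size()
        if (group_sizes >= 2).sum() >= 2:
            comparison = cond.compare_groups(records_cond, config.response)
            comparison.tukey.to_csv(out / "morpho_tukey.csv", index=False)
    except Exception as exc:
        raise StageError("morphometrics", exc) from exc

    summary = {
        "a0": fit.a0, "a1": fit.a1, "b0": fit.b0, "b1": fit.b1,
        "crit_area_cm2": scheme.crit_area_report,
        "crit_perimeter_cm": scheme.crit_perimeter_report,
        "closure_day": closure.closure_day,
        "n_events": len(events),
        "n_sharks": len(histories),
        "class_counts": {str(k): v for k, v in labeled.counts.items()},
        "validation": {
            "n": val_summary.n if val_summary else len(records),
            "mean_abs_diff": val_summary.mean_abs_diff if val_summary else None,
            "sd_abs_diff": val_summary.sd_abs_diff if val_summary else None,
            "n_excluded": len(excluded),
        },
        "month_histogram": {
            str(m): int(c) for m, c in zip(hist["month"], hist["count"])
        },
        "seasonality": {
            "chi2": season_test.chi2 if season_test else None,
            "df": season_test.df if season_test else None,
            "p_value": season_test.p_value if season_test else None,
            "n_outside_window": outside,
        },
    }
    if comparison is not None:
        summary["morphometrics"] = {
            "response": comparison.response,
            "f_stat": comparison.f_stat,
            "df": [comparison.df_between, comparison.df_within],
            "p_value": comparison.p_value,
        }
    validate_summary(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
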