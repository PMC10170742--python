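"""Per-event age estimation by curve inversion, and pTAL-vs-TAL validation.

The fitted curves are inverted to relative ages:

* via area:      age = ((a0 - sqrt(area)) / a1)²,  valid while sqrt(area) < a0
* via perimeter: age = (b0 - perimeter) / b1

Both inversions clamp at zero: the area inversion squares a difference, so
a wound *larger* than the age-0 intercept would otherwise produce a ghost
positive age on the unphysical branch. The combined estimate is the
unweighted mean of the two (no variance components are available to weight
them). A closed wound (0, 0) is censored — the age is only bounded below by
the closure day — and censored events propagate exclusion rather than an
imputed age.

Validation compares, for recaptured sharks, the predicted elapsed time
between captures (pTAL, the difference of combined age estimates) with the
actual time at liberty (TAL, the date difference). Sharks used to construct
the regressions, and sharks with a closed wound at either capture, are
excluded with an explicit reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np

from .core import CaptureEvent, SharkHistory, elapsed_days
from .regression import WoundModelFit

EXCLUDED_TRAINING = "used to construct the regression relationships"
EXCLUDED_CENSORED = "closed umbilicus at initial capture and/or recapture"


@dataclass(frozen=True)
class AgeEstimate:
    """Relative age of one event from area, perimeter, and their mean."""

    age_from_area: float | None
    age_from_perimeter: float | None
    age_combined: float | None
    censored: bool

    def __post_init__(self) -> None:
        for v in (self.age_from_area, self.age_from_perimeter, self.age_combined):
            if v is not None and v < 0:
                raise ValueError("ages must be >= 0")


def invert_ages(
    area: np.ndarray, perimeter: np.ndarray, fit: WoundModelFit
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised curve inversion; NaN where censored ((0,0)) or missing."""
    area = np.asarray(area, dtype=float)
    perimeter = np.asarray(perimeter, dtype=float)
    with np.errstate(invalid="ignore"):
        s = np.sqrt(area)
        age_area = np.where(s < fit.a0, ((fit.a0 - s) / fit.a1) ** 2, 0.0)
        age_perim = np.maximum(0.0, (fit.b0 - perimeter) / fit.b1)
    censored = (area == 0) & (perimeter == 0)
    missing = np.isnan(area) | np.isnan(perimeter)
    bad = censored | missing
    age_area = np.where(bad, np.nan, age_area)
    age_perim = np.where(bad, np.nan, age_perim)
    return age_area, age_perim, (age_area + age_perim) / 2.0


def estimate_age(event: CaptureEvent, fit: WoundModelFit) -> AgeEstimate:
    """Invert both curves for one event (wound fields must be present)."""
    if event.wound_area is None or event.wound_perimeter is None:
        raise ValueError(f"event of {event.shark_id!r} has missing wound fields")
    if event.wound_closed:
        return AgeEstimate(None, None, None, censored=True)
    a, p, c = invert_ages(
        np.array([event.wound_area]), np.array([event.wound_perimeter]), fit
    )
    return AgeEstimate(float(a[0]), float(p[0]), float(c[0]), censored=False)


@dataclass(frozen=True)
class ValidationRecord:
    """Actual vs predicted time at liberty for one recaptured shark."""

    shark_id: str
    initial_date: date
    recapture_date: date
    tal: int
    ptal: float
    abs_diff: float


@dataclass(frozen=True)
class Exclusion:
    """A history omitted from validation, with the reason."""

    shark_id: str
    reason: str


def predict_tal(
    history: SharkHistory,
    fit: WoundModelFit,
    training_ids: Iterable[str] = (),
) -> ValidationRecord | Exclusion:
    """Predicted vs actual time at liberty for one recapture history.

    Uses the first and last events. Returns an :class:`Exclusion` when the
    shark was in the regression training set, or when either event is
    censored (closed wound) or has missing wound fields.
    """
    if len(history.events) < 2:
        raise ValueError(f"shark {history.shark_id!r} has no recapture")
    if history.shark_id in set(training_ids):
        return Exclusion(history.shark_id, EXCLUDED_TRAINING)
    first, last = history.events[0], history.events[-1]
    for ev in (first, last):
        if ev.wound_area is None or ev.wound_perimeter is None:
            return Exclusion(history.shark_id, "missing wound fields")
    est_first = estimate_age(first, fit)
    est_last = estimate_age(last, fit)
    if est_first.censored or est_last.censored:
        return Exclusion(history.shark_id, EXCLUDED_CENSORED)
    tal = elapsed_days(first.date, last.date)
    ptal = est_last.age_combined - est_first.age_combined
    return ValidationRecord(
        shark_id=history.shark_id,
        initial_date=first.date,
        recapture_date=last.date,
        tal=tal,
        ptal=ptal,
        abs_diff=abs(tal - ptal),
    )


@dataclass(frozen=True)
class ValidationSummary:
    """Mean and sample SD of |TAL − pTAL|, raw and rounded to whole days."""

    mean_abs_diff: float
    sd_abs_diff: float
    n: int

    @property
    def mean_days(self) -> int:
        return int(round(self.mean_abs_diff))

    @property
    def sd_days(self) -> int:
        return int(round(self.sd_abs_diff))


def summarize_validation(
    records: Sequence[ValidationRecord] | Sequence[float],
) -> ValidationSummary:
    """Mean and sample standard deviation (n−1) of the absolute TAL errors."""
    diffs = [
        r.abs_diff if isinstance(r, ValidationRecord) else float(r) for r in records
    ]
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least two validation records for a standard deviation")
    arr = np.asarray(diffs, dtype=float)
    return ValidationSummary(
        mean_abs_diff=float(arr.mean()),
        sd_abs_diff=float(arr.std(ddof=1)),
        n=n,
    )


def validate_cohort(
    histories: Sequence[SharkHistory],
    fit: WoundModelFit,
    training_ids: Iterable[str] = (),
) -> tuple[list[ValidationRecord], list[Exclusion]]:
    """Run :func:`predict_tal` over every recapture history."""
    records: list[ValidationRecord] = []
    excluded: list[Exclusion] = []
    training = set(training_ids)
    for h in histories:
        if len(h.events) < 2:
            continue
        out = predict_tal(h, fit, training)
        if isinstance(out, ValidationRecord):
            records.append(out)
        else:
            excluded.append(out)
    return records, excluded
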