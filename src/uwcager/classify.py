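"""Umbilical wound classes (UWC) derived from the fitted healing curves.

The four-class scheme splits the ~36-day healing window into three equal
neonatal intervals plus a healed juvenile class:

====  ===============  ==================  =====================
UWC   age (days)       area (cm²)          perimeter (cm)
====  ===============  ==================  =====================
1     0–12             > crit_area         > crit_perimeter
2     12–24            ≤ crit_area         > crit_perimeter
3     24–36            < crit_area         ≤ crit_perimeter
4     ≥ 36 (healed)    0                   0
====  ===============  ==================  =====================

with critical values read off the fitted curves: the area curve at the
first boundary (default 12 d) and the perimeter line at the second
(default 24 d). Area alone cannot separate UWC2 from UWC3 (their area
ranges overlap in the field data), so perimeter decides the 24-day
boundary first and area then separates UWC1 from UWC2; the combination
"area above critical but perimeter at or below critical" is not covered by
the scheme's table, is assigned UWC3 by that precedence, and is flagged as
inconsistent. Comparisons always use unrounded critical values; the
familiar rounded values (0.016 cm², 0.41 cm for the default fit) are for
reporting only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import CaptureEvent, events_to_frame
from .regression import WoundModelFit, WoundHealingModel, closure_age

logger = logging.getLogger(__name__)

DEFAULT_BOUNDARIES = (12.0, 24.0, 36.0)

UWC_LABELS = (1, 2, 3, 4)


@dataclass(frozen=True)
class UwcScheme:
    """Class boundaries in days plus the derived critical wound sizes."""

    boundaries: tuple[float, float, float]
    crit_area: float        # cm², unrounded; use crit_area_report for display
    crit_perimeter: float   # cm, unrounded
    source_fit: WoundModelFit | None = None

    def __post_init__(self) -> None:
        b = self.boundaries
        if not (0 <= b[0] < b[1] < b[2]):
            raise ValueError("boundaries must be non-negative and strictly increasing")
        if self.crit_area <= 0 or self.crit_perimeter <= 0:
            raise ValueError("critical values must be positive")

    @property
    def crit_area_report(self) -> float:
        """Critical area rounded to 3 d.p. for reporting."""
        return round(self.crit_area, 3)

    @property
    def crit_perimeter_report(self) -> float:
        """Critical perimeter rounded to 2 d.p. for reporting."""
        return round(self.crit_perimeter, 2)

    def interval(self, uwc: int) -> tuple[float, float]:
        """(t_min, t_max) in days of a neonatal class (UWC 1–3)."""
        edges = (0.0, *self.boundaries)
        if uwc not in (1, 2, 3):
            raise ValueError(f"no bounded age interval for UWC {uwc}")
        return edges[uwc - 1], edges[uwc]


def derive_scheme(
    fit: WoundModelFit, boundaries: Sequence[float] = DEFAULT_BOUNDARIES
) -> UwcScheme:
    """Evaluate the fitted curves at the class boundaries.

    crit_area is the area curve at ``boundaries[0]``; crit_perimeter is the
    perimeter line at ``boundaries[1]``. Boundaries must lie within the
    fitted healing window (0, closure day].
    """
    b = tuple(float(x) for x in boundaries)
    if len(b) != 3 or not (0 <= b[0] < b[1] < b[2]):
        raise ValueError("boundaries must be three strictly increasing ages")
    closure = closure_age(fit)
    if b[2] > closure.closure_day:
        raise ValueError(
            f"boundary {b[2]} d lies beyond wound closure ({closure.closure_day} d)"
        )
    crit_area = float((fit.a0 - fit.a1 * np.sqrt(b[0])) ** 2)
    crit_perimeter = float(fit.b0 - fit.b1 * b[1])
    return UwcScheme(
        boundaries=b, crit_area=crit_area, crit_perimeter=crit_perimeter,
        source_fit=fit,
    )


@dataclass(frozen=True)
class Classification:
    """A UWC label with its scheme-consistency flag.

    ``label`` is ``None`` (unclassifiable) when a wound measurement is
    missing; that is an outcome, not an error. ``consistent`` is False for
    the off-table combination area > crit_area with perimeter ≤
    crit_perimeter (assigned UWC3 by the perimeter-first precedence).
    """

    label: int | None
    consistent: bool | None


def classify(event: CaptureEvent | tuple, scheme: UwcScheme) -> Classification:
    """Assign a UWC to one event; total on non-negative (area, perimeter)."""
    if isinstance(event, CaptureEvent):
        area, perimeter = event.wound_area, event.wound_perimeter
    else:
        area, perimeter = event
    if area is None or perimeter is None:
        return Classification(label=None, consistent=None)
    if area < 0 or perimeter < 0:
        raise ValueError("wound sizes must be non-negative")
    if area == 0 and perimeter == 0:
        return Classification(label=4, consistent=True)
    if perimeter <= scheme.crit_perimeter:
        consistent = not area > scheme.crit_area
        if not consistent:
            logger.info(
                "off-table wound (area %.4g > crit, perimeter %.4g <= crit): UWC3",
                area, perimeter,
            )
        return Classification(label=3, consistent=consistent)
    if area > scheme.crit_area:
        return Classification(label=1, consistent=True)
    return Classification(label=2, consistent=True)


@dataclass
class CohortClassification:
    """Per-event labels plus class counts for a cohort."""

    frame: pd.DataFrame            # events + uwc, uwc_consistent columns
    counts: dict[int, int]         # label -> count over classifiable events
    n_unclassifiable: int

    @property
    def n_classified(self) -> int:
        return int(sum(self.counts.values()))


def classify_cohort(
    events: Sequence[CaptureEvent] | pd.DataFrame, scheme: UwcScheme
) -> CohortClassification:
    """Label every event; counts over labels sum to the classifiable events."""
    if isinstance(events, pd.DataFrame):
        frame = events.copy()
    else:
        frame = events_to_frame(events)
    labels: list[int | None] = []
    flags: list[bool | None] = []
    for area, perim in zip(frame["wound_area_cm2"], frame["wound_perimeter_cm"]):
        a = None if pd.isna(area) else float(area)
        p = None if pd.isna(perim) else float(perim)
        cls = classify((a, p), scheme)
        labels.append(cls.label)
        flags.append(cls.consistent)
    frame["uwc"] = pd.array(labels, dtype="Int64")
    frame["uwc_consistent"] = pd.array(flags, dtype="boolean")
    counts = {lab: int((frame["uwc"] == lab).sum()) for lab in UWC_LABELS}
    n_missing = int(frame["uwc"].isna().sum())
    if n_missing:
        logger.info("%d events unclassifiable (missing wound fields)", n_missing)
    return CohortClassification(frame=frame, counts=counts, n_unclassifiable=n_missing)


class UwcClassifier(BaseEstimator):
    """scikit-learn-style wrapper: fit a scheme, predict UWC labels.

    :meth:`fit` accepts either a training-pair frame (the healing model is
    fitted first) or a prefitted :class:`WoundModelFit` via the ``fit_result``
    parameter. :meth:`predict` maps a frame with wound columns to labels 1–4
    (NaN where unclassifiable).
    """

    def __init__(
        self,
        boundaries: tuple[float, float, float] = DEFAULT_BOUNDARIES,
        fit_result: WoundModelFit | None = None,
    ):
        self.boundaries = boundaries
        self.fit_result = fit_result

    def fit(self, X=None, y=None) -> "UwcClassifier":
        fit = self.fit_result
        if fit is None:
            if X is None:
                raise ValueError("need training pairs or a prefitted fit_result")
            fit = WoundHealingModel().fit(X).to_result()
        self.scheme_ = derive_scheme(fit, self.boundaries)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        area_col = "wound_area_cm2" if "wound_area_cm2" in X.columns else "area"
        per_col = (
            "wound_perimeter_cm" if "wound_perimeter_cm" in X.columns else "perimeter"
        )
        out = np.full(len(X), np.nan)
        for i, (a, p) in enumerate(zip(X[area_col], X[per_col])):
            cls = classify(
                (None if pd.isna(a) else float(a), None if pd.isna(p) else float(p)),
                self.scheme_,
            )
            if cls.label is not None:
                out[i] = cls.label
        return out
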