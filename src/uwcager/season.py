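"""Parturition back-calculation and birth-season analysis.

Each neonatal first capture (UWC 1–3) yields an estimated parturition date
by subtracting the midpoint age of its class from the capture date:

    t0 = t_capture − (t_min + t_max) / 2

where (t_min, t_max) is the age interval of the class — 6, 18 and 30 days
for the default 12/24/36-day boundaries. Juveniles (UWC4, healed wound)
carry no usable age and are skipped. Dates are absolute ordinal days, so a
January capture correctly back-calculates into December of the prior year.

The monthly distribution of back-calculated births is summarised and tested
against a uniform expectation over the season months with a Pearson
chi-square goodness-of-fit test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .classify import UwcScheme
from .simulate import SEASON_MONTHS

logger = logging.getLogger(__name__)


def midpoint_age(uwc: int, scheme: UwcScheme) -> float:
    """Midpoint (t_min + t_max)/2 of a neonatal class interval, in days."""
    if uwc == 4:
        raise ValueError(
            "UWC4 (closed umbilicus, juvenile) has no bounded age; "
            "juveniles are not considered in back-calculation"
        )
    t_min, t_max = scheme.interval(int(uwc))
    return (t_min + t_max) / 2.0


@dataclass(frozen=True)
class ParturitionEstimate:
    """Back-calculated birth date for one shark's first neonatal capture."""

    shark_id: str
    capture_date: date
    uwc: int
    t0: date

    def __post_init__(self) -> None:
        if self.uwc not in (1, 2, 3):
            raise ValueError("parturition estimates exist for UWC 1-3 only")

    @property
    def month(self) -> int:
        return self.t0.month


def backcalculate(
    labeled: pd.DataFrame, scheme: UwcScheme
) -> tuple[list[ParturitionEstimate], int]:
    """One parturition estimate per shark from its first classified capture.

    ``labeled`` needs columns ``shark_id``, ``date`` and ``uwc``. Returns the
    estimates and the count of sharks skipped (first capture UWC4 or
    unclassifiable). Fractional midpoints are rounded to whole days, since
    capture dates have daily resolution.
    """
    frame = labeled.copy()
    frame["date"] = pd.to_datetime(frame["date"]).dt.date
    firsts = (
        frame.sort_values(["shark_id", "date"], kind="stable")
        .groupby("shark_id", sort=True)
        .head(1)
    )
    estimates: list[ParturitionEstimate] = []
    skipped = 0
    for row in firsts.itertuples(index=False):
        if pd.isna(row.uwc) or int(row.uwc) not in (1, 2, 3):
            skipped += 1
            continue
        uwc = int(row.uwc)
        offset = int(round(midpoint_age(uwc, scheme)))
        estimates.append(
            ParturitionEstimate(
                shark_id=str(row.shark_id),
                capture_date=row.date,
                uwc=uwc,
                t0=row.date - timedelta(days=offset),
            )
        )
    if skipped:
        logger.info("%d sharks skipped in back-calculation (UWC4 or unclassifiable)", skipped)
    return estimates, skipped


def _season_order(months: tuple[int, ...]) -> list[int]:
    """Calendar months ordered along the season cycle starting in July."""
    return sorted(set(months), key=lambda m: (m - 7) % 12)


def month_distribution(
    estimates: list[ParturitionEstimate] | pd.Series,
) -> pd.DataFrame:
    """Counts and percentages of back-calculated births per calendar month.

    Months are ordered along the season cycle (July..June) so that a
    September–January season reads in chronological order. Counts sum to the
    number of estimates.
    """
    if isinstance(estimates, pd.Series):
        months = [int(m) for m in estimates]
    else:
        months = [e.month for e in estimates]
    if not months:
        return pd.DataFrame(columns=["month", "count", "pct"])
    counts = pd.Series(months).value_counts()
    order = _season_order(tuple(counts.index))
    total = counts.sum()
    return pd.DataFrame(
        {
            "month": order,
            "count": [int(counts[m]) for m in order],
            "pct": [100.0 * counts[m] / total for m in order],
        }
    )


@dataclass(frozen=True)
class SeasonalityTest:
    """Pearson chi-square of monthly birth counts against uniformity."""

    chi2: float
    df: int
    p_value: float


def seasonality_test(counts) -> SeasonalityTest:
    """Pearson chi-square of observed month counts vs a uniform expectation.

    ``counts`` is a sequence (or mapping month -> count) of observed births
    for the months included in the season window; df = months − 1.
    """
    if isinstance(counts, dict):
        observed = np.asarray(list(counts.values()), dtype=float)
    else:
        observed = np.asarray(list(counts), dtype=float)
    if observed.size < 2:
        raise ValueError("need at least two months to test seasonality")
    if observed.sum() <= 0:
        raise ValueError("expected count is zero for every month")
    chi2, p = stats.chisquare(observed)
    return SeasonalityTest(chi2=float(chi2), df=int(observed.size - 1), p_value=float(p))


def season_month_counts(
    estimates: list[ParturitionEstimate],
    season_months: tuple[int, ...] = SEASON_MONTHS,
) -> tuple[np.ndarray, int]:
    """Birth counts over the season months, plus the out-of-window count.

    Back-calculated dates can fall just outside the window (an early-
    September capture of a young class back-calculates into August); those
    are counted separately and logged, not silently dropped.
    """
    months = [e.month for e in estimates]
    counts = np.array([months.count(m) for m in season_months], dtype=float)
    outside = len(months) - int(counts.sum())
    if outside:
        logger.info("%d back-calculated births fall outside the season window", outside)
    return counts, outside
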