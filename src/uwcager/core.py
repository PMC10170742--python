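"""Domain types, date arithmetic and CSV I/O shared by every pipeline stage.

A capture record describes one measurement occasion of a tagged shark: the
date it was netted, the traced size of its umbilical wound (area in cm²,
perimeter in cm), and basic morphometrics (precaudal length in cm, total
body mass in kg). Recaptures of the same PIT-tagged individual are linked
into a :class:`SharkHistory`, whose inter-event day counts are the "time at
liberty" used throughout the analysis.

Dates are kept as calendar dates and converted to absolute proleptic
ordinal day counts for arithmetic, never day-of-year: the parturition
season spans a calendar year boundary (September–February), so a January
capture back-calculated by 30 days must land in December of the prior year.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: dd/mm/yyyy, the dialect used by the field records.
DEFAULT_DATE_FORMAT = "%d/%m/%Y"

#: Header of the capture-record CSV dialect.
CSV_COLUMNS = (
    "shark_id",
    "date",
    "wound_area_cm2",
    "wound_perimeter_cm",
    "pcl_cm",
    "mass_kg",
    "site",
    "sex",
    "cord_remnants",
)

REQUIRED_COLUMNS = ("shark_id", "date")


class RowError(ValueError):
    """A capture-record row that cannot be parsed or fails validation."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class CaptureEvent:
    """One measurement occasion of a single shark.

    A healed umbilicus is encoded as ``wound_area == 0`` and
    ``wound_perimeter == 0`` together; a missing measurement is ``None``,
    never zero. ``cord_remnants`` flags umbilical-cord remnants, which mark
    a days-old ("time zero") neonate.
    """

    shark_id: str
    date: date
    wound_area: float | None = None
    wound_perimeter: float | None = None
    pcl: float | None = None
    mass: float | None = None
    site: str | None = None
    sex: str | None = None
    cord_remnants: bool | None = None

    def __post_init__(self) -> None:
        if self.wound_area is not None and self.wound_area < 0:
            raise ValueError(f"negative wound area {self.wound_area!r}")
        if self.wound_perimeter is not None and self.wound_perimeter < 0:
            raise ValueError(f"negative wound perimeter {self.wound_perimeter!r}")
        if self.pcl is not None and self.pcl <= 0:
            raise ValueError(f"non-positive precaudal length {self.pcl!r}")
        if self.mass is not None and self.mass <= 0:
            raise ValueError(f"non-positive mass {self.mass!r}")
        if self.wound_area is not None and self.wound_perimeter is not None:
            # A healed wound has both measurements at zero.
            if (self.wound_area == 0) != (self.wound_perimeter == 0):
                raise ValueError(
                    "wound area and perimeter must be zero together "
                    f"(got area={self.wound_area}, perimeter={self.wound_perimeter})"
                )
        if self.cord_remnants and self.wound_area is not None and self.wound_area <= 0:
            raise ValueError("cord remnants imply an open (positive-area) wound")

    @property
    def wound_closed(self) -> bool | None:
        """True when both wound measurements are exactly zero."""
        if self.wound_area is None or self.wound_perimeter is None:
            return None
        return self.wound_area == 0 and self.wound_perimeter == 0


@dataclass(frozen=True)
class SharkHistory:
    """All capture events of one individual, in strictly ascending date order."""

    shark_id: str
    events: tuple[CaptureEvent, ...]

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.shark_id != self.shark_id:
                raise ValueError(
                    f"event shark_id {ev.shark_id!r} != history {self.shark_id!r}"
                )
        for a, b in zip(self.events, self.events[1:]):
            if a.date >= b.date:
                raise ValueError(
                    f"events of {self.shark_id!r} not strictly increasing in date"
                )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def is_recapture(self) -> bool:
        return len(self.events) >= 2


def to_ordinal(d: date) -> int:
    """Absolute proleptic ordinal day count of a calendar date."""
    return d.toordinal()


def from_ordinal(n: int) -> date:
    """Inverse of :func:`to_ordinal` (lossless round trip)."""
    return date.fromordinal(n)


def elapsed_days(d1: date, d2: date) -> int:
    """Whole days from ``d1`` to ``d2``; negative when ``d2`` precedes ``d1``."""
    return (d2 - d1).days


def parse_date(text: str, date_format: str = DEFAULT_DATE_FORMAT) -> date:
    return datetime.strptime(text.strip(), date_format).date()


def _parse_float(cell, row: int, column: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise RowError(row, f"unparseable {column} value {text!r}") from exc


def _parse_bool(cell) -> bool | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip().lower()
    if text == "":
        return None
    if text in ("true", "1", "yes", "t"):
        return True
    if text in ("false", "0", "no", "f"):
        return False
    raise ValueError(f"unparseable boolean {cell!r}")


def read_captures(
    path: str | Path, date_format: str = DEFAULT_DATE_FORMAT
) -> list[CaptureEvent]:
    """Read capture events from a CSV file.

    Missing numeric cells become ``None`` (missing), never zero. Errors carry
    the 1-based data-row number.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    events: list[CaptureEvent] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        rec = dict(zip(frame.columns, row))
        try:
            when = parse_date(rec["date"], date_format)
        except ValueError as exc:
            raise RowError(i, f"unparseable date {rec['date']!r}") from exc
        try:
            events.append(
                CaptureEvent(
                    shark_id=str(rec["shark_id"]).strip(),
                    date=when,
                    wound_area=_parse_float(rec.get("wound_area_cm2"), i, "wound_area_cm2"),
                    wound_perimeter=_parse_float(
                        rec.get("wound_perimeter_cm"), i, "wound_perimeter_cm"
                    ),
                    pcl=_parse_float(rec.get("pcl_cm"), i, "pcl_cm"),
                    mass=_parse_float(rec.get("mass_kg"), i, "mass_kg"),
                    site=(rec.get("site") or "").strip() or None,
                    sex=(rec.get("sex") or "").strip() or None,
                    cord_remnants=_parse_bool(rec.get("cord_remnants")),
                )
            )
        except RowError:
            raise
        except ValueError as exc:
            raise RowError(i, str(exc)) from exc
    return events


def write_captures(
    events: Iterable[CaptureEvent],
    path: str | Path,
    date_format: str = DEFAULT_DATE_FORMAT,
) -> None:
    """Write capture events in the CSV dialect read by :func:`read_captures`."""
    events_to_frame(events, date_format).to_csv(path, index=False)


def events_to_frame(
    events: Iterable[CaptureEvent], date_format: str | None = None
) -> pd.DataFrame:
    """Tabulate events; dates stay ``datetime.date`` unless a format is given."""
    rows = []
    for ev in events:
        rows.append(
            {
                "shark_id": ev.shark_id,
                "date": ev.date.strftime(date_format) if date_format else ev.date,
                "wound_area_cm2": ev.wound_area,
                "wound_perimeter_cm": ev.wound_perimeter,
                "pcl_cm": ev.pcl,
                "mass_kg": ev.mass,
                "site": ev.site,
                "sex": ev.sex,
                "cord_remnants": ev.cord_remnants,
            }
        )
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def build_histories(events: Sequence[CaptureEvent]) -> list[SharkHistory]:
    """Group events by shark and sort each group by date.

    Two events for one shark on the same date are ambiguous (a tag collision
    or double entry) and raise a ``ValueError``. Singleton histories are
    allowed; the total event count is conserved.
    """
    by_id: dict[str, list[CaptureEvent]] = {}
    for ev in events:
        by_id.setdefault(ev.shark_id, []).append(ev)
    histories = []
    for shark_id in sorted(by_id):
        evs = sorted(by_id[shark_id], key=lambda e: e.date)
        for a, b in zip(evs, evs[1:]):
            if a.date == b.date:
                raise ValueError(
                    f"shark {shark_id!r} has two events on {a.date} (ambiguous recapture)"
                )
        histories.append(SharkHistory(shark_id=shark_id, events=tuple(evs)))
    return histories
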