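"""Published field records shipped with the package.

The Moorea blacktip reef shark mark-recapture program reported a validation
set of 17 recaptured neonates: for each, the actual time at liberty (TAL,
days between initial capture and recapture) and the TAL predicted from
wound-size-inferred ages (pTAL). The underlying wound measurements were not
published, so the pTAL column is reference data only; the dates and TAL
column exercise the package's date arithmetic.

One row (shark 3) is stored exactly as printed even though its dates are 40
days apart while its printed TAL is 9 — a typo in the source; tests that
check TAL-from-dates use internally consistent rows only.
"""

from __future__ import annotations

import pandas as pd

from .core import SharkHistory, build_histories, CaptureEvent, parse_date

#: (shark, initial capture, recapture, TAL d, pTAL d, |TAL - pTAL| d)
FIELD_VALIDATION_ROWS: tuple[tuple[str, str, str, int, int, int], ...] = (
    ("1", "18/11/2016", "02/12/2016", 14, 18, 4),
    ("2", "20/11/2016", "04/12/2016", 14, 9, 5),
    ("3", "01/12/2016", "10/01/2017", 9, 10, 1),
    ("4", "22/12/2016", "07/01/2017", 16, 8, 8),
    ("5", "06/12/2017", "22/12/2017", 16, 14, 2),
    ("6", "06/12/2017", "22/12/2017", 16, 13, 3),
    ("7", "17/01/2018", "26/01/2018", 9, 13, 4),
    ("8", "13/11/2019", "04/12/2019", 21, 10, 11),
    ("9", "04/12/2019", "12/12/2019", 8, 14, 6),
    ("10", "04/12/2019", "12/12/2019", 8, 12, 4),
    ("11", "06/10/2020", "22/10/2020", 16, 19, 3),
    ("12", "06/10/2020", "22/10/2020", 16, 7, 9),
    ("13", "05/10/2021", "26/10/2021", 21, 12, 9),
    ("14", "11/10/2021", "25/10/2021", 14, 15, 1),
    ("15", "12/11/2021", "26/11/2021", 14, 22, 8),
    ("16", "30/11/2021", "28/12/2021", 28, 25, 3),
    ("17", "06/12/2021", "20/12/2021", 14, 16, 2),
)


def load_field_validation() -> pd.DataFrame:
    """Validation records as a frame with parsed dates and reference columns."""
    frame = pd.DataFrame(
        FIELD_VALIDATION_ROWS,
        columns=["shark_id", "initial_date", "recapture_date", "tal", "ptal", "abs_diff"],
    )
    frame["initial_date"] = frame["initial_date"].map(parse_date)
    frame["recapture_date"] = frame["recapture_date"].map(parse_date)
    return frame


def field_validation_histories() -> list[SharkHistory]:
    """The 17 capture/recapture pairs as :class:`SharkHistory` objects.

    Wound sizes were not published, so events carry dates only.
    """
    events: list[CaptureEvent] = []
    for shark_id, first, second, *_ in FIELD_VALIDATION_ROWS:
        events.append(CaptureEvent(shark_id=shark_id, date=parse_date(first)))
        events.append(CaptureEvent(shark_id=shark_id, date=parse_date(second)))
    return build_histories(events)
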