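"""Synthetic mark-recapture cohorts with the structure the analysis assumes.

The generator emulates a single parturition season of a gillnet survey for
neonatal blacktip reef sharks:

* per-shark umbilical-wound trajectories following the two healing curves —
  sqrt(area) linear in sqrt(age), perimeter linear in age — with per-shark
  random intercepts and measurement noise on the transformed scales (the
  scales on which the models are linear);
* a September–January multinomial birth-month distribution, realised as a
  continuous piecewise-linear daily parturition intensity whose month
  marginals equal the configured probabilities (a seasonal birth pulse does
  not jump at calendar-month boundaries);
* a small "time zero" subcohort of days-old neonates (umbilical-cord
  remnants present) that are deliberately recaptured, mirroring the field
  training set used to build the regressions (13 recaptured once, 3 twice);
* a survey cohort captured once at a uniform age within the sampling
  window, with Bernoulli recaptures;
* morphometrics: precaudal length around 41.7 ± 2.0 cm at birth with slow
  linear growth, and mass derived from a Fulton's-K condition factor that
  declines linearly with age (so body condition falls across wound classes).

Wound closure is a *state*, not a noisy measurement: an individual's wound
is closed from the first whole day at or after the larger of its two
noise-free x-intercepts, and closed wounds are recorded as exactly (0, 0).
Open wounds always have strictly positive measurements (mean-preserving
symmetric truncated-normal noise; an infinitesimal positive floor when the
noise SD is 0 or the individual curve has already reached zero), which
preserves the invariant that area and perimeter are zero together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr, ndtri

from .core import CaptureEvent

#: Season months in order (September through January; January belongs to the
#: calendar year after the season start).
SEASON_MONTHS: tuple[int, ...] = (9, 10, 11, 12, 1)

_SITES = (
    "Apaura", "Haapiti", "Maharepa", "Paorea", "Papetoai",
    "Pihaena", "Tiki", "Vaiane", "Vaiare", "Valorie",
)

#: Positive floor for open-wound measurements when the noise SD is zero.
_OPEN_FLOOR = 1e-9


@dataclass
class SyntheticConfig:
    """All generator parameters.

    Healing-curve coefficients default to the published Moorea estimates;
    variance components are not published and default to values calibrated
    (see ``scripts/calibrate_noise.py``) so that the end-to-end validation
    error, mean |TAL − pTAL| on recaptured synthetic neonates, lands in the
    3–7 day band reported for the field classification.
    """

    # healing-curve fixed effects: sqrt(area) = a0 - a1*sqrt(age),
    # perimeter = b0 - b1*age
    a0: float = 0.311          # sqrt(cm²) at age 0
    a1: float = 0.053          # sqrt(cm²) per sqrt(day)
    b0: float = 1.299          # cm at age 0
    b1: float = 0.037          # cm per day
    # variance components (random intercepts, measurement noise), on the
    # transformed scales
    sigma_id_area: float = 0.018
    sigma_id_perim: float = 0.07
    sigma_eps_area: float = 0.038
    sigma_eps_perim: float = 0.24
    # season: P(birth month) over SEASON_MONTHS, Sep..Jan
    month_probs: tuple[float, ...] = (0.052, 0.327, 0.413, 0.176, 0.032)
    season_start_year: int = 2016
    # sampling design
    n_sharks: int = 500            # survey sharks (excluding the time-zero subcohort)
    recapture_prob: float = 0.085
    capture_window: int = 45       # days post-birth during which capture can occur
    recapture_delay: tuple[int, int] = (7, 28)  # days between captures, inclusive
    n_timezero_once: int = 13      # time-zero sharks recaptured once
    n_timezero_twice: int = 3      # time-zero sharks recaptured twice
    cord_max_age: int = 2          # cord remnants persist through this age (days)
    # morphometrics
    pcl_birth_mean: float = 41.7   # cm
    pcl_birth_sd: float = 2.0      # cm
    pcl_growth_per_day: float = 0.03  # cm/day
    k_age0: float = 1.25           # Fulton's K at birth (10^5 kg cm^-3 scale)
    k_age60: float = 1.05          # Fulton's K at 60 days (floor thereafter)
    k_sd: float = 0.1              # per-event K noise
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.month_probs) - 1.0) > 1e-12:
            raise ValueError("month_probs must sum to 1")
        if len(self.month_probs) != len(SEASON_MONTHS):
            raise ValueError("month_probs must have one entry per season month")
        for name in ("sigma_id_area", "sigma_id_perim", "sigma_eps_area",
                     "sigma_eps_perim", "pcl_birth_sd", "k_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.recapture_prob <= 1.0:
            raise ValueError("recapture_prob must be in [0, 1]")
        if self.n_sharks < 0 or self.n_timezero_once < 0 or self.n_timezero_twice < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.capture_window <= 0:
            raise ValueError("capture_window must be positive")
        lo, hi = self.recapture_delay
        if not 0 < lo <= hi:
            raise ValueError("recapture_delay must satisfy 0 < lo <= hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("month_probs", "recapture_delay"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["month_probs"] = list(self.month_probs)
        data["recapture_delay"] = list(self.recapture_delay)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class TrueState:
    """Ground truth for one simulated shark (recovery-test oracle).

    ``ages`` are continuous: the birth instant falls at a uniform sub-day
    offset within ``birth_date``, so the true age at a capture differs from
    the whole-day date difference by up to half a day.
    """

    shark_id: str
    birth_date: date
    u_area: float            # random intercept, sqrt-area scale
    v_perim: float           # random intercept, perimeter scale
    ages: tuple[float, ...]  # true age (days) at each capture event
    closure_day: int         # first whole day with a closed wound

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.ages):
            raise ValueError("true ages must be >= 0")


def _month_year(month: int, season_start_year: int) -> int:
    return season_start_year if month >= 7 else season_start_year + 1


def _days_in_month(month: int, year: int) -> int:
    nxt = date(year + 1, 1, 1) if month == 12 else date(year, month + 1, 1)
    return (nxt - date(year, month, 1)).days


def _day_weights(config: SyntheticConfig) -> list[np.ndarray]:
    """Within-month birth-day weights from a smooth daily intensity.

    The seasonal birth pulse is modelled as a smooth (C¹) daily intensity:
    within each month a cubic smoothstep ramps between month-edge intensity
    values solved so that every month integrates exactly to its configured
    probability ((e_{i-1} + e_i)/2 · L_i = p_i, starting from zero at the
    season opening). The intensity is continuous with zero slope at every
    month boundary, and non-negative whenever the forward solve is (true
    for any unimodal probability vector); otherwise the generator falls
    back to uniform days within each month. A month-block-uniform density
    would jump at calendar-month boundaries, which no biological birth
    pulse does.
    """
    years = [_month_year(m, config.season_start_year) for m in SEASON_MONTHS]
    lengths = [_days_in_month(m, y) for m, y in zip(SEASON_MONTHS, years)]
    edges = [0.0]
    for p, L in zip(config.month_probs, lengths):
        edges.append(2.0 * p / L - edges[-1])
    smooth = all(e >= 0 for e in edges)
    weights = []
    for i, L in enumerate(lengths):
        if smooth:
            s = (np.arange(1, L + 1) - 0.5) / L
            ramp = 3.0 * s**2 - 2.0 * s**3  # zero slope at both edges
            w = edges[i] + (edges[i + 1] - edges[i]) * ramp
        else:
            w = np.full(L, 1.0 / L)
        total = w.sum()
        weights.append(w / total if total > 0 else np.full(L, 1.0 / L))
    return weights


def _draw_birth_ordinals(
    rng: np.random.Generator, n: int, config: SyntheticConfig
) -> np.ndarray:
    month_idx = rng.choice(len(SEASON_MONTHS), size=n, p=np.asarray(config.month_probs))
    weights = _day_weights(config)
    days = np.zeros(n, dtype=int)
    for i in range(len(SEASON_MONTHS)):
        mask = month_idx == i
        k = int(mask.sum())
        if k:
            days[mask] = rng.choice(len(weights[i]), size=k, p=weights[i]) + 1
    ordinals = np.empty(n, dtype=int)
    for j in range(n):
        m = SEASON_MONTHS[month_idx[j]]
        ordinals[j] = date(_month_year(m, config.season_start_year), m, int(days[j])).toordinal()
    return ordinals


def _observe_open(rng: np.random.Generator, mu: np.ndarray, sd: float) -> np.ndarray:
    """Noisy measurement of an open wound with noise-free mean ``mu``.

    Noise is a *symmetric* truncated normal on (0, 2·mu): the conditional
    mean stays exactly on the healing curve at every open age (an asymmetric
    clamp at zero would otherwise lift the curve tail and bias the fitted
    slopes even asymptotically), the measurement stays positive, and its
    spread shrinks as the wound vanishes — tiny wounds are traced with tiny
    absolute error. Where the individual's own curve has already reached
    zero while the other keeps the wound open, the measurement collapses to
    an infinitesimal positive floor (unmeasurably small but not healed).
    """
    mu = np.asarray(mu, dtype=float)
    out = np.full(mu.shape, _OPEN_FLOOR)
    pos = mu > _OPEN_FLOOR
    if sd == 0:
        out[pos] = mu[pos]
        return out
    half = ndtr(mu[pos] / sd) - 0.5  # P(0 < X - mu < mu) on either side
    u = rng.uniform(size=mu.shape)   # one draw per slot keeps streams aligned
    q = 0.5 + (2.0 * u[pos] - 1.0) * half
    q = np.clip(q, 1e-15, 1.0 - 1e-15)
    out[pos] = np.maximum(mu[pos] + sd * ndtri(q), _OPEN_FLOOR)
    return out


def _closure_day(a0i: float, a1: float, b0i: float, b1: float) -> int:
    x_area = (a0i / a1) ** 2 if a0i > 0 else 0.0
    x_perim = b0i / b1 if b0i > 0 else 0.0
    return int(math.ceil(max(x_area, x_perim)))


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[CaptureEvent], list[TrueState]]:
    """Simulate one season's cohort; fully reproducible from ``config.seed``.

    Returns the observable capture events and, separately, the ground truth
    per shark (birth date, random intercepts, true ages, closure day).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_tz = config.n_timezero_once + config.n_timezero_twice
    n = n_tz + config.n_sharks
    if n == 0:
        return [], []

    ids = [f"T{i + 1:03d}" for i in range(n_tz)] + [
        f"S{i + 1:05d}" for i in range(config.n_sharks)
    ]
    birth_ord = _draw_birth_ordinals(rng, n, config)
    u = rng.normal(0.0, config.sigma_id_area, size=n)
    v = rng.normal(0.0, config.sigma_id_perim, size=n)
    pcl_birth = rng.normal(config.pcl_birth_mean, config.pcl_birth_sd, size=n)
    sexes = rng.choice(["F", "M"], size=n)
    sites = rng.choice(_SITES, size=n)

    # Birth instants sit at a uniform sub-day offset within the birth date;
    # captures happen at the sampling hour, so the continuous age at a
    # capture is the whole-day date difference plus (offset - 1/2). A shark
    # cannot be caught before it is born, which halves the chance of a
    # capture on the birth date itself.
    birth_offset = rng.uniform(size=n)

    # capture ages per shark (whole days between dates)
    ages_per_shark: list[list[int]] = []
    lo, hi = config.recapture_delay
    for j in range(n):
        if j < n_tz:
            first = int(rng.integers(0, config.cord_max_age + 1))
            if first == 0 and birth_offset[j] < 0.5 and config.cord_max_age >= 1:
                first = int(rng.integers(1, config.cord_max_age + 1))
            n_rec = 2 if j < config.n_timezero_twice else 1
            ages = [first]
            for _ in range(n_rec):
                ages.append(ages[-1] + int(rng.integers(lo, hi + 1)))
        else:
            ages = [int(rng.integers(0, config.capture_window))]
            if ages[0] == 0 and birth_offset[j] < 0.5:
                ages[0] = int(rng.integers(1, config.capture_window))
            if rng.random() < config.recapture_prob:
                ages.append(ages[0] + int(rng.integers(lo, hi + 1)))
        ages_per_shark.append(ages)

    shark_idx = np.concatenate(
        [np.full(len(a), j, dtype=int) for j, a in enumerate(ages_per_shark)]
    )
    day_flat = np.concatenate([np.asarray(a, dtype=float) for a in ages_per_shark])
    age_flat = np.maximum(0.0, day_flat + birth_offset[shark_idx] - 0.5)

    closure = np.array(
        [
            _closure_day(config.a0 + u[j], config.a1, config.b0 + v[j], config.b1)
            for j in range(n)
        ]
    )
    open_mask = age_flat < closure[shark_idx]

    sqrt_area = np.zeros_like(age_flat)
    perim = np.zeros_like(age_flat)
    mu_a = (config.a0 + u[shark_idx] - config.a1 * np.sqrt(age_flat))[open_mask]
    mu_p = (config.b0 + v[shark_idx] - config.b1 * age_flat)[open_mask]
    sqrt_area[open_mask] = _observe_open(rng, mu_a, config.sigma_eps_area)
    perim[open_mask] = _observe_open(rng, mu_p, config.sigma_eps_perim)
    area = sqrt_area**2

    pcl = pcl_birth[shark_idx] + config.pcl_growth_per_day * age_flat
    k_slope = (config.k_age0 - config.k_age60) / 60.0
    k_true = np.maximum(config.k_age60, config.k_age0 - k_slope * age_flat)
    k_obs = np.maximum(0.3, k_true + rng.normal(0.0, config.k_sd, size=age_flat.shape))
    mass = k_obs * pcl**3 / 1e5

    events: list[CaptureEvent] = []
    states: list[TrueState] = []
    pos = 0
    for j in range(n):
        ages = ages_per_shark[j]
        birth = date.fromordinal(int(birth_ord[j]))
        true_ages = []
        for t in ages:
            is_open = bool(open_mask[pos])
            true_ages.append(float(age_flat[pos]))
            events.append(
                CaptureEvent(
                    shark_id=ids[j],
                    date=birth + timedelta(days=int(t)),
                    wound_area=float(area[pos]),
                    wound_perimeter=float(perim[pos]),
                    pcl=float(pcl[pos]),
                    mass=float(mass[pos]),
                    site=str(sites[j]),
                    sex=str(sexes[j]),
                    cord_remnants=bool(is_open and t <= config.cord_max_age),
                )
            )
            pos += 1
        states.append(
            TrueState(
                shark_id=ids[j],
                birth_date=birth,
                u_area=float(u[j]),
                v_perim=float(v[j]),
                ages=tuple(true_ages),
                closure_day=int(closure[j]),
            )
        )
    return events, states


def truth_to_frame(states: list[TrueState]) -> pd.DataFrame:
    """One row per capture event with the generating ground truth."""
    rows = []
    for st in states:
        for i, t in enumerate(st.ages):
            rows.append(
                {
                    "shark_id": st.shark_id,
                    "event_index": i,
                    "birth_date": st.birth_date,
                    "true_age_days": t,
                    "u_area": st.u_area,
                    "v_perim": st.v_perim,
                    "closure_day": st.closure_day,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "shark_id", "event_index", "birth_date", "true_age_days",
            "u_area", "v_perim", "closure_day",
        ],
    )


def training_pairs_from_truth(
    events: list[CaptureEvent], states: list[TrueState]
) -> pd.DataFrame:
    """(shark, true age, area, perimeter) rows for every event, via ground truth.

    The oracle counterpart of assembling training pairs from cord-remnant
    anchors: ages are the generator's continuous ground-truth ages, so every
    shark contributes regardless of whether it was caught days-old.
    Closed-wound rows are flagged, not dropped.
    """
    true_ages = {st.shark_id: list(st.ages) for st in states}
    seen: dict[str, int] = {}
    rows = []
    for ev in events:
        k = seen.get(ev.shark_id, 0)
        seen[ev.shark_id] = k + 1
        rows.append(
            {
                "shark_id": ev.shark_id,
                "age": float(true_ages[ev.shark_id][k]),
                "area": ev.wound_area,
                "perimeter": ev.wound_perimeter,
                "closed": bool(ev.wound_closed),
            }
        )
    return pd.DataFrame(rows, columns=["shark_id", "age", "area", "perimeter", "closed"])
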