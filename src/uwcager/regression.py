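"""Temporal wound-healing regressions fitted from recaptured days-old neonates.

Two models are fitted, each a linear mixed-effects model with a per-shark
random intercept, estimated by restricted maximum likelihood:

* sqrt(wound area)  = a0 - a1 * sqrt(age) + u_shark + error
* wound perimeter   = b0 - b1 * age      + v_shark + error

The "quadratic decline" of wound area is linear on the square-root scales;
the back-transformed curve (a0 - a1*sqrt(t))^2 is used for display and
inversion. Random slopes are not identifiable with at most three
observations per shark, so only intercepts vary. When the random-intercept
variance degenerates to (numerically) zero, or the mixed fit fails to
converge, the fit falls back to ordinary least squares and records the
fallback in its metadata.

Closed-wound observations (area and perimeter both exactly zero) are
recorded but excluded from the response: the linear models are unbounded
below, and zero-truncated points would bias the fit. For the same reason
each model also drops rows whose *own* response is unmeasurably small
(below 1e-6): a vanishing measurement on a still-open wound pins the curve
tail at zero and attenuates the slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .core import CaptureEvent, SharkHistory, elapsed_days

#: REML convergence tolerance on the log-likelihood.
_REML_TOL = 1e-8
#: Random-intercept variance below this (relative to residual) is degenerate.
_DEGENERATE_RATIO = 1e-6
#: Responses at or below this are treated as censored for that model.
_MEASURE_FLOOR = 1e-6

PAIR_COLUMNS = ("shark_id", "age", "area", "perimeter", "closed")


def assemble_training_pairs(histories: Sequence[SharkHistory]) -> pd.DataFrame:
    """Build (shark, age, area, perimeter) training rows from recapture histories.

    Only histories whose *first* event carries cord remnants qualify: the
    remnants anchor that event at age 0, and later events get their age from
    elapsed days. Cord remnants on a non-first event contradict the aging
    anchor (remnants are shed within days of birth) and raise an error.
    Closed-wound events are kept as rows with ``closed=True`` so callers can
    count them, but carry no usable response.
    """
    rows = []
    for h in histories:
        for ev in h.events[1:]:
            if ev.cord_remnants:
                raise ValueError(
                    f"shark {h.shark_id!r}: cord remnants on a non-first event "
                    "(inconsistent aging anchor)"
                )
        first = h.events[0]
        if not first.cord_remnants:
            continue
        for ev in h.events:
            if ev.wound_area is None or ev.wound_perimeter is None:
                continue
            rows.append(
                {
                    "shark_id": h.shark_id,
                    "age": float(elapsed_days(first.date, ev.date)),
                    "area": float(ev.wound_area),
                    "perimeter": float(ev.wound_perimeter),
                    "closed": bool(ev.wound_closed),
                }
            )
    return pd.DataFrame(rows, columns=list(PAIR_COLUMNS))


@dataclass
class WoundModelFit:
    """Fixed/random-effect estimates of the two healing regressions."""

    a0: float
    a1: float
    b0: float
    b1: float
    var_id_area: float
    var_id_perim: float
    var_eps_area: float
    var_eps_perim: float
    n_individuals: int
    n_observations: int
    method_area: str = "reml"   # "reml" or "ols" (fallback)
    method_perim: str = "reml"
    shrinking: bool = True      # False flags a non-shrinking (a1<=0 or b1<=0) fit

    def area_at(self, age) -> np.ndarray | float:
        """Mean wound area (cm²) at an age, truncated at zero."""
        return np.maximum(0.0, self.a0 - self.a1 * np.sqrt(age)) ** 2

    def perimeter_at(self, age) -> np.ndarray | float:
        """Mean wound perimeter (cm) at an age, truncated at zero."""
        return np.maximum(0.0, self.b0 - self.b1 * np.asarray(age, dtype=float))

    def to_dict(self) -> dict:
        return {
            "a0": self.a0, "a1": self.a1, "b0": self.b0, "b1": self.b1,
            "var_id_area": self.var_id_area, "var_id_perim": self.var_id_perim,
            "var_eps_area": self.var_eps_area, "var_eps_perim": self.var_eps_perim,
            "n_individuals": self.n_individuals,
            "n_observations": self.n_observations,
            "method_area": self.method_area, "method_perim": self.method_perim,
            "shrinking": self.shrinking,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "WoundModelFit":
        return cls(**{k: data[k] for k in cls.__dataclass_fields__ if k in data})


@dataclass(frozen=True)
class ClosureResult:
    """x-intercepts of the two healing curves and the integer closure day."""

    age_area: float
    age_perimeter: float
    closure_day: int


def closure_age(fit: WoundModelFit) -> ClosureResult:
    """Ages at which the fitted curves reach zero, and their ceiling in days.

    The wound is closed once *both* curves have reached zero, so the closure
    day is the ceiling of the larger x-intercept.
    """
    if fit.a1 <= 0 or fit.b1 <= 0:
        raise ValueError("closure age requires shrinking wounds (a1 > 0 and b1 > 0)")
    x_area = (fit.a0 / fit.a1) ** 2 if fit.a0 > 0 else 0.0
    x_perim = fit.b0 / fit.b1 if fit.b0 > 0 else 0.0
    return ClosureResult(
        age_area=x_area,
        age_perimeter=x_perim,
        closure_day=int(np.ceil(max(x_area, x_perim))),
    )


def _fit_single(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    """Fit y = c0 + c1*x with a per-group random intercept; REML with OLS fallback.

    Returns (intercept, slope, var_id, var_eps, method).
    """
    exog = sm.add_constant(x)
    n_groups = len(np.unique(groups))
    ols = sm.OLS(y, exog).fit()
    resid_var = float(ols.scale)
    use_ols = n_groups < 2 or len(y) - 2 <= 0
    if not use_ols:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, exog, groups=groups)
                result = model.fit(reml=True, method="lbfgs", tol=_REML_TOL)
            var_id = float(np.asarray(result.cov_re)[0, 0])
            var_eps = float(result.scale)
            degenerate = (
                not np.all(np.isfinite(result.params))
                or var_id <= _DEGENERATE_RATIO * max(var_eps, 1e-300)
            )
            if not degenerate:
                return (
                    float(result.fe_params[0]),
                    float(result.fe_params[1]),
                    var_id,
                    var_eps,
                    "reml",
                )
        except Exception:
            pass
    return float(ols.params[0]), float(ols.params[1]), 0.0, resid_var, "ols"


class WoundHealingModel(BaseEstimator):
    """Mixed-effects wound-healing regressions with an age-inversion predictor.

    Follows the scikit-learn estimator protocol: :meth:`fit` consumes a
    training-pair frame (``shark_id``, ``age``, ``area``, ``perimeter``,
    optional ``closed``), :meth:`predict` inverts the fitted curves to a
    per-event relative age in days.

    Parameters
    ----------
    min_individuals, min_observations, min_distinct_ages :
        Minimum data requirements for an identifiable fit.

    Attributes (after fit)
    ----------------------
    a0_, a1_, b0_, b1_ : fixed effects of the two curves.
    var_id_area_, var_eps_area_, var_id_perim_, var_eps_perim_ : variances.
    method_area_, method_perim_ : "reml", or "ols" after a degenerate fallback.
    n_individuals_, n_observations_ : training-set sizes (open wounds).
    """

    def __init__(
        self,
        min_individuals: int = 2,
        min_observations: int = 4,
        min_distinct_ages: int = 2,
    ):
        self.min_individuals = min_individuals
        self.min_observations = min_observations
        self.min_distinct_ages = min_distinct_ages

    def fit(self, pairs: pd.DataFrame, y=None) -> "WoundHealingModel":
        pairs = pd.DataFrame(pairs)
        for col in ("shark_id", "age", "area", "perimeter"):
            if col not in pairs.columns:
                raise ValueError(f"training pairs need column {col!r}")
        if "closed" in pairs.columns:
            open_pairs = pairs.loc[~pairs["closed"].astype(bool)]
        else:
            open_pairs = pairs.loc[
                (pairs["area"] > 0) | (pairs["perimeter"] > 0)
            ]
        open_pairs = open_pairs.dropna(subset=["age", "area", "perimeter"])
        n_obs = len(open_pairs)
        n_ind = open_pairs["shark_id"].nunique()
        if n_obs < self.min_observations:
            raise ValueError(
                f"{n_obs} open-wound observations < required {self.min_observations}"
            )
        if n_ind < self.min_individuals:
            raise ValueError(f"{n_ind} individuals < required {self.min_individuals}")
        if open_pairs["age"].nunique() < self.min_distinct_ages:
            raise ValueError("need at least two distinct ages to fit a slope")

        age = open_pairs["age"].to_numpy(dtype=float)
        groups = open_pairs["shark_id"].to_numpy()
        area = open_pairs["area"].to_numpy(dtype=float)
        perim = open_pairs["perimeter"].to_numpy(dtype=float)
        a_rows = area > _MEASURE_FLOOR
        p_rows = perim > _MEASURE_FLOOR
        if a_rows.sum() < self.min_observations or p_rows.sum() < self.min_observations:
            raise ValueError("too few measurable observations after censoring")
        c0, c1, vid, veps, meth = _fit_single(
            np.sqrt(area[a_rows]), np.sqrt(age[a_rows]), groups[a_rows]
        )
        self.a0_, self.a1_ = c0, -c1
        self.var_id_area_, self.var_eps_area_ = vid, veps
        self.method_area_ = meth
        c0, c1, vid, veps, meth = _fit_single(
            perim[p_rows], age[p_rows], groups[p_rows]
        )
        self.b0_, self.b1_ = c0, -c1
        self.var_id_perim_, self.var_eps_perim_ = vid, veps
        self.method_perim_ = meth
        self.n_individuals_ = int(n_ind)
        self.n_observations_ = int(n_obs)
        self.shrinking_ = bool(self.a1_ > 0 and self.b1_ > 0)
        if not self.shrinking_:
            warnings.warn(
                "non-shrinking wound fit (a1 <= 0 or b1 <= 0)", UserWarning
            )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Combined relative age (days) per event; NaN where censored/missing.

        ``X`` needs columns ``wound_area_cm2`` and ``wound_perimeter_cm`` (or
        ``area``/``perimeter``).
        """
        from .validation import invert_ages  # local import: avoid cycle

        X = pd.DataFrame(X)
        area_col = "wound_area_cm2" if "wound_area_cm2" in X.columns else "area"
        per_col = (
            "wound_perimeter_cm" if "wound_perimeter_cm" in X.columns else "perimeter"
        )
        fit = self.to_result()
        area = X[area_col].to_numpy(dtype=float)
        perim = X[per_col].to_numpy(dtype=float)
        return invert_ages(area, perim, fit)[2]

    def to_result(self) -> WoundModelFit:
        if not hasattr(self, "a0_"):
            raise ValueError("model is not fitted")
        return WoundModelFit(
            a0=self.a0_, a1=self.a1_, b0=self.b0_, b1=self.b1_,
            var_id_area=self.var_id_area_, var_id_perim=self.var_id_perim_,
            var_eps_area=self.var_eps_area_, var_eps_perim=self.var_eps_perim_,
            n_individuals=self.n_individuals_, n_observations=self.n_observations_,
            method_area=self.method_area_, method_perim=self.method_perim_,
            shrinking=self.shrinking_,
        )


def fit_wound_models(pairs: pd.DataFrame) -> WoundModelFit:
    """Fit both healing regressions from a training-pair frame."""
    return WoundHealingModel().fit(pairs).to_result()
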