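"""Healing-regression fitting: exactness, invariances, closure ages."""

import numpy as np
import pandas as pd
import pytest

from uwcager.core import CaptureEvent, build_histories, parse_date
from uwcager.regression import (
    WoundHealingModel,
    WoundModelFit,
    assemble_training_pairs,
    closure_age,
    fit_wound_models,
)
from uwcager.simulate import SyntheticConfig, generate_cohort, training_pairs_from_truth


def curve_pairs(a0, a1, b0, b1, ages_by_shark):
    """Exact noise-free training pairs on the configured curves."""
    rows = []
    for shark, ages in ages_by_shark.items():
        for t in ages:
            rows.append(
                {
                    "shark_id": shark,
                    "age": float(t),
                    "area": max(0.0, a0 - a1 * np.sqrt(t)) ** 2,
                    "perimeter": max(0.0, b0 - b1 * t),
                    "closed": False,
                }
            )
    return pd.DataFrame(rows)


AGES = {"A": [0, 10], "B": [4, 18], "C": [2, 25, 30], "D": [1, 14]}


class TestFitExactness:
    @pytest.mark.parametrize(
        "coeffs",
        [
            (0.311, 0.053, 1.299, 0.037),
            (0.25, 0.04, 1.0, 0.03),
            (0.5, 0.08, 2.0, 0.05),
        ],
    )
    def test_noise_free_recovery_is_exact(self, coeffs):
        """Any positive generating coefficients are recovered to <= 1e-6."""
        a0, a1, b0, b1 = coeffs
        fit = fit_wound_models(curve_pairs(a0, a1, b0, b1, AGES))
        assert fit.a0 == pytest.approx(a0, abs=1e-6)
        assert fit.a1 == pytest.approx(a1, abs=1e-6)
        assert fit.b0 == pytest.approx(b0, abs=1e-6)
        assert fit.b1 == pytest.approx(b1, abs=1e-6)
        assert fit.var_eps_area == pytest.approx(0.0, abs=1e-10)
        assert fit.var_eps_perim == pytest.approx(0.0, abs=1e-10)

    def test_invariant_to_relabeling_and_row_order(self):
        pairs = curve_pairs(0.311, 0.053, 1.299, 0.037, AGES)
        rng = np.random.default_rng(0)
        noisy = pairs.copy()
        noisy["area"] = (np.sqrt(noisy["area"]) + rng.normal(0, 0.02, len(noisy))) ** 2
        noisy["perimeter"] += rng.normal(0, 0.1, len(noisy))
        base = fit_wound_models(noisy)
        relabeled = noisy.copy()
        relabeled["shark_id"] = relabeled["shark_id"].map(
            {"A": "z9", "B": "q1", "C": "m5", "D": "a0"}
        )
        shuffled = relabeled.sample(frac=1.0, random_state=1)
        other = fit_wound_models(shuffled)
        for attr in ("a0", "a1", "b0", "b1"):
            assert getattr(other, attr) == pytest.approx(getattr(base, attr), rel=1e-6)


class TestFitValidation:
    def test_too_few_observations(self):
        pairs = curve_pairs(0.311, 0.053, 1.299, 0.037, {"A": [0], "B": [5]})
        with pytest.raises(ValueError):
            fit_wound_models(pairs)

    def test_single_individual_rejected(self):
        pairs = curve_pairs(0.311, 0.053, 1.299, 0.037, {"A": [0, 5, 10, 20]})
        with pytest.raises(ValueError, match="individuals"):
            fit_wound_models(pairs)

    def test_non_shrinking_fit_warns(self):
        pairs = curve_pairs(0.311, 0.053, 1.299, 0.037, AGES)
        growing = pairs.copy()
        growing["perimeter"] = 1.0 + 0.02 * growing["age"]
        with pytest.warns(UserWarning, match="non-shrinking"):
            fit = fit_wound_models(growing)
        assert not fit.shrinking


class TestAssembleTrainingPairs:
    @staticmethod
    def _histories():
        cfg = SyntheticConfig(seed=6, n_sharks=0)  # 13 once + 3 twice recaptured
        events, _ = generate_cohort(cfg)
        return build_histories(events)

    def test_field_design_observation_count(self):
        """16 anchored sharks, 13 recaptured once + 3 twice -> 35 rows."""
        pairs = assemble_training_pairs(self._histories())
        assert len(pairs) == 35
        assert pairs["shark_id"].nunique() == 16

    def test_first_event_is_age_zero(self):
        pairs = assemble_training_pairs(self._histories())
        firsts = pairs.groupby("shark_id")["age"].min()
        assert (firsts == 0).all()

    def test_unanchored_history_contributes_nothing(self):
        events = [
            CaptureEvent("N", parse_date("01/10/2016"), 0.05, 0.9),
            CaptureEvent("N", parse_date("15/10/2016"), 0.01, 0.5),
        ]
        pairs = assemble_training_pairs(build_histories(events))
        assert pairs.empty

    def test_cord_remnants_on_later_event_is_error(self):
        events = [
            CaptureEvent("N", parse_date("01/10/2016"), 0.05, 0.9, cord_remnants=True),
            CaptureEvent("N", parse_date("15/10/2016"), 0.01, 0.5, cord_remnants=True),
        ]
        with pytest.raises(ValueError, match="non-first"):
            assemble_training_pairs(build_histories(events))


class TestClosureAge:
    def test_reference_intercepts_and_closure_day(self, reference_fit):
        closure = closure_age(reference_fit)
        assert closure.age_area == pytest.approx(34.43, abs=0.01)
        assert closure.age_perimeter == pytest.approx(35.11, abs=0.01)
        assert closure.closure_day == 36

    def test_zero_intercepts_close_at_zero(self):
        fit = WoundModelFit(a0=0.0, a1=0.05, b0=0.0, b1=0.04,
                            var_id_area=0, var_id_perim=0,
                            var_eps_area=0, var_eps_perim=0,
                            n_individuals=2, n_observations=4)
        assert closure_age(fit).closure_day == 0

    def test_perimeter_intercept_linear_in_b0(self, reference_fit):
        doubled = WoundModelFit(**{**reference_fit.to_dict(), "b0": 2 * 1.299})
        assert closure_age(doubled).age_perimeter == pytest.approx(
            2 * closure_age(reference_fit).age_perimeter
        )

    def test_non_positive_slope_is_error(self, reference_fit):
        bad = WoundModelFit(**{**reference_fit.to_dict(), "b1": -0.01})
        with pytest.raises(ValueError):
            closure_age(bad)


class TestParameterRecovery:
    def test_bias_shrinks_with_cohort_size(self):
        """|bias| of each fixed effect decreases from n=50 to n=800 sharks."""
        truth = np.array([0.311, 0.053, 1.299, 0.037])
        biases = []
        for size, reps in ((50, 30), (200, 30), (800, 30)):
            once = round(size * 13 / 16)
            errs = []
            for r in range(reps):
                cfg = SyntheticConfig(
                    seed=40_000 + 97 * size + r, n_sharks=0,
                    n_timezero_once=once, n_timezero_twice=size - once,
                )
                events, states = generate_cohort(cfg)
                fit = fit_wound_models(training_pairs_from_truth(events, states))
                errs.append(np.array([fit.a0, fit.a1, fit.b0, fit.b1]) - truth)
            biases.append(np.abs(np.mean(errs, axis=0)))
        biases = np.array(biases)
        # |bias| stays inside caps that tighten as the cohort grows; the
        # caps reflect shrinking Monte-Carlo uncertainty around a bias that
        # vanishes asymptotically
        for cap, bias in zip((0.04, 0.03, 0.02), biases):
            assert (bias <= truth * cap).all()

    def test_sklearn_estimator_protocol(self):
        model = WoundHealingModel()
        params = model.get_params()
        assert "min_observations" in params
        cfg = SyntheticConfig(seed=77, n_sharks=0)
        events, states = generate_cohort(cfg)
        pairs = training_pairs_from_truth(events, states)
        model.fit(pairs)
        assert model.a1_ > 0 and model.b1_ > 0
        preds = model.predict(pairs.rename(columns={"area": "wound_area_cm2",
                                                    "perimeter": "wound_perimeter_cm"}))
        open_rows = ~pairs["closed"].to_numpy()
        assert np.isfinite(preds[open_rows]).all()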