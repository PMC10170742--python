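"""Tuning script for the generator's default variance components.

The field study reports no residual or random-intercept variances for the
healing regressions, so the generator's noise defaults are calibrated here
against two end-to-end targets, evaluated on the pipeline itself:

1. validation error: the mean |TAL - pTAL| on recaptured synthetic
   neonates should land in the 3-7 day band reported for the field
   classification (around 5 days), and
2. identifiability: the four fixed effects must remain recoverable to
   within 10% from a 200-shark tracked cohort, so parameter-recovery
   checks stay meaningful.

Run:  python scripts/calibrate_noise.py [--seeds N]

The chosen defaults (sigma_id_area=0.018, sigma_id_perim=0.07,
sigma_eps_area=0.038, sigma_eps_perim=0.24) are the row of this grid that
meets both targets; they are frozen in ``SyntheticConfig``.
"""

from __future__ import annotations

import argparse
import dataclasses

import numpy as np

import uwcager as u
from uwcager.simulate import training_pairs_from_truth

GRID = [
    # (sigma_id_area, sigma_id_perim, sigma_eps_area, sigma_eps_perim)
    (0.018, 0.07, 0.031, 0.171),
    (0.018, 0.07, 0.035, 0.190),
    (0.018, 0.07, 0.038, 0.240),   # frozen defaults
    (0.025, 0.08, 0.042, 0.270),
]

TRUTH = (0.311, 0.053, 1.299, 0.037)


def validation_error(sig: tuple, n_seeds: int) -> float:
    means = []
    for s in range(n_seeds):
        cfg = u.SyntheticConfig(
            seed=2000 + s, n_sharks=1500,
            sigma_id_area=sig[0], sigma_id_perim=sig[1],
            sigma_eps_area=sig[2], sigma_eps_perim=sig[3],
        )
        events, _ = u.generate_cohort(cfg)
        histories = u.build_histories(events)
        pairs = u.assemble_training_pairs(histories)
        fit = u.fit_wound_models(pairs)
        recs, _ = u.validate_cohort(histories, fit, set(pairs["shark_id"]))
        means.append(u.summarize_validation(recs).mean_abs_diff)
    return float(np.mean(means))


def recovery_rate(sig: tuple, n_seeds: int) -> float:
    ok = 0
    for s in range(n_seeds):
        cfg = u.SyntheticConfig(
            seed=1000 + s, n_sharks=0, n_timezero_once=162, n_timezero_twice=38,
            sigma_id_area=sig[0], sigma_id_perim=sig[1],
            sigma_eps_area=sig[2], sigma_eps_perim=sig[3],
        )
        events, states = u.generate_cohort(cfg)
        fit = u.fit_wound_models(training_pairs_from_truth(events, states))
        rel = [
            abs(est - tru) / tru
            for est, tru in zip((fit.a0, fit.a1, fit.b0, fit.b1), TRUTH)
        ]
        ok += max(rel) <= 0.10
    return ok / n_seeds


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seeds", type=int, default=20)
    args = parser.parse_args()
    print(f"{'id_area':>8} {'id_perim':>8} {'eps_area':>8} {'eps_perim':>9} "
          f"{'mean|TAL-pTAL|':>15} {'recovery<=10%':>14}")
    for sig in GRID:
        err = validation_error(sig, args.seeds)
        rec = recovery_rate(sig, args.seeds)
        print(f"{sig[0]:>8} {sig[1]:>8} {sig[2]:>8} {sig[3]:>9} "
              f"{err:>15.2f} {rec:>14.0%}")


if __name__ == "__main__":
    main()
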