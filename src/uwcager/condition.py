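"""Body condition (Fulton's K) and morphometric comparisons across UWCs.

Fulton's condition factor is computed on the 10^5 kg cm^-3 scale,

    K = 10^5 * M / PCL^3,

with mass M in kilograms and precaudal length PCL in centimetres, so a
well-conditioned neonate sits near K ≈ 1.2–1.4.

Group comparisons follow the field protocol: a Shapiro–Wilk normality
screen per group (W < 0.90 flags a departure; the screen is reported but
does not gate the ANOVA), a one-way ANOVA across wound classes, and Tukey
HSD pairwise comparisons at family α = 0.05 when groups differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

#: Shapiro–Wilk W below this flags non-normality in the screening step.
SHAPIRO_W_CRITICAL = 0.90

RESPONSES = ("pcl", "mass", "k")


def fulton_k(mass, pcl):
    """Fulton's condition factor 10^5 * mass / pcl^3 (kg, cm).

    Accepts scalars or arrays; all inputs must be strictly positive.
    """
    mass = np.asarray(mass, dtype=float)
    pcl = np.asarray(pcl, dtype=float)
    if np.any(mass <= 0) or np.any(pcl <= 0):
        raise ValueError("mass and precaudal length must be positive")
    out = 1e5 * mass / pcl**3
    return float(out) if out.ndim == 0 else out


def condition_records(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per-event condition table (shark_id, uwc, pcl, mass, k).

    Rows with a missing label, mass or length are dropped and counted; no
    imputation.
    """
    frame = labeled.loc[:, ["shark_id", "uwc", "pcl_cm", "mass_kg"]].rename(
        columns={"pcl_cm": "pcl", "mass_kg": "mass"}
    )
    n_before = len(frame)
    frame = frame.dropna(subset=["uwc", "pcl", "mass"])
    dropped = n_before - len(frame)
    if dropped:
        logger.info("%d events dropped from condition analysis (missing fields)", dropped)
    frame = frame[(frame["pcl"] > 0) & (frame["mass"] > 0)]
    frame["uwc"] = frame["uwc"].astype(int)
    frame["k"] = fulton_k(frame["mass"].to_numpy(), frame["pcl"].to_numpy())
    return frame.reset_index(drop=True)


@dataclass
class GroupComparison:
    """Normality screen, one-way ANOVA and Tukey HSD for one response."""

    response: str
    shapiro: pd.DataFrame          # group, n, W, p, flagged (W < 0.90)
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame            # group1, group2, meandiff, p_adj, reject
    excluded_groups: tuple = ()


def compare_groups(records: pd.DataFrame, response: str) -> GroupComparison:
    """Compare one morphometric response (pcl, mass or k) across UWC groups.

    Groups with fewer than two records are excluded with a warning. Requires
    at least two remaining groups.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}")
    groups: dict[int, np.ndarray] = {}
    excluded = []
    for label, sub in records.groupby("uwc"):
        values = sub[response].to_numpy(dtype=float)
        if len(values) < 2:
            excluded.append(int(label))
            logger.warning("UWC%d excluded from ANOVA (n=%d < 2)", label, len(values))
            continue
        groups[int(label)] = values
    if len(groups) < 2:
        raise ValueError("need at least two groups with two or more records")

    shapiro_rows = []
    for label, values in sorted(groups.items()):
        if len(values) >= 3 and np.ptp(values) > 0:
            w, p = stats.shapiro(values)
        else:
            w, p = np.nan, np.nan
        shapiro_rows.append(
            {
                "group": label,
                "n": len(values),
                "W": float(w),
                "p": float(p),
                "flagged": bool(w < SHAPIRO_W_CRITICAL) if np.isfinite(w) else False,
            }
        )

    f_stat, p_value = stats.f_oneway(*[groups[g] for g in sorted(groups)])
    n_total = sum(len(v) for v in groups.values())
    k = len(groups)

    values = np.concatenate([groups[g] for g in sorted(groups)])
    labels = np.concatenate(
        [np.full(len(groups[g]), g) for g in sorted(groups)]
    )
    hsd = pairwise_tukeyhsd(values, labels, alpha=0.05)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    ).rename(columns={"p-adj": "p_adj"})

    return GroupComparison(
        response=response,
        shapiro=pd.DataFrame(shapiro_rows),
        f_stat=float(f_stat),
        df_between=k - 1,
        df_within=n_total - k,
        p_value=float(p_value),
        tukey=tukey,
        excluded_groups=tuple(excluded),
    )
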