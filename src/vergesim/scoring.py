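"""Turn shot records into hitting deviation, HFV and total vergence.

Definitions
-----------
Hitting deviation (theta_HD) for a condition is the mean of the absolute
per-shot horizontal deviations.  Horizontal fusional vergence, a.k.a. total
vergence amplitude, is

    HFV = theta_CR - theta_HD

where theta_CR is the imposed camera-rotation demand.  Cohort summaries
aggregate in two stages: per-subject means first, then mean and SD across
subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .protocol import CONDITIONS

__all__ = [
    "ConditionSummary",
    "hfv",
    "summarize_condition",
    "summarize_cohort",
    "subject_condition_means",
    "bias_corrected_amplitude",
    "TABLE_ORDER",
]

logger = logging.getLogger(__name__)

#: Row order used by the report table: control, convergence, divergence.
TABLE_ORDER = ("CONTROL", "PFV10", "PFV20", "NFV10", "NFV20")


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    theta_cr_pd: float
    mean_abs_deviation_pd: float
    sd_deviation_pd: float
    total_vergence_pd: float
    n_subjects: int
    n_shots: int
    note: str = ""


def hfv(theta_cr_pd: float, theta_hd_pd: float) -> float:
    """Horizontal fusional vergence: ``theta_CR - theta_HD``, unclamped."""
    if theta_cr_pd < 0:
        raise ValueError(f"theta_CR must be >= 0, got {theta_cr_pd!r}")
    if theta_hd_pd < 0:
        raise ValueError(f"theta_HD must be >= 0, got {theta_hd_pd!r}")
    return theta_cr_pd - theta_hd_pd


def summarize_condition(records: pd.DataFrame, theta_cr_pd: float) -> ConditionSummary:
    """Summarize the shots of a single condition (single- or pooled-subject).

    Mean and SD are taken over the absolute per-shot deviations.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty set of shot records")
    conditions = records["condition"].unique()
    if len(conditions) != 1:
        raise ValueError(f"records mix conditions: {sorted(conditions)}")
    abs_dev = records["deviation_pd"].abs().to_numpy()
    mean_abs = float(abs_dev.mean())
    sd = float(abs_dev.std(ddof=1)) if len(abs_dev) > 1 else 0.0
    note = "" if theta_cr_pd > 0 else "control: total vergence is degenerate (0 - deviation)"
    return ConditionSummary(
        condition=str(conditions[0]),
        theta_cr_pd=theta_cr_pd,
        mean_abs_deviation_pd=mean_abs,
        sd_deviation_pd=sd,
        total_vergence_pd=hfv(theta_cr_pd, mean_abs),
        n_subjects=int(records["subject_id"].nunique()),
        n_shots=int(len(records)),
        note=note,
    )


def subject_condition_means(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-condition mean absolute deviation (long format)."""
    frame = records.assign(abs_dev=records["deviation_pd"].abs())
    out = (
        frame.groupby(["subject_id", "condition"], sort=True)["abs_dev"]
        .agg(mean_abs_deviation_pd="mean", n_shots="size")
        .reset_index()
    )
    return out


def summarize_cohort(records: pd.DataFrame) -> list[ConditionSummary]:
    """Two-stage cohort summary, ordered like the report table.

    Subjects missing a condition are excluded from that condition with a
    logged warning.
    """
    if len(records) == 0:
        raise ValueError("no shot records")
    per_subject = subject_condition_means(records)
    n_total_subjects = per_subject["subject_id"].nunique()
    summaries: list[ConditionSummary] = []
    present = [c for c in TABLE_ORDER if c in set(per_subject["condition"])]
    extra = sorted(set(per_subject["condition"]) - set(TABLE_ORDER))
    for label in present + extra:
        theta_cr = CONDITIONS[label].theta_cr_pd if label in CONDITIONS else float("nan")
        rows = per_subject[per_subject["condition"] == label]
        if rows["subject_id"].nunique() < n_total_subjects:
            missing = n_total_subjects - rows["subject_id"].nunique()
            logger.warning("condition %s: %d subject(s) have no shots; excluded", label, missing)
        means = rows["mean_abs_deviation_pd"].to_numpy()
        cohort_mean = float(means.mean())
        if len(means) > 1:
            cohort_sd = float(means.std(ddof=1))
            note = ""
        else:
            cohort_sd = 0.0
            note = "single subject: SD undefined, reported as 0"
        if theta_cr == 0:
            note = (note + "; " if note else "") + "control: total vergence is degenerate"
        summaries.append(
            ConditionSummary(
                condition=label,
                theta_cr_pd=theta_cr,
                mean_abs_deviation_pd=cohort_mean,
                sd_deviation_pd=cohort_sd,
                total_vergence_pd=hfv(theta_cr, cohort_mean) if theta_cr >= 0 else float("nan"),
                n_subjects=int(rows["subject_id"].nunique()),
                n_shots=int(rows["n_shots"].sum()),
                note=note,
            )
        )
    return summaries


def bias_corrected_amplitude(
    summary: ConditionSummary, control: ConditionSummary
) -> float:
    """Fusional-amplitude estimate with the baseline aiming error removed.

    Subtracts the control condition's mean deviation (pure aiming error)
    from the test condition's before applying the HFV formula:
    ``theta_CR - (theta_HD - theta_HD_control)``.  Useful when the test
    demand exceeds the amplitude, where the residual-demand model makes
    this an unbiased estimate of the amplitude itself.
    """
    if control.theta_cr_pd != 0:
        raise ValueError("control summary must have zero demand")
    corrected_hd = max(0.0, summary.mean_abs_deviation_pd - control.mean_abs_deviation_pd)
    return hfv(summary.theta_cr_pd, corrected_hd)


def summaries_to_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def render_table(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Report-style table: condition, total vergence, average deviation."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "condition": s.condition,
                "theta_cr_pd": s.theta_cr_pd,
                "total_vergence_pd": round(s.total_vergence_pd, 2),
                "average_deviation_pd": round(s.mean_abs_deviation_pd, 2),
                "sd_deviation_pd": round(s.sd_deviation_pd, 2),
                "n_subjects": s.n_subjects,
            }
        )
    return pd.DataFrame(rows)
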