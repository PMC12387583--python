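"""Paired comparisons against the control condition and SSQ scoring.

Gate logic: the paired differences are tested for normality with
Shapiro-Wilk at alpha = 0.05; if they pass, a two-tailed paired t-test is
used, otherwise the Wilcoxon signed-rank test.  SSQ items are ordinal and
always use the Wilcoxon branch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "ALPHA",
    "compare_paired",
    "compare_to_control",
    "holm_adjust",
    "ssq_summary",
    "SSQ_CSV_COLUMNS",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05

SSQ_CSV_COLUMNS = ["subject_id", "phase", "item", "score"]


@dataclass(frozen=True)
class ComparisonResult:
    condition: str
    reference: str
    test_used: str  # paired_t | wilcoxon_signed_rank
    normality_p: float
    p_value: float
    significant: bool
    n: int
    adjusted_p: float | None = None


def _wilcoxon_p(diff: np.ndarray) -> float:
    nonzero = diff[diff != 0]
    if len(nonzero) == 0:
        return 1.0  # all pairs tied: no evidence against the null
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.wilcoxon(nonzero, alternative="two-sided").pvalue)


def compare_paired(
    test_values: np.ndarray,
    reference_values: np.ndarray,
    condition: str = "",
    reference: str = "CONTROL",
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Paired two-tailed comparison with a Shapiro-Wilk normality gate."""
    test_values = np.asarray(test_values, dtype=float)
    reference_values = np.asarray(reference_values, dtype=float)
    if test_values.shape != reference_values.shape:
        raise ValueError("paired samples must have equal length")
    n = len(test_values)
    if n < 3:
        raise ValueError(f"paired comparison undefined for n < 3 (got n={n})")
    diff = test_values - reference_values

    if np.ptp(diff) == 0:
        # constant differences: Shapiro-Wilk is undefined; fall through to
        # the rank branch, which yields p = 1 when every difference is zero
        normality_p = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normality_p = float(sps.shapiro(diff).pvalue)

    if normality_p > alpha:
        test_used = "paired_t"
        p_value = float(sps.ttest_rel(test_values, reference_values).pvalue)
    else:
        test_used = "wilcoxon_signed_rank"
        p_value = _wilcoxon_p(diff)
    return ComparisonResult(
        condition=condition,
        reference=reference,
        test_used=test_used,
        normality_p=normality_p,
        p_value=p_value,
        significant=bool(p_value <= alpha),
        n=n,
    )


def compare_to_control(
    per_subject: pd.DataFrame,
    reference: str = "CONTROL",
    alpha: float = ALPHA,
    holm: bool = False,
) -> list[ComparisonResult]:
    """Compare each condition's per-subject mean deviations to the control.

    ``per_subject`` is the long-format table from
    :func:`vergesim.scoring.subject_condition_means`.  Only subjects with
    data in both conditions enter a comparison.
    """
    wide = per_subject.pivot(
        index="subject_id", columns="condition", values="mean_abs_deviation_pd"
    )
    if reference not in wide.columns:
        raise ValueError(f"reference condition {reference!r} absent from records")
    results = []
    for condition in [c for c in wide.columns if c != reference]:
        paired = wide[[condition, reference]].dropna()
        if len(paired) < len(wide):
            logger.warning(
                "comparison %s vs %s: %d subject(s) dropped (missing data)",
                condition, reference, len(wide) - len(paired),
            )
        results.append(
            compare_paired(
                paired[condition].to_numpy(),
                paired[reference].to_numpy(),
                condition=condition,
                reference=reference,
                alpha=alpha,
            )
        )
    if holm:
        results = holm_adjust(results, alpha=alpha)
    return results


def holm_adjust(
    results: list[ComparisonResult], alpha: float = ALPHA
) -> list[ComparisonResult]:
    """Holm step-down adjustment across a family of comparisons."""
    order = np.argsort([r.p_value for r in results])
    m = len(results)
    adjusted = [0.0] * m
    running_max = 0.0
    for rank, idx in enumerate(order):
        adj = min(1.0, (m - rank) * results[idx].p_value)
        running_max = max(running_max, adj)
        adjusted[idx] = running_max
    return [
        ComparisonResult(
            condition=r.condition,
            reference=r.reference,
            test_used=r.test_used,
            normality_p=r.normality_p,
            p_value=r.p_value,
            significant=bool(adjusted[i] <= alpha),
            n=r.n,
            adjusted_p=adjusted[i],
        )
        for i, r in enumerate(results)
    ]


def _validate_ssq(responses: pd.DataFrame) -> pd.DataFrame:
    missing = set(SSQ_CSV_COLUMNS) - set(responses.columns)
    if missing:
        raise ValueError(f"SSQ table missing columns: {sorted(missing)}")
    bad_phase = set(responses["phase"].unique()) - {"pre", "post"}
    if bad_phase:
        raise ValueError(f"SSQ phase must be 'pre' or 'post', got {sorted(bad_phase)}")
    scores = responses["score"]
    if not scores.isin([1, 2, 3, 4]).all():
        raise ValueError("SSQ scores must be integers in 1..4")
    return responses


def ssq_summary(responses: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Per-item pre/post means, delta and paired Wilcoxon p-value.

    Subjects missing one phase for an item are excluded pairwise (with a
    warning).  Raises if any item is left with fewer than two pairs.
    """
    responses = _validate_ssq(responses)
    rows = []
    for item, group in responses.groupby("item", sort=True):
        wide = group.pivot_table(
            index="subject_id", columns="phase", values="score", aggfunc="first"
        )
        for phase in ("pre", "post"):
            if phase not in wide.columns:
                wide[phase] = np.nan
        complete = wide[["pre", "post"]].dropna()
        dropped = len(wide) - len(complete)
        if dropped:
            logger.warning("SSQ item %r: %d subject(s) missing a phase; excluded", item, dropped)
        if len(complete) < 2:
            raise ValueError(
                f"SSQ item {item!r}: paired test undefined with {len(complete)} pair(s)"
            )
        pre = complete["pre"].to_numpy(dtype=float)
        post = complete["post"].to_numpy(dtype=float)
        p = _wilcoxon_p(post - pre)
        rows.append(
            {
                "item": item,
                "n": len(complete),
                "mean_pre": float(pre.mean()),
                "mean_post": float(post.mean()),
                "delta": float(post.mean() - pre.mean()),
                "p_value": p,
                "significant": bool(p <= alpha),
            }
        )
    return pd.DataFrame(rows)
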