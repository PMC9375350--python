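"""Adjusted caries increment (ADJCI) at the child level.

The crude increment — the count P of surfaces that progressed — is
inflated by examiner reversals.  The adjusted caries increment shrinks
it by the reversal rate implied by the R regressed surfaces among the
N surfaces that neither progressed nor regressed:

    ADJCI = P * N / (R + N)

When R + N = 0 (every surface progressed) the formula is 0/0 and the
natural limit P is returned.  ADJCI is always in [0, P]: the
adjustment can only shrink the crude count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CohortFrame, Risk, VISIT_BY_MONTHS
from .transitions import Cutoff, TransitionCounts, cohort_transition_table

__all__ = ["AdjciValue", "adjci", "adjci_from_counts_frame", "child_adjci", "increment_table"]

#: Label of the pooled (all-risk) row in increment tables.
POOLED = "ALL"


@dataclass(frozen=True)
class AdjciValue:
    value: float
    counts: TransitionCounts


def adjci(counts: TransitionCounts) -> AdjciValue:
    """Child-level adjusted caries increment from P/R/N counts."""
    if counts.R + counts.N == 0:
        return AdjciValue(float(counts.P), counts)
    return AdjciValue(counts.P * counts.N / (counts.R + counts.N), counts)


def adjci_from_counts_frame(counts: pd.DataFrame) -> pd.Series:
    """Vectorised ADJCI over a frame with integer columns P, R, N."""
    p = counts["P"].to_numpy(dtype=float)
    r = counts["R"].to_numpy(dtype=float)
    n = counts["N"].to_numpy(dtype=float)
    denom = r + n
    frac = np.divide(n, denom, out=np.ones_like(n), where=denom > 0)
    out = np.where(denom > 0, p * frac, p)
    return pd.Series(out, index=counts.index, name="adjci")


def child_adjci(cohort: CohortFrame, cutoff: Cutoff, months: int) -> pd.DataFrame:
    """Per-child ADJCI for one cumulative interval (observed children only).

    Returns columns ``child_id, risk, visit, cutoff, P, R, N, adjci``.
    """
    visit = VISIT_BY_MONTHS[months]
    counts = cohort_transition_table(cohort, cutoff, visit)
    counts["adjci"] = adjci_from_counts_frame(counts)
    return counts


def _cells(values: pd.DataFrame, cutoff: Cutoff, months: int) -> pd.DataFrame:
    rows = []
    for risk in [r.value for r in Risk] + [POOLED]:
        sub = values if risk == POOLED else values[values["risk"] == risk]
        n = len(sub)
        rows.append(
            {
                "cutoff": Cutoff(cutoff).value,
                "risk": risk,
                "months": months,
                "n": n,
                "mean": sub["adjci"].mean() if n else np.nan,
                "sd": sub["adjci"].std(ddof=1) if n > 1 else (0.0 if n == 1 else np.nan),
                "empty": n == 0,
            }
        )
    return pd.DataFrame(rows)


def increment_table(
    cohort: CohortFrame,
    cutoff: Cutoff,
    months: int,
    values: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean +/- SD of child-level ADJCI per risk stratum, plus a pooled row.

    By default only children observed at both interval ends contribute;
    pass ``values`` (a completed per-child frame with ``risk`` and
    ``adjci`` columns, e.g. one imputed dataset) to override.  A
    stratum with no contributing children is flagged ``empty`` with
    NaN mean, never reported as zero.  SD uses the n-1 denominator.
    """
    if values is None:
        values = child_adjci(cohort, cutoff, months)
    return _cells(values, cutoff, months)
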