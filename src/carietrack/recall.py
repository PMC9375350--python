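"""Risk-based recall-interval recommendations.

The rule: for each (risk stratum, diagnostic cutoff) cell, the
recommended months until the next examination is the earliest
follow-up interval (6, 12 or 18 months) whose adjusted p-value falls
below alpha — i.e. the earliest point at which a real caries
increment is demonstrable — and the 18-month study horizon when no
interval is significant.

The 6-month entry has no earlier reference interval; its evidence is
a one-sample t-test of the 6-month increments against zero, on the
same Bonferroni-adjusted scale as the 12-vs-6 and 18-vs-6 post hocs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data_model import Risk
from .transitions import Cutoff

__all__ = [
    "RecallRecommendation",
    "IncompleteEvidenceError",
    "recommend",
    "recommendation_table",
]

INTERVALS = (6, 12, 18)
HORIZON = 18


class IncompleteEvidenceError(ValueError):
    """A required interval p-value is missing."""


@dataclass(frozen=True)
class RecallRecommendation:
    risk: str
    cutoff: str
    months: int
    trigger: int | None  # earliest significant interval, or None
    pvalues: dict[int, float]
    override: bool = False


def recommend(
    risk: Risk | str,
    cutoff: Cutoff | str,
    pvalues: dict[int, float],
    alpha: float = 0.05,
) -> RecallRecommendation:
    """Recall months for one risk x cutoff cell from its p-value pattern.

    ``pvalues`` maps each interval in (6, 12, 18) to its adjusted
    p-value.  The recommendation is the earliest interval with
    p < alpha, else the 18-month horizon.
    """
    missing = [i for i in INTERVALS if i not in pvalues]
    if missing:
        raise IncompleteEvidenceError(f"missing p-values for intervals {missing}")
    trigger = next((i for i in INTERVALS if pvalues[i] < alpha), None)
    return RecallRecommendation(
        risk=Risk(risk).value,
        cutoff=Cutoff(cutoff).value,
        months=trigger if trigger is not None else HORIZON,
        trigger=trigger,
        pvalues={i: float(pvalues[i]) for i in INTERVALS},
    )


def recommendation_table(
    evidence: dict[tuple[str, str], dict[int, float]],
    alpha: float = 0.05,
    published_a6_override: bool = False,
) -> pd.DataFrame:
    """Apply :func:`recommend` to all 3 risks x 2 cutoffs.

    ``evidence`` maps (risk, cutoff) to the per-interval adjusted
    p-values.  Returns an audit table with one row per cell: risk,
    cutoff, months, trigger, and the three p-values.

    ``published_a6_override`` forces 6 months for every stratum under
    the A-6 cutoff regardless of the evidence.  This reproduces the
    published recommendation that once non-cavitated lesions are
    counted no stratum's recall should exceed 6 months — a policy
    stance that for the medium-risk stratum is not supported by its
    own (non-significant) increment comparisons; the flag exists so
    that departure from the evidence is explicit.
    """
    rows = []
    for cutoff in Cutoff:
        for risk in Risk:
            rec = recommend(risk, cutoff, evidence[(risk.value, cutoff.value)], alpha)
            months, override = rec.months, False
            if published_a6_override and cutoff is Cutoff.ALL_A_6 and months > 6:
                months, override = 6, True
            rows.append(
                {
                    "risk": risk.value,
                    "cutoff": cutoff.value,
                    "months": months,
                    "trigger": rec.trigger,
                    "override": override,
                    "p_6": rec.pvalues[6],
                    "p_12": rec.pvalues[12],
                    "p_18": rec.pvalues[18],
                    "alpha": alpha,
                }
            )
    return pd.DataFrame(rows)
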