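"""Surface-transition classification under a diagnostic cutoff.

Each surface's change from baseline to a follow-up visit is classified
as PROGRESSION, REGRESSION, or NEITHER after collapsing the
modified-ICDAS state under one of two diagnostic cutoffs:

* ``CAV_3_6`` — only cavitated lesions (ICDAS 3-6) count as decay;
  code A collapses to sound.
* ``ALL_A_6`` — non-cavitated code A lesions count as decay too.

The per-child counts (P, R, N) feed the adjusted caries increment.
Intervals are cumulative (baseline vs 6, 12, 18 months), not
consecutive-visit.

Classification rules (total over all 8x8 collapsed-state pairs):

* identical states, and anything starting from MISSING or CROWNED,
  are NEITHER (terminal states);
* onset or worsening of decay, loss of the surface, or restorative
  treatment of a sound/non-cavitated surface is PROGRESSION;
* return toward sound (including filled-to-sound) is REGRESSION;
* transitions from cavitated decay (filled or not) other than reversal
  to sound are NEITHER — restoration of an established cavity is
  expected care, not increment.

Biologically implausible reversals are deliberately not filtered: the
adjusted-increment formula corrects for examiner reversals in
aggregate and cannot distinguish plausible from implausible ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .data_model import Attendance, CohortFrame, SurfaceState

__all__ = [
    "Cutoff",
    "CollapsedState",
    "TransitionClass",
    "TransitionCounts",
    "UnobservedIntervalError",
    "collapse",
    "classify_transition",
    "count_transitions",
    "cohort_transition_table",
]


class Cutoff(str, Enum):
    """Diagnostic threshold for what counts as decay."""

    CAV_3_6 = "3-6"
    ALL_A_6 = "A-6"


class CollapsedState(str, Enum):
    """Surface state after applying a cutoff (8 values)."""

    SOUND = "SOUND"
    NONCAV = "NONCAV"
    CAV = "CAV"
    FILLED_SOUND = "FILLED_SOUND"
    FILLED_NONCAV = "FILLED_NONCAV"
    FILLED_CAV = "FILLED_CAV"
    MISSING = "MISSING"
    CROWNED = "CROWNED"


class TransitionClass(str, Enum):
    PROGRESSION = "PROGRESSION"
    REGRESSION = "REGRESSION"
    NEITHER = "NEITHER"


@dataclass(frozen=True)
class TransitionCounts:
    """Per-child counts of progressed / regressed / unchanged surfaces."""

    P: int
    R: int
    N: int

    def __post_init__(self) -> None:
        if self.P < 0 or self.R < 0 or self.N < 0:
            raise ValueError("transition counts must be non-negative")

    @property
    def total(self) -> int:
        return self.P + self.R + self.N


class UnobservedIntervalError(ValueError):
    """The child did not attend both ends of the requested interval."""


_CAV = {SurfaceState.CAV3, SurfaceState.CAV4, SurfaceState.CAV5, SurfaceState.CAV6}


def collapse(state: SurfaceState, cutoff: Cutoff) -> CollapsedState:
    """Collapse a modified-ICDAS state under a diagnostic cutoff.

    Under ``CAV_3_6`` the non-cavitated code A maps to SOUND (and
    FILLED_NONCAV to FILLED_SOUND); under ``ALL_A_6`` it stays a
    lesion.  Codes 3-6 always map to CAV.
    """
    state = SurfaceState(state)
    if state in _CAV:
        return CollapsedState.CAV
    if state is SurfaceState.NONCAV_A:
        return CollapsedState.SOUND if cutoff is Cutoff.CAV_3_6 else CollapsedState.NONCAV
    if state is SurfaceState.FILLED_NONCAV:
        return (
            CollapsedState.FILLED_SOUND
            if cutoff is Cutoff.CAV_3_6
            else CollapsedState.FILLED_NONCAV
        )
    return CollapsedState(state.value)


_S = CollapsedState
_TERMINAL = {_S.MISSING, _S.CROWNED}
_FROM_CAV_REGRESSIONS = {
    (_S.CAV, _S.SOUND),
    (_S.FILLED_CAV, _S.SOUND),
    (_S.FILLED_CAV, _S.FILLED_NONCAV),
}


def classify_transition(before: CollapsedState, after: CollapsedState) -> TransitionClass:
    """Classify one collapsed-state pair; total over all 8x8 pairs."""
    before, after = CollapsedState(before), CollapsedState(after)
    if before is after:
        return TransitionClass.NEITHER
    if before in _TERMINAL:
        return TransitionClass.NEITHER
    if before in (_S.CAV, _S.FILLED_CAV):
        if (before, after) in _FROM_CAV_REGRESSIONS:
            return TransitionClass.REGRESSION
        return TransitionClass.NEITHER
    if before is _S.SOUND:
        return TransitionClass.PROGRESSION
    if before is _S.NONCAV:
        if after is _S.SOUND:
            return TransitionClass.REGRESSION
        return TransitionClass.PROGRESSION
    if before is _S.FILLED_SOUND:
        if after is _S.SOUND:
            return TransitionClass.REGRESSION
        return TransitionClass.PROGRESSION
    # before is FILLED_NONCAV
    if after in (_S.SOUND, _S.FILLED_SOUND):
        return TransitionClass.REGRESSION
    if after is _S.NONCAV:
        return TransitionClass.NEITHER
    return TransitionClass.PROGRESSION


# Integer-coded lookup tables for vectorised classification.
_STATES = list(SurfaceState)
_STATE_CODE = {s.value: i for i, s in enumerate(_STATES)}
_COLLAPSED = list(CollapsedState)
_COLLAPSED_CODE = {s: i for i, s in enumerate(_COLLAPSED)}
_CLASSES = (TransitionClass.PROGRESSION, TransitionClass.REGRESSION, TransitionClass.NEITHER)
_CLASS_CODE = {c: i for i, c in enumerate(_CLASSES)}

_COLLAPSE_LUT = {
    cut: np.array([_COLLAPSED_CODE[collapse(s, cut)] for s in _STATES]) for cut in Cutoff
}
_CLASSIFY_LUT = np.array(
    [[_CLASS_CODE[classify_transition(b, a)] for a in _COLLAPSED] for b in _COLLAPSED]
)


def _classified_pairs(cohort: CohortFrame, follow_up_visit: int, cutoff: Cutoff) -> pd.DataFrame:
    """Pair baseline with follow-up observations and classify each surface.

    Surfaces newly present at follow-up (erupted between visits) are
    classified against an implied SOUND baseline; surfaces seen only at
    baseline are excluded.
    """
    cutoff = Cutoff(cutoff)
    base = cohort.observations_at(0)[["child_id", "tooth", "surface", "condition"]]
    fup = cohort.observations_at(follow_up_visit)[["child_id", "tooth", "surface", "condition"]]
    pairs = base.merge(
        fup, on=["child_id", "tooth", "surface"], how="right", suffixes=("_before", "_after")
    )
    pairs["condition_before"] = pairs["condition_before"].fillna(SurfaceState.SOUND.value)

    before_raw = pairs["condition_before"].map(_STATE_CODE).to_numpy()
    after_raw = pairs["condition_after"].map(_STATE_CODE).to_numpy()
    lut = _COLLAPSE_LUT[cutoff]
    b, a = lut[before_raw], lut[after_raw]
    cls = _CLASSIFY_LUT[b, a]

    out = pairs[["child_id", "tooth", "surface"]].copy()
    out["before"] = [_COLLAPSED[i].value for i in b]
    out["after"] = [_COLLAPSED[i].value for i in a]
    out["transition"] = [_CLASSES[i].value for i in cls]
    out["visit"] = follow_up_visit
    out["cutoff"] = cutoff.value
    return out


def count_transitions(
    cohort: CohortFrame, child_id: str, follow_up_visit: int, cutoff: Cutoff
) -> tuple[TransitionCounts, pd.DataFrame]:
    """Count P/R/N for one child over baseline -> ``follow_up_visit``.

    Returns the counts plus the audit table of per-surface
    classifications (columns ``child_id, visit, tooth, surface, before,
    after, transition, cutoff``).

    Raises
    ------
    UnobservedIntervalError
        If the child was absent or dropped at either end of the
        interval; callers route such children to imputation.
    """
    att = cohort.children.set_index("child_id")
    if child_id not in att.index:
        raise KeyError(f"unknown child {child_id!r}")
    for v in (0, follow_up_visit):
        if att.loc[child_id, f"att{v}"] != Attendance.ATTENDED.value:
            raise UnobservedIntervalError(
                f"child {child_id} did not attend visit {v}; interval unobserved"
            )
    sub = CohortFrame(
        cohort.children[cohort.children["child_id"] == child_id],
        cohort.observations[cohort.observations["child_id"] == child_id],
    )
    audit = _classified_pairs(sub, follow_up_visit, cutoff)
    counts = TransitionCounts(
        P=int((audit["transition"] == TransitionClass.PROGRESSION.value).sum()),
        R=int((audit["transition"] == TransitionClass.REGRESSION.value).sum()),
        N=int((audit["transition"] == TransitionClass.NEITHER.value).sum()),
    )
    return counts, audit


def cohort_transition_table(
    cohort: CohortFrame, cutoff: Cutoff, follow_up_visit: int
) -> pd.DataFrame:
    """P/R/N per child for every child observed at both interval ends.

    Children absent or dropped at baseline or at the follow-up are
    omitted (they are imputation's concern).  Returns a frame with
    columns ``child_id, risk, visit, cutoff, P, R, N``.
    """
    cutoff = Cutoff(cutoff)
    observed = cohort.attended_ids(0) & cohort.attended_ids(follow_up_visit)
    sub = CohortFrame(
        cohort.children[cohort.children["child_id"].isin(observed)],
        cohort.observations[
            cohort.observations["child_id"].isin(observed)
            & cohort.observations["visit"].isin([0, follow_up_visit])
        ],
    )
    audit = _classified_pairs(sub, follow_up_visit, cutoff)
    counts = (
        audit.pivot_table(
            index="child_id", columns="transition", aggfunc="size", fill_value=0
        )
        .reindex(columns=[c.value for c in _CLASSES], fill_value=0)
        .rename(
            columns={
                TransitionClass.PROGRESSION.value: "P",
                TransitionClass.REGRESSION.value: "R",
                TransitionClass.NEITHER.value: "N",
            }
        )
        .reindex(sorted(observed), fill_value=0)
    )
    counts.index.name = "child_id"
    out = counts.reset_index()
    out.insert(1, "risk", out["child_id"].map(cohort.risk_of()))
    out.insert(2, "visit", follow_up_visit)
    out.insert(3, "cutoff", cutoff.value)
    return out
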