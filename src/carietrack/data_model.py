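"""Domain types and file I/O for longitudinal surface-level caries data.

The central container is :class:`CohortFrame`: a long-format exam table
(one row per child x visit x tooth x surface, holding a modified-ICDAS
surface condition) together with per-child metadata (risk stratum,
sociodemographics, per-visit attendance).

Conventions
-----------
* Teeth use FDI two-digit notation; the dentition is fixed to the 28
  permanent teeth 11-17, 21-27, 31-37, 41-47 (third molars excluded,
  matching an 11-12-year-old study population).
* Every tooth carries the same five surface slots (mesial, occlusal,
  distal, buccal, lingual); for anterior teeth OCCLUSAL is read as the
  incisal edge.
* Visits are indexed 0-3 at a fixed six-month spacing (0, 6, 12, 18
  months from baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "SurfaceState",
    "Surface",
    "Risk",
    "Sex",
    "Residence",
    "SchoolType",
    "Attendance",
    "PERMANENT_TEETH",
    "VISITS",
    "MONTHS_BY_VISIT",
    "VISIT_BY_MONTHS",
    "Violation",
    "CohortFrame",
    "CohortParseError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]


class SurfaceState(str, Enum):
    """Modified-ICDAS condition of one tooth surface at one visit.

    ``NONCAV_A`` is the merged ICDAS code A (codes 1 and 2, initial
    non-cavitated lesions); ``CAV3``..``CAV6`` map to ICDAS codes 3-6
    (cavitated).  The ``FILLED_*`` states carry the restorative status
    with the lesion severity of any decay associated with the filling.
    """

    SOUND = "SOUND"
    NONCAV_A = "NONCAV_A"
    CAV3 = "CAV3"
    CAV4 = "CAV4"
    CAV5 = "CAV5"
    CAV6 = "CAV6"
    FILLED_SOUND = "FILLED_SOUND"
    FILLED_NONCAV = "FILLED_NONCAV"
    FILLED_CAV = "FILLED_CAV"
    MISSING = "MISSING"
    CROWNED = "CROWNED"


class Surface(str, Enum):
    MESIAL = "MESIAL"
    OCCLUSAL = "OCCLUSAL"
    DISTAL = "DISTAL"
    BUCCAL = "BUCCAL"
    LINGUAL = "LINGUAL"


class Risk(str, Enum):
    LOW = "LOW"
    MEDIUM = "MEDIUM"
    HIGH = "HIGH"


class Sex(str, Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"


class Residence(str, Enum):
    URBAN = "URBAN"
    RURAL = "RURAL"


class SchoolType(str, Enum):
    PUBLIC = "PUBLIC"
    PRIVATE = "PRIVATE"


class Attendance(str, Enum):
    ATTENDED = "ATTENDED"
    ABSENT = "ABSENT"
    DROPPED = "DROPPED"


#: FDI numbers of the 28 permanent teeth scored (third molars excluded).
PERMANENT_TEETH: tuple[int, ...] = tuple(
    10 * q + t for q in (1, 2, 3, 4) for t in range(1, 8)
)

VISITS: tuple[int, ...] = (0, 1, 2, 3)
MONTHS_BY_VISIT: dict[int, int] = {v: 6 * v for v in VISITS}
VISIT_BY_MONTHS: dict[int, int] = {6 * v: v for v in VISITS}

_OBS_COLUMNS = ["child_id", "visit", "tooth", "surface", "condition"]
_ATT_COLUMNS = ["att0", "att1", "att2", "att3"]
_CHILD_COLUMNS = ["child_id", "risk", "sex", "residence", "school_type", *_ATT_COLUMNS]


class CohortParseError(ValueError):
    """A file token could not be parsed into a domain value."""


class CohortValidationError(ValueError):
    """The parsed data violates a cohort invariant."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        msg = "; ".join(str(v) for v in violations[:10])
        if len(violations) > 10:
            msg += f" ... ({len(violations)} total)"
        super().__init__(msg)


@dataclass(frozen=True)
class Violation:
    """One broken invariant, located as precisely as the rule allows."""

    rule: str
    child_id: str
    visit: int | None = None
    tooth: int | None = None
    surface: str | None = None
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f"child {self.child_id}"
        if self.visit is not None:
            loc += f", visit {self.visit}"
        if self.tooth is not None:
            loc += f", tooth {self.tooth} {self.surface}"
        return f"[{self.rule}] {loc}: {self.detail}"


@dataclass
class CohortFrame:
    """Long-format longitudinal exam data plus child metadata.

    Attributes
    ----------
    children:
        One row per child: ``child_id, risk, sex, residence,
        school_type, att0..att3`` (attendance flag per visit).
    observations:
        One row per observed surface: ``child_id, visit, tooth,
        surface, condition``.
    """

    children: pd.DataFrame
    observations: pd.DataFrame

    def __post_init__(self) -> None:
        self.children = self.children.reindex(columns=_CHILD_COLUMNS)
        self.observations = self.observations.reindex(columns=_OBS_COLUMNS)

    @property
    def child_ids(self) -> pd.Series:
        return self.children["child_id"]

    def attendance(self, visit: int) -> pd.Series:
        """Attendance flag per child_id at one visit."""
        return self.children.set_index("child_id")[f"att{visit}"]

    def attended_ids(self, visit: int) -> set[str]:
        att = self.attendance(visit)
        return set(att.index[att == Attendance.ATTENDED.value])

    def observations_at(self, visit: int) -> pd.DataFrame:
        return self.observations[self.observations["visit"] == visit]

    def risk_of(self) -> pd.Series:
        return self.children.set_index("child_id")["risk"]

    def n_children(self) -> int:
        return len(self.children)

    def sorted(self) -> "CohortFrame":
        """Copy with deterministic row ordering."""
        ch = self.children.sort_values("child_id", kind="mergesort").reset_index(drop=True)
        obs = self.observations.sort_values(
            ["child_id", "visit", "tooth", "surface"], kind="mergesort"
        ).reset_index(drop=True)
        return CohortFrame(ch, obs)

    def equals(self, other: "CohortFrame") -> bool:
        a, b = self.sorted(), other.sorted()
        return a.children.equals(b.children) and a.observations.equals(b.observations)


def _parse_enum(series: pd.Series, enum_cls, column: str) -> pd.Series:
    """Case-insensitive parsing of an enum column; names the bad row."""
    upper = series.astype(str).str.strip().str.upper()
    valid = {e.value for e in enum_cls}
    bad = ~upper.isin(valid)
    if bad.any():
        i = bad.idxmax()
        raise CohortParseError(
            f"unknown {column} token {series[i]!r} at row {i} "
            f"(expected one of {sorted(valid)})"
        )
    return upper


def read_cohort(exams_path: str | Path, children_path: str | Path) -> CohortFrame:
    """Read and validate a cohort from the two CSV files.

    Raises
    ------
    CohortParseError
        On an unknown enumeration token (names the offending row).
    CohortValidationError
        On duplicate surface rows, observations at unattended visits,
        or any other broken invariant.
    """
    obs = pd.read_csv(exams_path, dtype={"child_id": str})
    ch = pd.read_csv(children_path, dtype={"child_id": str})
    missing = [c for c in _OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise CohortParseError(f"exam file missing columns {missing}")
    missing = [c for c in _CHILD_COLUMNS if c not in ch.columns]
    if missing:
        raise CohortParseError(f"children file missing columns {missing}")

    obs = obs[_OBS_COLUMNS].copy()
    ch = ch[_CHILD_COLUMNS].copy()
    obs["condition"] = _parse_enum(obs["condition"], SurfaceState, "condition")
    obs["surface"] = _parse_enum(obs["surface"], Surface, "surface")
    obs["visit"] = pd.to_numeric(obs["visit"], errors="raise").astype(int)
    obs["tooth"] = pd.to_numeric(obs["tooth"], errors="raise").astype(int)
    ch["risk"] = _parse_enum(ch["risk"], Risk, "risk")
    ch["sex"] = _parse_enum(ch["sex"], Sex, "sex")
    ch["residence"] = _parse_enum(ch["residence"], Residence, "residence")
    ch["school_type"] = _parse_enum(ch["school_type"], SchoolType, "school_type")
    for c in _ATT_COLUMNS:
        ch[c] = _parse_enum(ch[c], Attendance, c)

    cohort = CohortFrame(ch, obs)
    violations = validate_cohort(cohort)
    if violations:
        raise CohortValidationError(violations)
    return cohort


def write_cohort(
    cohort: CohortFrame, exams_path: str | Path, children_path: str | Path
) -> None:
    """Write the two CSV files with deterministic row ordering."""
    s = cohort.sorted()
    s.observations.to_csv(exams_path, index=False)
    s.children.to_csv(children_path, index=False)


def _enum_violations(
    frame: pd.DataFrame, column: str, enum_cls, rule: str, out: list[Violation]
) -> None:
    valid = {e.value for e in enum_cls}
    for _, row in frame[~frame[column].isin(valid)].iterrows():
        out.append(
            Violation(
                rule=rule,
                child_id=str(row.get("child_id", "?")),
                visit=int(row["visit"]) if "visit" in row else None,
                detail=f"invalid {column} {row[column]!r}",
            )
        )


def validate_cohort(cohort: CohortFrame) -> list[Violation]:
    """Check every cohort invariant; violations are data, not exceptions.

    Returns the empty list iff the cohort is valid.  Rules checked:
    tooth/surface/condition domains, duplicate surface rows, unknown
    child ids, observations at unattended visits, dropped-is-absorbing
    attendance, and missing-is-absorbing surface state.
    """
    out: list[Violation] = []
    ch, obs = cohort.children, cohort.observations

    dup = ch["child_id"].duplicated()
    for cid in ch.loc[dup, "child_id"]:
        out.append(Violation("unique-child", str(cid), detail="duplicate child_id"))

    _enum_violations(obs, "condition", SurfaceState, "condition-domain", out)
    _enum_violations(obs, "surface", Surface, "surface-domain", out)
    _enum_violations(ch, "risk", Risk, "risk-domain", out)
    for c in _ATT_COLUMNS:
        _enum_violations(ch, c, Attendance, "attendance-domain", out)

    bad_tooth = ~obs["tooth"].isin(PERMANENT_TEETH)
    for _, row in obs[bad_tooth].iterrows():
        out.append(
            Violation(
                "tooth-domain",
                str(row["child_id"]),
                int(row["visit"]),
                int(row["tooth"]),
                str(row["surface"]),
                detail="not one of the 28 permanent teeth 11-47 (no third molars)",
            )
        )

    dup = obs.duplicated(subset=["child_id", "visit", "tooth", "surface"])
    for _, row in obs[dup].iterrows():
        out.append(
            Violation(
                "unique-surface",
                str(row["child_id"]),
                int(row["visit"]),
                int(row["tooth"]),
                str(row["surface"]),
                detail="duplicate observation",
            )
        )

    known = set(ch["child_id"])
    for cid in obs.loc[~obs["child_id"].isin(known), "child_id"].unique():
        out.append(Violation("known-child", str(cid), detail="observation for unknown child"))

    # Dropout is absorbing in the attendance flags.
    att = ch[_ATT_COLUMNS].to_numpy()
    for i, row in enumerate(att):
        dropped = False
        for v, flag in enumerate(row):
            if dropped and flag != Attendance.DROPPED.value:
                out.append(
                    Violation(
                        "dropped-absorbing",
                        str(ch["child_id"].iloc[i]),
                        v,
                        detail=f"status {flag} after DROPPED",
                    )
                )
            dropped = dropped or flag == Attendance.DROPPED.value

    # Observations only at attended visits.
    att_long = ch.melt(
        id_vars="child_id", value_vars=_ATT_COLUMNS, var_name="att", value_name="flag"
    )
    att_long["visit"] = att_long["att"].str[-1].astype(int)
    merged = obs.merge(att_long[["child_id", "visit", "flag"]], on=["child_id", "visit"], how="left")
    not_attended = merged["flag"].notna() & (merged["flag"] != Attendance.ATTENDED.value)
    for _, row in merged[not_attended].drop_duplicates(["child_id", "visit"]).iterrows():
        out.append(
            Violation(
                "observed-implies-attended",
                str(row["child_id"]),
                int(row["visit"]),
                detail=f"observations present while {row['flag']}",
            )
        )

    # MISSING is absorbing per surface.
    valid_cond = obs["condition"].isin({e.value for e in SurfaceState})
    o = obs[valid_cond].sort_values(["child_id", "tooth", "surface", "visit"], kind="mergesort")
    grp = o.groupby(["child_id", "tooth", "surface"], sort=False)
    was_missing = (
        (o["condition"] == SurfaceState.MISSING.value).groupby(grp.ngroup().values).cummax()
    )
    relapse = was_missing.to_numpy() & (o["condition"] != SurfaceState.MISSING.value).to_numpy()
    for _, row in o[relapse].iterrows():
        out.append(
            Violation(
                "missing-absorbing",
                str(row["child_id"]),
                int(row["visit"]),
                int(row["tooth"]),
                str(row["surface"]),
                detail=f"{row['condition']} after MISSING",
            )
        )

    return out
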