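"""Cohort container, CSV round-trip, and invariant validation."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from carietrack.data_model import (
    Attendance,
    CohortFrame,
    CohortParseError,
    CohortValidationError,
    SurfaceState,
    read_cohort,
    validate_cohort,
    write_cohort,
)
from conftest import build_cohort, child_row, uniform_child_obs


def write_files(tmp_path, exams_text, children_text):
    e = tmp_path / "exams.csv"
    c = tmp_path / "children.csv"
    e.write_text(exams_text)
    c.write_text(children_text)
    return e, c


CHILD_HEADER = "child_id,risk,sex,residence,school_type,att0,att1,att2,att3\n"
EXAM_HEADER = "child_id,visit,tooth,surface,condition\n"
ONE_CHILD = CHILD_HEADER + "c1,LOW,MALE,URBAN,PUBLIC,ATTENDED,ATTENDED,ATTENDED,ATTENDED\n"


class TestReadCohort:
    def test_minimal_valid_file(self, tmp_path):
        e, c = write_files(tmp_path, EXAM_HEADER + "c1,0,16,OCCLUSAL,SOUND\n", ONE_CHILD)
        cohort = read_cohort(e, c)
        assert cohort.n_children() == 1
        assert len(cohort.observations) == 1
        assert cohort.observations.iloc[0]["condition"] == "SOUND"

    def test_case_insensitive_tokens(self, tmp_path):
        e, c = write_files(
            tmp_path,
            EXAM_HEADER + "c1,0,16,occlusal,sound\n",
            CHILD_HEADER + "c1,low,male,Urban,public,attended,attended,attended,attended\n",
        )
        cohort = read_cohort(e, c)
        assert cohort.children.iloc[0]["risk"] == "LOW"
        assert cohort.observations.iloc[0]["surface"] == "OCCLUSAL"

    def test_unknown_condition_names_row(self, tmp_path):
        e, c = write_files(
            tmp_path,
            EXAM_HEADER + "c1,0,16,OCCLUSAL,SOUND\nc1,0,16,MESIAL,WIBBLE\n",
            ONE_CHILD,
        )
        with pytest.raises(CohortParseError, match="WIBBLE"):
            read_cohort(e, c)

    def test_third_molar_rejected(self, tmp_path):
        e, c = write_files(tmp_path, EXAM_HEADER + "c1,0,18,OCCLUSAL,SOUND\n", ONE_CHILD)
        with pytest.raises(CohortValidationError, match="tooth"):
            read_cohort(e, c)

    def test_duplicate_surface_rejected(self, tmp_path):
        e, c = write_files(
            tmp_path,
            EXAM_HEADER + "c1,0,16,OCCLUSAL,SOUND\nc1,0,16,OCCLUSAL,CAV3\n",
            ONE_CHILD,
        )
        with pytest.raises(CohortValidationError, match="unique-surface"):
            read_cohort(e, c)

    def test_observation_at_absent_visit_rejected(self, tmp_path):
        e, c = write_files(
            tmp_path,
            EXAM_HEADER + "c1,1,16,OCCLUSAL,SOUND\n",
            CHILD_HEADER + "c1,LOW,MALE,URBAN,PUBLIC,ATTENDED,ABSENT,ATTENDED,ATTENDED\n",
        )
        with pytest.raises(CohortValidationError, match="observed-implies-attended"):
            read_cohort(e, c)


class TestWriteCohort:
    def test_empty_cohort_writes_headers(self, tmp_path):
        cohort = build_cohort([], [])
        write_cohort(cohort, tmp_path / "e.csv", tmp_path / "c.csv")
        assert (tmp_path / "e.csv").read_text().strip() == EXAM_HEADER.strip()
        assert (tmp_path / "c.csv").read_text().strip() == CHILD_HEADER.strip()

    def test_missing_token_serialized_verbatim(self, tmp_path):
        cohort = build_cohort(
            [child_row("c1")], [("c1", 0, 16, "OCCLUSAL", "MISSING")]
        )
        write_cohort(cohort, tmp_path / "e.csv", tmp_path / "c.csv")
        assert "c1,0,16,OCCLUSAL,MISSING" in (tmp_path / "e.csv").read_text()

    def test_round_trip_identity_on_simulated_cohort(self, tmp_path, default_cohort):
        cohort, _ = default_cohort
        write_cohort(cohort, tmp_path / "e.csv", tmp_path / "c.csv")
        back = read_cohort(tmp_path / "e.csv", tmp_path / "c.csv")
        assert back.equals(cohort)


class TestValidateCohort:
    def test_valid_cohort_no_violations(self):
        cohort = build_cohort(
            [child_row("c1")],
            uniform_child_obs("c1", [0, 1], {0: "SOUND", 1: "SOUND"}, n_surfaces=4),
        )
        assert validate_cohort(cohort) == []

    def test_missing_is_absorbing(self):
        cohort = build_cohort(
            [child_row("c1")],
            [("c1", 1, 16, "OCCLUSAL", "MISSING"), ("c1", 2, 16, "OCCLUSAL", "SOUND")],
        )
        violations = validate_cohort(cohort)
        assert [v.rule for v in violations] == ["missing-absorbing"]
        v = violations[0]
        assert (v.child_id, v.visit, v.tooth, v.surface) == ("c1", 2, 16, "OCCLUSAL")

    def test_dropped_is_absorbing(self):
        cohort = build_cohort(
            [child_row("c1", att=("ATTENDED", "DROPPED", "ATTENDED", "DROPPED"))], []
        )
        violations = validate_cohort(cohort)
        assert [v.rule for v in violations] == ["dropped-absorbing"]

    def test_unknown_child_observation(self):
        cohort = build_cohort([child_row("c1")], [("cX", 0, 16, "OCCLUSAL", "SOUND")])
        assert [v.rule for v in validate_cohort(cohort)] == ["known-child"]


# Soundness: randomized corruptions of a valid cohort are always caught.
_CORRUPTIONS = st.sampled_from(
    ["bad_tooth", "dup_surface", "obs_when_absent", "drop_then_attend", "missing_relapse"]
)


@settings(max_examples=25, deadline=None)
@given(corruption=_CORRUPTIONS, data=st.data())
def test_validator_catches_random_corruptions(corruption, data):
    cohort = build_cohort(
        [child_row("c1"), child_row("c2", risk="HIGH")],
        uniform_child_obs("c1", [0, 1, 2, 3], {v: "SOUND" for v in range(4)}, 6)
        + uniform_child_obs("c2", [0, 1, 2, 3], {v: "NONCAV_A" for v in range(4)}, 6),
    )
    assert validate_cohort(cohort) == []
    obs, ch = cohort.observations, cohort.children
    i = data.draw(st.integers(0, len(obs) - 1))
    if corruption == "bad_tooth":
        obs.loc[i, "tooth"] = data.draw(st.sampled_from([18, 28, 48, 55, 99]))
    elif corruption == "dup_surface":
        cohort.observations = pd.concat([obs, obs.iloc[[i]]], ignore_index=True)
    elif corruption == "obs_when_absent":
        v = int(obs.loc[i, "visit"])
        ch.loc[ch["child_id"] == obs.loc[i, "child_id"], f"att{v}"] = "ABSENT"
    elif corruption == "drop_then_attend":
        ch.loc[0, "att1"] = "DROPPED"  # att2 remains ATTENDED
        cohort.observations = obs[~((obs["child_id"] == "c1") & (obs["visit"] >= 1))]
    elif corruption == "missing_relapse":
        sel = (obs["child_id"] == "c1") & (obs["visit"] == 1)
        obs.loc[sel & (obs["tooth"] == 11), "condition"] = "MISSING"
    assert validate_cohort(cohort) != []
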