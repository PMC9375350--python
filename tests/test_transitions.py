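"""Cutoff collapse, transition classification, and per-child counting."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from carietrack.data_model import SurfaceState
from carietrack.transitions import (
    CollapsedState,
    Cutoff,
    TransitionClass,
    UnobservedIntervalError,
    classify_transition,
    cohort_transition_table,
    collapse,
    count_transitions,
)
from conftest import build_cohort, child_row, uniform_child_obs

S = CollapsedState
P, R, N = TransitionClass.PROGRESSION, TransitionClass.REGRESSION, TransitionClass.NEITHER


class TestCollapse:
    @pytest.mark.parametrize(
        "state, cutoff, expected",
        [
            (SurfaceState.NONCAV_A, Cutoff.CAV_3_6, S.SOUND),
            (SurfaceState.NONCAV_A, Cutoff.ALL_A_6, S.NONCAV),
            (SurfaceState.FILLED_NONCAV, Cutoff.CAV_3_6, S.FILLED_SOUND),
            (SurfaceState.FILLED_NONCAV, Cutoff.ALL_A_6, S.FILLED_NONCAV),
            (SurfaceState.CAV3, Cutoff.CAV_3_6, S.CAV),
            (SurfaceState.CAV5, Cutoff.CAV_3_6, S.CAV),
            (SurfaceState.CAV5, Cutoff.ALL_A_6, S.CAV),
            (SurfaceState.CAV6, Cutoff.ALL_A_6, S.CAV),
            (SurfaceState.SOUND, Cutoff.CAV_3_6, S.SOUND),
            (SurfaceState.MISSING, Cutoff.ALL_A_6, S.MISSING),
            (SurfaceState.CROWNED, Cutoff.CAV_3_6, S.CROWNED),
            (SurfaceState.FILLED_CAV, Cutoff.CAV_3_6, S.FILLED_CAV),
        ],
    )
    def test_collapse_map(self, state, cutoff, expected):
        assert collapse(state, cutoff) is expected

    def test_noncav_never_survives_3_6(self):
        collapsed = {collapse(s, Cutoff.CAV_3_6) for s in SurfaceState}
        assert S.NONCAV not in collapsed
        assert S.FILLED_NONCAV not in collapsed


class TestClassifyTransition:
    def test_total_over_all_pairs(self):
        for b, a in itertools.product(CollapsedState, CollapsedState):
            assert classify_transition(b, a) in TransitionClass

    @pytest.mark.parametrize(
        "before, after, expected",
        [
            # onset and worsening of decay
            (S.SOUND, S.NONCAV, P),
            (S.SOUND, S.CAV, P),
            (S.NONCAV, S.CAV, P),
            # loss of the surface from a sound-ish start
            (S.SOUND, S.MISSING, P),
            (S.NONCAV, S.CROWNED, P),
            # treatment of a sound/non-cavitated surface
            (S.SOUND, S.FILLED_SOUND, P),
            (S.NONCAV, S.FILLED_CAV, P),
            # decay around an existing filling
            (S.FILLED_NONCAV, S.CAV, P),
            (S.FILLED_NONCAV, S.FILLED_CAV, P),
            # reversals
            (S.NONCAV, S.SOUND, R),
            (S.CAV, S.SOUND, R),
            (S.FILLED_NONCAV, S.SOUND, R),
            (S.FILLED_CAV, S.SOUND, R),
            (S.FILLED_CAV, S.FILLED_NONCAV, R),
            (S.FILLED_SOUND, S.SOUND, R),
            # no change / terminal starts / established cavities
            (S.SOUND, S.SOUND, N),
            (S.MISSING, S.MISSING, N),
            (S.MISSING, S.SOUND, N),
            (S.CROWNED, S.CAV, N),
            (S.CAV, S.CAV, N),
            (S.CAV, S.FILLED_CAV, N),
            (S.CAV, S.MISSING, N),
            (S.FILLED_CAV, S.CROWNED, N),
        ],
    )
    def test_classification_rules(self, before, after, expected):
        assert classify_transition(before, after) is expected


def _one_child_cohort(condition_by_visit, n_surfaces=10, att=("ATTENDED",) * 4):
    return build_cohort(
        [child_row("c1", att=att)],
        uniform_child_obs("c1", sorted(condition_by_visit), condition_by_visit, n_surfaces),
    )


class TestCountTransitions:
    def test_all_unchanged(self):
        cohort = _one_child_cohort({0: "SOUND", 1: "SOUND"}, n_surfaces=12)
        counts, audit = count_transitions(cohort, "c1", 1, Cutoff.ALL_A_6)
        assert (counts.P, counts.R, counts.N) == (0, 0, 12)
        assert len(audit) == 12

    @pytest.mark.parametrize(
        "cutoff, expected", [(Cutoff.ALL_A_6, (3, 0, 123)), (Cutoff.CAV_3_6, (0, 0, 126))]
    )
    def test_three_new_noncav_lesions_under_both_cutoffs(self, cutoff, expected):
        after = ["NONCAV_A"] * 3 + ["SOUND"] * 123
        cohort = _one_child_cohort({0: "SOUND", 1: after}, n_surfaces=126)
        counts, _ = count_transitions(cohort, "c1", 1, cutoff)
        assert (counts.P, counts.R, counts.N) == expected

    def test_erupted_surface_counts_against_implied_sound(self):
        # surface present only at follow-up: treated as SOUND -> state
        cohort = build_cohort(
            [child_row("c1")],
            [("c1", 0, 16, "OCCLUSAL", "SOUND"),
             ("c1", 1, 16, "OCCLUSAL", "SOUND"),
             ("c1", 1, 17, "OCCLUSAL", "CAV3")],
        )
        counts, _ = count_transitions(cohort, "c1", 1, Cutoff.CAV_3_6)
        assert (counts.P, counts.R, counts.N) == (1, 0, 1)

    def test_unobserved_interval_raises(self):
        cohort = build_cohort(
            [child_row("c1", att=("ATTENDED", "ABSENT", "ATTENDED", "ATTENDED"))],
            uniform_child_obs("c1", [0, 2], {0: "SOUND", 2: "SOUND"}, 4),
        )
        with pytest.raises(UnobservedIntervalError):
            count_transitions(cohort, "c1", 1, Cutoff.CAV_3_6)
        counts, _ = count_transitions(cohort, "c1", 2, Cutoff.CAV_3_6)
        assert counts.N == 4


class TestCohortLevelCounts:
    def test_conservation_and_audit_recount_on_simulated_children(self, default_cohort):
        """P+R+N equals surfaces classified; counts equal a brute-force
        re-count over the per-surface audit list."""
        cohort, _ = default_cohort
        observed = sorted(cohort.attended_ids(0) & cohort.attended_ids(3))
        table = cohort_transition_table(cohort, Cutoff.ALL_A_6, 3).set_index("child_id")
        for cid in observed[:40]:
            counts, audit = count_transitions(cohort, cid, 3, Cutoff.ALL_A_6)
            assert counts.total == len(audit)
            brute = audit["transition"].value_counts()
            assert counts.P == brute.get("PROGRESSION", 0)
            assert counts.R == brute.get("REGRESSION", 0)
            assert counts.N == brute.get("NEITHER", 0)
            row = table.loc[cid]
            assert (row["P"], row["R"], row["N"]) == (counts.P, counts.R, counts.N)

    def test_cutoff_monotonicity_for_a_only_changes(self):
        """A cohort whose only change is SOUND -> code A progresses under
        A-6 but not under 3-6."""
        after = ["NONCAV_A"] * 4 + ["SOUND"] * 6
        cohort = _one_child_cohort({0: "SOUND", 1: after}, n_surfaces=10)
        p_a6 = cohort_transition_table(cohort, Cutoff.ALL_A_6, 1)["P"].iloc[0]
        p_36 = cohort_transition_table(cohort, Cutoff.CAV_3_6, 1)["P"].iloc[0]
        assert p_36 == 0
        assert p_a6 == 4 >= p_36

    def test_children_missing_an_end_are_omitted(self):
        cohort = build_cohort(
            [child_row("c1"), child_row("c2", att=("ATTENDED", "ABSENT", "ATTENDED", "ATTENDED"))],
            uniform_child_obs("c1", [0, 1], {0: "SOUND", 1: "SOUND"}, 4)
            + uniform_child_obs("c2", [0], {0: "SOUND"}, 4),
        )
        table = cohort_transition_table(cohort, Cutoff.CAV_3_6, 1)
        assert table["child_id"].tolist() == ["c1"]
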