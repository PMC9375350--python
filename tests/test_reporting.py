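"""Summary-table artifacts and the end-to-end pipeline."""

import json

import numpy as np
import pandas as pd
import pytest

from carietrack.data_model import Attendance, Risk
from carietrack.reporting import (
    percentage,
    round_half_up,
    run_pipeline,
    table_response_rates,
    table_risk_by_demographics,
    table_surface_distribution,
)
from conftest import build_cohort, child_row, uniform_child_obs


class TestRounding:
    @pytest.mark.parametrize(
        "x, decimals, expected",
        [(0.845, 2, 0.85), (39.75, 1, 39.8), (0.125, 2, 0.13), (2.5, 0, 3.0)],
    )
    def test_round_half_up(self, x, decimals, expected):
        assert round_half_up(x, decimals) == expected

    def test_percentage_from_counts(self):
        assert percentage(90, 226, 1) == 39.8
        assert percentage(515, 28_415, 2) == 1.81
        assert percentage(0, 0) != percentage(0, 0)  # NaN on empty denominator


def attendance_cohort(flag_rows):
    """Cohort with explicit per-child attendance and no observations."""
    rows = [child_row(f"c{i}", risk=r, att=att) for i, (r, att) in enumerate(flag_rows)]
    return build_cohort(rows, [])


class TestResponseRates:
    def test_full_attendance_all_rates_100(self):
        cohort = attendance_cohort([("LOW", ("ATTENDED",) * 4)] * 5)
        table = table_response_rates(cohort).table
        rates = table[table["status"] == "RESPONSE_RATE_PCT"]["total"]
        assert (rates == 100).all()

    def test_study_first_follow_up_rate(self):
        """174 attendees of 226 enrolled is a 77% response rate."""
        flags = [("LOW", ("ATTENDED", "ATTENDED", "ATTENDED", "ATTENDED"))] * 174
        flags += [("LOW", ("ATTENDED", "ABSENT", "ATTENDED", "ATTENDED"))] * 22
        flags += [("LOW", ("ATTENDED", "DROPPED", "DROPPED", "DROPPED"))] * 30
        cohort = attendance_cohort(flags)
        table = table_response_rates(cohort).table
        row = table[(table["visit"] == 1) & (table["status"] == "RESPONSE_RATE_PCT")]
        assert row["total"].item() == 77.0

    def test_rates_match_direct_recount(self, default_cohort):
        cohort, _ = default_cohort
        table = table_response_rates(cohort).table
        for v in range(4):
            expected = (cohort.children[f"att{v}"] == Attendance.ATTENDED.value).sum()
            got = table[(table["visit"] == v) & (table["status"] == "ATTENDED")]["total"].item()
            assert got == expected
            rate = table[(table["visit"] == v) & (table["status"] == "RESPONSE_RATE_PCT")]["total"].item()
            assert rate == percentage(expected, len(cohort.children), 0)


class TestSurfaceDistribution:
    def test_all_sound_cohort(self):
        cohort = build_cohort(
            [child_row("c1")], uniform_child_obs("c1", [0], {0: "SOUND"}, 8)
        )
        table = table_surface_distribution(cohort, 0).table.set_index("code")
        assert table.loc["Sound", "percent"] == 100.0
        assert table.loc["A", "count"] == 0

    def test_percentages_rederive_from_counts(self, default_cohort):
        cohort, _ = default_cohort
        for v in range(4):
            art = table_surface_distribution(cohort, v)
            total = art.metadata["total_surfaces"]
            for _, row in art.table.iterrows():
                assert row["percent"] == percentage(row["count"], total, 2)


class TestRiskByDemographics:
    def test_study_marginals(self):
        """90/69/67 children of 226 give 39.8/30.5/29.6% risk shares
        (the third share is 67/226 = 29.646%, count-derived)."""
        flags = (
            [("LOW", ("ATTENDED",) * 4)] * 90
            + [("MEDIUM", ("ATTENDED",) * 4)] * 69
            + [("HIGH", ("ATTENDED",) * 4)] * 67
        )
        cohort = attendance_cohort(flags)
        table = table_risk_by_demographics(cohort).table
        top = table[table["characteristic"] == "all"].iloc[0]
        assert (top["low_pct"], top["medium_pct"], top["high_pct"]) == (39.8, 30.5, 29.6)

    def test_single_stratum_flags_degenerate_tables(self):
        cohort = attendance_cohort([("LOW", ("ATTENDED",) * 4)] * 10)
        table = table_risk_by_demographics(cohort).table
        tested = table[table["characteristic"] != "all"]
        assert (tested["flag"] == "degenerate-table").all()
        assert tested["chi_square_p"].isna().all()

    def test_row_percentages_rederive(self, default_cohort):
        cohort, _ = default_cohort
        table = table_risk_by_demographics(cohort).table
        for _, row in table.iterrows():
            for r in ("low", "medium", "high"):
                assert row[f"{r}_pct"] == percentage(row[f"{r}_n"], row["n"], 1)


class TestPipeline:
    def test_default_run_emits_all_artifacts(self, tmp_path):
        manifest = run_pipeline(tmp_path / "run", seed=2, m=5)
        names = {p.name for p in (tmp_path / "run").iterdir()}
        assert {
            "table_response_rates.csv",
            "table_surface_distribution.csv",
            "table_risk_by_demographics.csv",
            "table_increment_comparison.csv",
            "table_recommendations.csv",
            "manifest.json",
        } <= names
        assert manifest["stages"] == ["simulate", "tables", "increment", "recommend"]
        recs = pd.read_csv(tmp_path / "run" / "table_recommendations.csv")
        assert set(recs["months"]) <= {6, 12, 18}

    def test_same_seed_byte_identical_manifests(self, tmp_path):
        run_pipeline(tmp_path / "a", seed=3, m=4)
        run_pipeline(tmp_path / "b", seed=3, m=4)
        assert (tmp_path / "a" / "manifest.json").read_bytes() == (
            tmp_path / "b" / "manifest.json"
        ).read_bytes()
        assert (tmp_path / "a" / "table_increment_comparison.csv").read_bytes() == (
            tmp_path / "b" / "table_increment_comparison.csv"
        ).read_bytes()

    def test_no_missingness_run_skips_imputation(self, tmp_path):
        manifest = run_pipeline(
            tmp_path / "full",
            seed=4,
            config_overrides={
                "absence_prob": (0.0,) * 4,
                "dropout_prob": (0.0,) * 4,
            },
        )
        assert manifest["imputation"]["applied"] is False
        assert "skipped" in manifest["imputation"]["reason"]
        saved = json.loads((tmp_path / "full" / "manifest.json").read_text())
        assert saved["imputation"]["applied"] is False
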