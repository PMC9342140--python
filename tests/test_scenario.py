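"""Scenario simulation, fixtures, feasibility, tabular I/O and the harness."""

import numpy as np
import pandas as pd
import pytest

from cvrmodel import (
    SimConfig,
    ValidationError,
    check_feasibility,
    fixture_graded_test,
    fixture_rest_exercise,
    read_scenario,
    reference_profile,
    regress_predicted_vs_measured,
    simulate,
    write_results,
    write_scenario,
)


@pytest.fixture(scope="module")
def fit():
    return reference_profile("fit")


@pytest.fixture(scope="module")
def unfit():
    return reference_profile("unfit")


class TestFixtures:
    def test_graded_test_layout(self):
        sc = fixture_graded_test("fit", "thermoneutral")
        assert len(sc) == 10
        assert sc["phase"].tolist() == ["rest"] + ["exercise"] * 9
        np.testing.assert_allclose(
            sc["workload_fraction"], [0.0] + [0.2 + 0.1 * i for i in range(9)]
        )
        np.testing.assert_allclose(np.diff(sc["time_min"]), 2.0)

    def test_heated_preset_environment(self):
        sc = fixture_graded_test("fit", "heated")
        ex = sc[sc["phase"] == "exercise"]
        assert (ex["t_body_C"] == 39.0).all()
        assert (ex["mass_loss_kg"] == 1.5).all()

    def test_high_altitude_preset(self):
        sc = fixture_graded_test("fit", "high_altitude")
        assert (sc["altitude_km"] == 5.0).all()

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValidationError):
            fixture_graded_test("fit", "tropical")
        with pytest.raises(ValidationError):
            fixture_graded_test("elite", "heated")

    def test_rest_exercise_layout(self):
        sc = fixture_rest_exercise("fixed_load_heat")
        assert sc["time_min"].iloc[0] == 0.0
        assert sc["time_min"].iloc[-1] == 90.0
        np.testing.assert_allclose(np.diff(sc["time_min"]), 5.0)
        rest = sc[sc["phase"] == "rest"]
        assert rest["time_min"].max() == 30.0  # 30-min rest lead-in

    def test_altitude_protocols(self):
        sc = fixture_rest_exercise("altitude_absolute")
        assert (sc["altitude_km"] == 4.0).all()
        ex = sc[sc["phase"] == "exercise"]
        assert set(ex["workload_fraction"]) == {0.35, 0.50}
        with pytest.raises(ValidationError):
            fixture_rest_exercise("spaceflight")


class TestSimulate:
    def test_thermoneutral_endpoint_reaches_hr_max(self, fit):
        sc = fixture_graded_test("fit", "thermoneutral")
        sc["t_body_C"] = 36.54  # strictly zero strain
        sc["mass_loss_kg"] = 0.0
        res = simulate(fit, sc)
        assert res.table["hr_bpm"].iloc[-1] == pytest.approx(190.5, rel=1e-12)

    def test_heated_hr_exceeds_thermoneutral_at_same_vo2(self, fit):
        heated = simulate(fit, fixture_graded_test("fit", "heated"))
        neutral = simulate(fit, fixture_graded_test("fit", "thermoneutral"))
        ex = heated.table["phase"] == "exercise"
        assert (heated.table.loc[ex, "hr_bpm"].to_numpy()
                > neutral.table.loc[ex, "hr_bpm"].to_numpy()).all()

    def test_heated_worked_chain_row(self, fit):
        # vo2 2.0 with T_body 39 and 2% dehydration: hand-derived chain
        sc = pd.DataFrame({
            "time_min": [0.0, 60.0],
            "phase": ["rest", "exercise"],
            "workload_vo2_L_min": [None, 2.0],
            "t_body_C": [39.0, 39.0],
            "mass_loss_kg": [0.0, 1.5],
        })
        res = simulate(fit, sc)
        row = res.table.iloc[-1]
        assert row["dehydration_pct"] == pytest.approx(2.0)
        assert row["chsi"] == pytest.approx(2.23)
        assert row["hr_bpm"] == pytest.approx(151.1, abs=0.05)

    def test_supramaximal_altitude_workload_fails(self, fit):
        # 0.8 x 4.0 = 3.2 L/min demanded against a 2.70 L/min cap at 5 km
        sc = pd.DataFrame({
            "time_min": [0.0, 10.0],
            "phase": ["rest", "exercise"],
            "workload_fraction": [0.0, 0.8],
            "altitude_km": [5.0, 5.0],
        })
        res = simulate(fit, sc)
        row = res.table.iloc[-1]
        assert row["vo2max_env_L_min"] == pytest.approx(2.70, rel=1e-12)
        assert not row["feasible"]
        assert row["limiting_factor"] == "vo2max_exceeded"
        assert res.first_failure_time_min == 10.0
        assert res.limiting_factor == "vo2max_exceeded"

    def test_relative_workload_stays_feasible_at_altitude(self, fit):
        sc = pd.DataFrame({
            "time_min": [0.0, 10.0],
            "phase": ["rest", "exercise"],
            "workload_fraction": [0.0, 0.8],
            "altitude_km": [5.0, 5.0],
        })
        res = simulate(fit, sc, SimConfig(workload_relative_to_env=True))
        row = res.table.iloc[-1]
        assert row["vo2_L_min"] == pytest.approx(0.8 * 2.70, rel=1e-9)
        assert row["feasible"]

    def test_determinism(self, fit):
        sc = fixture_graded_test("fit", "heated")
        a = simulate(fit, sc).table
        b = simulate(fit, sc).table
        pd.testing.assert_frame_equal(a, b)

    def test_dehydration_accrues_only_during_exercise(self, fit):
        sc = fixture_rest_exercise("fixed_load_heat", total_mass_loss_kg=1.5)
        res = simulate(fit, sc)
        t = res.table
        assert (t.loc[t["phase"] == "rest", "dehydration_pct"] == 0.0).all()
        ex = t[t["phase"] == "exercise"]
        d = ex["dehydration_pct"].to_numpy()
        assert (np.diff(d) > 0).all()
        assert d[-1] == pytest.approx(2.0)  # 1.5 kg of 75 kg

    def test_validation_errors_name_the_row(self, fit):
        sc = pd.DataFrame({
            "time_min": [0.0, 10.0, 5.0],
            "phase": ["rest", "exercise", "exercise"],
            "workload_fraction": [0.0, 0.5, 0.5],
        })
        with pytest.raises(ValidationError, match="row 2"):
            simulate(fit, sc)
        sc2 = pd.DataFrame({
            "time_min": [0.0, 10.0],
            "phase": ["rest", "exercise"],
            "workload_fraction": [0.0, None],
        })
        with pytest.raises(ValidationError, match="row 1"):
            simulate(fit, sc2)

    def test_unsupported_altitude_rejected(self, fit):
        sc = pd.DataFrame({
            "time_min": [0.0, 10.0],
            "phase": ["rest", "exercise"],
            "workload_fraction": [0.0, 0.5],
            "altitude_km": [9.0, 9.0],
        })
        with pytest.raises(ValidationError, match="altitude"):
            simulate(fit, sc)


class TestInheritedInvariants:
    """Fick closure and flow conservation over whole fixture runs."""

    @pytest.mark.parametrize("environment", [
        "thermoneutral", "heated", "high_altitude"
    ])
    @pytest.mark.parametrize("fit_level", ["fit", "unfit"])
    def test_fick_closure_every_row(self, fit_level, environment):
        res = simulate(
            reference_profile(fit_level),
            fixture_graded_test(fit_level, environment),
        )
        t = res.table
        np.testing.assert_allclose(
            t["co_L_min"] * t["avo2diff"], t["vo2_L_min"], rtol=1e-9
        )
        # the altitude-compensated CO satisfies Fick against its extraction too
        np.testing.assert_allclose(
            t["co_altitude_L_min"] * (t["vo2_L_min"] / t["co_altitude_L_min"]),
            t["vo2_L_min"], rtol=1e-9,
        )

    @pytest.mark.parametrize("environment", [
        "thermoneutral", "heated", "high_altitude"
    ])
    def test_flow_conservation_every_row(self, environment):
        res = simulate(
            reference_profile("fit"), fixture_graded_test("fit", environment)
        )
        t = res.table
        np.testing.assert_allclose(
            t["core_bf_L_min"] + t["skin_bf_L_min"] + t["muscle_bf_L_min"],
            t["co_L_min"], atol=1e-12,
        )


@pytest.fixture(scope="module")
def tables():
    out = {}
    for env in ("thermoneutral", "heated", "sea_level", "high_altitude"):
        out[env] = simulate(
            reference_profile("fit"), fixture_graded_test("fit", env)
        ).table
    return out


class TestGradedShapeChecks:
    """Qualitative shapes of the graded-test simulation."""

    def test_heated_rest_co_above_thermoneutral(self, tables):
        assert (tables["heated"]["co_L_min"].iloc[0]
                > tables["thermoneutral"]["co_L_min"].iloc[0])

    def test_heated_max_co_below_thermoneutral(self, tables):
        assert (tables["heated"]["co_L_min"].iloc[-1]
                < tables["thermoneutral"]["co_L_min"].iloc[-1])

    def test_heated_sv_below_thermoneutral_during_exercise(self, tables):
        heated = tables["heated"]
        neutral = tables["thermoneutral"]
        ex = heated["phase"] == "exercise"
        assert (heated.loc[ex, "sv_mL"].to_numpy()
                < neutral.loc[ex, "sv_mL"].to_numpy()).all()

    def test_altitude_extraction_below_sea_level_everywhere(self, tables):
        assert (tables["high_altitude"]["avo2diff"].to_numpy()
                < tables["sea_level"]["avo2diff"].to_numpy()).all()

    def test_unfit_hr_exceeds_fit_at_equal_absolute_vo2(self):
        # same absolute workloads for both individuals
        vo2 = [0.8, 1.2, 1.6, 2.0]
        sc = pd.DataFrame({
            "time_min": [0.0] + [2.0 * (i + 1) for i in range(4)],
            "phase": ["rest"] + ["exercise"] * 4,
            "workload_vo2_L_min": [None] + vo2,
        })
        fit_hr = simulate(reference_profile("fit"), sc).table["hr_bpm"]
        unfit_hr = simulate(reference_profile("unfit"), sc).table["hr_bpm"]
        assert (unfit_hr.to_numpy() > fit_hr.to_numpy()).all()


class TestFeasibility:
    def test_feasible_case(self):
        assert check_feasibility(2.0, 3.26, 151.1, 190.5) == (True, "none")

    def test_vo2_violation_named_first(self):
        feasible, limiting = check_feasibility(3.2, 2.70, 200.0, 190.5)
        assert not feasible and limiting == "vo2max_exceeded"

    def test_hr_ceiling_violation(self):
        feasible, limiting = check_feasibility(2.0, 3.26, 151.1, 190.5,
                                               hr_ceiling=140.0)
        assert not feasible and limiting == "hr_ceiling"

    def test_hr_max_violation(self):
        feasible, limiting = check_feasibility(2.0, 3.26, 195.0, 190.5)
        assert not feasible and limiting == "hr_ceiling"


class TestRegressionHarness:
    def test_identity_pairs(self):
        pred = np.linspace(80, 180, 20)
        fits = regress_predicted_vs_measured(pred, pred)
        f = fits["pooled"]
        assert f.slope == pytest.approx(1.0)
        assert f.intercept == pytest.approx(0.0, abs=1e-9)
        assert f.r_squared == pytest.approx(1.0)

    def test_recovers_synthetic_linear_relation(self):
        pred = np.linspace(80, 180, 25)
        measured = 0.76 * pred + 18.8
        f = regress_predicted_vs_measured(pred, measured)["pooled"]
        assert f.slope == pytest.approx(0.76, rel=1e-12)
        assert f.intercept == pytest.approx(18.8, rel=1e-12)
        assert f.r_squared == pytest.approx(1.0)

    def test_strata(self):
        pred = np.array([80, 100, 120, 90, 110, 130.0])
        measured = np.where(
            np.array([0, 0, 0, 1, 1, 1]) == 0, pred * 1.1, pred * 0.9 + 5
        )
        fits = regress_predicted_vs_measured(pred, measured,
                                             ["a", "a", "a", "b", "b", "b"])
        assert set(fits) == {"pooled", "a", "b"}
        assert fits["a"].slope == pytest.approx(1.1)
        assert fits["b"].slope == pytest.approx(0.9)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValidationError):
            regress_predicted_vs_measured([100, 110, 120], [150, 150, 150])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            regress_predicted_vs_measured([100, 110], [101, 111])


class TestTabularIO:
    def test_minimal_file_parses(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text(
            "time_min,phase,workload_fraction\n0,rest,0\n10,exercise,0.5\n"
        )
        sc = read_scenario(path)
        assert len(sc) == 2

    def test_both_workload_columns_rejected(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text(
            "time_min,phase,workload_fraction,workload_vo2_L_min\n"
            "0,rest,,\n10,exercise,0.5,2.0\n"
        )
        with pytest.raises(ValidationError, match="mutually"):
            read_scenario(path)

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("time_min,phase,workload_fraction\n0,rest,0\nten,exercise,0.5\n")
        with pytest.raises(ValidationError):
            read_scenario(path)

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("time_min,workload_fraction\n0,0\n")
        with pytest.raises(ValidationError, match="phase"):
            read_scenario(path)

    def test_round_trip_bit_identical(self, tmp_path):
        sc = fixture_graded_test("fit", "heated")
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_scenario(p1, sc)
        back = read_scenario(p1)
        write_scenario(p2, back)
        assert p1.read_bytes() == p2.read_bytes()
        pd.testing.assert_frame_equal(sc, back)

    def test_write_results(self, tmp_path, fit):
        res = simulate(fit, fixture_graded_test("fit", "thermoneutral"))
        out = tmp_path / "r.csv"
        write_results(out, res)
        back = pd.read_csv(out)
        assert len(back) == len(res.table)
        assert "hr_bpm" in back.columns
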