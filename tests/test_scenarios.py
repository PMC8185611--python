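"""Scenario orchestration: sample filters, multiplier linearity, perspective
nesting, the sensitivity grid, and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from trialcea.cohort import CohortParams, generate_cohort
from trialcea.inference import RegressionSpec, bootstrap_sur, regression_impute
from trialcea.scenarios import (
    ScenarioConfig,
    add_outcome_columns,
    build_analysis_frame,
    cost_category_table,
    run_matrix,
    run_scenario,
    sensitivity_grid,
    write_table_csv,
)


class TestScenarioConfig:
    def test_completers_with_imputation_rejected(self):
        with pytest.raises(ValueError, match="completers"):
            ScenarioConfig(sample="completers", impute=True)

    def test_validation(self):
        with pytest.raises(ValueError):
            ScenarioConfig(perspective="employer")
        with pytest.raises(ValueError):
            ScenarioConfig(intervention_cost_multiplier=0.0)
        with pytest.raises(ValueError):
            ScenarioConfig(B=50)

    def test_default_grid_follows_outcome(self):
        assert ScenarioConfig(outcome="qaly").grid().lambdas[-1] == 50_000.0
        assert ScenarioConfig(outcome="symptom_free").grid().lambdas[-1] == 5_000.0


class TestMainScenario:
    def test_dominant_direction_on_default_cohort(self, default_cohort):
        """Under the study conditions (cheaper and more effective intervention)
        the societal evaluation flags dominance."""
        res = run_scenario(default_cohort, ScenarioConfig(B=500, seed=7))
        assert res.delta_cost < 0
        assert res.delta_effect > 0
        assert res.icer.dominant
        assert res.quadrants["SE"] > 50.0

    def test_deterministic_given_seeds(self, default_cohort):
        a = run_scenario(default_cohort, ScenarioConfig(B=300, seed=5))
        b = run_scenario(default_cohort, ScenarioConfig(B=300, seed=5))
        assert a.delta_cost == b.delta_cost
        assert a.delta_cost_ci == b.delta_cost_ci
        assert a.icer_ci == b.icer_ci
        pd.testing.assert_frame_equal(a.ceac, b.ceac)

    def test_completers_equal_itt_without_dropout(self, no_dropout_cohort):
        itt = run_scenario(no_dropout_cohort, ScenarioConfig(B=300, seed=5))
        comp = run_scenario(
            no_dropout_cohort, ScenarioConfig(B=300, seed=5, sample="completers")
        )
        assert itt.delta_cost == comp.delta_cost
        assert itt.delta_effect == comp.delta_effect
        assert itt.quadrants == comp.quadrants


class TestMultiplierLinearity:
    def test_public_incremental_cost_shifts_by_exact_price_fraction(self, default_cohort):
        """Scaling the intervention price enters the cost response as a
        constant times the arm indicator, so every replicate's incremental
        cost shifts by exactly that constant."""
        specs = (
            RegressionSpec("cost_total", ("age", "baseline_depression")),
            RegressionSpec("qaly", ("utility_t0",)),
        )
        clouds = []
        for mult in (1.0, 1.2):
            frame = build_analysis_frame(default_cohort, intervention_cost_multiplier=mult)
            frame = regression_impute(frame)
            frame = add_outcome_columns(frame, "public_health_care")
            clouds.append(bootstrap_sur(frame, *specs, B=300, seed=11))
        shift = 0.2 * 299.0
        assert clouds[1].point[0] - clouds[0].point[0] == pytest.approx(shift, abs=1e-8)
        assert np.allclose(clouds[1].pairs[:, 0] - clouds[0].pairs[:, 0], shift, atol=1e-8)
        assert np.allclose(clouds[1].pairs[:, 1], clouds[0].pairs[:, 1], atol=1e-12)


class TestPerspectiveNesting:
    def test_societal_minus_public_equals_rest_per_replicate(self, no_dropout_cohort):
        """With a shared covariate set in both equations the SUR is linear in
        the cost response, so the nesting identity holds replicate by
        replicate: societal dC - public dC = patient/family + productivity dC."""
        covs = ("age", "baseline_depression")
        effect_spec = RegressionSpec("qaly", covs)
        base = build_analysis_frame(no_dropout_cohort)
        frames = {}
        for persp in ("societal", "public_health_care"):
            frames[persp] = add_outcome_columns(base, persp)
        rest = frames["societal"].copy()
        rest["cost_total"] = (
            frames["societal"]["cost_total"] - frames["public_health_care"]["cost_total"]
        )
        clouds = {
            name: bootstrap_sur(frame, RegressionSpec("cost_total", covs), effect_spec,
                                B=300, seed=13)
            for name, frame in (("soc", frames["societal"]),
                                ("pub", frames["public_health_care"]), ("rest", rest))
        }
        assert np.allclose(
            clouds["soc"].pairs[:, 0] - clouds["pub"].pairs[:, 0],
            clouds["rest"].pairs[:, 0],
            atol=1e-7,
        )


class TestSensitivityGrid:
    def test_grid_has_eleven_unique_scenarios(self):
        grid = sensitivity_grid()
        assert len(grid) == 11
        assert len({c.scenario_id for c in grid}) == 11
        assert sum(c.presenteeism_method == "hlq" for c in grid) == 1
        assert sum(c.sample == "completers" for c in grid) == 2

    def test_matrix_rows_populated_and_reproducible(self, tmp_path):
        cohort = generate_cohort(CohortParams(n_per_arm=24, seed=3))
        grid = sensitivity_grid(B=120)
        table1, _ = run_matrix(cohort, grid, master_seed=99)
        table2, _ = run_matrix(cohort, grid, master_seed=99)
        assert len(table1) == 11
        assert table1["delta_cost"].notna().all()
        pd.testing.assert_frame_equal(table1, table2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_table_csv(table1, p1, seed=99)
        write_table_csv(table2, p2, seed=99)
        assert p1.read_bytes() == p2.read_bytes()

    def test_hlq_incremental_cost_closer_to_zero(self, default_cohort):
        """The HLQ presenteeism variant values only the recoverable share of
        lost production, shrinking the (negative) societal incremental cost."""
        ost = run_scenario(default_cohort, ScenarioConfig(B=300, seed=17))
        hlq = run_scenario(
            default_cohort,
            ScenarioConfig(scenario_id="hlq", presenteeism_method="hlq", B=300, seed=17),
        )
        assert abs(hlq.delta_cost) < abs(ost.delta_cost)

    def test_duplicate_scenario_ids_rejected(self, default_cohort):
        grid = [ScenarioConfig(B=120), ScenarioConfig(B=120)]
        with pytest.raises(ValueError, match="unique"):
            run_matrix(default_cohort, grid)


class TestCostCategoryTable:
    def test_arm_means_and_incremental(self, no_dropout_cohort):
        frame = build_analysis_frame(no_dropout_cohort)
        out = cost_category_table(frame, B=200, seed=1)
        assert len(out) == 11  # one row per cost category
        gp = out.set_index("category").loc["gp"]
        expected = frame.loc[frame["arm"] == 1, "cost_gp"].mean()
        assert gp["intervention_mean"] == pytest.approx(expected)
        assert gp["incremental"] == pytest.approx(
            expected - frame.loc[frame["arm"] == 0, "cost_gp"].mean()
        )
        assert gp["intervention_lo"] <= gp["intervention_mean"] <= gp["intervention_hi"]

    def test_fixed_intervention_price_row(self, no_dropout_cohort):
        frame = build_analysis_frame(no_dropout_cohort)
        row = cost_category_table(frame, B=200, seed=1).set_index("category").loc["intervention"]
        assert row["intervention_mean"] == pytest.approx(299.0)
        assert row["control_mean"] == 0.0


class TestResultSerialisation:
    def test_to_row_shape(self, default_cohort):
        res = run_scenario(default_cohort, ScenarioConfig(B=300, seed=5))
        row = res.to_row()
        assert row["scenario"] == "main"
        assert row["pct_NE"] + row["pct_NW"] + row["pct_SE"] + row["pct_SW"] == 100
        assert row["B"] == 300

    def test_ceac_lookup(self, default_cohort):
        res = run_scenario(default_cohort, ScenarioConfig(B=300, seed=5))
        assert 0.0 <= res.ceac_at(20_000.0) <= 1.0
        with pytest.raises(ValueError):
            res.ceac_at(123.45)
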