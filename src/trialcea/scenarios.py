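"""Scenario orchestration: full evaluations across perspectives and
sensitivity variants from a single configuration.

A scenario fixes the costing perspective (societal vs public health care),
the health outcome (symptom-free status vs QALYs), the presenteeism valuation
(Osterhaus vs HLQ), an intervention-price multiplier, and the analysis sample
(intention-to-treat with regression imputation, or completers only). The
default sensitivity grid reproduces the 11 published variants: HLQ
presenteeism (societal only), intervention price +/-20% and +/-50% under both
perspectives, and a completers-only analysis under both perspectives.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import __version__
from .cohort import ParticipantRecord
from .costing import (
    ALL_CATEGORIES,
    DIRECT_MEDICAL,
    PERSPECTIVES,
    UnitCostTable,
    cost_participant,
)
from .decision import (
    EvaluationResult,
    WtpGrid,
    ceac,
    icer,
    icer_acceptability_ci,
    icer_mean_of_ratios,
    quadrant_distribution,
)
from .inference import (
    RegressionSpec,
    ReimputePlan,
    ReplicateImputer,
    ResponsePlan,
    bca_ci,
    bootstrap_sur,
    jackknife_sur,
    regression_impute,
)
from .outcomes import symptom_free_status

__all__ = [
    "ScenarioConfig",
    "cost_category_table",
    "build_analysis_frame",
    "add_outcome_columns",
    "run_scenario",
    "sensitivity_grid",
    "run_matrix",
    "write_table_csv",
]

OUTCOMES = ("symptom_free", "qaly")
COST_COLUMNS = {cat: f"cost_{cat}" for cat in ALL_CATEGORIES}


@dataclass(frozen=True)
class ScenarioConfig:
    """One evaluation scenario.

    ``impute=None`` resolves to imputation for the intention-to-treat sample
    and no imputation for completers; explicitly requesting imputation
    together with the completers sample is a configuration error.
    """

    scenario_id: str = "main"
    perspective: str = "societal"
    outcome: str = "qaly"
    presenteeism_method: str = "osterhaus"
    intervention_cost_multiplier: float = 1.0
    sample: str = "itt"
    B: int = 2500
    seed: int | None = 0
    wtp_grid: WtpGrid | None = None
    impute: bool | None = None
    icer_mean_of_ratios: bool = False

    def __post_init__(self) -> None:
        if self.perspective not in PERSPECTIVES:
            raise ValueError(f"perspective must be one of {PERSPECTIVES}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        if self.presenteeism_method not in ("osterhaus", "hlq"):
            raise ValueError("presenteeism_method must be 'osterhaus' or 'hlq'")
        if self.intervention_cost_multiplier <= 0:
            raise ValueError("intervention_cost_multiplier must be positive")
        if self.sample not in ("itt", "completers"):
            raise ValueError("sample must be 'itt' or 'completers'")
        if self.B < 100:
            raise ValueError("B must be >= 100")
        if self.sample == "completers" and self.impute:
            raise ValueError(
                "conflicting configuration: completers-only analysis excludes "
                "participants with missing follow-up instead of imputing"
            )

    @property
    def do_impute(self) -> bool:
        if self.impute is None:
            return self.sample == "itt"
        return self.impute

    def grid(self) -> WtpGrid:
        if self.wtp_grid is not None:
            return self.wtp_grid
        return WtpGrid.for_qaly() if self.outcome == "qaly" else WtpGrid.for_symptom_free()

    def digest(self) -> str:
        data = asdict(self)
        data["wtp_grid"] = list(self.grid().lambdas)
        return hashlib.sha256(json.dumps(data, sort_keys=True).encode()).hexdigest()[:12]


def build_analysis_frame(
    cohort: list[ParticipantRecord],
    table: UnitCostTable | None = None,
    presenteeism_method: str = "osterhaus",
    intervention_cost_multiplier: float = 1.0,
    intervention_cost: float = 299.0,
) -> pd.DataFrame:
    """One row per participant: arm indicator, baseline covariates, outcomes
    at the three assessment points, and per-category 6-month costs (NaN where
    follow-up resource use is missing)."""
    table = table or UnitCostTable()
    rows = []
    for rec in cohort:
        breakdown = cost_participant(
            rec,
            table,
            presenteeism_method=presenteeism_method,
            intervention_cost=intervention_cost,
            intervention_cost_multiplier=intervention_cost_multiplier,
        )
        row = {
            "id": rec.id,
            "arm": 1 if rec.arm == "intervention" else 0,
            "age": rec.age,
            "baseline_depression": rec.baseline_depression,
            "gross_daily_wage": rec.gross_daily_wage,
            "isi_t0": rec.isi[0], "isi_t1": rec.isi[1], "isi_t2": rec.isi[2],
            "utility_t0": rec.utility[0], "utility_t1": rec.utility[1],
            "utility_t2": rec.utility[2],
            "completed_followup": rec.completed_followup,
        }
        row.update({COST_COLUMNS[cat]: getattr(breakdown, cat) for cat in ALL_CATEGORIES})
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["times"] = cohort[0].times if cohort else (0.0, 8 / 52, 0.5)
    return frame


def add_outcome_columns(frame: pd.DataFrame, perspective: str) -> pd.DataFrame:
    """Derive ``qaly``, ``symptom_free`` (0/1) and the perspective's
    ``cost_total`` from a (complete) analysis frame."""
    out = frame.copy()
    times = np.asarray(out.attrs.get("times", (0.0, 8 / 52, 0.5)), float)
    utils = out[["utility_t0", "utility_t1", "utility_t2"]].to_numpy(float)
    out["qaly"] = np.trapezoid(utils, times, axis=1)
    out["symptom_free"] = symptom_free_status(out["isi_t2"].to_numpy(float)).astype(float)
    cats = DIRECT_MEDICAL if perspective == "public_health_care" else ALL_CATEGORIES
    out["cost_total"] = out[[COST_COLUMNS[c] for c in cats]].sum(axis=1, skipna=False)
    out.attrs = dict(frame.attrs)
    return out


def _specs(config: ScenarioConfig) -> tuple[RegressionSpec, RegressionSpec]:
    cost_spec = RegressionSpec("cost_total", ("age", "baseline_depression"), family="gamma")
    if config.outcome == "qaly":
        effect_spec = RegressionSpec("qaly", ("utility_t0",))
    else:
        effect_spec = RegressionSpec("symptom_free", ())
    return cost_spec, effect_spec


#: Baseline predictors the imputation regressions condition on (the treatment
#: indicator plus predictors of outcome and of dropout).
IMPUTATION_PREDICTORS = ("arm", "utility_t0", "isi_t0", "baseline_depression", "age")


def _reimpute_plan(raw: pd.DataFrame, config: ScenarioConfig) -> ReimputePlan:
    """Plan to re-run the regression imputation within every bootstrap or
    jackknife resample, built from the un-imputed frame."""
    times = np.asarray(raw.attrs.get("times", (0.0, 8 / 52, 0.5)), float)
    work = add_outcome_columns(raw, config.perspective)  # cost_total with NaN
    imputer = ReplicateImputer.from_frame(
        work, IMPUTATION_PREDICTORS, ("cost_total", "utility_t2", "isi_t2")
    )
    cost_plan = ResponsePlan(column="cost_total")
    if config.outcome == "qaly":
        # trapezoid weights: qaly = w0*u0 + w1*u1 + w2*u2 with u0, u1 observed
        w0 = (times[1] - times[0]) / 2
        w1 = (times[2] - times[0]) / 2
        w2 = (times[2] - times[1]) / 2
        base = (
            w0 * raw["utility_t0"].to_numpy(float) + w1 * raw["utility_t1"].to_numpy(float)
        )
        effect_plan = ResponsePlan(column="utility_t2", coef=w2, base=base)
    else:
        effect_plan = ResponsePlan(column="isi_t2", threshold=8.0)
    return ReimputePlan(imputer=imputer, cost=cost_plan, effect=effect_plan)


def run_scenario(
    cohort: list[ParticipantRecord],
    config: ScenarioConfig,
    table: UnitCostTable | None = None,
) -> EvaluationResult:
    """Evaluate one scenario end to end on a cohort.

    Applies the sample filter (completers drop incomplete participants; the
    intention-to-treat sample is completed by regression imputation), the
    presenteeism method, the intervention-cost multiplier and the perspective;
    then fits the SUR, bootstraps it, and assembles the decision analytics.
    """
    frame = build_analysis_frame(
        cohort,
        table,
        presenteeism_method=config.presenteeism_method,
        intervention_cost_multiplier=config.intervention_cost_multiplier,
    )
    n_imputed = 0
    plan = None
    if config.sample == "completers":
        frame = frame.loc[frame["completed_followup"]].reset_index(drop=True)
    elif config.do_impute and frame.drop(columns=["id"]).isna().any().any():
        plan = _reimpute_plan(frame, config)
        frame = regression_impute(frame)
        n_imputed = int(frame["imputed"].sum())
    frame = add_outcome_columns(frame, config.perspective)

    cost_spec, effect_spec = _specs(config)
    cloud = bootstrap_sur(
        frame, cost_spec, effect_spec, B=config.B, seed=config.seed, reimpute=plan
    )
    jk = jackknife_sur(frame, cost_spec, effect_spec, reimpute=plan)
    dc, de = cloud.point
    ci_cost = bca_ci(cloud.delta_cost, dc, jk[:, 0])
    ci_eff = bca_ci(cloud.delta_effect, de, jk[:, 1])
    icer_point = icer(dc, de)
    boot_mean = icer_mean_of_ratios(cloud.pairs)
    if config.icer_mean_of_ratios:
        icer_point = replace(icer_point, value=boot_mean)
    return EvaluationResult(
        scenario_id=config.scenario_id,
        perspective=config.perspective,
        outcome=config.outcome,
        delta_cost=dc,
        delta_cost_ci=ci_cost,
        delta_effect=de,
        delta_effect_ci=ci_eff,
        icer=icer_point,
        icer_ci=icer_acceptability_ci(cloud.pairs),
        icer_bootstrap_mean=boot_mean,
        quadrants=quadrant_distribution(cloud.pairs),
        ceac=ceac(cloud.pairs, config.grid()),
        B=config.B,
        seed=config.seed,
        n_participants=len(frame),
        n_imputed=n_imputed,
        cloud=cloud.to_frame(),
    )


def sensitivity_grid(outcome: str = "qaly", B: int = 2500) -> list[ScenarioConfig]:
    """The 11 published sensitivity scenarios for one outcome: societal HLQ
    presenteeism, intervention price x {0.5, 0.8, 1.2, 1.5} under both
    perspectives, and completers-only under both perspectives."""
    configs = [
        ScenarioConfig("societal_hlq", "societal", outcome, presenteeism_method="hlq", B=B)
    ]
    for perspective in PERSPECTIVES:
        tag = "societal" if perspective == "societal" else "public"
        for mult in (1.2, 1.5, 0.8, 0.5):
            configs.append(
                ScenarioConfig(
                    f"{tag}_price_x{mult:g}",
                    perspective,
                    outcome,
                    intervention_cost_multiplier=mult,
                    B=B,
                )
            )
        configs.append(
            ScenarioConfig(f"{tag}_completers", perspective, outcome, sample="completers", B=B)
        )
    return configs


def run_matrix(
    cohort: list[ParticipantRecord],
    configs: list[ScenarioConfig],
    master_seed: int = 0,
    table: UnitCostTable | None = None,
) -> tuple[pd.DataFrame, list[EvaluationResult]]:
    """Run a list of scenarios with per-scenario seeds derived deterministically
    from a master seed; returns a summary table (one row per scenario) and the
    full results."""
    ids = [c.scenario_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ValueError("scenario ids must be unique")
    children = np.random.SeedSequence(master_seed).spawn(len(configs))
    results = []
    for config, child in zip(configs, children):
        seed = int(child.generate_state(1)[0] % 2**31)
        try:
            results.append(run_scenario(cohort, replace(config, seed=seed), table))
        except Exception as exc:
            raise RuntimeError(f"scenario {config.scenario_id!r} failed: {exc}") from exc
    return pd.DataFrame([r.to_row() for r in results]), results


def cost_category_table(
    frame: pd.DataFrame, B: int = 1000, seed: int = 0, level: float = 0.95
) -> pd.DataFrame:
    """Cost-table summary: per-category arm means with bootstrap percentile
    confidence intervals and the incremental difference, mirroring the layout
    of published per-category cost tables."""
    rng = np.random.default_rng(seed)
    alpha = 1.0 - level
    rows = []
    arm_idx = {a: np.flatnonzero(frame["arm"].to_numpy() == a) for a in (1, 0)}
    for cat in ALL_CATEGORIES:
        col = frame[COST_COLUMNS[cat]].to_numpy(float)
        row: dict[str, object] = {"category": cat}
        for arm_val, label in ((1, "intervention"), (0, "control")):
            vals = col[arm_idx[arm_val]]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                row[f"{label}_mean"] = np.nan
                row[f"{label}_lo"] = row[f"{label}_hi"] = np.nan
                continue
            boots = vals[rng.integers(0, vals.size, size=(B, vals.size))].mean(axis=1)
            row[f"{label}_mean"] = vals.mean()
            row[f"{label}_lo"] = np.quantile(boots, alpha / 2)
            row[f"{label}_hi"] = np.quantile(boots, 1 - alpha / 2)
        row["incremental"] = row["intervention_mean"] - row["control_mean"]
        rows.append(row)
    return pd.DataFrame(rows)


def write_table_csv(df: pd.DataFrame, path, seed=None, config_digest: str = "") -> None:
    """Write a results table with a commented metadata header block."""
    with open(path, "w") as fh:
        fh.write(f"# trialcea {__version__}\n")
        fh.write(f"# seed: {seed}\n")
        fh.write(f"# config: {config_digest}\n")
        df.to_csv(fh, index=False)
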