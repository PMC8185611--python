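"""Synthetic two-arm insomnia-trial cohorts.

The trial this package evaluates randomized 2 x 64 schoolteachers with
clinically significant insomnia to a guided internet-based CBT-I intervention
or a wait-list control, both with access to usual care. Individual patient
data are not available, so this module generates cohorts with the same
statistical structure the downstream analysis assumes:

* arm-level remission probabilities at 6 months (defaults 0.42 vs 0.06);
* SF-6D utility trajectories that are linear in time, yielding a configured
  mean QALY increment (default 0.019 over 0.5 years);
* right-skewed cost components: two-part (Bernoulli use x gamma magnitude)
  draws whose unconditional means match printed arm-level category means,
  with a multiplicative mean-one dependence on baseline depressive symptoms
  so that imputation has a real missing-at-random mechanism to correct for;
* ~12% dropout at follow-up, missing at random given baseline covariates.

Resource-use *counts* are derived from the drawn category costs by dividing
by the unit price, so costing a generated record recovers the drawn cost
exactly; counts are therefore continuous intensities rather than integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .costing import UnitCostTable

__all__ = [
    "DEFAULT_COST_MEANS",
    "DEFAULT_USE_PROBABILITIES",
    "CohortParams",
    "ResourceUse",
    "ParticipantRecord",
    "generate_cohort",
    "apply_dropout",
    "write_cohort_csv",
    "read_cohort_csv",
]

ARMS = ("intervention", "control")

#: 6-month per-participant cost-component means in EUR, (intervention, control),
#: seeded from the trial's printed cost table. The control-arm domestic-help
#: mean is chosen so the printed incremental (+15) is respected.
DEFAULT_COST_MEANS: dict[str, tuple[float, float]] = {
    "gp": (36.0, 51.0),
    "mental_health": (150.0, 163.0),
    "medication": (2.0, 5.0),
    "allied_health": (105.0, 170.0),
    "inpatient_psychiatric": (0.0, 0.0),
    "inpatient_psychosomatic": (0.0, 0.0),
    "informal_care": (884.0, 1260.0),
    "domestic_help": (310.0, 295.0),
    "out_of_pocket": (45.0, 73.0),
    "travel": (8.0, 15.0),
    "absenteeism": (1005.0, 1104.0),
    "presenteeism": (1185.0, 1883.0),
}

#: Probability that a participant has any use of a category within a recall
#: window (the Bernoulli part of the two-part cost model); plausible values
#: for an employed population with insomnia, configurable per category.
DEFAULT_USE_PROBABILITIES: dict[str, float] = {
    "gp": 0.70,
    "mental_health": 0.35,
    "medication": 0.25,
    "allied_health": 0.50,
    "inpatient_psychiatric": 0.05,
    "inpatient_psychosomatic": 0.05,
    "informal_care": 0.40,
    "domestic_help": 0.50,
    "out_of_pocket": 0.60,
    "travel": 0.70,
    "absenteeism": 0.50,
    "presenteeism": 0.80,
}

#: Assessment schedule in years: baseline, posttreatment (8 weeks), 6 months.
ASSESSMENT_TIMES = (0.0, 8 / 52, 0.5)


@dataclass
class CohortParams:
    """Generator configuration; defaults reproduce the trial's study conditions."""

    n_per_arm: int = 64
    p_remission_int: float = 0.42
    p_remission_ctr: float = 0.06
    utility_baseline_mean: float = 0.70
    utility_baseline_sd: float = 0.08
    utility_noise_sd: float = 0.05
    qaly_gain_int: float = 0.019  # QALYs over the 0.5-year horizon
    cost_component_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COST_MEANS)
    )
    use_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_USE_PROBABILITIES)
    )
    cost_cv: float = 1.0  # coefficient of variation of the gamma magnitude
    intervention_cost: float = 299.0
    dropout_rate: float = 0.12
    dropout_covariate_beta: float = 0.5  # log-odds per SD of baseline depression
    cost_covariate_loggamma: float = 0.2  # mean-one multiplicative depression effect
    depression_utility_slope: float = 0.03  # utility decrease per SD of depression
    covariate_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "age": (48.0, 10.0),
            "baseline_depression": (15.0, 8.0),
            "gross_daily_wage": (150.0, 35.0),
        }
    )
    n_windows: int = 2  # TiC-P recall windows covering the 6-month horizon
    workdays_per_window: float = 65.0
    workday_hours: float = 8.0
    recover_fraction: float = 0.3  # HLQ recoverable share of Osterhaus loss
    psychiatrist_cost_share: float = 0.5
    medication_agent: str = "antidepressant"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "p_remission_int": self.p_remission_int,
            "p_remission_ctr": self.p_remission_ctr,
            "dropout_rate": self.dropout_rate,
            "recover_fraction": self.recover_fraction,
            "psychiatrist_cost_share": self.psychiatrist_cost_share,
        }
        for name, p in probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name, p in self.use_probabilities.items():
            if not 0 <= p <= 1:
                raise ValueError(f"use probability for {name!r} must lie in [0, 1]")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if self.cost_cv <= 0:
            raise ValueError("cost_cv must be positive")
        for cat, means in self.cost_component_means.items():
            if min(means) < 0:
                raise ValueError(f"cost means for {cat!r} must be nonnegative")
        if self.intervention_cost < 0:
            raise ValueError("intervention_cost must be nonnegative")
        if not 0 <= self.utility_baseline_mean <= 1:
            raise ValueError("utility_baseline_mean must lie in [0, 1]")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")


@dataclass
class ResourceUse:
    """One recall window of self-reported resource use.

    Counts, hours, km and EUR amounts are nonnegative (NaN marks a missing
    window); ``inefficiency_score`` is the fraction of productivity lost on
    impaired workdays, and ``hours_to_recover`` feeds the HLQ presenteeism
    variant.
    """

    gp_visits: float = 0.0
    internal_medicine_visits: float = 0.0
    psychiatrist_sessions: float = 0.0
    psychotherapist_sessions: float = 0.0
    inpatient_days_psychiatric: float = 0.0
    inpatient_days_psychosomatic: float = 0.0
    allied_health_contacts: float = 0.0
    medication_ddd: dict[str, float] = field(default_factory=dict)
    informal_care_hours: float = 0.0
    domestic_help_hours: float = 0.0
    out_of_pocket: float = 0.0
    travel_km: float = 0.0
    absenteeism_days: float = 0.0
    presenteeism_days: float = 0.0
    inefficiency_score: float = 0.0
    hours_to_recover: float = 0.0
    workdays: float = 65.0

    @property
    def mental_health_sessions(self) -> float:
        return self.psychiatrist_sessions + self.psychotherapist_sessions

    def __post_init__(self) -> None:
        numeric = (
            "gp_visits internal_medicine_visits psychiatrist_sessions "
            "psychotherapist_sessions inpatient_days_psychiatric "
            "inpatient_days_psychosomatic allied_health_contacts "
            "informal_care_hours domestic_help_hours out_of_pocket travel_km "
            "absenteeism_days presenteeism_days hours_to_recover workdays"
        ).split()
        for name in numeric:
            if getattr(self, name) < 0:  # NaN compares False
                raise ValueError(f"{name} must be nonnegative")
        s = self.inefficiency_score
        if s < 0 or s > 1:
            raise ValueError("inefficiency_score must lie in [0, 1]")
        if self.presenteeism_days > self.workdays:
            raise ValueError("presenteeism_days cannot exceed workdays in the window")
        if any(v < 0 for v in self.medication_ddd.values()):
            raise ValueError("medication DDDs must be nonnegative")


@dataclass
class ParticipantRecord:
    """One trial participant: arm, baseline covariates, outcomes at three
    assessment points, per-window resource use, and missingness flags."""

    id: str
    arm: str
    age: float
    baseline_depression: float
    gross_daily_wage: float
    times: tuple[float, ...] = ASSESSMENT_TIMES
    isi: tuple[float, ...] = (0.0, 0.0, 0.0)
    utility: tuple[float, ...] = (0.0, 0.0, 0.0)
    resource_use: list[ResourceUse] = field(default_factory=list)
    completed_followup: bool = True
    missing_fields: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        if not all(t2 > t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("assessment times must be strictly increasing")
        for s in self.isi:
            if s < 0 or s > 28:  # NaN passes (missing)
                raise ValueError("ISI scores must lie in [0, 28]")
        for u in self.utility:
            if u < 0 or u > 1:
                raise ValueError("utilities must lie in [0, 1] when present")


def _gamma_components(rng, mean, p_use, cv, n, factor):
    """Two-part cost draw: Bernoulli(p_use) x gamma with unconditional mean
    ``mean``; ``factor`` is a mean-one multiplicative covariate effect."""
    if mean <= 0:
        return np.zeros(n)
    shape = 1.0 / cv**2
    scale = mean * cv**2 / p_use
    using = rng.random(n) < p_use
    draws = rng.gamma(shape, scale, size=n) * factor
    return np.where(using, draws, 0.0)


def generate_cohort(
    params: CohortParams, unit_costs: UnitCostTable | None = None
) -> list[ParticipantRecord]:
    """Generate ``2 * n_per_arm`` participant records under the configured
    study conditions; fully reproducible under a fixed seed.

    Dropout (``params.dropout_rate``) is applied with a seed derived from the
    cohort seed, so cohorts generated with different dropout rates share the
    same underlying complete data.
    """
    table = unit_costs or UnitCostTable()
    ss = np.random.SeedSequence(params.seed)
    gen_ss, drop_ss = ss.spawn(2)
    rng = np.random.default_rng(gen_ss)

    records: list[ParticipantRecord] = []
    for arm, p_rem in (("intervention", params.p_remission_int), ("control", params.p_remission_ctr)):
        records.extend(_generate_arm(rng, arm, p_rem, params, table))
    if params.dropout_rate > 0:
        records = apply_dropout(
            records,
            params.dropout_rate,
            seed=drop_ss,
            covariate="baseline_depression",
            beta=params.dropout_covariate_beta,
        )
    return records


def _generate_arm(rng, arm, p_remission, params, table):
    n = params.n_per_arm
    cv = params.cost_cv
    age_m, age_s = params.covariate_params["age"]
    dep_m, dep_s = params.covariate_params["baseline_depression"]
    wage_m, wage_s = params.covariate_params["gross_daily_wage"]

    z_dep = rng.standard_normal(n)  # latent standardized depressive burden
    age = np.clip(rng.normal(age_m, age_s, n), 25.0, 67.0)
    depression = np.clip(dep_m + dep_s * z_dep, 0.0, 52.0)
    wage = np.clip(rng.normal(wage_m, wage_s, n), 60.0, 320.0)

    # Utility trajectory: truncated-normal baseline, linear arm effect from t0
    # to t2 sized so the expected QALY (trapezoid AUC) increment is qaly_gain.
    horizon = ASSESSMENT_TIMES[-1]
    delta = (params.qaly_gain_int / (0.5 * horizon)) if arm == "intervention" else 0.0
    u0 = np.clip(
        rng.normal(
            params.utility_baseline_mean - params.depression_utility_slope * z_dep,
            params.utility_baseline_sd,
        ),
        0.0,
        1.0,
    )
    utilities = []
    for t in ASSESSMENT_TIMES:
        noise = rng.normal(0.0, params.utility_noise_sd, n) if t > 0 else 0.0
        utilities.append(np.clip(u0 + delta * (t / horizon) + noise, 0.0, 1.0))

    # ISI: baseline above the trial's inclusion threshold; final score drawn
    # below/above the symptom-free cutoff according to the remission draw.
    isi0 = np.rint(np.clip(rng.normal(19.0, 3.0, n), 15.0, 28.0))
    remitted = rng.random(n) < p_remission
    isi2 = np.where(remitted, rng.integers(2, 8, n), rng.integers(8, 25, n)).astype(float)
    isi1 = np.rint(np.clip((isi0 + isi2) / 2.0 + rng.normal(0.0, 2.0, n), 0.0, 28.0))

    # Per-window category costs (EUR), two-part gamma with a mean-one
    # multiplicative dependence on depressive burden.
    g = params.cost_covariate_loggamma
    factor = np.exp(g * z_dep - g**2 / 2.0)
    arm_idx = 0 if arm == "intervention" else 1
    window_costs: dict[str, list[np.ndarray]] = {}
    for cat, means in params.cost_component_means.items():
        mean_w = means[arm_idx] / params.n_windows
        p_use = params.use_probabilities.get(cat, 1.0)
        window_costs[cat] = [
            _gamma_components(rng, mean_w, p_use, cv, n, factor)
            for _ in range(params.n_windows)
        ]

    # Presenteeism decomposition (days x inefficiency x wage); when the drawn
    # cost implies more impaired days than the window holds, days are capped
    # at the workdays and the inefficiency score raised to preserve the cost
    # (clipped at full-loss, which truncates a negligible tail).
    ineff = rng.uniform(0.2, 0.6, (params.n_windows, n))
    med_price = table.medication_price(params.medication_agent)
    share = params.psychiatrist_cost_share

    prefix = "I" if arm == "intervention" else "C"
    records = []
    for i in range(n):
        windows = []
        for w in range(params.n_windows):
            c = {cat: window_costs[cat][w][i] for cat in window_costs}
            pres_ineff = ineff[w, i]
            pres_days = c["presenteeism"] / (pres_ineff * wage[i])
            if pres_days > params.workdays_per_window:
                pres_days = params.workdays_per_window
                pres_ineff = min(c["presenteeism"] / (pres_days * wage[i]), 1.0)
            windows.append(
                ResourceUse(
                    gp_visits=c["gp"] / table.price("gp_visit"),
                    psychiatrist_sessions=share * c["mental_health"]
                    / table.price("psychiatrist_session"),
                    psychotherapist_sessions=(1 - share) * c["mental_health"]
                    / table.price("psychotherapist_session"),
                    inpatient_days_psychiatric=c["inpatient_psychiatric"]
                    / table.price("inpatient_day_psychiatric"),
                    inpatient_days_psychosomatic=c["inpatient_psychosomatic"]
                    / table.price("inpatient_day_psychosomatic"),
                    allied_health_contacts=c["allied_health"]
                    / table.price("allied_health_contact"),
                    medication_ddd={params.medication_agent: c["medication"] / med_price},
                    informal_care_hours=c["informal_care"]
                    / table.price("opportunity_cost_per_hour"),
                    domestic_help_hours=c["domestic_help"]
                    / table.price("replacement_cost_per_hour"),
                    out_of_pocket=c["out_of_pocket"],
                    travel_km=c["travel"] / table.price("travel_per_km"),
                    absenteeism_days=c["absenteeism"] / wage[i],
                    presenteeism_days=pres_days,
                    inefficiency_score=pres_ineff,
                    hours_to_recover=params.recover_fraction
                    * pres_days
                    * pres_ineff
                    * params.workday_hours,
                    workdays=params.workdays_per_window,
                )
            )
        records.append(
            ParticipantRecord(
                id=f"{prefix}{i + 1:04d}",
                arm=arm,
                age=float(age[i]),
                baseline_depression=float(depression[i]),
                gross_daily_wage=float(wage[i]),
                isi=(float(isi0[i]), float(isi1[i]), float(isi2[i])),
                utility=tuple(float(u[i]) for u in utilities),
                resource_use=windows,
            )
        )
    return records


def apply_dropout(
    cohort: list[ParticipantRecord],
    rate: float,
    seed,
    covariate: str = "baseline_depression",
    beta: float = 0.5,
) -> list[ParticipantRecord]:
    """Mark follow-up fields of a random subset of participants as missing.

    Dropout is missing at random given the chosen baseline covariate: the
    per-participant probability is logistic in the standardized covariate with
    slope ``beta`` (log-odds per SD), and the intercept is calibrated so the
    cohort-mean probability equals ``rate``. Baseline fields are never removed.
    Returns new records; the input list is not modified.
    """
    if not 0 <= rate <= 1:
        raise ValueError("dropout rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if rate == 0:
        return [replace(rec) for rec in cohort]
    x = np.array([getattr(rec, covariate) for rec in cohort], dtype=float)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    if rate == 1:
        p = np.ones_like(z)
    elif beta == 0:
        p = np.full_like(z, rate)
    else:
        def mean_prob(alpha):
            return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + beta * z))))) - rate

        alpha = brentq(mean_prob, -30.0, 30.0)
        p = 1.0 / (1.0 + np.exp(-(alpha + beta * z)))

    dropped = rng.random(len(cohort)) < p
    out = []
    for rec, drop in zip(cohort, dropped):
        if not drop:
            out.append(replace(rec))
            continue
        nan = float("nan")
        out.append(
            replace(
                rec,
                isi=rec.isi[:-1] + (nan,),
                utility=rec.utility[:-1] + (nan,),
                resource_use=[
                    ResourceUse(
                        **{
                            **{k: nan for k in (
                                "gp_visits internal_medicine_visits psychiatrist_sessions "
                                "psychotherapist_sessions inpatient_days_psychiatric "
                                "inpatient_days_psychosomatic allied_health_contacts "
                                "informal_care_hours domestic_help_hours out_of_pocket "
                                "travel_km absenteeism_days presenteeism_days "
                                "inefficiency_score hours_to_recover"
                            ).split()},
                            "medication_ddd": {},
                            "workdays": use.workdays,
                        }
                    )
                    for use in rec.resource_use
                ],
                completed_followup=False,
                missing_fields={"isi_t2", "utility_t2", "resource_use"},
            )
        )
    return out


# ---------------------------------------------------------------------------
# Delimited-text persistence: one row per participant per recall window.
# Participant-level fields are repeated on every row; `window` indexes the
# recall window. `missing_fields` is a ';'-joined set. The reader reverses
# the writer losslessly (up to float formatting, which uses repr round-trip).

_PARTICIPANT_COLS = [
    "id", "arm", "age", "baseline_depression", "gross_daily_wage",
    "isi_t0", "isi_t1", "isi_t2", "utility_t0", "utility_t1", "utility_t2",
    "completed_followup", "missing_fields",
]
_USE_COLS = [
    "gp_visits", "internal_medicine_visits", "psychiatrist_sessions",
    "psychotherapist_sessions", "inpatient_days_psychiatric",
    "inpatient_days_psychosomatic", "allied_health_contacts",
    "informal_care_hours", "domestic_help_hours", "out_of_pocket",
    "travel_km", "absenteeism_days", "presenteeism_days",
    "inefficiency_score", "hours_to_recover", "workdays",
]


def cohort_to_frame(cohort: list[ParticipantRecord]) -> pd.DataFrame:
    """Long-format view: one row per participant per recall window."""
    rows = []
    for rec in cohort:
        base = {
            "id": rec.id,
            "arm": rec.arm,
            "age": rec.age,
            "baseline_depression": rec.baseline_depression,
            "gross_daily_wage": rec.gross_daily_wage,
            "isi_t0": rec.isi[0], "isi_t1": rec.isi[1], "isi_t2": rec.isi[2],
            "utility_t0": rec.utility[0], "utility_t1": rec.utility[1],
            "utility_t2": rec.utility[2],
            "completed_followup": rec.completed_followup,
            "missing_fields": ";".join(sorted(rec.missing_fields)),
        }
        for w, use in enumerate(rec.resource_use):
            row = dict(base, window=w)
            for col in _USE_COLS:
                row[col] = getattr(use, col)
            row["medication_ddd"] = ";".join(
                f"{agent}={float(ddd)!r}" for agent, ddd in sorted(use.medication_ddd.items())
            )
            rows.append(row)
    return pd.DataFrame(rows, columns=_PARTICIPANT_COLS[:-1] + ["missing_fields", "window"]
                        + _USE_COLS + ["medication_ddd"])


def write_cohort_csv(cohort: list[ParticipantRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[ParticipantRecord]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    records = []
    for pid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("window")
        first = grp.iloc[0]
        windows = []
        for _, row in grp.iterrows():
            ddd = {}
            med = row["medication_ddd"]
            if isinstance(med, str) and med:
                for item in med.split(";"):
                    agent, val = item.split("=")
                    ddd[agent] = float(val)
            windows.append(
                ResourceUse(**{col: float(row[col]) for col in _USE_COLS},
                            medication_ddd=ddd)
            )
        missing = first["missing_fields"]
        records.append(
            ParticipantRecord(
                id=str(pid),
                arm=str(first["arm"]),
                age=float(first["age"]),
                baseline_depression=float(first["baseline_depression"]),
                gross_daily_wage=float(first["gross_daily_wage"]),
                isi=(float(first["isi_t0"]), float(first["isi_t1"]), float(first["isi_t2"])),
                utility=(float(first["utility_t0"]), float(first["utility_t1"]),
                         float(first["utility_t2"])),
                resource_use=windows,
                completed_followup=bool(first["completed_followup"]),
                missing_fields=set(str(missing).split(";")) if isinstance(missing, str) and missing else set(),
            )
        )
    return records
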