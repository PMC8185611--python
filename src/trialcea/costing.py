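"""Per-participant costing under societal and public-health-care perspectives.

Resource-use records are valued with a unit-cost table (German 2013 guideline
prices, indexed by the consumer price index and convertible to pound sterling
at purchasing-power parity). Cost categories follow the usual trial-based
economic-evaluation layout:

* direct medical costs  -- intervention, GP/somatic care, mental health care,
  medication, allied health services;
* patient and family costs -- informal care, domestic help, out-of-pocket
  expenses, travel;
* productivity costs -- absenteeism (human capital approach) and presenteeism
  (Osterhaus inefficiency weighting, or the lower-bound HLQ recoverable-hours
  variant used in sensitivity analysis).

All internal arithmetic is carried out at full floating-point precision;
half-up rounding is applied only when reporting (2 decimal places for unit
prices, nearest integer for aggregate amounts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import math

import yaml

__all__ = [
    "ConfigurationError",
    "UnitCostTable",
    "CostBreakdown",
    "PERSPECTIVES",
    "round_half_up",
    "index_price",
    "convert_eur_to_gbp",
    "cost_health_care",
    "cost_medication",
    "cost_patient_family",
    "cost_absenteeism",
    "cost_presenteeism_osterhaus",
    "cost_presenteeism_hlq",
    "cost_participant",
    "aggregate",
    "DEFAULT_PRICES",
    "DEFAULT_MEDICATION_PRICES",
]


class ConfigurationError(KeyError):
    """A unit-cost table is missing a price the costing step needs."""


#: 2013 German guideline unit prices in EUR (consumer-price-index factor 1.04
#: already applied). ``allied_health_contact`` is not a guideline price; it is
#: a configurable assumption documented in docs/methods.md.
DEFAULT_PRICES: dict[str, float] = {
    "gp_visit": 20.92,
    "internal_medicine": 68.06,
    "psychiatrist_session": 46.55,
    "psychotherapist_session": 81.44,
    "inpatient_day_psychiatric": 335.52,
    "inpatient_day_psychosomatic": 306.41,
    "allied_health_contact": 30.00,
    "travel_per_km": 0.30,
    "opportunity_cost_per_hour": 23.10,
    "replacement_cost_per_hour": 18.33,
}

#: Synthetic per-DDD prices (statutory, private) in EUR; stands in for a
#: drug-registry lookup, which is out of scope.
DEFAULT_MEDICATION_PRICES: dict[str, tuple[float, float]] = {
    "antidepressant": (0.72, 0.95),
    "hypnotic": (0.80, 1.05),
}

PERSPECTIVES = ("societal", "public_health_care")


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero, the convention of printed cost tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class UnitCostTable:
    """Service-to-price mapping with indexation and currency-conversion factors.

    Parameters
    ----------
    reference_year : int
        Year the prices refer to (after indexation).
    index_factor : float
        Consumer-price-index multiplier applied to bring older prices to the
        reference year.
    ppp_eur_to_gbp : float
        Purchasing-power-parity rate; EUR 1 == GBP ``ppp_eur_to_gbp``.
    prices : mapping
        EUR unit prices by service key (see ``DEFAULT_PRICES``).
    medication_prices : mapping
        Per defined-daily-dose EUR prices by agent; either a single float or a
        ``(statutory, private)`` pair weighted by ``statutory_share``.
    statutory_share : float
        Fraction of the population with statutory health insurance.
    """

    reference_year: int = 2013
    index_factor: float = 1.04
    ppp_eur_to_gbp: float = 0.85
    prices: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PRICES))
    medication_prices: dict[str, object] = field(
        default_factory=lambda: dict(DEFAULT_MEDICATION_PRICES)
    )
    statutory_share: float = 0.89

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.prices.values()):
            raise ValueError("unit prices must be nonnegative")
        if not 0 < self.ppp_eur_to_gbp <= 1.5:
            raise ValueError("ppp_eur_to_gbp must lie in (0, 1.5]")
        if not 0 <= self.statutory_share <= 1:
            raise ValueError("statutory_share must lie in [0, 1]")
        if self.index_factor <= 0:
            raise ValueError("index_factor must be positive")

    def price(self, key: str) -> float:
        try:
            return self.prices[key]
        except KeyError:
            raise ConfigurationError(f"no unit price configured for service {key!r}")

    def medication_price(self, agent: str) -> float:
        """Weighted EUR price per defined daily dose for one agent.

        A ``(statutory, private)`` pair is weighted by the statutory population
        share; a single listed price is returned as is.
        """
        try:
            entry = self.medication_prices[agent]
        except KeyError:
            raise ConfigurationError(f"no medication price configured for agent {agent!r}")
        if isinstance(entry, (tuple, list)):
            statutory, private = entry
            return self.statutory_share * statutory + (1 - self.statutory_share) * private
        return float(entry)

    @classmethod
    def from_yaml(cls, path) -> "UnitCostTable":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "medication_prices" in data:
            data["medication_prices"] = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in data["medication_prices"].items()
            }
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["medication_prices"] = {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in self.medication_prices.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


#: CostBreakdown categories by perspective block.
DIRECT_MEDICAL = ("intervention", "gp", "mental_health", "medication", "allied_health")
PATIENT_FAMILY = ("informal_care", "domestic_help", "out_of_pocket", "travel")
PRODUCTIVITY = ("absenteeism", "presenteeism")
ALL_CATEGORIES = DIRECT_MEDICAL + PATIENT_FAMILY + PRODUCTIVITY


@dataclass
class CostBreakdown:
    """Per-participant 6-month EUR costs by category.

    Categories may be NaN when the underlying resource-use record is missing
    (lost to follow-up); imputation fills them before aggregation.
    """

    intervention: float = 0.0
    gp: float = 0.0
    mental_health: float = 0.0
    medication: float = 0.0
    allied_health: float = 0.0
    informal_care: float = 0.0
    domestic_help: float = 0.0
    out_of_pocket: float = 0.0
    travel: float = 0.0
    absenteeism: float = 0.0
    presenteeism: float = 0.0

    def __post_init__(self) -> None:
        for cat in ALL_CATEGORIES:
            v = getattr(self, cat)
            if v < 0:  # NaN passes, by design
                raise ValueError(f"cost category {cat!r} must be nonnegative, got {v}")

    @property
    def direct_medical(self) -> float:
        return float(sum(getattr(self, c) for c in DIRECT_MEDICAL))

    @property
    def patient_family(self) -> float:
        return float(sum(getattr(self, c) for c in PATIENT_FAMILY))

    @property
    def productivity(self) -> float:
        return float(sum(getattr(self, c) for c in PRODUCTIVITY))

    @property
    def societal_total(self) -> float:
        return self.direct_medical + self.patient_family + self.productivity

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in ALL_CATEGORIES}


def index_price(price_eur: float, index_factor: float, decimals: int | None = 2) -> float:
    """Bring a unit price to the reference year via a consumer-price-index factor.

    Rounded half-up to ``decimals`` places (unit prices are reported at 2 dp);
    pass ``decimals=None`` for the unrounded product.
    """
    if price_eur < 0:
        raise ValueError("price must be nonnegative")
    if index_factor <= 0:
        raise ValueError("index factor must be positive")
    out = price_eur * index_factor
    return out if decimals is None else round_half_up(out, decimals)


def convert_eur_to_gbp(amount_eur: float, ppp: float = 0.85, aggregate: bool = False) -> float:
    """Convert EUR to GBP at purchasing power parity.

    Unit-level amounts are reported at 2 decimal places, aggregate amounts at
    the nearest integer (half-up), matching printed-table conventions.
    """
    if ppp <= 0:
        raise ValueError("ppp rate must be positive")
    out = amount_eur * ppp
    return round_half_up(out, 0 if aggregate else 2)


def cost_health_care(use, table: UnitCostTable) -> dict[str, float]:
    """Value health-care utilization: units of resource use x unit prices.

    Returns the direct-medical service categories (excluding the fixed
    intervention price and medication, which are costed separately):
    ``gp`` covers GP visits plus internal-medicine consults; ``mental_health``
    covers psychiatrist/psychotherapist sessions and inpatient days by
    hospital type; ``allied_health`` covers allied-health contacts.
    """
    gp = use.gp_visits * table.price("gp_visit") + use.internal_medicine_visits * table.price(
        "internal_medicine"
    )
    mental = (
        use.psychiatrist_sessions * table.price("psychiatrist_session")
        + use.psychotherapist_sessions * table.price("psychotherapist_session")
        + use.inpatient_days_psychiatric * table.price("inpatient_day_psychiatric")
        + use.inpatient_days_psychosomatic * table.price("inpatient_day_psychosomatic")
    )
    allied = use.allied_health_contacts * table.price("allied_health_contact")
    return {"gp": gp, "mental_health": mental, "allied_health": allied}


def cost_medication(ddd_by_agent: Mapping[str, float], table: UnitCostTable) -> float:
    """Sum of defined daily doses x insurance-weighted per-DDD prices."""
    total = 0.0
    for agent, ddd in ddd_by_agent.items():
        total += ddd * table.medication_price(agent)
    return total


def cost_patient_family(use, table: UnitCostTable) -> dict[str, float]:
    """Value patient/family inputs: travel per km, informal care at the
    opportunity-cost rate, domestic help at the replacement rate, and
    out-of-pocket expenses passed through."""
    return {
        "travel": use.travel_km * table.price("travel_per_km"),
        "informal_care": use.informal_care_hours * table.price("opportunity_cost_per_hour"),
        "domestic_help": use.domestic_help_hours * table.price("replacement_cost_per_hour"),
        "out_of_pocket": use.out_of_pocket,
    }


def cost_absenteeism(days: float, gross_daily_wage: float) -> float:
    """Human capital approach: lost workdays valued at the gross daily wage."""
    if days < 0 or gross_daily_wage < 0:
        raise ValueError("days and wage must be nonnegative")
    return days * gross_daily_wage


def cost_presenteeism_osterhaus(
    days_impaired: float, inefficiency_score: float, gross_daily_wage: float
) -> float:
    """Osterhaus method: impaired workdays weighted by the self-reported
    inefficiency fraction, valued at the gross daily wage."""
    if not (0 <= inefficiency_score <= 1) and not math.isnan(inefficiency_score):
        raise ValueError("inefficiency_score must lie in [0, 1]")
    if days_impaired < 0 or gross_daily_wage < 0:
        raise ValueError("days and wage must be nonnegative")
    return days_impaired * inefficiency_score * gross_daily_wage


def cost_presenteeism_hlq(hours_to_recover: float, gross_hourly_wage: float) -> float:
    """HLQ method: recoverable, not-yet-compensated production hours valued at
    the gross hourly wage; a lower-bound alternative to the Osterhaus method."""
    if hours_to_recover < 0 or gross_hourly_wage < 0:
        raise ValueError("hours and wage must be nonnegative")
    return hours_to_recover * gross_hourly_wage


def cost_participant(
    record,
    table: UnitCostTable,
    presenteeism_method: str = "osterhaus",
    intervention_cost: float = 299.0,
    intervention_cost_multiplier: float = 1.0,
    workday_hours: float = 8.0,
) -> CostBreakdown:
    """Cost one participant's resource use over all recall windows.

    The intervention price is charged once to intervention-arm participants
    (scaled by the scenario multiplier) and is never missing; all other
    categories sum over recall windows and propagate NaN when a window is
    flagged missing.
    """
    if presenteeism_method not in ("osterhaus", "hlq"):
        raise ValueError(f"unknown presenteeism method {presenteeism_method!r}")
    totals = {c: 0.0 for c in ALL_CATEGORIES}
    totals["intervention"] = (
        intervention_cost * intervention_cost_multiplier
        if record.arm == "intervention"
        else 0.0
    )
    missing = "resource_use" in record.missing_fields
    for use in record.resource_use:
        hc = cost_health_care(use, table)
        pf = cost_patient_family(use, table)
        totals["gp"] += hc["gp"]
        totals["mental_health"] += hc["mental_health"]
        totals["allied_health"] += hc["allied_health"]
        totals["medication"] += cost_medication(use.medication_ddd, table)
        for k, v in pf.items():
            totals[k] += v
        totals["absenteeism"] += cost_absenteeism(use.absenteeism_days, record.gross_daily_wage)
        if presenteeism_method == "osterhaus":
            totals["presenteeism"] += cost_presenteeism_osterhaus(
                use.presenteeism_days, use.inefficiency_score, record.gross_daily_wage
            )
        else:
            totals["presenteeism"] += cost_presenteeism_hlq(
                use.hours_to_recover, record.gross_daily_wage / workday_hours
            )
    if missing:
        for c in ALL_CATEGORIES:
            if c != "intervention":
                totals[c] = float("nan")
    return CostBreakdown(**totals)


def aggregate(breakdown: CostBreakdown, perspective: str) -> float:
    """Total EUR cost under a perspective.

    ``public_health_care`` selects direct medical costs only; ``societal``
    adds patient/family and productivity costs.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}; expected one of {PERSPECTIVES}")
    for cat in ALL_CATEGORIES:
        if getattr(breakdown, cat, None) is None:
            raise ValueError(f"cost breakdown is missing category {cat!r}")
    if perspective == "public_health_care":
        return breakdown.direct_medical
    return breakdown.societal_total
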