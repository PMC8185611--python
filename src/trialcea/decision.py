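"""Decision analytics over the bootstrap cloud.

Turns (incremental cost, incremental effect) replicates into the outputs a
reimbursement decision needs: the incremental cost-effectiveness ratio (ICER)
with its bootstrap-acceptability confidence interval, the distribution of
replicates over the cost-effectiveness plane quadrants, and cost-effectiveness
acceptability curves (CEACs) over a willingness-to-pay grid.

Conventions (documented, cosmetic for continuous clouds):

* quadrant boundaries: dE = 0 counts as "not more effective" (west side),
  dC = 0 as "not more costly" (south side);
* a replicate is cost-effective at willingness-to-pay lambda iff its net
  monetary benefit lambda * dE - dC is strictly positive (ties are not
  cost-effective);
* the reported ICER is the ratio of the point-estimate incremental cost to
  the point-estimate incremental effect; the bootstrap mean of per-replicate
  ratios is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WtpGrid",
    "ICERResult",
    "EvaluationResult",
    "icer",
    "icer_mean_of_ratios",
    "classify_quadrant",
    "quadrant_distribution",
    "ceac",
    "icer_acceptability_ci",
]

QUADRANTS = ("NE", "NW", "SE", "SW")


@dataclass(frozen=True)
class WtpGrid:
    """Ordered willingness-to-pay values (currency per effect unit), starting at 0."""

    lambdas: tuple[float, ...]

    def __post_init__(self) -> None:
        lams = tuple(float(x) for x in self.lambdas)
        if not lams or lams[0] != 0:
            raise ValueError("willingness-to-pay grid must start at 0")
        if any(b < a for a, b in zip(lams, lams[1:])) or any(x < 0 for x in lams):
            raise ValueError("willingness-to-pay grid must be nondecreasing and nonnegative")
        object.__setattr__(self, "lambdas", lams)

    @classmethod
    def for_qaly(cls, stop: float = 50_000.0, step: float = 250.0) -> "WtpGrid":
        return cls(tuple(np.arange(0.0, stop + step / 2, step)))

    @classmethod
    def for_symptom_free(cls, stop: float = 5_000.0, step: float = 50.0) -> "WtpGrid":
        return cls(tuple(np.arange(0.0, stop + step / 2, step)))


@dataclass(frozen=True)
class ICERResult:
    """ICER point value with a dominance flag; when the intervention is
    dominant (cheaper and more effective) the ratio is suppressed in reports."""

    value: float
    dominant: bool

    def report(self) -> str:
        return "dominant" if self.dominant else f"{self.value:.0f}"


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """Incremental cost-effectiveness ratio dC / dE.

    Raises on dE == 0 (the ratio is undefined); flags dominance when the
    intervention is cheaper (dC < 0) and more effective (dE > 0).
    """
    if delta_effect == 0:
        raise ZeroDivisionError("incremental effect is zero; the ICER is undefined")
    return ICERResult(
        value=float(delta_cost / delta_effect),
        dominant=bool(delta_cost < 0 and delta_effect > 0),
    )


def icer_mean_of_ratios(cloud_pairs: np.ndarray) -> float:
    """Bootstrap mean of per-replicate dC/dE ratios (alternative ICER
    convention; unstable when replicate effects approach zero)."""
    pairs = np.asarray(cloud_pairs, float)
    de = pairs[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = pairs[:, 0] / de
    return float(np.mean(ratios[np.isfinite(ratios)]))


def classify_quadrant(delta_cost: float, delta_effect: float) -> str:
    """Cost-effectiveness plane quadrant of one replicate (effects on the
    horizontal axis, costs on the vertical axis)."""
    if not (np.isfinite(delta_cost) and np.isfinite(delta_effect)):
        raise ValueError("replicate must be finite")
    if delta_effect > 0:
        return "NE" if delta_cost > 0 else "SE"
    return "NW" if delta_cost > 0 else "SW"


def quadrant_distribution(cloud_pairs: np.ndarray) -> dict[str, float]:
    """Percentage of replicates per quadrant (exact, before any report
    rounding); the four values sum to 100."""
    pairs = np.asarray(cloud_pairs, float)
    if pairs.size == 0:
        raise ValueError("bootstrap cloud is empty")
    dc, de = pairs[:, 0], pairs[:, 1]
    n = len(pairs)
    return {
        "NE": 100.0 * np.count_nonzero((de > 0) & (dc > 0)) / n,
        "NW": 100.0 * np.count_nonzero((de <= 0) & (dc > 0)) / n,
        "SE": 100.0 * np.count_nonzero((de > 0) & (dc <= 0)) / n,
        "SW": 100.0 * np.count_nonzero((de <= 0) & (dc <= 0)) / n,
    }


def ceac(cloud_pairs: np.ndarray, grid: WtpGrid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: for each willingness-to-pay
    lambda, the fraction of replicates with net monetary benefit
    lambda * dE - dC > 0."""
    pairs = np.asarray(cloud_pairs, float)
    if pairs.size == 0:
        raise ValueError("bootstrap cloud is empty")
    lams = np.asarray(grid.lambdas, float)
    nmb = lams[:, None] * pairs[None, :, 1] - pairs[None, :, 0]
    prob = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"wtp": lams, "probability_cost_effective": prob})


def icer_acceptability_ci(cloud_pairs: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Bootstrap-acceptability confidence interval around the ICER.

    Replicates are ordered by their angle on the cost-effectiveness plane,
    measured counterclockwise from the south axis (pure cost saving), so the
    ordering runs SE (dominant) -> NE (increasing ICER) -> NW (dominated) and
    respects dominance. The interval endpoints are the ICERs of the replicates
    at the (1 -/+ level)/2 positions of this ordering; endpoints may be
    negative when the cloud spans dominance quadrants.
    """
    pairs = np.asarray(cloud_pairs, float)
    if len(pairs) < 100:
        raise ValueError("need at least 100 replicates for an acceptability interval")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    dc, de = pairs[:, 0], pairs[:, 1]
    # atan2 angle from the east axis, shifted so the south axis maps to 0 and
    # the angle grows counterclockwise: south 0, east pi/2, north pi, west 3pi/2.
    phi = np.mod(np.arctan2(dc, de) + np.pi / 2.0, 2.0 * np.pi)
    order = np.argsort(phi, kind="stable")
    alpha = 1.0 - level
    lo_idx = order[int(np.floor(alpha / 2 * (len(pairs) - 1)))]
    hi_idx = order[int(np.ceil((1 - alpha / 2) * (len(pairs) - 1)))]
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = dc[lo_idx] / de[lo_idx]
        hi = dc[hi_idx] / de[hi_idx]
    return (float(lo), float(hi))


@dataclass
class EvaluationResult:
    """Complete decision-analytic summary of one scenario."""

    scenario_id: str
    perspective: str
    outcome: str
    delta_cost: float
    delta_cost_ci: tuple[float, float]
    delta_effect: float
    delta_effect_ci: tuple[float, float]
    icer: ICERResult
    icer_ci: tuple[float, float]
    icer_bootstrap_mean: float
    quadrants: dict[str, float]
    ceac: pd.DataFrame = field(repr=False)
    B: int = 2500
    seed: int | None = None
    n_participants: int = 0
    n_imputed: int = 0
    cloud: pd.DataFrame | None = field(default=None, repr=False)

    def ceac_at(self, wtp: float) -> float:
        """Probability of cost-effectiveness at one willingness-to-pay value."""
        table = self.ceac
        match = table.loc[np.isclose(table["wtp"], wtp), "probability_cost_effective"]
        if match.empty:
            raise ValueError(f"willingness-to-pay {wtp} not on the evaluated grid")
        return float(match.iloc[0])

    def to_row(self) -> dict[str, object]:
        """Flat summary row (sensitivity-table shape)."""
        q = {k: round(v) for k, v in self.quadrants.items()}
        return {
            "scenario": self.scenario_id,
            "perspective": self.perspective,
            "outcome": self.outcome,
            "delta_cost": self.delta_cost,
            "delta_cost_lo": self.delta_cost_ci[0],
            "delta_cost_hi": self.delta_cost_ci[1],
            "delta_effect": self.delta_effect,
            "delta_effect_lo": self.delta_effect_ci[0],
            "delta_effect_hi": self.delta_effect_ci[1],
            "icer": self.icer.report(),
            "icer_lo": self.icer_ci[0],
            "icer_hi": self.icer_ci[1],
            "pct_NE": q["NE"],
            "pct_NW": q["NW"],
            "pct_SE": q["SE"],
            "pct_SW": q["SW"],
            "B": self.B,
            "n": self.n_participants,
        }
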