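"""Health outcomes: insomnia symptom-free status and SF-6D-based QALYs.

Symptom-free status is the dichotomized Insomnia Severity Index (ISI, 0-28):
a score strictly below 8 counts as symptom-free. QALYs are the area under the
curve of linearly interpolated health-state utilities over the follow-up
horizon (0.5 years by default), with utilities treated as pipeline inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ISI_SYMPTOM_FREE_CUTOFF",
    "UtilityTrajectory",
    "symptom_free_status",
    "qaly_auc",
    "remission_rate",
]

ISI_SYMPTOM_FREE_CUTOFF = 8  # symptom-free iff ISI < 8 (strict)


@dataclass(frozen=True)
class UtilityTrajectory:
    """Health-state utilities aligned to assessment times (years since
    randomization). Times must be strictly increasing; utilities in [0, 1]."""

    times: tuple[float, ...]
    utilities: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        u = np.asarray(self.utilities, dtype=float)
        if t.size < 2 or t.size != u.size:
            raise ValueError("trajectory needs >= 2 aligned (time, utility) points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(u)):
            raise ValueError("utilities must be finite")
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError("utilities must lie in [0, 1]")


def symptom_free_status(isi_score):
    """True iff the ISI score is strictly below the symptom-free cutoff of 8.

    Accepts scalars or arrays; scores outside [0, 28] are rejected.
    """
    arr = np.asarray(isi_score, dtype=float)
    if np.any(arr < 0) or np.any(arr > 28):
        raise ValueError("ISI scores must lie in [0, 28]")
    out = arr < ISI_SYMPTOM_FREE_CUTOFF
    return bool(out) if np.isscalar(isi_score) or arr.ndim == 0 else out


def qaly_auc(traj_or_times, utilities: Sequence[float] | None = None) -> float:
    """QALYs as the trapezoid integral of linearly interpolated utilities.

    Accepts either a :class:`UtilityTrajectory` or ``(times, utilities)``
    arrays. For a constant utility ``u`` over ``T`` years this returns
    ``u * T``.
    """
    if utilities is None:
        traj = traj_or_times
        times, utils = traj.times, traj.utilities
    else:
        times, utils = traj_or_times, utilities
        UtilityTrajectory(tuple(float(t) for t in times), tuple(float(u) for u in utils))
    return float(np.trapezoid(np.asarray(utils, float), np.asarray(times, float)))


def remission_rate(cohort, arm: str) -> float:
    """Proportion of an arm's participants who are symptom-free at the final
    follow-up, among those with an observed final ISI score."""
    scores = [
        rec.isi[-1]
        for rec in cohort
        if rec.arm == arm and not np.isnan(rec.isi[-1]) and "isi_t2" not in rec.missing_fields
    ]
    if not scores:
        raise ValueError(f"no participants with observed final ISI in arm {arm!r}")
    return float(np.mean([symptom_free_status(s) for s in scores]))
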