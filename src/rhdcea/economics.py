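"""Cost accounting, ICERs, dominance and threshold classification.

Direct medical costs per arm combine hospitalization costs per episode with
lifetime follow-up costs per incident case (interpolated in age at
diagnosis; the secondary-prophylaxis component scaled by the arm's
adherence).  Program costs accrue to the intervention arm only.  ICERs use
the convention (intervention - control) cost over (control - intervention)
DALYs, so a dominant (cost-saving) program reports a negative ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .cohort_model import EventLedger
from .parameters import CostSchedule, ParameterSet, Thresholds

__all__ = [
    "CostResult",
    "CeaClassification",
    "lifetime_cost",
    "arm_costs",
    "combine_costs",
    "icer",
    "program_cost_ceiling",
]

#: lifetime-cost state -> prophylaxis class of Table 2
_PROPHYLAXIS_CLASS = {
    "arf": "arf_alone",
    "rhd_mild": "arf_with_rhd",
    "rhd_severe": "arf_with_rhd",
    "surgery": "arf_with_rhd",
}

#: ledger events billed as hospitalizations, by hospitalization category.
#: A recurrent episode in an established RHD patient is admitted under the
#: corresponding RHD category, not the uncomplicated-ARF tariff.
_HOSPITALIZATION_EVENTS = {
    "arf": ("first_arf", "recurrence_arf_history"),
    "rhd_mild": ("rhd_onset_mild", "recurrent_rhd_onset_mild",
                 "recurrence_rhd_history_mild"),
    "rhd_severe": (
        "rhd_onset_severe", "recurrent_rhd_onset_severe",
        "recurrence_rhd_history_severe", "progression",
    ),
}

#: ledger events carrying a lifetime follow-up cost, by lifetime state.
#: Acute deaths (during an episode) incur no lifetime follow-up; end-stage
#: chronic deaths incur the severe-RHD stream, progression deaths the
#: mild-RHD stream they lived in beforehand.
_LIFETIME_EVENTS = {
    "arf": ("final_arf_only",),
    "rhd_mild": ("final_rhd_mild", "progression_death"),
    "rhd_severe": ("final_rhd_severe", "chronic_rhd_death"),
    "surgery": ("final_post_surgery",),
}


def _interp_range(pair, age: float, age_min: float, age_max: float) -> float:
    young, old = pair
    frac = np.clip((age - age_min) / (age_max - age_min), 0.0, 1.0)
    return float(young + (old - young) * frac)


def lifetime_cost(
    state: str, age_at_diagnosis: float, costs: CostSchedule, arm,
    age_min: float = 5.0, age_max: float = 24.0,
) -> float:
    """Lifetime direct medical cost for one incident case of ``state``.

    Linear interpolation between the young (age ``age_min``) and old
    (age ``age_max``) endpoints of the published range; the secondary
    prophylaxis component is rescaled by the arm's adherence fraction.
    """
    if state not in costs.lifetime_range:
        raise ValueError(f"no lifetime cost range for state {state!r}")
    label = arm.label if hasattr(arm, "label") else str(arm)
    total = _interp_range(costs.lifetime_range[state], age_at_diagnosis,
                          age_min, age_max)
    proph = _interp_range(
        costs.prophylaxis_range[_PROPHYLAXIS_CLASS[state]], age_at_diagnosis,
        age_min, age_max,
    )
    adherence = costs.adherence[label]
    return total - proph + proph * adherence


@dataclass
class ArmCosts:
    arm: str
    medical_cost: float
    program_cost: float

    @property
    def total(self) -> float:
        return self.medical_cost + self.program_cost


@dataclass
class CostResult:
    """Per-arm cost components and the incremental comparison."""

    per_arm: Dict[str, ArmCosts]

    @property
    def incremental_cost(self) -> float:
        return self.per_arm["intervention"].total - self.per_arm["control"].total

    @property
    def medical_savings(self) -> float:
        return (
            self.per_arm["control"].medical_cost
            - self.per_arm["intervention"].medical_cost
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"arm": ac.arm, "component": "medical_cost", "value": ac.medical_cost}
            for ac in self.per_arm.values()
        ] + [
            {"arm": ac.arm, "component": "program_cost", "value": ac.program_cost}
            for ac in self.per_arm.values()
        ] + [
            {"arm": "comparison", "component": "incremental_cost",
             "value": self.incremental_cost},
            {"arm": "comparison", "component": "medical_savings",
             "value": self.medical_savings},
        ]
        return pd.DataFrame(rows, columns=["arm", "component", "value"])


def arm_costs(
    ledger: EventLedger, params: ParameterSet, arm,
    medical_multiplier: float = 1.0, program_multiplier: float = 1.0,
) -> ArmCosts:
    """Direct medical plus (intervention-only) program cost for one arm.

    The multipliers implement the sensitivity-analysis scaling of all
    medical costs and all program costs respectively.
    """
    label = arm.label if hasattr(arm, "label") else str(arm)
    costs = params.costs
    cohort = params.cohort
    ages = ledger.ages.astype(float)

    hosp = 0.0
    for category, events in _HOSPITALIZATION_EVENTS.items():
        n_events = sum(ledger.total(e) for e in events)
        hosp += costs.hospitalization[category] * n_events

    lifetime = 0.0
    for state, events in _LIFETIME_EVENTS.items():
        per_age = np.array([
            lifetime_cost(state, a, costs, label, cohort.age_min, cohort.age_max)
            for a in ages
        ])
        for event in events:
            lifetime += float(ledger.events[event].sum(axis=0) @ per_age)

    medical = (hosp + lifetime) * medical_multiplier
    program = (
        costs.program_total * program_multiplier
        if label == "intervention" else 0.0
    )
    return ArmCosts(arm=label, medical_cost=medical, program_cost=program)


def combine_costs(control: ArmCosts, intervention: ArmCosts) -> CostResult:
    return CostResult(per_arm={"control": control, "intervention": intervention})


@dataclass
class CeaClassification:
    """An ICER with dominance flags and nested threshold labels."""

    icer: Optional[float]
    cost_saving: bool
    undefined: bool = False
    dominated: bool = False
    labels: Dict[str, bool] = field(default_factory=dict)


def icer(
    incremental_cost: float,
    dalys_averted: float,
    thresholds: Optional[Thresholds] = None,
) -> CeaClassification:
    """Classify an incremental cost / DALYs-averted pair.

    Positive health gain with negative incremental cost is dominant
    (cost saving); the negative ratio is still reported.  Zero health gain
    yields the ``undefined`` flag; negative health gain with extra cost is
    ``dominated``.  Labels are nested: cost saving implies best buy implies
    very cost-effective implies cost-effective.
    """
    t = thresholds or Thresholds()
    if dalys_averted == 0.0:
        return CeaClassification(
            icer=None, cost_saving=False, undefined=True,
            labels={k: False for k in
                    ("cost_saving", "best_buy", "very_cost_effective",
                     "cost_effective")},
        )
    ratio = incremental_cost / dalys_averted
    if dalys_averted > 0:
        cost_saving = incremental_cost < 0.0
        labels = {
            "cost_saving": cost_saving,
            "best_buy": ratio <= t.best_buy,
            "very_cost_effective": ratio <= t.very_cost_effective,
            "cost_effective": ratio <= t.cost_effective,
        }
        return CeaClassification(icer=ratio, cost_saving=cost_saving,
                                 labels=labels)
    # dalys_averted < 0: the program loses health
    return CeaClassification(
        icer=ratio, cost_saving=False, dominated=incremental_cost >= 0.0,
        labels={k: False for k in
                ("cost_saving", "best_buy", "very_cost_effective",
                 "cost_effective")},
    )


def program_cost_ceiling(
    medical_savings: float, dalys_averted: float, threshold: float
) -> float:
    """Largest program cost keeping the ICER at or below ``threshold``:
    medical savings plus threshold x DALYs averted."""
    if dalys_averted < 0:
        raise ValueError("dalys_averted must be >= 0")
    return medical_savings + threshold * dalys_averted
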