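"""DALY computation: years of life lost, years lived with disability.

YLL follows the Global Burden of Disease closed form with age weighting
``C x e^{-beta x}`` modulated by ``K`` and an optional discount rate ``r``:

    YLL(a, L) = K*C/beta^2 * [e^{-beta a}(beta a + 1)
                              - e^{-beta(a+L)}(beta(a+L) + 1)] + (1-K) L

for ``r = 0`` (the analytic limit of the discounted form, used exactly —
not a numerical approximation), and the full discounted expression for
``r > 0``.  ``L`` is the residual life expectancy at the age of death,
linearly interpolated from the parameter set's life table.  YLD is
disability weight x duration, without age weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .cohort_model import DEATH_EVENTS, EventLedger
from .parameters import CohortSpec, DalyParams

__all__ = ["DalyResult", "yll", "yld", "compute_dalys", "residual_life_expectancy"]


def residual_life_expectancy(age: float, params: DalyParams) -> float:
    """Residual life expectancy at ``age`` (linear interpolation)."""
    ages = sorted(params.life_table)
    if not ages or age < ages[0] or age > ages[-1]:
        raise ValueError(
            f"age {age} outside the life table range "
            f"[{ages[0] if ages else None}, {ages[-1] if ages else None}]"
        )
    return float(np.interp(age, ages, [params.life_table[a] for a in ages]))


def _yll_weighted_undiscounted(a: float, L: float, C: float, beta: float) -> float:
    b = beta
    return (C / b**2) * (
        math.exp(-b * a) * (b * a + 1.0) - math.exp(-b * (a + L)) * (b * (a + L) + 1.0)
    )


def _yll_weighted_discounted(
    a: float, L: float, C: float, beta: float, r: float
) -> float:
    # integral over x in [a, a+L] of C x e^{-beta x} e^{-r(x-a)}
    rb = r + beta
    upper = math.exp(-rb * (a + L)) * (rb * (a + L) + 1.0)
    lower = math.exp(-rb * a) * (rb * a + 1.0)
    return (C * math.exp(r * a) / rb**2) * (lower - upper)


def yll(age_at_death: float, params: DalyParams) -> float:
    """Years of life lost for one death at ``age_at_death``.

    Raises ``ValueError`` if the age is not covered by the life table.
    """
    a = float(age_at_death)
    if a < 0:
        raise ValueError(f"age_at_death must be >= 0, got {a}")
    L = residual_life_expectancy(a, params)
    if L <= 0:
        return 0.0
    K, C, beta, r = params.K, params.C, params.beta, params.r
    if r == 0.0:
        weighted = _yll_weighted_undiscounted(a, L, C, beta)
        unweighted = L
    else:
        weighted = _yll_weighted_discounted(a, L, C, beta, r)
        unweighted = (1.0 - math.exp(-r * L)) / r
    return K * weighted + (1.0 - K) * unweighted


def yld(disability_weight: float, duration: float) -> float:
    """Years lived with disability: weight x duration (no age weighting)."""
    if not 0.0 <= disability_weight <= 1.0:
        raise ValueError(f"disability weight {disability_weight} outside [0, 1]")
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    return disability_weight * duration


@dataclass
class DalyResult:
    """YLL / YLD / DALY totals per arm plus the averted difference."""

    per_arm: Dict[str, Dict[str, float]]
    averted: Dict[str, float] = field(default_factory=dict)
    averted_per_100k: float = 0.0

    def daly(self, arm: str) -> float:
        return self.per_arm[arm]["daly"]


def _arm_burden(ledger: EventLedger, params: DalyParams) -> Dict[str, float]:
    yll_total = 0.0
    for event in DEATH_EVENTS:
        counts = ledger.events[event]
        if counts.sum() == 0.0:
            continue
        offset = ledger.age_offsets[event]
        per_age = np.array(
            [yll(float(age) + offset, params) for age in ledger.ages]
        )
        yll_total += float(counts.sum(axis=0) @ per_age)
    weights = params.disability_weights
    yld_total = sum(
        yld(weights[state], years)
        for state, years in ledger.person_years.items()
    )
    return {
        "yll": yll_total,
        "yld": float(yld_total),
        "daly": yll_total + float(yld_total),
    }


def compute_dalys(
    ledger_control: EventLedger,
    ledger_intervention: EventLedger,
    params: DalyParams,
    cohort: CohortSpec,
) -> DalyResult:
    """DALYs per arm and averted (control minus intervention).

    Both ledgers must come from the same cohort specification; YLL accrues
    at each death's attained age, YLD from person-years in disabled states.
    """
    if ledger_control.cohort_size != ledger_intervention.cohort_size:
        raise ValueError(
            "ledgers were produced from different cohort sizes "
            f"({ledger_control.cohort_size} vs {ledger_intervention.cohort_size})"
        )
    per_arm = {
        ledger_control.arm: _arm_burden(ledger_control, params),
        ledger_intervention.arm: _arm_burden(ledger_intervention, params),
    }
    control = per_arm[ledger_control.arm]
    intervention = per_arm[ledger_intervention.arm]
    averted = {
        key: control[key] - intervention[key] for key in ("yll", "yld", "daly")
    }
    return DalyResult(
        per_arm=per_arm,
        averted=averted,
        averted_per_100k=averted["daly"] / cohort.size * 1e5,
    )


def daly_result_frame(result: DalyResult) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    rows = [
        {"arm": arm, "component": comp, "value": val}
        for arm, comps in result.per_arm.items()
        for comp, val in comps.items()
    ]
    rows += [
        {"arm": "averted", "component": comp, "value": val}
        for comp, val in result.averted.items()
    ]
    rows.append(
        {"arm": "averted", "component": "daly_per_100k",
         "value": result.averted_per_100k}
    )
    return pd.DataFrame(rows, columns=["arm", "component", "value"])
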