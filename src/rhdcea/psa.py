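"""Probabilistic sensitivity analysis.

Each Monte Carlo draw samples every transition probability from a beta
distribution parameterised by its 95% bounds (method of moments: the bound
midpoint, or the point estimate when it is not the midpoint, as the mean;
``(high - low) / (2 x 1.96)`` as the standard deviation), and independent
medical and program cost multipliers from Uniform(0.5, 2.0).  The full
pipeline — cohort engine, DALYs, costs, ICER classification — is re-run per
draw with one seeded generator and a documented draw order (probability
edges in sorted (edge, arm) order, then the medical, then the program
multiplier), so identical seeds give identical per-draw tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .cohort_model import run_cohort_with_overrides
from .economics import arm_costs, combine_costs, icer
from .health_outcomes import compute_dalys
from .parameters import ParameterSet, ProbabilityEstimate
from .scenarios import BASE_CASE, Scenario, apply_scenario

__all__ = ["BetaFitError", "PsaSummary", "beta_from_bounds", "run_psa"]

_LABELS = ("cost_saving", "best_buy", "very_cost_effective", "cost_effective")


class BetaFitError(ValueError):
    """Raised when (low, high) bounds are too wide for a beta fit."""


def beta_from_bounds(low: float, high: float) -> Tuple[float, float]:
    """Method-of-moments beta parameters from a symmetric 95% range.

    Mean ``m = (low + high) / 2``, standard deviation
    ``s = (high - low) / (2 x 1.96)``; requires ``s^2 < m(1 - m)``.
    ``low == high`` signals a point mass and is handled by the caller.
    """
    if not 0.0 <= low < high <= 1.0:
        raise ValueError(f"bounds must satisfy 0 <= low < high <= 1, got "
                         f"({low}, {high})")
    m = 0.5 * (low + high)
    s = (high - low) / (2.0 * 1.96)
    return _beta_moments(m, s)


def _beta_moments(m: float, s: float) -> Tuple[float, float]:
    var = s * s
    if var >= m * (1.0 - m):
        raise BetaFitError(
            f"variance {var:.3g} >= m(1-m) = {m * (1 - m):.3g}; widen the "
            f"source denominator n so the bounds admit a beta fit"
        )
    nu = m * (1.0 - m) / var - 1.0
    return m * nu, (1.0 - m) * nu


def _sampler_for(est: ProbabilityEstimate):
    """A ``draw(rng) -> float`` callable for one probability estimate.

    Point masses (low == high) return the point.  Interior point estimates
    recenter the fitted beta on the point (same spread); boundary points
    (0 or 1) fall back to the bound midpoint, which the rule-of-three bound
    keeps strictly inside (0, 1).
    """
    low, high = float(est.low), float(est.high)
    if low == high:
        value = est.point
        return lambda rng: value
    s = (high - low) / (2.0 * 1.96)
    m = est.point if 0.0 < est.point < 1.0 else 0.5 * (low + high)
    alpha, beta = _beta_moments(m, s)
    return lambda rng: float(rng.beta(alpha, beta))


@dataclass
class PsaSummary:
    """Summary of one PSA run (Table-3-style row)."""

    n_draws: int
    seed: int
    scenario: str
    mean_icer: float                    # mean of per-draw ICERs
    ratio_of_means_icer: float          # mean incremental cost / mean DALYs
    interval: Tuple[float, float]       # 2.5th / 97.5th percentile of ICERs
    probabilities: Dict[str, float]
    n_excluded: int = 0                 # draws with DALYs averted <= 0
    n_rejected: int = 0                 # invalid draws resampled

    def nested(self) -> bool:
        p = self.probabilities
        return (p["cost_saving"] <= p["best_buy"]
                <= p["very_cost_effective"] <= p["cost_effective"])


def run_psa(
    params: ParameterSet,
    scenario: Optional[Scenario] = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> Tuple[PsaSummary, pd.DataFrame]:
    """Run ``n_draws`` Monte Carlo draws of the full pipeline.

    Returns the summary plus the per-draw table (sampled probabilities,
    cost multipliers, DALYs averted, incremental cost, ICER and labels).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    scenario = scenario or BASE_CASE
    base = apply_scenario(params, scenario)
    lo, hi = base.cost_multiplier_bounds

    keys = sorted(
        (edge, arm)
        for edge, by_arm in base.probabilities.items()
        for arm in by_arm
    )
    samplers = {
        key: _sampler_for(base.probabilities[key[0]][key[1]]) for key in keys
    }

    rng = np.random.default_rng(seed)
    thresholds = base.thresholds
    records: List[dict] = []
    n_rejected = 0
    for draw_index in range(n_draws):
        while True:
            sampled = {key: samplers[key](rng) for key in keys}
            if all(0.0 <= v <= 1.0 for v in sampled.values()):
                break
            n_rejected += 1  # defensive: beta draws already lie in [0, 1]
        medical_mult = lo + (hi - lo) * rng.random()
        program_mult = lo + (hi - lo) * rng.random()

        overrides = {
            arm: {edge: sampled[(edge, a)] for (edge, a) in keys if a == arm}
            for arm in ("control", "intervention")
        }
        ledger_c = run_cohort_with_overrides(base, "control",
                                             overrides["control"])
        ledger_i = run_cohort_with_overrides(base, "intervention",
                                             overrides["intervention"])
        dalys = compute_dalys(ledger_c, ledger_i, base.daly, base.cohort)
        cost = combine_costs(
            arm_costs(ledger_c, base, "control", medical_mult, program_mult),
            arm_costs(ledger_i, base, "intervention", medical_mult,
                      program_mult),
        )
        cls = icer(cost.incremental_cost, dalys.averted["daly"], thresholds)
        record = {
            "draw_index": draw_index,
            "medical_multiplier": medical_mult,
            "program_multiplier": program_mult,
            "dalys_averted": dalys.averted["daly"],
            "incremental_cost": cost.incremental_cost,
            "medical_savings": cost.medical_savings,
            "icer": np.nan if cls.icer is None else cls.icer,
            **{f"label_{k}": cls.labels[k] for k in _LABELS},
        }
        record.update({f"p_{edge}__{arm}": v
                       for (edge, arm), v in sampled.items()})
        records.append(record)

    table = pd.DataFrame(records)
    valid = table["dalys_averted"] > 0.0
    icers = table.loc[valid, "icer"].to_numpy(dtype=float)
    n_excluded = int((~valid).sum())
    mean_icer = float(np.mean(icers)) if icers.size else float("nan")
    interval = (
        (float(np.percentile(icers, 2.5)), float(np.percentile(icers, 97.5)))
        if icers.size else (float("nan"), float("nan"))
    )
    mean_dalys = float(table["dalys_averted"].mean())
    ratio_of_means = (
        float(table["incremental_cost"].mean()) / mean_dalys
        if mean_dalys != 0.0 else float("nan")
    )
    probabilities = {
        k: float(table[f"label_{k}"].mean()) for k in _LABELS
    }
    summary = PsaSummary(
        n_draws=n_draws, seed=seed, scenario=scenario.name,
        mean_icer=mean_icer, ratio_of_means_icer=ratio_of_means,
        interval=interval, probabilities=probabilities,
        n_excluded=n_excluded, n_rejected=n_rejected,
    )
    return summary, table
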