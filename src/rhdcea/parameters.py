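"""Model inputs: parameter types, defaults, validation and (de)serialisation.

Every quantity the model consumes lives in a :class:`ParameterSet`:
the cohort definition, first-episode ARF incidence per arm, the
transition probabilities of the decision tree (point estimates with
binomial uncertainty bounds), cost schedules, DALY constants, and the
WHO-CHOICE style cost-effectiveness thresholds.  Defaults are the
published inputs of the Pinar del Rio ARF/RHD program evaluation
(2010 USD throughout); unpublished tree edges carry documented,
calibrated placeholder values (see docs/methods.md).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import pandas as pd

__all__ = [
    "ProbabilityEstimate",
    "IncidenceSeries",
    "CohortSpec",
    "CostSchedule",
    "DalyParams",
    "Thresholds",
    "ParameterSet",
    "ConfigurationError",
    "binomial_bounds",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "validate",
]

ARMS = ("control", "intervention")

#: z value used for the 95% binomial bounds that parameterise the PSA betas.
Z_95 = 1.96


class ConfigurationError(ValueError):
    """Raised when a configuration document cannot be turned into a valid
    :class:`ParameterSet` (unknown keys, schema violations, invalid values)."""


def binomial_bounds(point: float, n: int) -> Tuple[float, float]:
    """95% bounds for a binomial proportion via the normal (Wald) formula.

    ``low = max(0, p - 1.96*sqrt(p(1-p)/n))`` and symmetrically for ``high``.
    At the degenerate points ``p in {0, 1}`` the normal standard error is
    zero; the open side is then bounded with the rule of three (``3/n``) so
    that downstream beta fitting never collapses to a point mass.

    Parameters
    ----------
    point : probability in [0, 1]
    n : denominator (number at risk), ``n >= 1``
    """
    if n < 1:
        raise ValueError(f"binomial_bounds requires n >= 1, got {n}")
    if not 0.0 <= point <= 1.0:
        raise ValueError(f"point must lie in [0, 1], got {point}")
    if point == 0.0:
        return 0.0, min(1.0, 3.0 / n)
    if point == 1.0:
        return max(0.0, 1.0 - 3.0 / n), 1.0
    se = math.sqrt(point * (1.0 - point) / n)
    return max(0.0, point - Z_95 * se), min(1.0, point + Z_95 * se)


@dataclass
class ProbabilityEstimate:
    """A transition probability with 95% uncertainty bounds.

    When ``n_source`` is given, the bounds are recomputed from the binomial
    formula so that (point, low, high, n_source) stay mutually consistent.
    """

    name: str
    point: float
    low: Optional[float] = None
    high: Optional[float] = None
    n_source: Optional[int] = None
    arm_specific: bool = True

    def __post_init__(self) -> None:
        if self.n_source is not None and (self.low is None or self.high is None):
            self.low, self.high = binomial_bounds(self.point, self.n_source)
        if self.low is None:
            self.low = self.point
        if self.high is None:
            self.high = self.point


@dataclass
class IncidenceSeries:
    """First-episode ARF incidence per 100,000 person-years over the program."""

    arm: str
    rates: Dict[int, float]

    def years(self) -> List[int]:
        return sorted(self.rates)

    def as_array(self) -> List[float]:
        return [self.rates[y] for y in self.years()]


@dataclass
class CohortSpec:
    """The closed 1986 cohort pushed through the decision tree."""

    size: int = 273_933
    age_min: int = 5
    age_max: int = 24
    index_year: int = 1986
    program_years: int = 10
    #: discrete distribution of age at first ARF episode (defaults uniform)
    onset_age_distribution: Dict[int, float] = field(default_factory=dict)
    #: years from a first episode to recurrence / surgery (and one further
    #: year to progression); chronic RHD death follows after
    #: ``DalyParams.chronic_rhd_duration`` years
    event_lag: float = 1.0

    def __post_init__(self) -> None:
        if not self.onset_age_distribution:
            ages = range(self.age_min, self.age_max + 1)
            w = 1.0 / len(list(ages))
            self.onset_age_distribution = {
                a: w for a in range(self.age_min, self.age_max + 1)
            }


@dataclass
class CostSchedule:
    """Hospitalization, lifetime and program costs (2010 USD).

    Lifetime ranges are stored as ``(cost_young, cost_old)``: the larger
    endpoint maps to the youngest diagnosis age (longer remaining follow-up),
    interpolated linearly in age at diagnosis between the cohort age limits.
    The secondary-prophylaxis component of each lifetime cost is scaled by
    the arm's adherence fraction.
    """

    hospitalization: Dict[str, float] = field(default_factory=dict)
    lifetime_range: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    prophylaxis_range: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    adherence: Dict[str, float] = field(default_factory=dict)
    program_components: Dict[str, float] = field(default_factory=dict)

    @property
    def program_total(self) -> float:
        return float(sum(self.program_components.values()))


@dataclass
class DalyParams:
    """Constants of the Global Burden of Disease DALY formulas.

    ``C`` and ``beta`` are the classic GBD age-weighting constants,
    ``K`` modulates age weighting (K=0 recovers unweighted DALYs) and
    ``r`` is the discount rate (0 by default: the evaluation did not
    discount).  ``life_table`` maps age to residual life expectancy in
    years and is linearly interpolated.
    """

    C: float = 0.1658
    beta: float = 0.04
    K: float = 1.0
    r: float = 0.0
    disability_weights: Dict[str, float] = field(default_factory=dict)
    arf_episode_duration: float = 0.25
    chronic_rhd_duration: float = 5.0
    life_table: Dict[float, float] = field(default_factory=dict)


@dataclass
class Thresholds:
    """Cost-effectiveness acceptability thresholds (USD per DALY averted)."""

    best_buy: float = 100.0
    very_cost_effective: float = 5702.0
    cost_effective: float = 17_106.0


@dataclass
class ParameterSet:
    cohort: CohortSpec
    incidence: Dict[str, IncidenceSeries]
    probabilities: Dict[str, Dict[str, ProbabilityEstimate]]
    costs: CostSchedule
    daly: DalyParams
    thresholds: Thresholds
    cost_multiplier_bounds: Tuple[float, float] = (0.5, 2.0)
    #: per-field provenance ("default" or "override"), filled by the loader
    provenance: Dict[str, str] = field(default_factory=dict, compare=False)

    def prob(self, edge: str, arm: str) -> float:
        try:
            return self.probabilities[edge][arm].point
        except KeyError as exc:
            raise ConfigurationError(
                f"missing transition probability for edge {edge!r}, arm {arm!r}"
            ) from exc

    def estimate(self, edge: str, arm: str) -> ProbabilityEstimate:
        try:
            return self.probabilities[edge][arm]
        except KeyError as exc:
            raise ConfigurationError(
                f"missing transition probability for edge {edge!r}, arm {arm!r}"
            ) from exc

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

#: First-episode ARF incidence per 100,000 person-years (index year 1986).
#: The do-nothing counterfactual holds the 1986 rate constant.
DEFAULT_INCIDENCE = {
    "control": {y: 12.2 for y in range(1986, 1996)},
    "intervention": {
        1986: 12.2,
        1987: 7.4,
        1988: 2.6,
        1989: 2.7,
        1990: 2.8,
        1991: 3.0,
        1992: 3.2,
        1993: 4.1,
        1994: 1.9,
        1995: 2.0,
    },
}

# Transition probabilities of the decision tree, per arm, as
# (point, n_source).  Published rows carry their published point values;
# the remaining edges are calibrated reconstructions of the unpublished
# supplementary list, fitted once to the published base-case aggregates
# (docs/methods.md).  n_source values are the model's own implied at-risk
# counts rounded to integers (floored at 5 so uncertainty bounds stay
# meaningful for near-empty intervention strata).
DEFAULT_PROBABILITIES: Dict[str, Dict[str, Tuple[float, int]]] = {
    # death during a first ARF episode
    "arf_cfr": {"control": (0.014, 334), "intervention": (0.014, 115)},
    # new RHD among survivors of a first ARF episode  [calibrated]
    "rhd_given_first_arf": {"control": (0.60, 330), "intervention": (0.05, 113)},
    # severe carditis among new RHD at first presentation  [calibrated]
    "severe_given_first_rhd": {"control": (0.10, 198), "intervention": (0.05, 6)},
    # death given severe carditis at first presentation
    "cfr_first_severe": {"control": (0.357, 20), "intervention": (0.0, 5)},
    # valve surgery among surviving RHD at first presentation
    "surgery_first_rhd": {"control": (0.071, 190), "intervention": (0.0, 6)},
    # >=1 ARF recurrence, history of ARF without RHD
    "recurrence_arf_history": {"control": (0.567, 132), "intervention": (0.176, 108)},
    # >=1 ARF recurrence, history of RHD
    "recurrence_rhd_history": {"control": (0.778, 176), "intervention": (0.250, 6)},
    # new RHD among survivors of a recurrence (no prior RHD)  [calibrated]
    "rhd_given_recurrence": {"control": (0.80, 75), "intervention": (0.05, 19)},
    # severe carditis with a recurrent episode  [calibrated]
    "severe_given_recurrent_rhd": {"control": (0.10, 197), "intervention": (0.05, 5)},
    # death given severe carditis with a recurrent episode
    "cfr_recurrent_severe": {"control": (0.444, 20), "intervention": (0.0, 5)},
    # progression of established mild-moderate RHD  [calibrated]
    "progression_given_mild": {"control": (0.25, 218), "intervention": (0.05, 6)},
    # death with progression of RHD
    "cfr_progression": {"control": (0.385, 54), "intervention": (0.0, 5)},
    # valve surgery with progression of RHD
    "surgery_progression": {"control": (0.154, 33), "intervention": (0.0, 5)},
}

DEFAULT_HOSPITALIZATION = {"arf": 1490.0, "rhd_mild": 2139.0, "rhd_severe": 6343.0}

# (cost at diagnosis age 5, cost at diagnosis age 24)
DEFAULT_LIFETIME_RANGE = {
    "arf": (18_699.0, 15_515.0),
    "rhd_mild": (25_259.0, 21_359.0),
    "rhd_severe": (49_298.0, 40_714.0),
    "surgery": (62_532.0, 56_285.0),
}

DEFAULT_PROPHYLAXIS_RANGE = {
    "arf_alone": (6222.0, 3205.0),
    "arf_with_rhd": (11_161.0, 7262.0),
}

DEFAULT_ADHERENCE = {"control": 0.683, "intervention": 0.969}

# Printed components sum to 202,889; the printed grand total is 202,890
# (component rounding in the source).  Components are rescaled by the
# sub-cent factor 202,890/202,889 so that additivity and the printed total
# hold simultaneously.
_PRINTED_PROGRAM_COMPONENTS = {
    "administration": 43_372.0,
    "education_health_workers": 151_206.0,
    "education_community": 1360.0,
    "survey_before": 1796.0,
    "survey_after": 4021.0,
    "external_evaluation": 1134.0,
}
_PROGRAM_TOTAL = 202_890.0
_scale = _PROGRAM_TOTAL / sum(_PRINTED_PROGRAM_COMPONENTS.values())
DEFAULT_PROGRAM_COMPONENTS = {
    k: v * _scale for k, v in _PRINTED_PROGRAM_COMPONENTS.items()
}

# GBD 2010 disability weights used as documented placeholders: acute
# infectious episode (severe) for an ARF attack, heart-failure weights for
# mild-moderate and severe RHD.  Overridable; results that depend on them
# are dominated by YLL, not YLD.
DEFAULT_DISABILITY_WEIGHTS = {
    "arf_episode": 0.210,
    "rhd_mild": 0.070,
    "rhd_severe": 0.186,
    "post_surgery": 0.070,
}

# Synthetic standard residual-life-expectancy table, consistent in shape
# and level with the GBD-era reference life tables (values rounded to 0.1
# years); linearly interpolated between knots, overridable in config.
DEFAULT_LIFE_TABLE = {
    0: 82.5, 1: 82.0, 5: 78.1, 10: 73.2, 15: 68.3, 20: 63.4, 25: 58.6,
    30: 53.8, 35: 49.0, 40: 44.2, 45: 39.4, 50: 34.7, 55: 30.0, 60: 25.4,
    65: 21.0, 70: 16.9, 75: 13.1, 80: 9.8, 85: 7.1, 90: 5.0, 95: 3.5,
    100: 2.5,
}


def default_parameters() -> ParameterSet:
    """The published base-case parameterization (plus documented defaults)."""
    probabilities = {
        edge: {
            arm: ProbabilityEstimate(name=f"{edge}/{arm}", point=p, n_source=n)
            for arm, (p, n) in by_arm.items()
        }
        for edge, by_arm in DEFAULT_PROBABILITIES.items()
    }
    params = ParameterSet(
        cohort=CohortSpec(),
        incidence={
            arm: IncidenceSeries(arm=arm, rates=dict(rates))
            for arm, rates in DEFAULT_INCIDENCE.items()
        },
        probabilities=probabilities,
        costs=CostSchedule(
            hospitalization=dict(DEFAULT_HOSPITALIZATION),
            lifetime_range={k: tuple(v) for k, v in DEFAULT_LIFETIME_RANGE.items()},
            prophylaxis_range={
                k: tuple(v) for k, v in DEFAULT_PROPHYLAXIS_RANGE.items()
            },
            adherence=dict(DEFAULT_ADHERENCE),
            program_components=dict(DEFAULT_PROGRAM_COMPONENTS),
        ),
        daly=DalyParams(
            disability_weights=dict(DEFAULT_DISABILITY_WEIGHTS),
            life_table={float(k): float(v) for k, v in DEFAULT_LIFE_TABLE.items()},
        ),
        thresholds=Thresholds(),
    )
    params.provenance = {key: "default" for key in _flatten(_to_dict(params))}
    return params


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check(violations: List[str], ok: bool, message: str) -> None:
    if not ok:
        violations.append(message)


def validate(params: ParameterSet) -> List[str]:
    """Return a list of invariant violations (empty iff the set is valid)."""
    v: List[str] = []
    c = params.cohort
    _check(v, c.size > 0, f"cohort.size: {c.size} must be > 0")
    _check(v, c.age_min < c.age_max,
           f"cohort.age_min/age_max: {c.age_min} must be < {c.age_max}")
    _check(v, c.program_years > 0,
           f"cohort.program_years: {c.program_years} must be > 0")
    total_w = sum(c.onset_age_distribution.values())
    _check(v, abs(total_w - 1.0) < 1e-9,
           f"cohort.onset_age_distribution: weights sum to {total_w}, not 1")
    _check(v, all(c.age_min <= a <= c.age_max for a in c.onset_age_distribution),
           "cohort.onset_age_distribution: ages outside [age_min, age_max]")

    for arm in ARMS:
        _check(v, arm in params.incidence, f"incidence.{arm}: missing series")
    for arm, series in params.incidence.items():
        years = series.years()
        _check(v, len(years) == c.program_years,
               f"incidence.{arm}: {len(years)} years, expected {c.program_years}")
        _check(v, years == list(range(years[0], years[0] + len(years))) if years
               else False, f"incidence.{arm}: years must be consecutive")
        for y, r in series.rates.items():
            _check(v, r >= 0, f"incidence.{arm}.{y}: rate {r} must be >= 0")

    for edge, by_arm in params.probabilities.items():
        for arm in ARMS:
            _check(v, arm in by_arm, f"probabilities.{edge}: missing arm {arm!r}")
        for arm, est in by_arm.items():
            prefix = f"probabilities.{edge}.{arm}"
            _check(v, 0.0 <= est.point <= 1.0,
                   f"{prefix}.point: {est.point} outside [0, 1]")
            _check(v, est.low <= est.point <= est.high,
                   f"{prefix}: bounds ({est.low}, {est.high}) do not bracket "
                   f"point {est.point}")
            _check(v, 0.0 <= est.low and est.high <= 1.0,
                   f"{prefix}: bounds ({est.low}, {est.high}) outside [0, 1]")
            if est.n_source is not None:
                _check(v, est.n_source >= 1,
                       f"{prefix}.n_source: {est.n_source} must be >= 1")

    costs = params.costs
    for name, value in costs.hospitalization.items():
        _check(v, value >= 0, f"costs.hospitalization.{name}: {value} < 0")
    for name, (young, old) in costs.lifetime_range.items():
        _check(v, young >= old >= 0,
               f"costs.lifetime_range.{name}: requires cost_young >= cost_old "
               f">= 0, got ({young}, {old})")
    for name, (young, old) in costs.prophylaxis_range.items():
        _check(v, young >= old >= 0,
               f"costs.prophylaxis_range.{name}: requires cost_young >= "
               f"cost_old >= 0, got ({young}, {old})")
    for arm, a in costs.adherence.items():
        _check(v, 0.0 <= a <= 1.0, f"costs.adherence.{arm}: {a} outside [0, 1]")
    for name, value in costs.program_components.items():
        _check(v, value >= 0, f"costs.program_components.{name}: {value} < 0")

    d = params.daly
    _check(v, 0.0 <= d.K <= 1.0, f"daly.K: {d.K} outside [0, 1]")
    _check(v, d.r >= 0.0, f"daly.r: {d.r} must be >= 0")
    _check(v, d.C > 0.0, f"daly.C: {d.C} must be > 0")
    _check(v, d.beta > 0.0, f"daly.beta: {d.beta} must be > 0")
    _check(v, d.chronic_rhd_duration > 0.0,
           f"daly.chronic_rhd_duration: {d.chronic_rhd_duration} must be > 0")
    _check(v, d.arf_episode_duration >= 0.0,
           f"daly.arf_episode_duration: {d.arf_episode_duration} must be >= 0")
    for state, w in d.disability_weights.items():
        _check(v, 0.0 <= w <= 1.0,
               f"daly.disability_weights.{state}: {w} outside [0, 1]")
    ages = sorted(d.life_table)
    _check(v, bool(ages), "daly.life_table: empty")
    if ages:
        les = [d.life_table[a] for a in ages]
        _check(v, all(b < a for a, b in zip(les, les[1:])),
               "daly.life_table: residual life expectancy must be strictly "
               "decreasing in age")
        max_reach = c.age_max + c.program_years + 2 + d.chronic_rhd_duration
        _check(v, ages[0] <= c.age_min and ages[-1] >= max_reach,
               f"daly.life_table: must cover ages [{c.age_min}, {max_reach}]")

    t = params.thresholds
    _check(v, 0 < t.best_buy < t.very_cost_effective < t.cost_effective,
           f"thresholds: must satisfy 0 < best_buy < very_cost_effective < "
           f"cost_effective, got ({t.best_buy}, {t.very_cost_effective}, "
           f"{t.cost_effective})")

    lo, hi = params.cost_multiplier_bounds
    _check(v, 0 < lo < hi, f"cost_multiplier_bounds: invalid ({lo}, {hi})")
    return v


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def _to_dict(params: ParameterSet) -> dict:
    d = {
        "cohort": asdict(params.cohort),
        "incidence": {
            arm: {str(y): r for y, r in s.rates.items()}
            for arm, s in params.incidence.items()
        },
        "probabilities": {
            edge: {
                arm: {
                    "point": est.point,
                    "low": est.low,
                    "high": est.high,
                    "n_source": est.n_source,
                }
                for arm, est in by_arm.items()
            }
            for edge, by_arm in params.probabilities.items()
        },
        "costs": {
            "hospitalization": dict(params.costs.hospitalization),
            "lifetime_range": {k: list(v) for k, v in
                               params.costs.lifetime_range.items()},
            "prophylaxis_range": {k: list(v) for k, v in
                                  params.costs.prophylaxis_range.items()},
            "adherence": dict(params.costs.adherence),
            "program_components": dict(params.costs.program_components),
        },
        "daly": {
            "C": params.daly.C,
            "beta": params.daly.beta,
            "K": params.daly.K,
            "r": params.daly.r,
            "disability_weights": dict(params.daly.disability_weights),
            "arf_episode_duration": params.daly.arf_episode_duration,
            "chronic_rhd_duration": params.daly.chronic_rhd_duration,
            "life_table": {str(a): v for a, v in params.daly.life_table.items()},
        },
        "thresholds": asdict(params.thresholds),
        "cost_multiplier_bounds": list(params.cost_multiplier_bounds),
    }
    d["cohort"]["onset_age_distribution"] = {
        str(a): w for a, w in params.cohort.onset_age_distribution.items()
    }
    return d


def _flatten(d: Mapping, prefix: str = "") -> Dict[str, object]:
    out: Dict[str, object] = {}
    for k, val in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(val, Mapping):
            out.update(_flatten(val, key))
        else:
            out[key] = val
    return out


def _deep_update(base: dict, override: Mapping, path: str = "") -> List[str]:
    """Update ``base`` in place; return the dotted keys that were overridden.

    Unknown keys raise :class:`ConfigurationError`.
    """
    touched: List[str] = []
    for k, val in override.items():
        key = f"{path}.{k}" if path else str(k)
        if k not in base:
            raise ConfigurationError(f"unknown configuration key: {key!r}")
        if isinstance(base[k], dict):
            if not isinstance(val, Mapping):
                raise ConfigurationError(
                    f"configuration key {key!r} expects a mapping, got "
                    f"{type(val).__name__}"
                )
            touched.extend(_deep_update(base[k], val, key))
        else:
            base[k] = val
            touched.append(key)
    return touched


def _from_dict(d: dict) -> ParameterSet:
    try:
        cohort_d = dict(d["cohort"])
        cohort_d["onset_age_distribution"] = {
            int(a): float(w)
            for a, w in cohort_d.get("onset_age_distribution", {}).items()
        }
        cohort = CohortSpec(**cohort_d)
        incidence = {
            arm: IncidenceSeries(
                arm=arm, rates={int(y): float(r) for y, r in rates.items()}
            )
            for arm, rates in d["incidence"].items()
        }
        probabilities = {}
        for edge, by_arm in d["probabilities"].items():
            probabilities[edge] = {}
            for arm, spec in by_arm.items():
                n = spec.get("n_source")
                if n is not None:
                    # keep (low, high) consistent with the binomial formula
                    est = ProbabilityEstimate(
                        name=f"{edge}/{arm}", point=float(spec["point"]),
                        n_source=int(n),
                    )
                else:
                    est = ProbabilityEstimate(
                        name=f"{edge}/{arm}", point=float(spec["point"]),
                        low=spec.get("low"), high=spec.get("high"),
                    )
                probabilities[edge][arm] = est
        costs = CostSchedule(
            hospitalization={k: float(x) for k, x in
                             d["costs"]["hospitalization"].items()},
            lifetime_range={k: (float(a), float(b)) for k, (a, b) in
                            d["costs"]["lifetime_range"].items()},
            prophylaxis_range={k: (float(a), float(b)) for k, (a, b) in
                               d["costs"]["prophylaxis_range"].items()},
            adherence={k: float(x) for k, x in d["costs"]["adherence"].items()},
            program_components={k: float(x) for k, x in
                                d["costs"]["program_components"].items()},
        )
        daly_d = d["daly"]
        daly = DalyParams(
            C=float(daly_d["C"]), beta=float(daly_d["beta"]),
            K=float(daly_d["K"]), r=float(daly_d["r"]),
            disability_weights={k: float(x) for k, x in
                                daly_d["disability_weights"].items()},
            arf_episode_duration=float(daly_d["arf_episode_duration"]),
            chronic_rhd_duration=float(daly_d["chronic_rhd_duration"]),
            life_table={float(a): float(x) for a, x in
                        daly_d["life_table"].items()},
        )
        thresholds = Thresholds(**d["thresholds"])
        bounds = tuple(float(x) for x in d["cost_multiplier_bounds"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed configuration: {exc}") from exc
    return ParameterSet(
        cohort=cohort, incidence=incidence, probabilities=probabilities,
        costs=costs, daly=daly, thresholds=thresholds,
        cost_multiplier_bounds=bounds,  # type: ignore[arg-type]
    )


def load_parameters(
    config_source: Union[None, str, Path, Mapping] = None
) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from defaults plus overrides.

    ``config_source`` may be absent (pure defaults), a mapping, or a path to
    a JSON document.  Overrides are merged key-by-key; unknown keys are
    rejected.  Per-field provenance ("default" vs "override") is retained
    on the returned object.
    """
    base = _to_dict(default_parameters())
    touched: List[str] = []
    if config_source is not None:
        if isinstance(config_source, (str, Path)):
            with open(config_source, "r", encoding="utf-8") as fh:
                override = json.load(fh)
        elif isinstance(config_source, Mapping):
            override = config_source
        else:
            raise ConfigurationError(
                f"unsupported configuration source: {type(config_source).__name__}"
            )
        touched = _deep_update(base, override)
    params = _from_dict(base)
    violations = validate(params)
    if violations:
        raise ConfigurationError(
            "invalid configuration:\n  " + "\n  ".join(violations)
        )
    params.provenance = {key: "default" for key in _flatten(base)}
    for key in touched:
        for flat in params.provenance:
            if flat == key or flat.startswith(key + "."):
                params.provenance[flat] = "override"
    return params


def save_parameters(params: ParameterSet, path: Union[str, Path]) -> None:
    """Write a ParameterSet to a JSON document (round-trips exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_to_dict(params), fh, indent=2, sort_keys=True)
        fh.write("\n")


def parameter_table(params: ParameterSet) -> pd.DataFrame:
    """Tidy table of every effective parameter with its provenance."""
    flat = _flatten(_to_dict(params))
    rows = [
        {"parameter": key, "value": value,
         "provenance": params.provenance.get(key, "default")}
        for key, value in sorted(flat.items())
    ]
    return pd.DataFrame(rows, columns=["parameter", "value", "provenance"])
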