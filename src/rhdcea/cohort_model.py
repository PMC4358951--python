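"""Decision-tree cohort engine for ARF/RHD natural history.

Two routes through the same tree topology:

* :func:`run_cohort` — deterministic expected-value engine.  Each program
  year's first ARF episodes (incidence x cohort size) are pushed along the
  tree edges by multiplying expected counts; chronic states run to death at
  the attained age.  All counts are real-valued expectations and are exactly
  linear in cohort size.
* :func:`microsimulate` — seeded individual-level simulation of the same
  topology with the same probabilities, used as an independent validation
  oracle (integer counts, reproducible by seed).

Tree topology (per first-episode cohort slice, annual cycle):

    first ARF ─┬─ die (ARF case fatality)
               └─ survive ─┬─ no RHD ──· possible recurrence ─· new RHD ...
                           └─ RHD at first presentation
                                ├─ severe carditis ── die / survive
                                ├─ mild-moderate
                                └─ surviving cases: valve surgery
    established RHD ── recurrence (RHD history) ── severe carditis ── die
    established mild-moderate ── progression ─┬─ die
                                              ├─ surgery
                                              └─ end-stage (chronic) severe
    chronic end-stage RHD ── death after a fixed duration

Recurrence, progression and surgery probabilities are one-shot lifetime
probabilities applied once per person at risk; background mortality is
ignored over the horizon (closed cohort, disease-attributable events only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .parameters import ARMS, ConfigurationError, ParameterSet

__all__ = [
    "Arm",
    "EventLedger",
    "REQUIRED_EDGES",
    "DEATH_EVENTS",
    "run_cohort",
    "microsimulate",
]

#: every edge the tree topology references; run_cohort refuses to start
#: if any is missing from the parameter set for the requested arm.
REQUIRED_EDGES = (
    "arf_cfr",
    "rhd_given_first_arf",
    "severe_given_first_rhd",
    "cfr_first_severe",
    "surgery_first_rhd",
    "recurrence_arf_history",
    "recurrence_rhd_history",
    "rhd_given_recurrence",
    "severe_given_recurrent_rhd",
    "cfr_recurrent_severe",
    "progression_given_mild",
    "cfr_progression",
    "surgery_progression",
)

#: ledger events that are deaths (YLL accrues at count x yll(attained age))
DEATH_EVENTS = (
    "arf_death",
    "first_rhd_death",
    "recurrence_death",
    "progression_death",
    "chronic_rhd_death",
)

#: terminal alive classes; together with deaths they exhaust each slice
ALIVE_CLASSES = (
    "final_arf_only",
    "final_rhd_mild",
    "final_rhd_severe",
    "final_post_surgery",
)


@dataclass(frozen=True)
class Arm:
    """One comparator arm; ``control`` is the do-nothing counterfactual."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in ARMS:
            raise ValueError(f"unknown arm {self.label!r}; expected one of {ARMS}")


CONTROL = Arm("control")
INTERVENTION = Arm("intervention")


def _as_label(arm) -> str:
    return arm.label if isinstance(arm, Arm) else str(arm)


@dataclass
class EventLedger:
    """Expected (or simulated) event counts by program year and onset age.

    ``events[name]`` is a ``(n_years, n_ages)`` array of counts for the
    cohort slice that had its first ARF episode in that year at that onset
    age.  ``age_offsets[name]`` gives the years between onset and the event,
    so the attained age at the event is ``onset_age + age_offsets[name]``.
    ``person_years`` holds total years lived in each disability state.
    """

    arm: str
    years: np.ndarray
    ages: np.ndarray
    events: Dict[str, np.ndarray]
    age_offsets: Dict[str, float]
    person_years: Dict[str, float]
    cohort_size: float

    def total(self, event: str) -> float:
        return float(self.events[event].sum())

    def totals(self) -> Dict[str, float]:
        return {name: self.total(name) for name in self.events}

    def deaths_total(self) -> float:
        return float(sum(self.total(e) for e in DEATH_EVENTS))

    def conservation_residual(self) -> float:
        """Max |inflow - outflow| over slices: first episodes must equal
        deaths plus terminal alive classes in every (year, age) cell."""
        outflow = sum(self.events[e] for e in DEATH_EVENTS + ALIVE_CLASSES)
        inflow = self.events["first_arf"]
        denom = np.maximum(inflow, 1e-300)
        return float(np.max(np.abs(inflow - outflow) / denom))

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (event, year, onset age) with the
        attained age at the event."""
        rows = []
        for name, arr in self.events.items():
            off = self.age_offsets.get(name, 0.0)
            for i, year in enumerate(self.years):
                for j, age in enumerate(self.ages):
                    if arr[i, j] != 0.0:
                        rows.append(
                            (self.arm, int(year), int(age), name,
                             float(age + off), float(arr[i, j]))
                        )
        frame = pd.DataFrame(
            rows,
            columns=["arm", "year", "onset_age", "event", "attained_age",
                     "expected_count"],
        )
        return frame.sort_values(["event", "year", "onset_age"]).reset_index(
            drop=True
        )


def _edge_values(
    params: ParameterSet, arm: str, overrides: Optional[Mapping[str, float]]
) -> Dict[str, float]:
    values: Dict[str, float] = {}
    for edge in REQUIRED_EDGES:
        if overrides is not None and edge in overrides:
            values[edge] = float(overrides[edge])
        else:
            values[edge] = params.prob(edge, arm)  # raises ConfigurationError
    return values


def _first_episodes(
    params: ParameterSet, arm: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(years, ages, F) where F[t, a] = expected first episodes."""
    cohort = params.cohort
    try:
        series = params.incidence[arm]
    except KeyError as exc:
        raise ConfigurationError(f"missing incidence series for arm {arm!r}") from exc
    years = np.asarray(series.years(), dtype=int)
    rates = np.asarray(series.as_array(), dtype=float) / 1e5
    ages = np.asarray(sorted(cohort.onset_age_distribution), dtype=int)
    weights = np.asarray(
        [cohort.onset_age_distribution[int(a)] for a in ages], dtype=float
    )
    F = cohort.size * rates[:, None] * weights[None, :]
    return years, ages, F


def _flows(F: np.ndarray, p: Mapping[str, float]) -> Dict[str, np.ndarray]:
    """Push expected counts along the tree edges (all arrays share F's shape)."""
    d_arf = F * p["arf_cfr"]
    surv = F - d_arf

    rhd1 = surv * p["rhd_given_first_arf"]
    arf_only = surv - rhd1
    sev1 = rhd1 * p["severe_given_first_rhd"]
    mild1 = rhd1 - sev1
    d_sev1 = sev1 * p["cfr_first_severe"]
    sev1_surv = sev1 - d_sev1
    op_sev = sev1_surv * p["surgery_first_rhd"]
    op_mild = mild1 * p["surgery_first_rhd"]
    surgery1 = op_sev + op_mild
    sev_pool = sev1_surv - op_sev
    mild_pool = mild1 - op_mild

    # recurrence among survivors with ARF history but no RHD
    rec_arf = arf_only * p["recurrence_arf_history"]
    new_rhd = rec_arf * p["rhd_given_recurrence"]
    sev_rec = new_rhd * p["severe_given_recurrent_rhd"]
    mild_rec = new_rhd - sev_rec
    d_rec_new = sev_rec * p["cfr_recurrent_severe"]
    sev_rec_surv = sev_rec - d_rec_new
    final_arf_only = arf_only - new_rhd

    # recurrence among unoperated established RHD
    rec_rhd_sev = sev_pool * p["recurrence_rhd_history"]
    rec_rhd_mild = mild_pool * p["recurrence_rhd_history"]
    rec_rhd = rec_rhd_sev + rec_rhd_mild
    d_rec_sev = rec_rhd_sev * p["severe_given_recurrent_rhd"] * p["cfr_recurrent_severe"]
    d_rec_mild = rec_rhd_mild * p["severe_given_recurrent_rhd"] * p["cfr_recurrent_severe"]
    sev_pool2 = sev_pool - d_rec_sev
    mild_pool2 = mild_pool - d_rec_mild

    # progression of established mild-moderate RHD
    mild_at_risk = mild_pool2 + mild_rec
    prog = mild_at_risk * p["progression_given_mild"]
    d_prog = prog * p["cfr_progression"]
    prog_surv = prog - d_prog
    surgery_prog = prog_surv * p["surgery_progression"]
    chronic_sev = prog_surv - surgery_prog  # end-stage RHD, fatal after duration
    final_mild = mild_at_risk - prog

    return {
        "first_arf": F,
        "arf_death": d_arf,
        "rhd_onset_mild": mild1,
        "rhd_onset_severe": sev1,
        "first_rhd_death": d_sev1,
        "surgery_first": surgery1,
        "recurrence_arf_history": rec_arf,
        "recurrence_rhd_history": rec_rhd,
        "recurrence_rhd_history_mild": rec_rhd_mild,
        "recurrence_rhd_history_severe": rec_rhd_sev,
        "recurrent_rhd_onset_mild": mild_rec,
        "recurrent_rhd_onset_severe": sev_rec,
        "recurrence_death": d_rec_new + d_rec_sev + d_rec_mild,
        "progression": prog,
        "progression_death": d_prog,
        "surgery_progression": surgery_prog,
        "chronic_rhd_death": chronic_sev,
        "final_arf_only": final_arf_only,
        "final_rhd_mild": final_mild,
        "final_rhd_severe": sev_pool2 + sev_rec_surv,
        "final_post_surgery": surgery1 + surgery_prog,
    }


def _assemble_ledger(
    arm: str,
    years: np.ndarray,
    ages: np.ndarray,
    flows: Dict[str, np.ndarray],
    params: ParameterSet,
) -> EventLedger:
    lag = params.cohort.event_lag
    duration = params.daly.chronic_rhd_duration
    age_offsets = {
        "first_arf": 0.0,
        "arf_death": 0.0,
        "rhd_onset_mild": 0.0,
        "rhd_onset_severe": 0.0,
        "first_rhd_death": 0.0,
        "surgery_first": lag,
        "recurrence_arf_history": lag,
        "recurrence_rhd_history": lag,
        "recurrence_rhd_history_mild": lag,
        "recurrence_rhd_history_severe": lag,
        "recurrent_rhd_onset_mild": lag,
        "recurrent_rhd_onset_severe": lag,
        "recurrence_death": lag,
        "progression": 2 * lag,
        "progression_death": 2 * lag,
        "surgery_progression": 2 * lag,
        "chronic_rhd_death": 2 * lag + duration,
        "final_arf_only": 0.0,
        "final_rhd_mild": 0.0,
        "final_rhd_severe": 0.0,
        "final_post_surgery": 0.0,
    }
    episodes = (
        flows["first_arf"].sum()
        + flows["recurrence_arf_history"].sum()
        + flows["recurrence_rhd_history"].sum()
    )
    person_years = {
        "arf_episode": float(episodes * params.daly.arf_episode_duration),
        "rhd_mild": float(
            flows["final_rhd_mild"].sum() * duration
            + flows["progression"].sum() * lag
        ),
        "rhd_severe": float(
            (flows["final_rhd_severe"].sum() + flows["chronic_rhd_death"].sum())
            * duration
        ),
        "post_surgery": float(flows["final_post_surgery"].sum() * duration),
    }
    return EventLedger(
        arm=arm,
        years=years,
        ages=ages,
        events=flows,
        age_offsets=age_offsets,
        person_years=person_years,
        cohort_size=float(params.cohort.size),
    )


def run_cohort(params: ParameterSet, arm) -> EventLedger:
    """Deterministic expected-value run of the decision tree for one arm."""
    label = _as_label(arm)
    p = _edge_values(params, label, None)
    years, ages, F = _first_episodes(params, label)
    return _assemble_ledger(label, years, ages, _flows(F, p), params)


def run_cohort_with_overrides(
    params: ParameterSet, arm, prob_values: Mapping[str, float]
) -> EventLedger:
    """As :func:`run_cohort` with edge probabilities replaced (PSA hot path)."""
    label = _as_label(arm)
    p = _edge_values(params, label, prob_values)
    years, ages, F = _first_episodes(params, label)
    return _assemble_ledger(label, years, ages, _flows(F, p), params)


# ---------------------------------------------------------------------------
# Individual-level oracle
# ---------------------------------------------------------------------------

#: column order of the per-case path matrix produced by :func:`_sample_paths`
PATH_FIELDS = (
    "die_arf",
    "rhd_first",
    "severe_first",
    "die_severe_first",
    "surgery_first",
    "recurrence_arf",
    "rhd_recurrent",
    "severe_recurrent",
    "die_recurrent",
    "recurrence_rhd",
    "severe_carditis_rhd_history",
    "die_recurrent_rhd_history",
    "progression",
    "die_progression",
    "surgery_progression",
    "chronic_death",
)


def _sample_paths(
    rng: np.random.Generator, p: Mapping[str, float], n_cases: int
) -> Dict[str, np.ndarray]:
    """Sample the post-first-episode path for ``n_cases`` ARF cases.

    Branches mirror :func:`_flows` exactly; every flag is conditioned on the
    flags before it, so aggregated counts are unbiased estimates of the
    expected-value engine's cells.
    """
    def bern(prob: float, mask: np.ndarray) -> np.ndarray:
        out = np.zeros(n_cases, dtype=bool)
        k = int(mask.sum())
        if k and prob > 0.0:
            out[mask] = rng.random(k) < prob
        return out

    everyone = np.ones(n_cases, dtype=bool)
    die_arf = bern(p["arf_cfr"], everyone)
    alive = ~die_arf

    rhd1 = bern(p["rhd_given_first_arf"], alive)
    sev1 = bern(p["severe_given_first_rhd"], rhd1)
    mild1 = rhd1 & ~sev1
    die_sev1 = bern(p["cfr_first_severe"], sev1)
    rhd1_alive = rhd1 & ~die_sev1
    op1 = bern(p["surgery_first_rhd"], rhd1_alive)

    arf_only = alive & ~rhd1
    rec_arf = bern(p["recurrence_arf_history"], arf_only)
    rhd_rec = bern(p["rhd_given_recurrence"], rec_arf)
    sev_rec = bern(p["severe_given_recurrent_rhd"], rhd_rec)
    die_rec = bern(p["cfr_recurrent_severe"], sev_rec)

    pool = rhd1_alive & ~op1
    rec_rhd = bern(p["recurrence_rhd_history"], pool)
    sevcard = bern(p["severe_given_recurrent_rhd"], rec_rhd)
    die_rec_hist = bern(p["cfr_recurrent_severe"], sevcard)

    mild_at_risk = (mild1 & ~op1 & ~die_rec_hist) | (rhd_rec & ~sev_rec)
    prog = bern(p["progression_given_mild"], mild_at_risk)
    die_prog = bern(p["cfr_progression"], prog)
    surg_prog = bern(p["surgery_progression"], prog & ~die_prog)
    chronic = prog & ~die_prog & ~surg_prog

    return {
        "die_arf": die_arf,
        "rhd_first": rhd1,
        "severe_first": sev1,
        "die_severe_first": die_sev1,
        "surgery_first": op1,
        "recurrence_arf": rec_arf,
        "rhd_recurrent": rhd_rec,
        "severe_recurrent": sev_rec,
        "die_recurrent": die_rec,
        "recurrence_rhd": rec_rhd,
        "severe_carditis_rhd_history": sevcard,
        "die_recurrent_rhd_history": die_rec_hist,
        "progression": prog,
        "die_progression": die_prog,
        "surgery_progression": surg_prog,
        "chronic_death": chronic,
    }


def _paths_to_event_counts(
    paths: Dict[str, np.ndarray],
    t_idx: np.ndarray,
    a_idx: np.ndarray,
    shape: tuple,
) -> Dict[str, np.ndarray]:
    """Aggregate per-case path flags into integer (year, age) count arrays."""
    def grid(mask: np.ndarray) -> np.ndarray:
        arr = np.zeros(shape, dtype=float)
        np.add.at(arr, (t_idx[mask], a_idx[mask]), 1.0)
        return arr

    sev_pool_alive = (
        paths["severe_first"] & ~paths["die_severe_first"]
        & ~paths["surgery_first"] & ~paths["die_recurrent_rhd_history"]
    )
    mild_first = paths["rhd_first"] & ~paths["severe_first"]
    alive = ~paths["die_arf"]
    arf_only = alive & ~paths["rhd_first"]
    final_arf_only = arf_only & ~paths["rhd_recurrent"]
    mild_at_risk = (
        (mild_first & ~paths["surgery_first"]
         & ~paths["die_recurrent_rhd_history"])
        | (paths["rhd_recurrent"] & ~paths["severe_recurrent"])
    )
    final_mild = mild_at_risk & ~paths["progression"]
    final_severe = sev_pool_alive | (
        paths["severe_recurrent"] & ~paths["die_recurrent"]
    )
    return {
        "first_arf": grid(np.ones_like(alive)),
        "arf_death": grid(paths["die_arf"]),
        "rhd_onset_mild": grid(mild_first),
        "rhd_onset_severe": grid(paths["severe_first"]),
        "first_rhd_death": grid(paths["die_severe_first"]),
        "surgery_first": grid(paths["surgery_first"]),
        "recurrence_arf_history": grid(paths["recurrence_arf"]),
        "recurrence_rhd_history": grid(paths["recurrence_rhd"]),
        "recurrence_rhd_history_mild": grid(
            paths["recurrence_rhd"] & ~paths["severe_first"]
        ),
        "recurrence_rhd_history_severe": grid(
            paths["recurrence_rhd"] & paths["severe_first"]
        ),
        "recurrent_rhd_onset_mild": grid(
            paths["rhd_recurrent"] & ~paths["severe_recurrent"]
        ),
        "recurrent_rhd_onset_severe": grid(paths["severe_recurrent"]),
        "recurrence_death": grid(
            paths["die_recurrent"] | paths["die_recurrent_rhd_history"]
        ),
        "progression": grid(paths["progression"]),
        "progression_death": grid(paths["die_progression"]),
        "surgery_progression": grid(paths["surgery_progression"]),
        "chronic_rhd_death": grid(paths["chronic_death"]),
        "final_arf_only": grid(final_arf_only),
        "final_rhd_mild": grid(final_mild),
        "final_rhd_severe": grid(final_severe),
        "final_post_surgery": grid(
            paths["surgery_first"] | paths["surgery_progression"]
        ),
    }


def microsimulate(
    params: ParameterSet, arm, n_individuals: int, seed: int
) -> EventLedger:
    """Individual-level stochastic run of the same topology (oracle).

    ``n_individuals`` cohort members are assigned onset-age strata by the
    onset-age distribution; first episodes arise binomially from the arm's
    incidence and each case's downstream path is sampled branch by branch.
    The same seed always reproduces the same ledger, and ledger cells scale
    to :func:`run_cohort` expectations times ``n_individuals / cohort.size``.
    """
    if n_individuals < 0:
        raise ValueError("n_individuals must be >= 0")
    label = _as_label(arm)
    p = _edge_values(params, label, None)
    years, ages, _ = _first_episodes(params, label)
    shape = (len(years), len(ages))
    rng = np.random.default_rng(seed)

    weights = np.asarray(
        [params.cohort.onset_age_distribution[int(a)] for a in ages]
    )
    if n_individuals == 0:
        counts_by_age = np.zeros(len(ages), dtype=int)
    else:
        counts_by_age = rng.multinomial(n_individuals, weights)
    rates = (
        np.asarray(params.incidence[label].as_array(), dtype=float) / 1e5
    )
    cases = rng.binomial(
        counts_by_age[None, :].repeat(len(years), axis=0), rates[:, None]
    )
    n_cases = int(cases.sum())
    t_idx, a_idx = np.nonzero(cases)
    t_per_case = np.repeat(t_idx, cases[t_idx, a_idx])
    a_per_case = np.repeat(a_idx, cases[t_idx, a_idx])
    paths = _sample_paths(rng, p, n_cases)
    flows = _paths_to_event_counts(paths, t_per_case, a_per_case, shape)

    scaled = params.copy()
    scaled.cohort.size = max(n_individuals, 1)
    ledger = _assemble_ledger(label, years, ages, flows, scaled)
    ledger.cohort_size = float(n_individuals)
    # person-years recomputed from simulated counts by _assemble_ledger
    return ledger
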