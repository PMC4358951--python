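"""Synthetic individual-level ARF/RHD registry data.

The original evaluation estimated its transition probabilities from
aggregated registry reports; the register itself is unavailable.  This
module generates synthetic patient line lists with exactly the statistical
structure the cohort model assumes — each history is a serialised trace of
the microsimulation's path sampler — and estimates transition probabilities
(with binomial bounds) back from such line lists, so the estimation step of
the analysis is exercisable end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .cohort_model import _edge_values, _sample_paths
from .parameters import ParameterSet, ProbabilityEstimate, binomial_bounds

__all__ = [
    "PatientHistory",
    "Registry",
    "EstimationError",
    "generate_registry",
    "estimate_probabilities",
]

_EVENT_COLUMNS = ["patient_id", "age", "year", "event", "detail"]


class EstimationError(ValueError):
    """Raised when probabilities cannot be estimated (e.g. empty registry)."""


@dataclass
class PatientHistory:
    """One patient's chronologically ordered clinical events."""

    patient_id: int
    onset_age: int
    onset_year: int
    events: List[Tuple[float, float, str, str]]  # (age, year, event, detail)

    def died(self) -> bool:
        return any(e == "death" for _, _, e, _ in self.events)


@dataclass
class Registry:
    """A synthetic patient register: one row per clinical event."""

    arm: str
    events: pd.DataFrame
    n_patients: int
    seed: Optional[int] = None

    def histories(self) -> Iterator[PatientHistory]:
        for pid, group in self.events.groupby("patient_id", sort=True):
            group = group.sort_values(["age", "event"])
            first = group.iloc[0]
            yield PatientHistory(
                patient_id=int(pid),
                onset_age=int(first["age"]),
                onset_year=int(first["year"]),
                events=[
                    (float(r.age), float(r.year), str(r.event), str(r.detail))
                    for r in group.itertuples()
                ],
            )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.events.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path], arm: str = "control") -> "Registry":
        events = pd.read_csv(path, keep_default_na=False)
        return cls(arm=arm, events=events,
                   n_patients=int(events["patient_id"].nunique()))

    @classmethod
    def pool(cls, *registries: "Registry") -> "Registry":
        """Concatenate disjoint registries (patient ids are re-offset)."""
        frames = []
        offset = 0
        for reg in registries:
            df = reg.events.copy()
            df["patient_id"] = df["patient_id"] + offset
            offset += reg.n_patients
            frames.append(df)
        events = pd.concat(frames, ignore_index=True) if frames else \
            pd.DataFrame(columns=_EVENT_COLUMNS)
        return cls(arm=registries[0].arm if registries else "control",
                   events=events,
                   n_patients=sum(r.n_patients for r in registries))


def _registry_seed(seed: int, arm: str, n_patients: int) -> int:
    """Derive an independent stream per (master seed, arm, n)."""
    arm_code = 1 if arm == "intervention" else 0
    return int((seed * 1_000_003 + arm_code * 7919 + n_patients) % (2**31 - 1))


def generate_registry(
    params: ParameterSet, arm, n_patients: int, seed: int
) -> Registry:
    """Sample ``n_patients`` ARF case histories for one arm.

    Onset years are drawn proportionally to the arm's incidence series,
    onset ages from the cohort's onset-age distribution; each downstream
    path is sampled from the decision-tree probabilities by the same path
    sampler that backs the microsimulation oracle.
    """
    if n_patients < 0:
        raise ValueError("n_patients must be >= 0")
    label = arm.label if hasattr(arm, "label") else str(arm)
    if n_patients == 0:
        return Registry(arm=label,
                        events=pd.DataFrame(columns=_EVENT_COLUMNS),
                        n_patients=0, seed=seed)
    rng = np.random.default_rng(_registry_seed(seed, label, n_patients))
    p = _edge_values(params, label, None)

    series = params.incidence[label]
    years = np.asarray(series.years())
    rates = np.asarray(series.as_array(), dtype=float)
    year_weights = rates / rates.sum() if rates.sum() > 0 else \
        np.full(len(rates), 1.0 / len(rates))
    ages = np.asarray(sorted(params.cohort.onset_age_distribution))
    age_weights = np.asarray(
        [params.cohort.onset_age_distribution[int(a)] for a in ages]
    )
    onset_year = years[rng.choice(len(years), size=n_patients, p=year_weights)]
    onset_age = ages[rng.choice(len(ages), size=n_patients, p=age_weights)]
    paths = _sample_paths(rng, p, n_patients)

    lag = params.cohort.event_lag
    duration = params.daly.chronic_rhd_duration
    pid = np.arange(n_patients)

    rows: List[pd.DataFrame] = []

    def add(mask: np.ndarray, offset: float, event: str, detail: str) -> None:
        if mask.any():
            rows.append(pd.DataFrame({
                "patient_id": pid[mask],
                "age": onset_age[mask] + offset,
                "year": onset_year[mask] + offset,
                "event": event,
                "detail": detail,
            }))

    everyone = np.ones(n_patients, dtype=bool)
    add(everyone, 0.0, "first_arf", "")
    add(paths["die_arf"], 0.0, "death", "arf")
    add(paths["rhd_first"] & ~paths["severe_first"], 0.0, "rhd_onset_first",
        "mild")
    add(paths["severe_first"], 0.0, "rhd_onset_first", "severe")
    add(paths["die_severe_first"], 0.0, "death", "first_severe")
    add(paths["surgery_first"], lag, "surgery", "first")
    add(paths["recurrence_arf"], lag, "recurrence", "arf_history")
    add(paths["recurrence_rhd"], lag, "recurrence", "rhd_history")
    add(paths["rhd_recurrent"] & ~paths["severe_recurrent"], lag,
        "rhd_onset_recurrent", "mild")
    add(paths["severe_recurrent"], lag, "rhd_onset_recurrent", "severe")
    add(paths["severe_carditis_rhd_history"], lag, "severe_carditis",
        "rhd_history")
    add(paths["die_recurrent"] | paths["die_recurrent_rhd_history"], lag,
        "death", "recurrent_severe")
    add(paths["progression"], 2 * lag, "progression", "")
    add(paths["die_progression"], 2 * lag, "death", "progression")
    add(paths["surgery_progression"], 2 * lag, "surgery", "progression")
    add(paths["chronic_death"], 2 * lag + duration, "death", "chronic_rhd")

    events = pd.concat(rows, ignore_index=True)
    events = events.sort_values(["patient_id", "age", "event"]).reset_index(
        drop=True
    )
    return Registry(arm=label, events=events, n_patients=n_patients, seed=seed)


def _patient_flags(events: pd.DataFrame) -> pd.DataFrame:
    """One row per patient with a boolean column per (event, detail)."""
    key = events["event"].str.cat(events["detail"].astype(str), sep="|")
    flags = pd.crosstab(events["patient_id"], key).astype(bool)
    return flags


def _estimate(name: str, k: int, n: int) -> Optional[ProbabilityEstimate]:
    if n == 0:
        return None  # edge never at risk: absent, not zero
    point = k / n
    low, high = binomial_bounds(point, n)
    return ProbabilityEstimate(name=name, point=point, low=low, high=high,
                               n_source=n)


def estimate_probabilities(
    registry: Registry,
) -> Dict[str, ProbabilityEstimate]:
    """Estimate every tree-edge probability from a registry line list.

    Each estimate is event count / number at risk with 95% binomial bounds
    (n = at-risk count); edges whose at-risk count is zero are omitted.
    Estimates are invariant to patient ordering, and counts from disjoint
    registries add exactly.
    """
    if registry.n_patients == 0 or registry.events.empty:
        raise EstimationError("cannot estimate probabilities from an empty "
                              "registry")
    flags = _patient_flags(registry.events)

    def col(name: str) -> pd.Series:
        if name in flags.columns:
            return flags[name]
        return pd.Series(False, index=flags.index)

    n_patients = len(flags)
    die_arf = col("death|arf")
    rhd_first = col("rhd_onset_first|mild") | col("rhd_onset_first|severe")
    severe_first = col("rhd_onset_first|severe")
    die_severe_first = col("death|first_severe")
    surgery_first = col("surgery|first")
    rec_arf = col("recurrence|arf_history")
    rec_rhd = col("recurrence|rhd_history")
    rhd_recurrent = (col("rhd_onset_recurrent|mild")
                     | col("rhd_onset_recurrent|severe"))
    severe_recurrent = col("rhd_onset_recurrent|severe")
    sevcard_hist = col("severe_carditis|rhd_history")
    die_recurrent = col("death|recurrent_severe")
    progression = col("progression|")
    die_progression = col("death|progression")
    surgery_progression = col("surgery|progression")

    survivors = ~die_arf
    rhd1_alive = rhd_first & ~die_severe_first
    pool = rhd1_alive & ~surgery_first
    die_rec_hist = die_recurrent & sevcard_hist
    mild_first = rhd_first & ~severe_first
    mild_at_risk = (
        (mild_first & ~surgery_first & ~die_rec_hist)
        | (rhd_recurrent & ~severe_recurrent)
    )
    severe_rec_pool = severe_recurrent | sevcard_hist
    prog_alive = progression & ~die_progression

    counts = {
        "arf_cfr": (int(die_arf.sum()), n_patients),
        "rhd_given_first_arf": (int(rhd_first.sum()), int(survivors.sum())),
        "severe_given_first_rhd":
            (int(severe_first.sum()), int(rhd_first.sum())),
        "cfr_first_severe":
            (int(die_severe_first.sum()), int(severe_first.sum())),
        "surgery_first_rhd":
            (int(surgery_first.sum()), int(rhd1_alive.sum())),
        "recurrence_arf_history":
            (int(rec_arf.sum()), int((survivors & ~rhd_first).sum())),
        "recurrence_rhd_history": (int(rec_rhd.sum()), int(pool.sum())),
        "rhd_given_recurrence":
            (int(rhd_recurrent.sum()), int(rec_arf.sum())),
        "severe_given_recurrent_rhd":
            (int(severe_rec_pool.sum()),
             int(rhd_recurrent.sum() + rec_rhd.sum())),
        "cfr_recurrent_severe":
            (int(die_recurrent.sum()), int(severe_rec_pool.sum())),
        "progression_given_mild":
            (int(progression.sum()), int(mild_at_risk.sum())),
        "cfr_progression":
            (int(die_progression.sum()), int(progression.sum())),
        "surgery_progression":
            (int(surgery_progression.sum()), int(prog_alive.sum())),
    }
    estimates = {}
    for edge, (k, n) in counts.items():
        est = _estimate(edge, k, n)
        if est is not None:
            estimates[edge] = est
    return estimates
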