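"""Synthetic registry generation and transition-probability estimation."""

import numpy as np
import pandas as pd
import pytest

from rhdcea import (
    compute_dalys,
    estimate_probabilities,
    generate_registry,
    run_cohort,
)
from rhdcea.synthetic_data import EstimationError, Registry


class TestGenerateRegistry:
    def test_empty_registry_for_zero_patients(self, params):
        reg = generate_registry(params, "control", 0, seed=1)
        assert reg.n_patients == 0
        assert reg.events.empty

    def test_same_seed_identical_line_lists(self, params):
        a = generate_registry(params, "control", 5000, seed=2)
        b = generate_registry(params, "control", 5000, seed=2)
        assert a.events.equals(b.events)

    def test_arms_use_independent_streams(self, params):
        a = generate_registry(params, "control", 2000, seed=3)
        b = generate_registry(params, "intervention", 2000, seed=3)
        assert not a.events.equals(b.events)

    def test_every_patient_starts_with_first_arf(self, params):
        reg = generate_registry(params, "control", 3000, seed=4)
        first = reg.events[reg.events["event"] == "first_arf"]
        assert len(first) == 3000
        assert set(first["patient_id"]) == set(range(3000))

    def test_events_chronological_and_single_death(self, params):
        reg = generate_registry(params, "control", 3000, seed=5)
        deaths = reg.events[reg.events["event"] == "death"]
        assert deaths["patient_id"].is_unique
        last_age = reg.events.groupby("patient_id")["age"].max()
        death_age = deaths.set_index("patient_id")["age"]
        # no event after death
        assert (last_age.loc[death_age.index] <= death_age + 1e-9).all()

    def test_histories_expose_ordered_events(self, params):
        reg = generate_registry(params, "control", 50, seed=6)
        histories = list(reg.histories())
        assert len(histories) == 50
        for h in histories:
            ages = [age for age, *_ in h.events]
            assert ages == sorted(ages)

    def test_recurrence_fraction_recovers_generating_value(self, params):
        """Observed recurrence fraction among ARF-history patients lies
        within the 99% binomial bounds of the generating 0.567."""
        reg = generate_registry(params, "control", 100_000, seed=7)
        est = estimate_probabilities(reg)["recurrence_arf_history"]
        p, n = 0.567, est.n_source
        half = 2.576 * np.sqrt(p * (1 - p) / n)
        assert p - half <= est.point <= p + half

    def test_csv_round_trip(self, params, tmp_path):
        reg = generate_registry(params, "control", 500, seed=8)
        path = tmp_path / "registry.csv"
        reg.to_csv(path)
        back = Registry.from_csv(path)
        assert back.n_patients == 500
        assert len(back.events) == len(reg.events)


class TestEstimateProbabilities:
    def test_empty_registry_rejected(self):
        empty = Registry(arm="control",
                         events=pd.DataFrame(
                             columns=["patient_id", "age", "year", "event",
                                      "detail"]),
                         n_patients=0)
        with pytest.raises(EstimationError):
            estimate_probabilities(empty)

    def test_certain_event_gets_rule_of_three_bound(self, params):
        """A registry in which every ARF patient recurs estimates the
        recurrence probability as 1.0 with a 3/n lower bound."""
        p = params.copy()
        est = p.probabilities["recurrence_arf_history"]["control"]
        est.point, est.low, est.high = 1.0, 1.0, 1.0
        reg = generate_registry(p, "control", 2000, seed=9)
        out = estimate_probabilities(reg)["recurrence_arf_history"]
        assert out.point == 1.0
        assert out.low == pytest.approx(1.0 - 3.0 / out.n_source)

    def test_estimates_invariant_to_patient_order(self, params):
        reg = generate_registry(params, "control", 5000, seed=10)
        shuffled = Registry(
            arm=reg.arm,
            events=reg.events.sample(frac=1.0, random_state=0)
                              .reset_index(drop=True),
            n_patients=reg.n_patients,
        )
        a = estimate_probabilities(reg)
        b = estimate_probabilities(shuffled)
        assert set(a) == set(b)
        for edge in a:
            assert a[edge].point == b[edge].point
            assert a[edge].n_source == b[edge].n_source

    def test_pooled_registries_add_counts_exactly(self, params):
        r1 = generate_registry(params, "control", 3000, seed=11)
        r2 = generate_registry(params, "control", 2000, seed=12)
        pooled = Registry.pool(r1, r2)
        a, b, p = (estimate_probabilities(x) for x in (r1, r2, pooled))
        for edge in p:
            k = round(a[edge].point * a[edge].n_source) + \
                round(b[edge].point * b[edge].n_source)
            n = a[edge].n_source + b[edge].n_source
            assert p[edge].n_source == n
            assert p[edge].point == pytest.approx(k / n)

    def test_coverage_of_95_percent_bounds(self, params):
        """Across registries and arms, at least 93% of estimated edges
        bracket their generating values within their own 95% bounds."""
        hits = trials = 0
        for seed in range(6):
            for arm in ("control", "intervention"):
                reg = generate_registry(params, arm, 20_000, seed=100 + seed)
                for edge, est in estimate_probabilities(reg).items():
                    truth = params.prob(edge, arm)
                    trials += 1
                    hits += est.low - 1e-12 <= truth <= est.high + 1e-12
        assert trials >= 150
        assert hits / trials >= 0.93


class TestParameterRecovery:
    def test_round_trip_reproduces_averted_dalys(self, params):
        """generate -> estimate -> re-run reproduces averted DALYs within
        5% at 100,000 patients per arm."""
        truth = compute_dalys(
            run_cohort(params, "control"), run_cohort(params, "intervention"),
            params.daly, params.cohort,
        ).averted["daly"]
        refit = params.copy()
        for arm in ("control", "intervention"):
            reg = generate_registry(params, arm, 100_000, seed=21)
            for edge, est in estimate_probabilities(reg).items():
                refit.probabilities[edge][arm] = est
        recovered = compute_dalys(
            run_cohort(refit, "control"), run_cohort(refit, "intervention"),
            refit.daly, refit.cohort,
        ).averted["daly"]
        assert recovered == pytest.approx(truth, rel=0.05)
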