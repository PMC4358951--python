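"""Parameter types, binomial bounds, validation and configuration I/O."""

import math

import pytest
from hypothesis import given, strategies as st

from rhdcea import (
    ConfigurationError,
    binomial_bounds,
    load_parameters,
    save_parameters,
    validate,
)
from rhdcea.parameters import ProbabilityEstimate, parameter_table


class TestBinomialBounds:
    @pytest.mark.parametrize(
        "point, n, expected",
        [
            # 1.96 * sqrt(0.567 * 0.433 / 30) = 0.1773
            (0.567, 30, (0.390, 0.744)),
            # rule of three on the open side at a degenerate point
            (1.0, 50, (0.94, 1.0)),
            (0.0, 50, (0.0, 0.06)),
        ],
    )
    def test_reference_values(self, point, n, expected):
        low, high = binomial_bounds(point, n)
        assert low == pytest.approx(expected[0], abs=1e-3)
        assert high == pytest.approx(expected[1], abs=1e-3)

    def test_large_n_collapses_to_point(self):
        low, high = binomial_bounds(0.5, 10**12)
        assert low == pytest.approx(0.5, abs=1e-5)
        assert high == pytest.approx(0.5, abs=1e-5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_bounds(0.5, 0)
        with pytest.raises(ValueError):
            binomial_bounds(1.2, 10)

    @given(st.floats(0.01, 0.99), st.integers(1, 10_000))
    def test_mirror_symmetry_about_half(self, p, n):
        """Bounds for p and 1-p mirror about 0.5."""
        low, high = binomial_bounds(p, n)
        low_m, high_m = binomial_bounds(1.0 - p, n)
        assert low == pytest.approx(1.0 - high_m, abs=1e-12)
        assert high == pytest.approx(1.0 - low_m, abs=1e-12)

    @given(st.floats(0.05, 0.95), st.integers(2, 5_000))
    def test_width_shrinks_with_n(self, p, n):
        w_small = math.fsum(
            (-1, 1)[i] * b for i, b in enumerate(binomial_bounds(p, n))
        )
        w_large = math.fsum(
            (-1, 1)[i] * b for i, b in enumerate(binomial_bounds(p, 2 * n))
        )
        assert w_large <= w_small + 1e-12


class TestDefaults:
    def test_published_incidence_series(self, params):
        assert all(
            r == 12.2 for r in params.incidence["control"].rates.values()
        )
        assert params.incidence["intervention"].rates[1995] == 2.0
        assert params.incidence["intervention"].rates[1986] == 12.2

    def test_published_costs(self, params):
        assert params.costs.hospitalization["rhd_severe"] == 6343.0
        assert params.costs.program_total == pytest.approx(202_890.0)
        # components still round to their printed dollar values
        assert round(params.costs.program_components["administration"]) == 43_372

    def test_published_probabilities(self, params):
        assert params.prob("arf_cfr", "control") == 0.014
        assert params.prob("recurrence_arf_history", "control") == 0.567
        assert params.prob("recurrence_arf_history", "intervention") == 0.176
        assert params.prob("cfr_first_severe", "intervention") == 0.0

    def test_bounds_consistent_with_n_source(self, params):
        for edge, by_arm in params.probabilities.items():
            for arm, est in by_arm.items():
                low, high = binomial_bounds(est.point, est.n_source)
                assert est.low == pytest.approx(low), (edge, arm)
                assert est.high == pytest.approx(high), (edge, arm)

    def test_default_set_is_valid(self, params):
        assert validate(params) == []

    def test_thresholds_are_nested_gdp_multiples(self, params):
        t = params.thresholds
        assert t.best_buy < t.very_cost_effective < t.cost_effective
        assert t.cost_effective == 3 * t.very_cost_effective


class TestValidation:
    def test_zero_cohort_size_rejected(self):
        with pytest.raises(ConfigurationError, match="cohort.size"):
            load_parameters({"cohort": {"size": 0}})

    def test_probability_above_one_flagged(self, params):
        broken = params.copy()
        broken.probabilities["arf_cfr"]["control"] = ProbabilityEstimate(
            name="arf_cfr/control", point=1.2, low=1.2, high=1.2
        )
        violations = validate(broken)
        assert len(violations) >= 1
        assert any("arf_cfr" in v for v in violations)

    def test_bounds_not_bracketing_point_flagged(self, params):
        broken = params.copy()
        broken.probabilities["arf_cfr"]["control"] = ProbabilityEstimate(
            name="arf_cfr/control", point=0.1, low=0.2, high=0.3
        )
        assert any("arf_cfr" in v for v in validate(broken))

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError, match="no_such_key"):
            load_parameters({"no_such_key": 1})

    def test_decreasing_life_table_enforced(self, params):
        broken = params.copy()
        broken.daly.life_table[20.0] = 80.0  # above the value at age 15
        assert any("life_table" in v for v in validate(broken))


class TestConfigurationIO:
    def test_round_trip_is_exact(self, params, tmp_path):
        path = tmp_path / "config.json"
        save_parameters(params, path)
        reloaded = load_parameters(path)
        assert reloaded.cohort == params.cohort
        assert reloaded.incidence == params.incidence
        assert reloaded.costs == params.costs
        assert reloaded.daly == params.daly
        assert reloaded.thresholds == params.thresholds
        assert reloaded.probabilities == params.probabilities

    def test_override_changes_value_and_provenance(self):
        p = load_parameters({"cohort": {"size": 1000}})
        assert p.cohort.size == 1000
        assert p.provenance["cohort.size"] == "override"
        assert p.provenance["cohort.index_year"] == "default"

    def test_parameter_table_has_provenance_column(self, params):
        table = parameter_table(params)
        assert list(table.columns) == ["parameter", "value", "provenance"]
        assert (table["provenance"] == "default").all()
        assert len(table) > 50
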