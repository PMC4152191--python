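"""Discounting, per-state cost channels, and outcome accumulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depmark import (
    ConfigurationError,
    CostParameters,
    StateDef,
    accumulate_outcomes,
    antidepressant_cost,
    convert_probability,
    discount_factor,
    expected_turnover_cost,
    lost_productive_time_cost,
    run_cohort,
    run_scenario,
    service_use_cost,
)

from conftest import make_toy_config

DEPRESSED_TREATED = StateDef(
    name="depressed_treated", depressed=True, in_treatment=True, employed=True
)
DEPRESSED_UNTREATED = StateDef(
    name="depressed_untreated", depressed=True, in_treatment=False, employed=True
)
RECOVERED = StateDef(name="recovered_untreated", depressed=False, employed=True)
RETIRED = StateDef(name="retired", absorbing=True, employed=False)


def _costs(**overrides) -> CostParameters:
    base = dict(
        absenteeism_days_per_cycle=0.0,
        presenteeism_days_per_cycle=0.0,
        daily_wage=0.0,
        annual_salary=0.0,
        turnover_probability_12m=0.0,
        service_contacts_per_year={},
        service_unit_costs={},
        antidepressant_use_prob_2wk=0.0,
        antidepressant_script_cost_3m=0.0,
    )
    base.update(overrides)
    return CostParameters(**base)


class TestDiscountFactor:
    def test_zero_rate_is_unity(self):
        assert all(discount_factor(t, 0.0, 0.25) == 1.0 for t in range(1, 30))

    @pytest.mark.parametrize(
        "cycle,expected",
        [(4, 1.0 / 1.03), (20, 1.03**-5)],  # one and five years of 3-month cycles
    )
    def test_three_percent_annual(self, cycle, expected):
        assert discount_factor(cycle, 0.03, 0.25) == pytest.approx(expected, rel=1e-12)

    def test_printed_precision_values(self):
        assert discount_factor(4, 0.03, 0.25) == pytest.approx(0.970874, abs=1e-6)
        assert discount_factor(20, 0.03, 0.25) == pytest.approx(0.862609, abs=1e-6)


class TestLostProductiveTime:
    def test_days_times_wage(self):
        costs = _costs(absenteeism_days_per_cycle=5.0, daily_wage=215.0)
        assert lost_productive_time_cost(DEPRESSED_TREATED, costs, "absenteeism") == 1075.0

    def test_scenario_selects_day_type(self):
        costs = _costs(
            absenteeism_days_per_cycle=5.0,
            presenteeism_days_per_cycle=2.0,
            daily_wage=100.0,
        )
        assert lost_productive_time_cost(DEPRESSED_TREATED, costs, "absenteeism") == 500.0
        assert lost_productive_time_cost(DEPRESSED_TREATED, costs, "presenteeism") == 200.0

    def test_recovered_and_retired_earn_nothing(self):
        costs = _costs(absenteeism_days_per_cycle=5.0, daily_wage=215.0)
        assert lost_productive_time_cost(RECOVERED, costs, "absenteeism") == 0.0
        assert lost_productive_time_cost(RETIRED, costs, "absenteeism") == 0.0


class TestTurnoverCost:
    def test_restricted_to_depressed_in_treatment(self):
        costs = _costs(turnover_probability_12m=0.105, annual_salary=55_595.0)
        assert expected_turnover_cost(DEPRESSED_UNTREATED, costs, 1.0) == 0.0
        assert expected_turnover_cost(RECOVERED, costs, 1.0) == 0.0
        assert expected_turnover_cost(RETIRED, costs, 1.0) == 0.0

    def test_converted_probability_times_salary(self):
        costs = _costs(turnover_probability_12m=0.105, annual_salary=55_595.0)
        expected = convert_probability(0.105, 1.0, 0.25) * 55_595.0
        got = expected_turnover_cost(DEPRESSED_TREATED, costs, 1.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1521.1, abs=1.0)  # 0.02736 x 55 595

    def test_zero_multiplier(self):
        costs = _costs(turnover_probability_12m=0.105, annual_salary=55_595.0)
        assert expected_turnover_cost(DEPRESSED_TREATED, costs, 0.0) == 0.0


class TestServiceUseCost:
    def test_quarterly_share_of_annual_contacts(self):
        costs = _costs(
            service_contacts_per_year={"gp": 4.0, "psychologist": 8.0},
            service_unit_costs={"gp": 35.0, "psychologist": 120.0},
        )
        # (1 x 35) + (2 x 120) per 3-month cycle
        assert service_use_cost(DEPRESSED_TREATED, costs) == pytest.approx(275.0)

    def test_not_in_treatment_and_empty_map(self):
        costs = _costs(
            service_contacts_per_year={"gp": 4.0}, service_unit_costs={"gp": 35.0}
        )
        assert service_use_cost(DEPRESSED_UNTREATED, costs) == 0.0
        assert service_use_cost(DEPRESSED_TREATED, _costs()) == 0.0

    def test_provider_without_unit_cost_raises(self):
        costs = _costs(service_contacts_per_year={"gp": 4.0}, service_unit_costs={})
        with pytest.raises(ConfigurationError, match="gp"):
            service_use_cost(DEPRESSED_TREATED, costs)


class TestAntidepressantCost:
    def test_degenerate_probabilities(self):
        assert (
            antidepressant_cost(
                DEPRESSED_TREATED,
                _costs(antidepressant_use_prob_2wk=0.0, antidepressant_script_cost_3m=80.0),
            )
            == 0.0
        )
        assert antidepressant_cost(
            DEPRESSED_TREATED,
            _costs(antidepressant_use_prob_2wk=1.0, antidepressant_script_cost_3m=80.0),
        ) == pytest.approx(80.0)

    def test_two_week_to_cycle_conversion(self):
        # exponent 0.25 / (2/52) = 6.5 fortnights per cycle
        costs = _costs(
            antidepressant_use_prob_2wk=0.3, antidepressant_script_cost_3m=80.0
        )
        expected = (1.0 - 0.7**6.5) * 80.0
        assert antidepressant_cost(DEPRESSED_TREATED, costs) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(72.13, abs=0.01)

    def test_only_in_treatment(self):
        costs = _costs(
            antidepressant_use_prob_2wk=0.3, antidepressant_script_cost_3m=80.0
        )
        assert antidepressant_cost(DEPRESSED_UNTREATED, costs) == 0.0


class TestAccumulateOutcomes:
    def test_static_cohort_qalys(self):
        """Whole cohort alive at utility 0.6 for 4 undiscounted cycles -> 0.6."""
        cfg = make_toy_config(death_per_cycle=0.0, utility_alive=0.6, horizon=4)
        out = run_scenario(cfg)
        assert out.qalys == pytest.approx(0.6, abs=1e-12)

    def test_zero_utilities_zero_qalys(self):
        cfg = make_toy_config(death_per_cycle=0.1, utility_alive=0.0, horizon=4)
        assert run_scenario(cfg).qalys == 0.0

    def test_toy_chain_geometric_cost(self):
        """death 0.1/cycle, 100/cycle alive, no discounting: 309.51 per worker."""
        cfg = make_toy_config(death_per_cycle=0.1, service_cost_per_cycle=100.0)
        out = run_scenario(cfg)
        assert out.cost_total == pytest.approx(309.51, abs=1e-9)
        assert out.cost_service == pytest.approx(309.51, abs=1e-9)

    def test_constant_payoff_matches_geometric_series(self):
        """No dynamics, payoff c, per-cycle factor d: total = c d (1-d^T)/(1-d)."""
        cfg = make_toy_config(
            death_per_cycle=0.0, service_cost_per_cycle=100.0, horizon=20, discount=0.03
        )
        out = run_scenario(cfg)
        d = 1.03**-0.25
        expected = 100.0 * d * (1.0 - d**20) / (1.0 - d)
        assert out.cost_total == pytest.approx(expected, abs=1e-9)

    def test_component_additivity(self, fixture_configs):
        for cfg in fixture_configs.values():
            out = run_scenario(cfg)
            assert out.cost_total == (
                out.cost_lpt
                + out.cost_turnover
                + out.cost_service
                + out.cost_antidepressant
            )

    def test_qaly_bound(self, fixture_configs):
        for cfg in fixture_configs.values():
            out = run_scenario(cfg)
            u_max = max(cfg.utilities.utilities.values())
            assert 0.0 <= out.qalys <= cfg.horizon * cfg.cycle_length * u_max + 1e-12

    def test_baseline_cycle_earns_nothing(self):
        """A one-cycle horizon accrues exactly one discounted payoff."""
        cfg = make_toy_config(
            death_per_cycle=0.0, service_cost_per_cycle=100.0, horizon=1, discount=0.03
        )
        assert run_scenario(cfg).cost_total == pytest.approx(100.0 * 1.03**-0.25)

    def test_half_cycle_correction_averages_occupancy(self):
        cfg = make_toy_config(death_per_cycle=0.1, service_cost_per_cycle=100.0, horizon=1)
        cfg.run.half_cycle_correction = True
        # membership weight (1000 + 900)/2 per initial 1000 workers
        assert run_scenario(cfg).cost_total == pytest.approx(95.0)

    def test_trace_config_mismatch(self, fixture_configs):
        trace = run_cohort(fixture_configs["absenteeism_blue"])
        from depmark import DepmarkError

        with pytest.raises(DepmarkError):
            accumulate_outcomes(trace, make_toy_config())

    @given(scale=st.floats(min_value=1.0, max_value=3.0))
    @settings(max_examples=20, deadline=None)
    def test_cost_monotone_in_wage_and_salary(self, scale, fixture_configs):
        cfg = fixture_configs["absenteeism_blue"]
        base = run_scenario(cfg)
        scaled = cfg.model_copy(deep=True)
        scaled.costs.daily_wage *= scale
        scaled.costs.annual_salary *= scale
        out = run_scenario(scaled)
        assert out.cost_total >= base.cost_total - 1e-9
        assert out.qalys == pytest.approx(base.qalys)

    def test_per_worker_normalizes_by_initial_cohort(self):
        small = make_toy_config(
            death_per_cycle=0.1, service_cost_per_cycle=100.0, cohort_size=10
        )
        big = make_toy_config(
            death_per_cycle=0.1, service_cost_per_cycle=100.0, cohort_size=100_000
        )
        assert run_scenario(small).cost_total == pytest.approx(
            run_scenario(big).cost_total, rel=1e-12
        )
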