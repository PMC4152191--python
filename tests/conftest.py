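import pytest

from depmark import (
    CostParameters,
    MortalityBand,
    RunSettings,
    ScenarioConfig,
    StateDef,
    TransitionParameters,
    UtilityParameters,
    packaged_fixture,
)


@pytest.fixture(scope="session")
def fixture_set():
    """The packaged frozen scenario quadruple and its reference outputs."""
    return packaged_fixture()


@pytest.fixture(scope="session")
def fixture_configs(fixture_set):
    return fixture_set[0]


@pytest.fixture(scope="session")
def fixture_refs(fixture_set):
    return fixture_set[1]


def make_toy_config(
    death_per_cycle: float = 0.1,
    service_cost_per_cycle: float = 0.0,
    utility_alive: float = 0.6,
    horizon: int = 4,
    discount: float = 0.0,
    cohort_size: int = 1000,
) -> ScenarioConfig:
    """Minimal two-state chain {alive, deceased} with optional per-cycle cost.

    The per-cycle death probability is achieved exactly by choosing the
    annual probability 1 - (1 - q)^4; a per-cycle service cost is attached by
    flagging the alive state as in-treatment with one provider billed at unit
    cost 1 and (cost x 4) contacts per year.
    """
    annual_death = 1.0 - (1.0 - death_per_cycle) ** 4
    return ScenarioConfig(
        scenario="absenteeism",
        occupation="pooled",
        states=[
            StateDef(name="alive", depressed=False, in_treatment=True, employed=True),
            StateDef(name="deceased", alive=False, absorbing=True, employed=False),
        ],
        initial={"alive": 1.0, "deceased": 0.0},
        transitions=TransitionParameters(
            remission_treated_12m=0.0,
            remission_untreated_12m=0.0,
            relapse_treated_12m=0.0,
            relapse_untreated_12m=0.0,
            treatment_initiation_12m=0.0,
            baseline_mortality_annual=[
                MortalityBand(age_from=0, male=annual_death, female=annual_death)
            ],
            suicide_mortality_multiplier=1.0,
            early_retirement_annual=0.0,
            cohort_start_age=40.0,
            sex_mix=0.5,
        ),
        costs=CostParameters(
            absenteeism_days_per_cycle=0.0,
            presenteeism_days_per_cycle=0.0,
            daily_wage=0.0,
            annual_salary=0.0,
            turnover_probability_12m=0.0,
            service_contacts_per_year=(
                {"flat": service_cost_per_cycle * 4.0} if service_cost_per_cycle else {}
            ),
            service_unit_costs={"flat": 1.0} if service_cost_per_cycle else {},
            antidepressant_use_prob_2wk=0.0,
            antidepressant_script_cost_3m=0.0,
        ),
        utilities=UtilityParameters(
            utilities={"alive": utility_alive, "deceased": 0.0}
        ),
        psa={},
        run=RunSettings(
            cohort_size=cohort_size,
            cycle_length=0.25,
            horizon=horizon,
            annual_discount_rate=discount,
            seed=0,
        ),
    )


@pytest.fixture
def toy_config():
    return make_toy_config(service_cost_per_cycle=100.0)
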