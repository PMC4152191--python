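"""Cost and QALY accumulation over a cohort trace.

Four cost channels are attached to health states, mirroring the composition
of depression-related workplace costs: lost productive time (disability days
valued at the daily wage, for employed depressed states), job turnover
(replacement cost as a multiple of annual salary, restricted to
depressed-in-treatment states in the base model), depression-related service
use (provider contacts at unit costs, in-treatment states), and
antidepressant scripts (in-treatment states). QALYs weight occupancy time by
per-state AQoL-4D utilities.

Payoffs accrue on end-of-cycle state membership from cycle 1 onward (cycle 0
is baseline and earns nothing); costs and QALYs are both discounted at the
annual rate compounded over elapsed years, and totals are reported per
worker by dividing cohort aggregates by the initial cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CostParameters, ScenarioConfig, StateDef
from .engine import CohortTrace, convert_probability
from .errors import ConfigurationError, DepmarkError

__all__ = [
    "CycleStateCost",
    "ScenarioOutcome",
    "discount_factor",
    "lost_productive_time_cost",
    "expected_turnover_cost",
    "service_use_cost",
    "antidepressant_cost",
    "state_cycle_cost",
    "accumulate_outcomes",
    "run_scenario",
]

#: Length of the 2-week antidepressant-use recall window, in years.
TWO_WEEKS_YEARS = 2.0 / 52.0

COST_COMPONENTS = ("lost_productive_time", "turnover", "service_use", "antidepressants")


def discount_factor(cycle: int, annual_rate: float, cycle_length: float) -> float:
    """Discount factor for a payoff accruing at the end of ``cycle``."""
    if not (0.0 <= annual_rate < 1.0):
        raise DepmarkError(f"discount rate {annual_rate} outside [0, 1)")
    return (1.0 + annual_rate) ** (-cycle * cycle_length)


@dataclass(frozen=True)
class CycleStateCost:
    """Per-person per-cycle cost of occupying one state, by channel (AUD)."""

    lost_productive_time: float
    turnover: float
    service_use: float
    antidepressants: float

    @property
    def total(self) -> float:
        return (
            self.lost_productive_time
            + self.turnover
            + self.service_use
            + self.antidepressants
        )


def lost_productive_time_cost(
    state: StateDef, costs: CostParameters, scenario: str
) -> float:
    """Disability days per cycle x daily wage, for employed depressed states."""
    if not (state.employed and state.depressed and state.alive):
        return 0.0
    days = (
        costs.absenteeism_days_per_cycle
        if scenario == "absenteeism"
        else costs.presenteeism_days_per_cycle
    )
    return days * costs.daily_wage


def expected_turnover_cost(
    state: StateDef,
    costs: CostParameters,
    multiplier: float,
    cycle_length: float = 0.25,
) -> float:
    """Expected per-cycle replacement cost; depressed-in-treatment states only."""
    if not (state.depressed and state.in_treatment and state.employed):
        return 0.0
    p_cycle = convert_probability(costs.turnover_probability_12m, 1.0, cycle_length)
    return p_cycle * multiplier * costs.annual_salary


def _turnover_cost_not_depressed(
    state: StateDef, costs: CostParameters, cycle_length: float
) -> float:
    # sensitivity-analysis channel, inactive (probability 0) in the base model
    if state.depressed or not state.employed or state.absorbing or not state.alive:
        return 0.0
    p = costs.turnover_probability_not_depressed_12m
    if p == 0.0:
        return 0.0
    p_cycle = convert_probability(p, 1.0, cycle_length)
    return p_cycle * costs.effective_multiplier_not_depressed() * costs.annual_salary


def service_use_cost(
    state: StateDef, costs: CostParameters, cycle_length: float = 0.25
) -> float:
    """Per-cycle share of annual provider contacts, costed at unit prices."""
    if not state.in_treatment:
        return 0.0
    missing = set(costs.service_contacts_per_year) - set(costs.service_unit_costs)
    if missing:
        raise ConfigurationError(
            f"providers without unit costs: {sorted(missing)}"
        )
    return sum(
        contacts * cycle_length * costs.service_unit_costs[prov]
        for prov, contacts in costs.service_contacts_per_year.items()
    )


def antidepressant_cost(
    state: StateDef, costs: CostParameters, cycle_length: float = 0.25
) -> float:
    """Probability of any use over the cycle (from the 2-week rate) x script cost."""
    if not state.in_treatment:
        return 0.0
    p_cycle = convert_probability(
        costs.antidepressant_use_prob_2wk, TWO_WEEKS_YEARS, cycle_length
    )
    return p_cycle * costs.antidepressant_script_cost_3m


def state_cycle_cost(
    state: StateDef,
    costs: CostParameters,
    scenario: str,
    multiplier: float,
    cycle_length: float = 0.25,
) -> CycleStateCost:
    """All four cost channels for one state, per person per cycle."""
    return CycleStateCost(
        lost_productive_time=lost_productive_time_cost(state, costs, scenario),
        turnover=expected_turnover_cost(state, costs, multiplier, cycle_length)
        + _turnover_cost_not_depressed(state, costs, cycle_length),
        service_use=service_use_cost(state, costs, cycle_length),
        antidepressants=antidepressant_cost(state, costs, cycle_length),
    )


@dataclass(frozen=True)
class ScenarioOutcome:
    """Discounted per-worker totals over the model horizon (2007 AUD, QALYs)."""

    cost_lpt: float
    cost_turnover: float
    cost_service: float
    cost_antidepressant: float
    qalys: float
    horizon: int

    @property
    def cost_total(self) -> float:
        return (
            self.cost_lpt
            + self.cost_turnover
            + self.cost_service
            + self.cost_antidepressant
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "cost_lpt": self.cost_lpt,
            "cost_turnover": self.cost_turnover,
            "cost_service": self.cost_service,
            "cost_antidepressant": self.cost_antidepressant,
            "cost_total": self.cost_total,
            "qalys": self.qalys,
        }

    def to_table(self) -> pd.DataFrame:
        """Cost-composition table: one row per channel plus the total."""
        rows = [
            ("Lost Productive Time", self.cost_lpt),
            ("Job Turnover", self.cost_turnover),
            ("Service Use", self.cost_service),
            ("Antidepressants", self.cost_antidepressant),
            ("Total", self.cost_total),
        ]
        return pd.DataFrame(rows, columns=["component", "cost_aud"])


def accumulate_outcomes(
    trace: CohortTrace, cfg: ScenarioConfig, multiplier: float | None = None
) -> ScenarioOutcome:
    """Attach costs/utilities to a trace and accumulate discounted totals.

    ``multiplier`` overrides the turnover cost multiplier for this
    accumulation (used by the PSA); by default the config's deterministic
    multiplier (explicit value or range midpoint) applies. With the
    half-cycle correction enabled, each cycle's payoff weights the average of
    start- and end-of-cycle occupancy instead of end-of-cycle membership.
    """
    if trace.state_names != cfg.state_names():
        raise DepmarkError("trace states do not match configuration states")
    if multiplier is None:
        multiplier = cfg.costs.effective_multiplier()

    cl = cfg.cycle_length
    states = cfg.states
    per_state = [
        state_cycle_cost(s, cfg.costs, cfg.scenario, multiplier, cl) for s in states
    ]
    cost_vectors = {
        comp: np.array([getattr(c, comp) for c in per_state])
        for comp in COST_COMPONENTS
    }
    util = np.array(
        [cfg.utilities.utilities.get(s.name, 0.0) if s.alive else 0.0 for s in states]
    )

    T = cfg.horizon
    totals = dict.fromkeys(COST_COMPONENTS, 0.0)
    qalys = 0.0
    for t in range(1, T + 1):
        w = trace.occupancy[t]
        if cfg.run.half_cycle_correction:
            w = 0.5 * (trace.occupancy[t - 1] + trace.occupancy[t])
        d = discount_factor(t, cfg.run.annual_discount_rate, cl)
        for comp in COST_COMPONENTS:
            totals[comp] += d * float(w @ cost_vectors[comp])
        qalys += d * float(w @ util) * cl

    N = trace.cohort_size
    return ScenarioOutcome(
        cost_lpt=totals["lost_productive_time"] / N,
        cost_turnover=totals["turnover"] / N,
        cost_service=totals["service_use"] / N,
        cost_antidepressant=totals["antidepressants"] / N,
        qalys=qalys / N,
        horizon=T,
    )


def run_scenario(
    cfg: ScenarioConfig, multiplier: float | None = None
) -> ScenarioOutcome:
    """Deterministic end-to-end run: propagate the cohort, accumulate outcomes."""
    from .engine import run_cohort

    return accumulate_outcomes(run_cohort(cfg), cfg, multiplier)
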