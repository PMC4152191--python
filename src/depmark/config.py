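"""Parameter data model for the absenteeism/presenteeism Markov cohort pipeline.

A :class:`ScenarioConfig` fully specifies one (scenario x occupation) stratum:
the health-state roster, the baseline distribution of the cohort over states,
12-month transition probabilities, cost and utility inputs, the probabilistic
sensitivity analysis (PSA) distribution specs, and run settings (cohort size,
cycle length, horizon, discount rate).

Structural validation (types, required keys) is handled by pydantic at load
time; the domain invariants (probabilities in [0,1], distributions summing
to one, distribution families matching parameter support, ...) are checked by
:func:`validate_scenario`, which reports violations as data rather than
raising, so that partially-invalid configurations can be inspected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigurationError

__all__ = [
    "StateDef",
    "MortalityBand",
    "TransitionParameters",
    "CostParameters",
    "UtilityParameters",
    "DistributionSpec",
    "RunSettings",
    "ScenarioConfig",
    "Violation",
    "load_scenario",
    "save_scenario",
    "validate_scenario",
    "parameter_support",
]

#: Maximum number of lost-work days in a 3-month cycle (365.25 / 4).
MAX_DAYS_PER_CYCLE = 91.25


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class StateDef(_Model):
    """One health state: flags drive transitions, costs and utilities.

    ``deceased`` and ``retired`` are absorbing; employment-related costs are
    only ever attached to employed states, treatment-related costs to
    ``in_treatment`` states, and the suicide mortality excess to ``depressed``
    states.
    """

    name: str
    alive: bool = True
    depressed: bool = False
    in_treatment: bool = False
    absorbing: bool = False
    employed: bool = True


class MortalityBand(_Model):
    """Annual all-cause death probability for ages >= ``age_from``, by sex."""

    age_from: float
    male: float
    female: float


class TransitionParameters(_Model):
    """12-month transition probabilities plus demographic settings.

    All clinical probabilities are expressed over 12 months and converted to
    the 3-month cycle by the engine. Mortality is age-band- and sex-specific;
    the cohort is a single stream with a scalar starting age and a fixed
    female proportion used to mix the sex-specific rates.
    """

    remission_treated_12m: float
    remission_untreated_12m: float
    relapse_treated_12m: float
    relapse_untreated_12m: float
    treatment_initiation_12m: float
    baseline_mortality_annual: list[MortalityBand]
    suicide_mortality_multiplier: float = 1.0
    early_retirement_annual: float = 0.0
    cohort_start_age: float = 40.0
    sex_mix: float = 0.5


class CostParameters(_Model):
    """Per-stratum cost inputs, all in 2007 Australian dollars.

    ``turnover_probability_12m`` applies to depressed-in-treatment states only;
    ``turnover_probability_not_depressed_12m`` (default 0, i.e. inactive in the
    base model) attaches to recovered employed states so that one-way
    sensitivity analysis can vary turnover for workers without depression
    symptoms. When ``turnover_cost_multiplier`` is unset, the midpoint of
    ``turnover_cost_multiplier_range`` is used for deterministic runs.
    """

    absenteeism_days_per_cycle: float
    presenteeism_days_per_cycle: float
    daily_wage: float
    annual_salary: float
    turnover_probability_12m: float
    turnover_cost_multiplier_range: tuple[float, float] = (0.75, 1.5)
    turnover_cost_multiplier: Optional[float] = None
    turnover_probability_not_depressed_12m: float = 0.0
    turnover_cost_multiplier_not_depressed: Optional[float] = None
    service_contacts_per_year: dict[str, float] = {}
    service_unit_costs: dict[str, float] = {}
    antidepressant_use_prob_2wk: float = 0.0
    antidepressant_script_cost_3m: float = 0.0

    def effective_multiplier(self) -> float:
        if self.turnover_cost_multiplier is not None:
            return self.turnover_cost_multiplier
        lo, hi = self.turnover_cost_multiplier_range
        return 0.5 * (lo + hi)

    def effective_multiplier_not_depressed(self) -> float:
        if self.turnover_cost_multiplier_not_depressed is not None:
            return self.turnover_cost_multiplier_not_depressed
        return self.effective_multiplier()


class UtilityParameters(_Model):
    """AQoL-4D utility weight per state, per year of occupancy."""

    utilities: dict[str, float]


class DistributionSpec(_Model):
    """PSA sampling spec for one parameter.

    beta(mean, se) for [0,1]-supported parameters, gamma(mean, se) for
    non-negative ones, uniform(low, high) where the functional form is
    unknown, and fixed to hold a parameter at its mean.
    """

    family: Literal["beta", "gamma", "uniform", "fixed"]
    mean: Optional[float] = None
    se: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None


class RunSettings(_Model):
    cohort_size: int = 1000
    cycle_length: float = 0.25
    horizon: int = 20
    annual_discount_rate: float = 0.03
    half_cycle_correction: bool = False
    seed: int = 0


def default_states() -> list[StateDef]:
    """Default six-state roster: depression x treatment, deceased, retired."""
    return [
        StateDef(name="depressed_treated", depressed=True, in_treatment=True),
        StateDef(name="depressed_untreated", depressed=True, in_treatment=False),
        StateDef(name="recovered_treated", depressed=False, in_treatment=True),
        StateDef(name="recovered_untreated", depressed=False, in_treatment=False),
        StateDef(name="retired", absorbing=True, employed=False),
        StateDef(name="deceased", alive=False, absorbing=True, employed=False),
    ]


class ScenarioConfig(_Model):
    """Full parameter set for one scenario x occupation stratum."""

    scenario: Literal["absenteeism", "presenteeism"]
    occupation: Literal["blue", "white", "pooled"]
    states: list[StateDef]
    initial: dict[str, float]
    transitions: TransitionParameters
    costs: CostParameters
    utilities: UtilityParameters
    psa: dict[str, DistributionSpec] = {}
    run: RunSettings = RunSettings()

    # -- convenience accessors -------------------------------------------
    @property
    def cohort_size(self) -> int:
        return self.run.cohort_size

    @property
    def cycle_length(self) -> float:
        return self.run.cycle_length

    @property
    def horizon(self) -> int:
        return self.run.horizon

    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    def state(self, name: str) -> StateDef:
        for s in self.states:
            if s.name == name:
                return s
        raise ConfigurationError(f"no state named '{name}'")


# ---------------------------------------------------------------------------
# load / save
# ---------------------------------------------------------------------------

def load_scenario(path: str | Path, strict: bool = True) -> ScenarioConfig:
    """Load and validate a scenario configuration from a JSON file.

    With ``strict`` (default), domain-invariant violations raise
    :class:`ConfigurationError`; set ``strict=False`` to obtain the parsed
    object regardless and inspect :func:`validate_scenario` output yourself.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: not valid JSON: {exc}") from exc
    try:
        cfg = ScenarioConfig.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigurationError(f"{path}: {details}") from exc
    if strict:
        violations = validate_scenario(cfg)
        if violations:
            raise ConfigurationError(
                f"{path}: " + "; ".join(str(v) for v in violations)
            )
    return cfg


def save_scenario(cfg: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario configuration as JSON (full float precision)."""
    Path(path).write_text(cfg.model_dump_json(indent=2))


# ---------------------------------------------------------------------------
# domain validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One invariant violation: the offending field, its value, the rule."""

    field: str
    value: object
    rule: str

    def __str__(self) -> str:  # pragma: no cover - formatting only
        return f"{self.field} = {self.value!r}: {self.rule}"


def parameter_support(path: str) -> str:
    """Support class of a dotted parameter path: 'unit', 'nonneg' or 'unknown'.

    Used to check PSA family assignments: beta requires unit-interval support,
    gamma non-negative support.
    """
    if path.startswith("utilities.") or path.startswith("initial."):
        return "unit"
    leaf = path.rsplit(".", 1)[-1]
    if leaf.endswith("_12m") or "prob" in leaf or leaf == "sex_mix":
        return "unit"
    if leaf in {"early_retirement_annual", "treatment_initiation_12m"}:
        return "unit"
    if path.startswith("transitions.baseline_mortality_annual"):
        return "unit"
    nonneg = {
        "absenteeism_days_per_cycle",
        "presenteeism_days_per_cycle",
        "daily_wage",
        "annual_salary",
        "antidepressant_script_cost_3m",
        "suicide_mortality_multiplier",
        "turnover_cost_multiplier",
        "turnover_cost_multiplier_not_depressed",
        "cohort_start_age",
    }
    if leaf in nonneg or path.startswith("costs.service_unit_costs") or path.startswith(
        "costs.service_contacts_per_year"
    ):
        return "nonneg"
    return "unknown"


def _check_prob(out: list[Violation], field: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        out.append(Violation(field, value, "probability must lie in [0, 1]"))


def validate_scenario(cfg: ScenarioConfig) -> list[Violation]:
    """Check every domain invariant; return an empty list iff all hold."""
    v: list[Violation] = []
    names = cfg.state_names()
    if len(set(names)) != len(names):
        v.append(Violation("states", names, "state names must be unique"))

    # state roster invariants
    deceased = [s for s in cfg.states if s.name == "deceased"]
    if len(deceased) != 1 or deceased[0].alive:
        v.append(
            Violation(
                "states", "deceased", "exactly one 'deceased' state with alive=false"
            )
        )
    for s in cfg.states:
        if s.absorbing and s.employed:
            v.append(Violation(f"states.{s.name}", "absorbing", "absorbing => not employed"))
        if not s.alive and (s.depressed or s.in_treatment):
            v.append(
                Violation(
                    f"states.{s.name}",
                    "flags",
                    "depressed/in_treatment must be false for non-alive states",
                )
            )
        if s.name == "retired" and not (s.absorbing and s.alive):
            v.append(Violation("states.retired", s, "'retired' must be absorbing and alive"))

    # initial distribution
    total = 0.0
    for name, p in cfg.initial.items():
        if name not in names:
            v.append(Violation(f"initial.{name}", p, "references unknown state"))
            continue
        _check_prob(v, f"initial.{name}", p)
        total += p
        if cfg.state(name).absorbing and p != 0.0:
            v.append(
                Violation(f"initial.{name}", p, "absorbing states must start empty")
            )
    if abs(total - 1.0) > 1e-9:
        v.append(
            Violation("initial", total, f"initial distribution sums to {total:.6g}")
        )

    # transitions
    t = cfg.transitions
    for field in (
        "remission_treated_12m",
        "remission_untreated_12m",
        "relapse_treated_12m",
        "relapse_untreated_12m",
        "treatment_initiation_12m",
        "early_retirement_annual",
        "sex_mix",
    ):
        _check_prob(v, f"transitions.{field}", getattr(t, field))
    if t.suicide_mortality_multiplier < 1.0:
        v.append(
            Violation(
                "transitions.suicide_mortality_multiplier",
                t.suicide_mortality_multiplier,
                "mortality multiplier must be >= 1",
            )
        )
    if t.cohort_start_age <= 0:
        v.append(
            Violation(
                "transitions.cohort_start_age", t.cohort_start_age, "must be positive"
            )
        )
    if not t.baseline_mortality_annual:
        v.append(
            Violation(
                "transitions.baseline_mortality_annual", [], "at least one age band"
            )
        )
    for i, band in enumerate(t.baseline_mortality_annual):
        _check_prob(v, f"transitions.baseline_mortality_annual[{i}].male", band.male)
        _check_prob(v, f"transitions.baseline_mortality_annual[{i}].female", band.female)

    # costs
    c = cfg.costs
    for field in (
        "daily_wage",
        "annual_salary",
        "antidepressant_script_cost_3m",
    ):
        if getattr(c, field) < 0:
            v.append(Violation(f"costs.{field}", getattr(c, field), "cost must be >= 0"))
    for field in ("absenteeism_days_per_cycle", "presenteeism_days_per_cycle"):
        days = getattr(c, field)
        if not (0.0 <= days <= MAX_DAYS_PER_CYCLE):
            v.append(
                Violation(
                    f"costs.{field}", days, f"days per cycle must lie in [0, {MAX_DAYS_PER_CYCLE}]"
                )
            )
    _check_prob(v, "costs.turnover_probability_12m", c.turnover_probability_12m)
    _check_prob(
        v,
        "costs.turnover_probability_not_depressed_12m",
        c.turnover_probability_not_depressed_12m,
    )
    _check_prob(v, "costs.antidepressant_use_prob_2wk", c.antidepressant_use_prob_2wk)
    lo, hi = c.turnover_cost_multiplier_range
    if lo > hi:
        v.append(
            Violation(
                "costs.turnover_cost_multiplier_range",
                (lo, hi),
                "multiplier range low must be <= high",
            )
        )
    if set(c.service_contacts_per_year) != set(c.service_unit_costs):
        v.append(
            Violation(
                "costs.service_unit_costs",
                sorted(set(c.service_contacts_per_year) ^ set(c.service_unit_costs)),
                "provider keys must match between contacts and unit costs",
            )
        )
    for prov, val in c.service_contacts_per_year.items():
        if val < 0:
            v.append(Violation(f"costs.service_contacts_per_year.{prov}", val, "must be >= 0"))
    for prov, val in c.service_unit_costs.items():
        if val < 0:
            v.append(Violation(f"costs.service_unit_costs.{prov}", val, "must be >= 0"))

    # utilities
    for name, u in cfg.utilities.utilities.items():
        if name not in names:
            v.append(Violation(f"utilities.{name}", u, "references unknown state"))
            continue
        if not (0.0 <= u <= 1.0):
            v.append(Violation(f"utilities.{name}", u, "utility must lie in [0, 1]"))
        if name == "deceased" and u != 0.0:
            v.append(Violation("utilities.deceased", u, "deceased utility must be 0"))
    for s in cfg.states:
        if s.alive and s.name not in cfg.utilities.utilities:
            v.append(
                Violation(f"utilities.{s.name}", None, "alive state lacks a utility")
            )

    # run settings
    r = cfg.run
    if r.horizon < 1:
        v.append(Violation("run.horizon", r.horizon, "horizon must be >= 1"))
    if r.cohort_size < 1:
        v.append(Violation("run.cohort_size", r.cohort_size, "cohort size must be >= 1"))
    if not (0.0 <= r.annual_discount_rate < 1.0):
        v.append(
            Violation(
                "run.annual_discount_rate",
                r.annual_discount_rate,
                "discount rate must lie in [0, 1)",
            )
        )
    if r.cycle_length <= 0:
        v.append(Violation("run.cycle_length", r.cycle_length, "cycle length must be > 0"))

    # PSA specs
    for path, spec in cfg.psa.items():
        support = parameter_support(path)
        f = f"psa.{path}"
        if spec.family == "beta":
            if support != "unit":
                v.append(Violation(f, spec.family, "beta family on unbounded parameter"))
            if spec.mean is None or spec.se is None:
                v.append(Violation(f, spec, "beta requires mean and se"))
            elif not (0.0 < spec.mean < 1.0):
                v.append(Violation(f, spec.mean, "beta mean must lie in (0, 1)"))
            elif spec.se <= 0:
                v.append(Violation(f, spec.se, "se must be > 0"))
            elif spec.se**2 >= spec.mean * (1.0 - spec.mean):
                v.append(Violation(f, spec.se, "beta requires se^2 < mean(1-mean)"))
        elif spec.family == "gamma":
            if support == "unknown":
                v.append(Violation(f, spec.family, "gamma family on unknown-support parameter"))
            if spec.mean is None or spec.se is None:
                v.append(Violation(f, spec, "gamma requires mean and se"))
            elif spec.mean <= 0 or spec.se <= 0:
                v.append(Violation(f, (spec.mean, spec.se), "gamma requires mean, se > 0"))
        elif spec.family == "uniform":
            if spec.low is None or spec.high is None:
                v.append(Violation(f, spec, "uniform requires low and high"))
            elif spec.low > spec.high:
                v.append(Violation(f, (spec.low, spec.high), "uniform low must be <= high"))
        else:  # fixed
            if spec.mean is None:
                v.append(Violation(f, spec, "fixed requires mean"))

    return v
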