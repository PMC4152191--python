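"""One-way (univariate) sensitivity analysis.

Each sweep reruns the deterministic model (point estimates, no Monte Carlo)
for every alternative value of a single parameter, in both the absenteeism
and presenteeism configurations, holding everything else at base values.
Turnover sweeps can target either the depressed-in-treatment turnover
channel of the base model or the (base-zero) turnover channel attached to
recovered workers, so tables can report "depressed" and "not depressed"
rows side by side. A dedicated sweep replaces blue- and white-collar wage
and salary with common values to isolate the income contribution to
occupational cost differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .config import ScenarioConfig
from .errors import ConfigurationError
from .outcomes import run_scenario
from .psa import apply_overrides

__all__ = ["SweepSpec", "SweepResult", "one_way_sensitivity", "uniform_wage_sweep"]

# turnover parameter paths redirected when a sweep targets workers without
# depression symptoms
_NOT_DEPRESSED_ALIASES = {
    "costs.turnover_probability_12m": "costs.turnover_probability_not_depressed_12m",
    "costs.turnover_cost_multiplier": "costs.turnover_cost_multiplier_not_depressed",
}


@dataclass(frozen=True)
class SweepSpec:
    """One-way sweep: a dotted parameter path and the values to evaluate."""

    parameter: str
    values: Sequence[float]
    applies_to: Literal["depressed", "not_depressed", "both"] = "both"

    def resolved_parameter(self) -> str:
        if self.applies_to == "not_depressed":
            return _NOT_DEPRESSED_ALIASES.get(self.parameter, self.parameter)
        return self.parameter


@dataclass
class SweepResult:
    """Long-format sweep output: one row per (value x scenario/stratum)."""

    rows: pd.DataFrame  # columns: parameter, value, scenario, occupation,
    #                              cost_total, qalys, baseline

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def table(self) -> pd.DataFrame:
        """Wide table: one row per value, one cost column per scenario."""
        return self.rows.pivot_table(
            index="value", columns="scenario", values="cost_total"
        )


def _run_row(cfg: ScenarioConfig, spec_param: str, value: float, baseline: bool):
    out = run_scenario(apply_overrides(cfg, {spec_param: value}))
    return {
        "parameter": spec_param,
        "value": value,
        "scenario": cfg.scenario,
        "occupation": cfg.occupation,
        "cost_total": out.cost_total,
        "qalys": out.qalys,
        "baseline": baseline,
    }


def one_way_sensitivity(
    cfg_abs: ScenarioConfig, cfg_pres: ScenarioConfig, sweep: SweepSpec
) -> SweepResult:
    """Deterministic rerun per sweep value for both scenarios."""
    if not sweep.values:
        raise ConfigurationError("sweep must supply at least one value")
    param = sweep.resolved_parameter()
    records = []
    for cfg in (cfg_abs, cfg_pres):
        # probing resolution up-front gives a clear error before any model run
        apply_overrides(cfg, {param: sweep.values[0]})
        base = _baseline_value(cfg, param)
        for value in sweep.values:
            records.append(_run_row(cfg, param, value, baseline=(value == base)))
    return SweepResult(rows=pd.DataFrame.from_records(records))


def _baseline_value(cfg: ScenarioConfig, path: str):
    obj = cfg
    for p in path.split("."):
        obj = obj[p] if isinstance(obj, dict) else getattr(obj, p)
    return obj


def uniform_wage_sweep(
    cfg_blue: ScenarioConfig | Sequence[ScenarioConfig],
    cfg_white: ScenarioConfig | Sequence[ScenarioConfig],
    common_wage: float,
    common_salary: float,
) -> SweepResult:
    """Rerun both occupation models with identical wage and salary.

    Isolates whether blue/white cost differences are driven by white-collar
    workers' higher income valuation: any residual gap under common income
    reflects non-income parameters.
    """
    configs: list[ScenarioConfig] = []
    for group in (cfg_blue, cfg_white):
        configs.extend([group] if isinstance(group, ScenarioConfig) else list(group))
    records = []
    for cfg in configs:
        overridden = apply_overrides(
            cfg,
            {"costs.daily_wage": common_wage, "costs.annual_salary": common_salary},
        )
        out = run_scenario(overridden)
        records.append(
            {
                "parameter": "income(common)",
                "value": common_wage,
                "scenario": cfg.scenario,
                "occupation": cfg.occupation,
                "cost_total": out.cost_total,
                "qalys": out.qalys,
                "baseline": False,
            }
        )
    return SweepResult(rows=pd.DataFrame.from_records(records))
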