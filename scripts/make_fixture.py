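"""Freeze the packaged synthetic fixture and its reference outputs.

Run once from the repository root:

    python scripts/make_fixture.py

Writes the four stratum configs plus ``references.json`` into
``src/depmark/data/fixture/``. Deterministic reference outcomes are computed
here by an independent verification path — repeated-squaring matrix powers
for the trace and explicitly re-derived per-state payoff vectors with a
closed-form discounted sum — not by the engine's cycle loop or the outcomes
accumulator. The PSA block is an engine-generated regression freeze
(seed 0, 1000 iterations).

The fixture is synthetic: it is a generator draw (seed 5) whose totals
reproduce the qualitative orderings of the study (absenteeism dearer than
presenteeism, white collar dearer than blue), not the original model inputs.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from depmark import (  # noqa: E402
    ScenarioConfig,
    build_transition_matrix,
    generate_scenario_set,
    run_psa,
    save_scenario,
    trace_oracle,
)

FIXTURE_SEED = 5
PSA_SEED = 0
PSA_N = 1000
OUT = Path(__file__).resolve().parents[1] / "src" / "depmark" / "data" / "fixture"


def oracle_outcomes(cfg: ScenarioConfig) -> dict[str, float]:
    """Discounted per-worker outcomes via matrix powers + closed-form sums."""
    cl = cfg.run.cycle_length
    T = cfg.run.horizon
    # time-homogeneity required for the matrix-power path: no mortality band
    # crossing and no age-50 cutoff crossing within the horizon
    ages = [cfg.transitions.cohort_start_age + t * cl for t in range(T)]
    assert all(a < 50 for a in ages) and all(
        _band(cfg, a) == _band(cfg, ages[0]) for a in ages
    ), "fixture horizon must be time-homogeneous"

    M = build_transition_matrix(cfg.transitions, cfg.states, 0, cfg)
    names = cfg.state_names()
    v0 = np.array([cfg.cohort_size * cfg.initial.get(n, 0.0) for n in names])

    c = cfg.costs
    mult = 0.5 * sum(c.turnover_cost_multiplier_range)
    p_turn = 1.0 - (1.0 - c.turnover_probability_12m) ** cl
    p_ad = 1.0 - (1.0 - c.antidepressant_use_prob_2wk) ** (cl / (2.0 / 52.0))
    days = (
        c.absenteeism_days_per_cycle
        if cfg.scenario == "absenteeism"
        else c.presenteeism_days_per_cycle
    )
    service_per_cycle = sum(
        n_contacts * cl * c.service_unit_costs[prov]
        for prov, n_contacts in c.service_contacts_per_year.items()
    )

    lpt = np.zeros(len(names))
    turn = np.zeros(len(names))
    svc = np.zeros(len(names))
    ad = np.zeros(len(names))
    util = np.zeros(len(names))
    for i, s in enumerate(cfg.states):
        if s.employed and s.depressed and s.alive:
            lpt[i] = days * c.daily_wage
        if s.depressed and s.in_treatment and s.employed:
            turn[i] = p_turn * mult * c.annual_salary
        if s.in_treatment:
            svc[i] = service_per_cycle
            ad[i] = p_ad * c.antidepressant_script_cost_3m
        if s.alive:
            util[i] = cfg.utilities.utilities[s.name]

    rate = cfg.run.annual_discount_rate
    totals = {"cost_lpt": 0.0, "cost_turnover": 0.0, "cost_service": 0.0,
              "cost_antidepressant": 0.0, "qalys": 0.0}
    for t in range(1, T + 1):
        v = trace_oracle(M, v0, t)
        d = (1.0 + rate) ** (-t * cl)
        totals["cost_lpt"] += d * float(v @ lpt)
        totals["cost_turnover"] += d * float(v @ turn)
        totals["cost_service"] += d * float(v @ svc)
        totals["cost_antidepressant"] += d * float(v @ ad)
        totals["qalys"] += d * float(v @ util) * cl
    totals = {k: v / cfg.cohort_size for k, v in totals.items()}
    totals["cost_total"] = (
        totals["cost_lpt"] + totals["cost_turnover"]
        + totals["cost_service"] + totals["cost_antidepressant"]
    )
    return totals


def _band(cfg: ScenarioConfig, age: float) -> float:
    chosen = cfg.transitions.baseline_mortality_annual[0].age_from
    for b in cfg.transitions.baseline_mortality_annual:
        if b.age_from <= age and b.age_from >= chosen:
            chosen = b.age_from
    return chosen


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    configs = generate_scenario_set(FIXTURE_SEED)

    deterministic = {}
    for key, cfg in configs.items():
        save_scenario(cfg, OUT / f"{key}.json")
        deterministic[key] = oracle_outcomes(cfg)

    # qualitative orderings the fixture must carry
    tot = {k: v["cost_total"] for k, v in deterministic.items()}
    assert tot["absenteeism_blue"] > tot["presenteeism_blue"]
    assert tot["absenteeism_white"] > tot["presenteeism_white"]
    assert tot["absenteeism_white"] > tot["absenteeism_blue"]
    assert tot["presenteeism_white"] > tot["presenteeism_blue"]

    psa_freeze = {}
    for key, cfg in configs.items():
        res = run_psa(cfg, PSA_N, PSA_SEED)
        psa_freeze[key] = {
            "n_iterations": res.n_iterations,
            "seed": res.seed,
            "summaries": {k: list(v) for k, v in res.summaries.items()},
        }

    references = {
        "generator_seed": FIXTURE_SEED,
        "deterministic": deterministic,
        "psa": psa_freeze,
    }
    (OUT / "references.json").write_text(json.dumps(references, indent=2))
    print(f"fixture written to {OUT}")
    for key, vals in deterministic.items():
        print(f"  {key}: total {vals['cost_total']:.2f} AUD, {vals['qalys']:.4f} QALYs")


if __name__ == "__main__":
    main()
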