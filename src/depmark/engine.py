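"""Markov cohort engine: per-cycle transition matrices and cohort propagation.

The cohort is closed (size N, default 1000) and redistributed over the health
states every 3-month cycle by a row-stochastic transition matrix built from
12-month clinical probabilities. Within a cycle, death is applied first; the
surviving mass is shared among the remaining named transitions (remission or
relapse, treatment initiation, early retirement) in proportion to their
per-cycle probabilities, and the residual stays in the current state. Named
per-cycle probabilities summing above 1 out of any state are rejected as
infeasible rather than rescaled.

Matrices are rebuilt each cycle only because mortality is age-band-specific
and early retirement switches off at age 50; everything else is
time-homogeneous, which is what makes the repeated-squaring oracle
(:func:`trace_oracle`) a valid independent check on :func:`run_cohort`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig, StateDef, TransitionParameters
from .errors import ConfigurationError, DepmarkError, InfeasibleParametersError

__all__ = [
    "TransitionMatrix",
    "CohortTrace",
    "convert_probability",
    "build_transition_matrix",
    "run_cohort",
    "trace_oracle",
]

#: Age at which the early-retirement pathway closes.
RETIREMENT_AGE_CUTOFF = 50.0


def convert_probability(p: float, t_from: float, t_to: float) -> float:
    """Re-express a probability over period ``t_from`` onto period ``t_to``.

    Uses the constant-hazard transform ``1 - (1 - p)**(t_to / t_from)``:
    monotone in ``p``, identity when the periods coincide, and exactly
    invertible (12m -> 3m -> 12m round-trips to machine precision).
    """
    if not (0.0 <= p <= 1.0):
        raise DepmarkError(f"probability {p} outside [0, 1]")
    if t_from <= 0 or t_to <= 0:
        raise DepmarkError("periods must be positive")
    if p == 1.0:
        return 1.0
    return 1.0 - (1.0 - p) ** (t_to / t_from)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic per-cycle matrix over the configured state set."""

    entries: np.ndarray
    state_names: list[str]

    def __post_init__(self):
        m = self.entries
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DepmarkError("transition matrix must be square")
        if m.shape[0] != len(self.state_names):
            raise DepmarkError("matrix size does not match state roster")

    def index(self, name: str) -> int:
        return self.state_names.index(name)


@dataclass
class CohortTrace:
    """Occupancy (persons) per state per cycle, plus cohort age per cycle."""

    occupancy: np.ndarray  # (horizon + 1, n_states)
    state_names: list[str]
    ages: np.ndarray  # (horizon + 1,), years at cycle start
    cohort_size: float

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=self.state_names)
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(df)))
        return df


def _mortality_annual(params: TransitionParameters, age: float) -> float:
    """Sex-mixed annual background death probability at a given age."""
    band = params.baseline_mortality_annual[0]
    for b in params.baseline_mortality_annual:
        if b.age_from <= age and b.age_from >= band.age_from:
            band = b
    return params.sex_mix * band.female + (1.0 - params.sex_mix) * band.male


def _find_target(
    states: list[StateDef], depressed: bool, in_treatment: bool
) -> StateDef | None:
    hits = [
        s
        for s in states
        if s.alive and not s.absorbing and s.depressed == depressed
        and s.in_treatment == in_treatment
    ]
    if len(hits) > 1:
        raise ConfigurationError(
            f"ambiguous target state (depressed={depressed}, in_treatment={in_treatment})"
        )
    return hits[0] if hits else None


def build_transition_matrix(
    params: TransitionParameters,
    states: list[StateDef],
    cycle_index: int,
    cfg: ScenarioConfig,
) -> TransitionMatrix:
    """Build the transition matrix applied during cycle ``cycle_index``.

    The cohort age used for the mortality band lookup and the age-50
    retirement cutoff is the age at the start of the cycle.
    """
    cl = cfg.cycle_length
    names = [s.name for s in states]
    n = len(states)
    idx = {s.name: i for i, s in enumerate(states)}
    age = params.cohort_start_age + cycle_index * cl

    try:
        i_dead = idx["deceased"]
    except KeyError:
        raise ConfigurationError("state roster lacks a 'deceased' state")
    i_ret = idx.get("retired")

    q_base = convert_probability(_mortality_annual(params, age), 1.0, cl)
    p_retire = (
        convert_probability(params.early_retirement_annual, 1.0, cl)
        if age < RETIREMENT_AGE_CUTOFF
        else 0.0
    )

    M = np.zeros((n, n))
    for i, s in enumerate(states):
        if s.absorbing or not s.alive:
            M[i, i] = 1.0
            continue

        q_death = q_base
        if s.depressed:
            q_death = min(1.0, q_base * params.suicide_mortality_multiplier)

        # named transitions conditional on surviving the cycle
        named: list[tuple[int, float]] = []
        if s.depressed:
            p12 = (
                params.remission_treated_12m
                if s.in_treatment
                else params.remission_untreated_12m
            )
            target = _find_target(states, depressed=False, in_treatment=s.in_treatment)
            if p12 > 0:
                if target is None:
                    raise ConfigurationError(
                        f"no recovered state to receive remission from '{s.name}'"
                    )
                named.append((idx[target.name], convert_probability(p12, 1.0, cl)))
            if not s.in_treatment and params.treatment_initiation_12m > 0:
                t_target = _find_target(states, depressed=True, in_treatment=True)
                if t_target is None:
                    raise ConfigurationError(
                        f"no in-treatment state to receive initiation from '{s.name}'"
                    )
                named.append(
                    (
                        idx[t_target.name],
                        convert_probability(params.treatment_initiation_12m, 1.0, cl),
                    )
                )
        else:
            p12 = (
                params.relapse_treated_12m
                if s.in_treatment
                else params.relapse_untreated_12m
            )
            if p12 > 0:
                target = _find_target(states, depressed=True, in_treatment=s.in_treatment)
                if target is None:
                    raise ConfigurationError(
                        f"no depressed state to receive relapse from '{s.name}'"
                    )
                named.append((idx[target.name], convert_probability(p12, 1.0, cl)))
        if s.employed and p_retire > 0:
            if i_ret is None:
                raise ConfigurationError("early retirement set but no 'retired' state")
            named.append((i_ret, p_retire))

        total_named = sum(p for _, p in named)
        if total_named > 1.0 + 1e-12:
            raise InfeasibleParametersError(s.name, total_named)

        M[i, i_dead] = q_death
        survive = 1.0 - q_death
        for j, p in named:
            M[i, j] += survive * p
        M[i, i] += survive * (1.0 - total_named)

    return TransitionMatrix(entries=M, state_names=names)


def run_cohort(cfg: ScenarioConfig) -> CohortTrace:
    """Propagate the cohort through ``horizon`` cycles.

    occupancy(0) = N x initial distribution; occupancy(t+1) = occupancy(t) . M(t).
    """
    names = cfg.state_names()
    n = len(names)
    T = cfg.horizon
    occ = np.zeros((T + 1, n))
    for name, p in cfg.initial.items():
        occ[0, names.index(name)] = cfg.cohort_size * p
    ages = cfg.transitions.cohort_start_age + np.arange(T + 1) * cfg.cycle_length

    for t in range(T):
        M = build_transition_matrix(cfg.transitions, cfg.states, t, cfg)
        nxt = occ[t] @ M.entries
        if np.any(nxt < -1e-9):
            raise DepmarkError(f"negative occupancy at cycle {t + 1}")
        occ[t + 1] = np.clip(nxt, 0.0, None)

    return CohortTrace(
        occupancy=occ, state_names=names, ages=ages, cohort_size=float(cfg.cohort_size)
    )


def trace_oracle(M: TransitionMatrix | np.ndarray, v0: np.ndarray, t: int) -> np.ndarray:
    """Occupancy after ``t`` cycles of a time-homogeneous chain: v0 . M^t.

    The matrix power is computed by repeated squaring, giving a verification
    path independent of :func:`run_cohort`'s cycle-by-cycle loop.
    """
    A = M.entries if isinstance(M, TransitionMatrix) else np.asarray(M, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DepmarkError("oracle requires a square matrix")
    if t < 0:
        raise DepmarkError("cycle count must be non-negative")
    result = np.eye(A.shape[0])
    base = A.copy()
    k = t
    while k:
        if k & 1:
            result = result @ base
        base = base @ base
        k >>= 1
    return np.asarray(v0, dtype=float) @ result
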