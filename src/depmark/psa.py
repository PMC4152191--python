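"""Probabilistic sensitivity analysis (PSA) by Monte Carlo resampling.

Each iteration draws one value per uncertain parameter from its configured
distribution (beta for probabilities and utilities, gamma for costs, uniform
where only a range is credible, fixed to pin a parameter), rebuilds the
model, reruns the cohort and accumulates outcomes. Means and equal-tailed
95% credible intervals are computed from the resulting outcome sample.

Beta and gamma distributions are parameterized from (mean, se) by the method
of moments. Percentiles use the nearest-rank definition, which is
deterministic and interpolation-free. Sampling is reproducible: iteration i
of a run seeded s uses an RNG stream derived from (s, i), so results are
bit-identical across repeats and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import MAX_DAYS_PER_CYCLE, DistributionSpec, ScenarioConfig
from .errors import (
    ConfigurationError,
    DepmarkError,
    InfeasibleMomentsError,
    InfeasibleParametersError,
)
from .outcomes import ScenarioOutcome, accumulate_outcomes
from .engine import run_cohort

__all__ = [
    "PSAResult",
    "ScenarioComparison",
    "fit_beta_from_moments",
    "fit_gamma_from_moments",
    "sample_parameter_draw",
    "apply_overrides",
    "run_psa",
    "credible_interval",
    "compare_scenarios",
]

OUTCOME_FIELDS = (
    "cost_lpt",
    "cost_turnover",
    "cost_service",
    "cost_antidepressant",
    "cost_total",
    "qalys",
)

MAX_REDRAWS = 10


def fit_beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) matching a given mean and se."""
    if not (0.0 < mean < 1.0):
        raise InfeasibleMomentsError(f"beta mean {mean} must lie in (0, 1)")
    if se <= 0:
        raise InfeasibleMomentsError("se must be positive")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"se {se} too large for beta with mean {mean} (need se^2 < mean(1-mean))"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a given mean and se."""
    if mean <= 0 or se <= 0:
        raise DepmarkError("gamma moments must be positive")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


def _draw_one(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.family == "fixed":
        return float(spec.mean)
    if spec.family == "uniform":
        return float(rng.uniform(spec.low, spec.high))
    if spec.family == "beta":
        a, b = fit_beta_from_moments(spec.mean, spec.se)
        return float(rng.beta(a, b))
    if spec.family == "gamma":
        shape, scale = fit_gamma_from_moments(spec.mean, spec.se)
        return float(rng.gamma(shape, scale))
    raise ConfigurationError(f"unknown distribution family {spec.family!r}")


def sample_parameter_draw(
    spec_set: dict[str, DistributionSpec], rng: np.random.Generator
) -> dict[str, float]:
    """One value per parameter path; iteration order is sorted for determinism.

    Days-per-cycle draws are capped at the 91.25-day cycle bound so every
    draw respects the parameter's support.
    """
    draw: dict[str, float] = {}
    for path in sorted(spec_set):
        value = _draw_one(spec_set[path], rng)
        if path.rsplit(".", 1)[-1].endswith("days_per_cycle"):
            value = min(value, MAX_DAYS_PER_CYCLE)
        draw[path] = value
    return draw


def apply_overrides(cfg: ScenarioConfig, overrides: dict[str, float]) -> ScenarioConfig:
    """Return a deep copy of ``cfg`` with dotted-path parameter overrides set."""
    out = cfg.model_copy(deep=True)
    for path, value in overrides.items():
        parts = path.split(".")
        obj = out
        for p in parts[:-1]:
            if isinstance(obj, dict):
                if p not in obj:
                    raise ConfigurationError(f"cannot resolve '{path}' at '{p}'")
                obj = obj[p]
            elif hasattr(obj, p):
                obj = getattr(obj, p)
            else:
                raise ConfigurationError(f"cannot resolve '{path}' at '{p}'")
        leaf = parts[-1]
        if isinstance(obj, dict):
            if leaf not in obj:
                raise ConfigurationError(f"cannot resolve '{path}': unknown key '{leaf}'")
            obj[leaf] = value
        elif hasattr(obj, leaf):
            setattr(obj, leaf, value)
        else:
            raise ConfigurationError(f"cannot resolve '{path}': unknown field '{leaf}'")
    return out


@dataclass
class PSAResult:
    """Monte Carlo outcome sample with per-outcome mean and 95% interval."""

    draws: list[ScenarioOutcome]
    summaries: dict[str, tuple[float, float, float]]  # field -> (mean, lo, hi)
    n_iterations: int
    seed: int
    horizon: int
    redraws: list[tuple[int, int]] = field(default_factory=list)  # (iteration, attempts)

    def mean(self, outcome: str) -> float:
        return self.summaries[outcome][0]

    def interval(self, outcome: str) -> tuple[float, float]:
        _, lo, hi = self.summaries[outcome]
        return lo, hi


def credible_interval(
    samples: Sequence[float], level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed nearest-rank percentile interval of a Monte Carlo sample."""
    n = len(samples)
    if n < 2:
        raise DepmarkError("credible interval requires at least two samples")
    if not (0.0 < level < 1.0):
        raise DepmarkError("level must lie in (0, 1)")
    s = sorted(samples)

    def rank(q: float) -> int:
        x = q * n
        # guard against float fuzz pushing an integer rank over the ceiling
        return max(1, min(n, math.ceil(x - 1e-9 * max(1.0, x))))

    return s[rank((1.0 - level) / 2.0) - 1], s[rank((1.0 + level) / 2.0) - 1]


def _iteration_rng(seed: int, iteration: int, attempt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, iteration, attempt]))


def run_psa(cfg: ScenarioConfig, n_iterations: int, seed: int) -> PSAResult:
    """Run the Monte Carlo PSA and summarize the outcome distribution.

    Iterations whose parameter draw is infeasible for the transition model
    (named per-cycle probabilities exceeding 1) are redrawn from a fresh
    substream, up to 10 times, and recorded in ``redraws``.
    """
    if n_iterations < 2:
        raise DepmarkError("PSA requires at least 2 iterations")
    draws: list[ScenarioOutcome] = []
    redraws: list[tuple[int, int]] = []
    for i in range(n_iterations):
        for attempt in range(MAX_REDRAWS + 1):
            rng = _iteration_rng(seed, i, attempt)
            overrides = sample_parameter_draw(cfg.psa, rng)
            trial = apply_overrides(cfg, overrides)
            try:
                trace = run_cohort(trial)
            except InfeasibleParametersError:
                continue
            if attempt:
                redraws.append((i, attempt))
            draws.append(accumulate_outcomes(trace, trial))
            break
        else:
            raise InfeasibleParametersError(
                f"iteration {i}", float("nan")
            )
    summaries = {}
    for name in OUTCOME_FIELDS:
        values = [getattr(d, name) for d in draws]
        lo, hi = credible_interval(values, 0.95)
        summaries[name] = (float(np.mean(values)), lo, hi)
    return PSAResult(
        draws=draws,
        summaries=summaries,
        n_iterations=n_iterations,
        seed=seed,
        horizon=cfg.horizon,
        redraws=redraws,
    )


@dataclass(frozen=True)
class ScenarioComparison:
    """Absenteeism-minus-presenteeism contrasts on PSA means."""

    delta_cost: float
    delta_qaly: float
    ci_overlap: dict[str, bool]
    icer: float | None  # AUD per QALY; None when delta_qaly == 0

    @property
    def significant_cost_difference(self) -> bool:
        return not self.ci_overlap["cost_total"]


def compare_scenarios(
    abs_result: PSAResult, pres_result: PSAResult
) -> ScenarioComparison:
    """Contrast two PSA runs (absenteeism vs presenteeism) on the same horizon."""
    if abs_result.horizon != pres_result.horizon:
        raise DepmarkError(
            f"horizon mismatch: {abs_result.horizon} vs {pres_result.horizon}"
        )
    delta_cost = abs_result.mean("cost_total") - pres_result.mean("cost_total")
    delta_qaly = abs_result.mean("qalys") - pres_result.mean("qalys")
    overlap = {}
    for name in OUTCOME_FIELDS:
        a_lo, a_hi = abs_result.interval(name)
        p_lo, p_hi = pres_result.interval(name)
        overlap[name] = a_lo <= p_hi and p_lo <= a_hi
    icer = delta_cost / delta_qaly if delta_qaly != 0 else None
    return ScenarioComparison(
        delta_cost=delta_cost, delta_qaly=delta_qaly, ci_overlap=overlap, icer=icer
    )


def run_psa_pair(
    cfg_abs: ScenarioConfig,
    cfg_pres: ScenarioConfig,
    n_iterations: int,
    seed: int,
    paired: bool = False,
) -> tuple[PSAResult, PSAResult, ScenarioComparison]:
    """PSA for both scenarios plus their comparison.

    By default the two scenarios use independent random streams; ``paired``
    reuses the same stream for both (common random numbers) to reduce the
    variance of the difference.
    """
    res_abs = run_psa(cfg_abs, n_iterations, seed)
    res_pres = run_psa(cfg_pres, n_iterations, seed if paired else seed + 1_000_003)
    return res_abs, res_pres, compare_scenarios(res_abs, res_pres)
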