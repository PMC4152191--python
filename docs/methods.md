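# Methods

## Model structure

The model is a closed-cohort state-transition (Markov) simulation of
employed adults with lifetime major depression. Six health states are
configured by default — depressed/in treatment, depressed/not in treatment,
recovered/in treatment, recovered/not in treatment, retired, deceased — but
the roster is data-driven: states are defined by flags (alive, depressed,
in_treatment, absorbing, employed) and the engine resolves transition
targets from those flags, so an additional state can be added in
configuration without engine changes. Retired and deceased are absorbing.
"In treatment" means any contact with a health professional for a mental
health problem within the last 12 months, which is why recovered states also
carry a treatment status (maintenance contact).

The cycle length is 3 months, matching the natural history of depressive
episodes; horizons of 4 and 20 cycles give the 1- and 5-year analyses. The
cohort is a single stream with a scalar starting age (default 40 years)
advancing 0.25 years per cycle and a fixed female proportion used to mix
sex-specific mortality; we deliberately do not split the cohort by sex or
age because the analysis compares scenarios under identical demographics,
where a sex-split changes both arms equally.

## Transition probabilities

Clinical inputs are expressed per 12 months and converted to the cycle with
the constant-hazard transform `p_Δ = 1 − (1 − p)^(Δ/T)`, the standard
choice when only a cumulative probability is reported. The transform is
exactly invertible, which the tests exploit (12m→3m→12m round-trip to
1e-12).

Within a cycle the ordering is: death first, then the named transitions
share the surviving mass in proportion to their converted probabilities,
and the residual probability is a self-transition. Named transitions are:
remission (depressed → recovered at the treated or untreated rate, keeping
treatment status), relapse (the converse), treatment initiation (depressed
not-in-treatment → depressed in-treatment only; we do not model initiating
mental-health treatment from a recovered state), and early retirement
(employed → retired, only while cohort age < 50). If the named per-cycle
probabilities out of any state sum above 1 the parameter set is rejected as
infeasible — named transitions are never rescaled to force a stochastic
row, because silent rescaling would distort the very probabilities a
sensitivity analysis is varying.

Background mortality is an age-banded annual probability per sex, mixed by
the cohort's female proportion, converted to the cycle, and multiplied by a
suicide-excess factor (≥ 1, capped so the product stays ≤ 1) in depressed
states. Matrices are rebuilt every cycle, but only the mortality band and
the age-50 retirement cutoff are time-varying; on horizons that cross
neither boundary the chain is time-homogeneous, which is what makes the
repeated-squaring matrix-power oracle (`trace_oracle`) a valid independent
check of the cycle loop (agreement demanded to 1e-10).

## Costs and health outcomes

Four cost channels attach to states, all in 2007 AUD:

- **Lost productive time** — disability days per cycle × daily wage, in
  employed depressed states. The absenteeism scenario uses absenteeism
  days, the presenteeism scenario presenteeism days; the two are mutually
  exclusive by construction (the other day count is zero).
- **Job turnover** — per-cycle turnover probability (converted from the
  12-month 10.5%) × cost multiplier × annual salary, restricted to
  depressed-in-treatment states. The multiplier's base range is 0.75–1.5 ×
  salary; deterministic runs use the midpoint (1.125) unless an explicit
  value is set, and the PSA samples it uniformly. A second, default-zero
  turnover channel attaches to recovered employed states purely so one-way
  analyses can vary turnover for workers without depression symptoms.
- **Service use** — annual provider contacts (GP, psychologist,
  psychiatrist, mental health nurse, alternative therapist) ÷ 4 × unit
  cost, in in-treatment states.
- **Antidepressants** — the 2-week use probability converted to the cycle
  (exponent 0.25/(2/52) = 6.5) × the 3-month script cost, in in-treatment
  states.

QALYs weight occupancy by per-state AQoL-4D utilities × 0.25 years per
cycle. Deceased carries zero cost and zero utility. Retired carries no
employment- or treatment-related cost and, by default, the
recovered-untreated utility — the least informative defensible choice,
flagged here because retirees' quality of life is genuinely outside the
model's evidence base.

Accrual timing: end-of-cycle membership earns that cycle's payoff and the
baseline cycle earns nothing, so cycle *t* is discounted by
`(1+r)^(−t·0.25)` with r = 0.03 annually for both costs and QALYs. No
half-cycle correction is applied by default; enabling the flag replaces
end-of-cycle membership with the average of start- and end-of-cycle
occupancy. Per-worker figures divide cohort aggregates by the initial
cohort size (1000), not by survivors.

## Probabilistic sensitivity analysis

Every uncertain parameter is sampled per iteration: beta for probabilities
and utilities, gamma for non-negative costs, uniform for the turnover
multiplier, "fixed" to pin a parameter. Beta and gamma are parameterized
from (mean, se) by the method of moments (`ν = m(1−m)/se² − 1`,
`α = mν, β = (1−m)ν`; `shape = (m/se)², scale = se²/m`); when a source
reports a 95% CI instead of an se, use `se = (high − low)/3.92`. Gamma
draws for day-count parameters are capped at the 91.25 days/cycle bound so
every draw respects the parameter's support.

The default is 1000 iterations — a conventional PSA size, configurable, and
not to be confused with the cohort size of 1000 workers. Iteration *i* of a
run seeded *s* draws from an RNG stream derived from (s, i), so runs are
bit-reproducible and insensitive to execution order; an infeasible draw is
redrawn from a fresh substream up to 10 times (each redraw logged) before
erroring. Summaries are the sample mean and the equal-tailed 95% interval
by nearest-rank percentiles (rank ⌈0.025·n⌉ and ⌈0.975·n⌉ of the sorted
sample) — deterministic and interpolation-free, at the price of a slightly
conservative interval at small n. The rank computation subtracts a relative
1e-9 before the ceiling so that exactly-integer ranks are not pushed up by
binary floating-point representation of 0.025.

Absenteeism and presenteeism PSAs use independent streams by default; a
paired mode (common random numbers) exists for variance reduction of the
difference. The scenario contrast reports mean differences, per-outcome
interval overlap, and the ICER Δcost/ΔQALY (undefined when ΔQALY = 0).

## One-way sensitivity analysis

Sweeps rerun the deterministic model per value — point estimates, no nested
PSA — because single-figure sensitivity tables are the target output shape.
Turnover sweeps can target the depressed-in-treatment channel or the
recovered-worker channel ("not depressed" rows). The uniform-income sweep
replaces wage and salary in both occupation models with common values
(e.g. 279 AUD/day, 72 517 AUD/year) to test how much of the blue/white cost
gap income explains. Asserted invariants: total cost is non-decreasing in
turnover probability, multiplier, wage and salary, and QALYs are invariant
under pure cost-parameter sweeps.

## Synthetic parameter generator

The generator emulates the *structure* of the original model's input
tables, not their values: a full, internally consistent configuration
quadruple (scenario × occupation) per seed. Anchored quantities are the
published ones — income anchors per occupation with a ±20% jitter shared
across occupations (so white-collar income strictly exceeds blue-collar in
every draw), the 10.5% turnover probability, the 0.75–1.5 multiplier range,
3% discounting, N = 1000 and 3-month cycles. Sampled ranges: 12-month
remission 0.3–0.7 treated / 0.1–0.4 untreated (treated ≥ untreated),
relapse 0.05–0.3 treated / 0.1–0.5 untreated (untreated ≥ treated),
treatment initiation 0.2–0.6, suicide mortality multiplier 1.5–2.5 (the
range of excess all-cause mortality reported for depression), early
retirement 1–5%/year, utilities 0.45–0.70 depressed / 0.75–0.90 recovered,
antidepressant 2-week use 0.2–0.5 with a 45–75 AUD 3-month script. The
mortality table uses approximate 2007 Australian life-table magnitudes by
5-year band. Baseline distributions are Dirichlet draws over the four
transient states, with absenteeism weighted toward current depression
(0.35/0.30/0.15/0.20 vs 0.20/0.15/0.25/0.40 expected shares) — a severity
gradient consistent with absenteeism reporters' worse observed outcomes.
Disability days per cycle are drawn from 10–25 (absenteeism) and 3–13
(presenteeism), encoding the same gradient in the lost-time channel.

What the generator does **not** emulate: real survey estimates (its numbers
are draws, not data), sex- or severity-stratified inputs, correlation
between parameters, or occupation differences beyond income, sex mix and
independent clinical draws. Passing tests therefore demonstrate the
*mechanics* — conservation, discounting, distribution fits, orderings
implied by construction — not agreement with any empirical cost estimate.

The packaged fixture is generator draw seed 5, chosen because its totals
reproduce the qualitative orderings of the study (absenteeism dearer than
presenteeism and white collar dearer than blue in both scenarios, with
ratios near the published ones). Its deterministic reference outputs were
computed by an independent path — repeated-squaring matrix powers plus
explicitly re-derived payoff vectors and discounted sums
(`scripts/make_fixture.py`) — before the engine was trusted against them;
the PSA block (seed 0, 1000 iterations) is an engine regression freeze.

## Numerical choices and problem sizes

- Row sums of every built matrix are exact to 1e-12; trace conservation to
  1e-9 on a cohort of 1000; tiny negative occupancies from float
  cancellation (> −1e-9) are clamped to zero, anything larger errors.
- Fixture deterministic regression compares at relative 1e-9: totals are
  10³–10⁴ AUD, so this demands agreement to ~10⁻⁵ cents while tolerating
  accumulation-order differences between the engine and the oracle path.
- Test and analysis problem sizes: 100 generated configurations (25 seeds ×
  4 strata) for conservation/monotonicity properties, 1000-iteration PSAs,
  a 100 000-draw moment check for the distribution fits, and a
  50 000-iteration PSA on a minimal linear model for the analytic-quantile
  convergence check (within 2%). The full suite runs in well under a
  minute.

## Limitations

- A single averaged cohort cannot express differential mortality or
  retirement by sex or age composition; only the mixed mean enters.
- Turnover restricted to depressed-in-treatment states understates turnover
  among untreated depressed workers; this mirrors the evidence restriction
  the design documents rather than a behavioural claim.
- No parameter correlation in the PSA; no severity stratification; no
  workplace-accident costs.
- The half-cycle correction is off by default, so costs and QALYs are
  end-of-cycle approximations; with 3-month cycles the bias is small
  relative to parameter uncertainty.
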