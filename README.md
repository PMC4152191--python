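# depmark

A state-transition Markov cohort model comparing the costs and health
outcomes of **absenteeism** (taking depression-specific disability days off
work) versus **presenteeism** (working through a depressive episode) among
employed adults with major depression, stratified by occupation (blue vs
white collar). It is aimed at health economists and occupational-health
researchers who want a transparent, scriptable alternative to spreadsheet or
TreeAge-style cohort models, with probabilistic and one-way sensitivity
analysis built in.

## The model

A closed cohort of N = 1000 employees moves between six health states in
3-month cycles:

- depressed, in treatment / not in treatment
- recovered, in treatment / not in treatment
- retired (absorbing)
- deceased (absorbing)

Writing the occupancy row vector at cycle *t* as **v**(t) and the per-cycle
transition matrix as **M**(t),

```
v(t+1) = v(t) · M(t),        v(0) = N · π₀
```

where π₀ is the baseline distribution. **M**(t) is built from 12-month
remission, relapse and treatment-initiation probabilities converted to the
3-month cycle by the constant-hazard transform `p_c = 1 − (1 − p₁₂)^(1/4)`,
age-band/sex-specific background mortality with a suicide-risk multiplier in
depressed states, and an early-retirement hazard that applies only while the
cohort is under 50. Within each cycle death is applied first; surviving mass
is shared among the named transitions in proportion to their per-cycle
probabilities, with the residual staying put — so rows are exactly
stochastic, and parameter draws whose named transitions exceed 1 are
rejected as infeasible rather than silently rescaled.

Per-worker outcomes over a horizon of T cycles (4 = one year, 20 = five
years) are discounted at annual rate r (default 3%):

```
Cost = (1/N) Σ_{t=1..T} (1+r)^(−t/4) · v(t) · c
QALY = (1/N) Σ_{t=1..T} (1+r)^(−t/4) · v(t) · u · (1/4)
```

with per-state cost vector **c** composed of four channels — lost productive
time (disability days × daily wage), job turnover (converted annual turnover
probability × multiplier × annual salary, restricted to
depressed-in-treatment states), depression-related service use (annual
provider contacts ÷ 4 × unit costs) and antidepressant scripts — and **u**
the AQoL-4D utility weights. All monetary values are 2007 Australian
dollars.

The probabilistic sensitivity analysis samples every uncertain parameter
(beta for probabilities and utilities, gamma for costs, uniform for the
turnover cost multiplier), reruns the model per draw, and reports means with
equal-tailed 95% credible intervals (nearest-rank percentiles). One-way
sweeps rerun the deterministic model over a grid for a single parameter.

Because the original model's full input tables are not redistributable, the
package ships a synthetic-parameter generator (`depmark.synthetic`) that
emulates their structure, anchored to published values (blue/white daily
wages 170/215 AUD, salaries 44 252/55 595 AUD, 10.5%/year turnover in
depressed-in-treatment states, 0.75–1.5 × salary replacement cost, 3%
discounting), plus one frozen draw with independently computed reference
outputs.

## Worked example

```python
from depmark import packaged_fixture, run_scenario, run_psa_pair

configs, _ = packaged_fixture()
out = run_scenario(configs["absenteeism_blue"])
print(f"cost {out.cost_total:.2f} AUD/worker, {out.qalys:.3f} QALYs")
# cost 7209.57 AUD/worker, 0.710 QALYs

res_abs, res_pres, comp = run_psa_pair(
    configs["absenteeism_blue"], configs["presenteeism_blue"], 1000, seed=0
)
print(f"delta cost {comp.delta_cost:+.0f} AUD, "
      f"CIs {'overlap' if comp.ci_overlap['cost_total'] else 'disjoint'}")
# delta cost +1018 AUD, CIs overlap
```

The first number is the discounted one-year cost per blue-collar worker
reporting absenteeism (lost productive time + turnover + service use +
antidepressants); the PSA contrast says absenteeism costs about a thousand 2007-AUD more per
worker than presenteeism under these synthetic inputs, but
the 95% credible intervals overlap, so the difference is not significant —
the same qualitative conclusion the underlying study design reaches.

The numbered scripts under `analysis/` run the full study sequence
(configuration materialization, deterministic outcomes over 1- and 5-year
horizons, PSA with scenario contrasts, one-way turnover/income sweeps) and
write their tables under `results/`. A `depmark` command-line tool exposes
the same steps (`depmark run|compare|psa|sweep|synth --help`).

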