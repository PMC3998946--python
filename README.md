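# fibersavings

A decision-analytic model of the annual **direct medical cost savings** the
U.S. would realize if people who currently eat less dietary fiber than
recommended increased their intake, thereby lowering the prevalence of
functional (chronic idiopathic) constipation. The package is aimed at
health-economics and nutrition-policy analysts who want a transparent,
fully parameterized budget-impact calculation with a complete
sensitivity-analysis program and an independent microsimulation
cross-check.

## The model

For each population stratum *s* (sex × age group) with denominator *N_s*:

```
eligible_s   = N_s · (1 − m_s)          m_s: fraction already meeting fiber recommendations
prevalent_s  = eligible_s · p_s         p_s: functional-constipation prevalence
responders_s = prevalent_s · ρ_s        ρ_s: fraction whose symptoms respond to fiber
averted_s    = responders_s · Σ_g f(g) · min(1, g·r)
savings_s    = averted_s · [π_s · C_rx,s + (1 − π_s) · C_otc,s]
```

where *f(g)* is the intake-shift distribution (the fraction of the
population adding *g* g/day of fiber), *r* the proportional reduction in
constipation prevalence per additional g/day, *π_s* the prescription share
of treated cases, and *C_rx*, *C_otc* the annual per-case treatment costs.
A *k*% fall in prevalence is assumed to avert *k*% of constipation
treatment costs. All costs are expressed in 2012 dollars; a medical-care
CPI module (`fibersavings.inflation`) converts costs published for other
years.

The defaults encode the published base case: 3% of adult men and 6% of
adult women meeting recommendations, 4.6% prevalence, 85% responders,
r = 1.9%/g, a uniform 9 g/day increase for adults (6 g/day for children
aged 5–17), and a 75%/25% prescription/OTC mix at $10,786.15 / $566.54 per
case-year ($3,032.97 all-prescription pediatric). Population denominators
are a documented calibration choice (240 M adults, 48.5% male; 54 M
children 5–17), not a published input.

Beyond the deterministic core the package provides:

- **`sensitivity`** — named scenario battery (the 13 published sensitivity
  rows), one-way sweeps, tornado rankings, and probabilistic SA over
  uniform/triangular/beta parameter distributions;
- **`dose_response`** — a weighted least-squares estimator of *r* from
  grouped (e.g. quintile) intake–prevalence data, with delta-method
  confidence intervals and a binomial simulation harness;
- **`microsim`** — a synthetic individual-level population (Bernoulli
  draws per person) whose Monte Carlo savings estimate has the cohort
  model as its analytic expectation, used as an independent oracle.

## Worked example

```python
>>> from fibersavings import default_base_case, run_model, run_scenario
>>> from fibersavings import builtin_table2_scenarios, run_microsim
>>> cfg = default_base_case("adult")
>>> result = run_model(cfg)
>>> round(result.total_annual_savings / 1e9, 1)
12.6
>>> round(result.total_averted_cases)
1531732
>>> spec = next(s for s in builtin_table2_scenarios() if s.name == "responders_50pct")
>>> round(run_scenario(cfg, spec).total_annual_savings / 1e9, 1)
7.4
>>> mc = run_microsim(cfg, 1_000_000, seed=1)
>>> round(mc.estimated_savings / 1e9, 1), round(mc.standard_error / 1e9, 2)
(12.5, 0.18)
```

About **$12.6 billion** in annual direct medical costs are averted in the
base case (≈1.53 million constipation cases resolved); halving the
responder fraction scales savings by exactly 50/85 to $7.4 billion; and a
million-person microsimulation reproduces the deterministic total within
one Monte Carlo standard error.

The same runs are available from the shell:

```bash
fibersavings run --scope adult          # base case, per-stratum CSV + JSON report
fibersavings scenarios                  # base case + all 13 sensitivity scenarios
fibersavings microsim --n 1000000 --seed 1
fibersavings fit-dr groups.csv          # estimate r from grouped data
fibersavings inflate 500 2007 2012      # medical-care CPI adjustment
```

Three published sensitivity figures ($21.9 B for a 15 g/day shift, the
$83.9 B best case and the $2.3 M worst case) are not recoverable from
their stated parameter changes under any plausible denominator; the
scenario report computes them from the stated overrides and prints the
discrepancy rather than forcing agreement.

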