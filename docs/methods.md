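# Methods

## Model

The cohort model is a single-year prevalence snapshot: no incidence,
remission, age progression or discounting. For each stratum it multiplies
the population denominator through five factors — the fraction *not*
meeting fiber recommendations, constipation prevalence, the responder
fraction, the expected proportional prevalence reduction, and the annual
per-case treatment cost — and sums over strata. The medical costs before
and after the hypothetical intake shift are compared; the difference is
the reported annual savings.

Key modelling assumptions, stated explicitly because they shape how the
outputs should be read:

- **Proportional cost aversion.** A k% fall in prevalence averts k% of
  constipation treatment cost. Severity migration (a case moving from
  prescription to OTC care rather than resolving) is plausible but not
  modelled; it would change the composition, not the expectation, of the
  savings under the mix parameter.
- **Eligibility.** People already meeting recommendations are outside the
  intervention: they are assigned no intake increment and contribute no
  savings. Prevalence applies to the non-meeting population.
- **Treated burden.** Every prevalent case incurs the stratum's blended
  annual cost `rx_frac · C_rx + (1 − rx_frac) · C_otc`; care-seeking is
  absorbed into that mix parameter rather than modelled separately.
- **Linear dose–response with a cap.** The prevalence reduction for an
  increment g is `min(1, g·r)`. The linear statement alone would exceed
  100% at extreme sweep values (e.g. r = 0.2 at 15 g/day); the cap keeps
  averted cases ≤ responder cases in every sweep. Below the cap the model
  is exactly linear in r, which the tests exploit as ratio identities.
- **No food-cost offset, no indirect costs.** Consumers are assumed to
  substitute similarly priced higher-fiber products, and lost
  productivity is out of scope, so the savings estimate is conservative
  on both counts.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| meeting recommendations, adult M/F | 0.03 / 0.06 | fraction | pediatric 0.03 both sexes |
| constipation prevalence | 0.046 | fraction | all strata; scenario varies to 0.01–0.07 and 0.040/0.102 by sex |
| responder fraction | 0.85 | fraction | |
| per-gram reduction r | 0.019 | fraction per g/day | interpreted as a relative reduction |
| intake shift | all mass at 9 g/day (adult), 6 g/day (pediatric) | fraction by increment | menu {0, 3, 5, 6, 7.5, 8, 9, 10, 15} g/day |
| prescription share | 0.75 adult, 1.0 pediatric | fraction | |
| annual cost, adult rx / OTC | $10,786.15 / $566.54 | 2012 USD per case-year | |
| annual cost, pediatric rx | $3,032.97 | 2012 USD per case-year | pediatric OTC defaults to the adult OTC value; inert while the pediatric prescription share is 1 |
| adult denominator | 240,000,000 (48.5% male) | persons | calibration choice, see below |
| pediatric denominator (ages 5–17) | 54,000,000 (split evenly) | persons | calibration choice |

All proportions are stored as fractions in [0, 1]; percent notation never
enters the code, which removes the usual 100× ambiguity. Configs are YAML
with a `schema_version` field; round-trips are lossless to full float
precision.

**Denominators.** The published inputs include no population counts, so
absolute dollar outputs cannot be reproduced exactly from the printed
parameters alone. The packaged defaults — 240 M adults at 48.5% male,
54 M children aged 5–17, both close to U.S. ~2012 demography — reproduce
the published base-case and pediatric totals within about 1%. They are
required config inputs like any other number, and every absolute-dollar
comparison inherits their uncertainty (the package treats ±5% adult /
±10% pediatric as the meaningful agreement band). Between-scenario
*ratios* cancel the denominators entirely and are exact.

**Dose–response interpretation.** Whether the 1.9%/g figure is a relative
or an absolute prevalence reduction is not stated where it is used; the
scenario arithmetic (e.g. a 3%/g variant scaling savings by 3/1.9) is
consistent only with the relative reading, which is what both the cohort
model and the estimator implement.

## Dose–response estimator

`fit_per_gram_reduction` fits relative prevalence
`p_k/p_1 = 1 − r·(x_k − x_1)` to grouped exposure data by weighted least
squares through the fixed point (x₁, 1), weights nₖ (uniform if absent).
This is deliberately the same functional form the cohort model consumes,
so a fitted r plugs in without transformation, and it makes the estimate
exactly invariant to rescaling all prevalences by a common factor. The
point estimate equals the closed-form two-point slope when only two
categories are given, and recovers a noiseless generating slope to
machine precision.

The confidence interval is delta-method rather than residual-based: the
shared reference denominator p₁ correlates all the relative prevalences,
and to a residual-based interval that common tilt looks like signal, so
it undercovers badly (≈80% in the validation simulation). Propagating
binomial variance pₖ(1−pₖ)/nₖ through the ratio restores ≈94% empirical
coverage at the validation design (5 quintiles, n = 2,000/group,
r = 0.019), with mean bias under 0.001 — the small negative bias is the
usual ratio-estimator effect from noise in p₁. When group sizes are
unknown the residual-based WLS interval is reported instead, as there is
nothing better available. The raw slope is reported alongside the
[0, 1]-clipped value the model accepts; validation statistics use the raw
slope so clipping cannot mask bias.

The simulation harness draws category case counts binomially on the
assumed line; a half-count continuity correction keeps an all-zero draw
inside the valid domain (probability < 10⁻³⁹ at the validation design).

## Microsimulation oracle

`generate_population` draws individuals with exactly the independence
structure the cohort model assumes: allocation to strata by
largest-remainder proportional shares, then per-person Bernoulli draws
for meeting recommendations, constipation (among non-meeting individuals
only), responder status and treatment type, and an increment sampled from
the applicable shift distribution. `estimate_savings_mc` resolves each
constipated responder's case with probability `min(1, g·r)` — an
all-or-nothing event per person, chosen because its expectation equals
the cohort model's proportional-cost arithmetic while keeping
per-individual outcomes interpretable. The estimate scales the resolved
annual costs by `total_population / n`; its standard error is the
empirical SE of the per-individual averted cost under the same scaling,
which captures the full sampling variability and is validated against
the across-seed spread by a chi-square test.

Randomness uses one `SeedSequence` per run spawned into one child stream
per stratum, so populations are byte-identical for a given seed and
insensitive to stratum evaluation order.

What the generator does *not* emulate: household or geographic
clustering, age structure within strata, correlation between fiber intake
and constipation risk at baseline, care-seeking behaviour, or any
longitudinal dynamics. Agreement between microsim and cohort model
therefore validates the *arithmetic* of the deterministic chain, not the
epidemiological realism of its inputs.

## Sensitivity program

The built-in battery reproduces the published sensitivity table: eight
single-parameter adult scenarios, a sex-specific prevalence scenario, a
15 g/day shift, a pediatric-only run, and multivariate best/worst cases.
Scenario overrides address config fields by dotted path, are validated
against the target field's invariants, and never mutate the base config.
One-way sweeps, a tornado ranking (ties broken by path name for
determinism) and a seeded probabilistic SA (uniform, triangular and beta
families) extend the battery.

Three published figures do not follow from their stated parameter
changes:

- **15 g/day → $21.9 B**: strict linearity gives 15/9 × base ≈ $21.0 B,
  ~4% below the printed value, where every other single-change row lands
  within ~2% — the source of the extra 3% is unexplained.
- **Best case → $83.9 B**: the stated overrides (1% meeting, 7%
  prevalence, 3%/g, all-prescription, 15 g/day) give $68.6 B with the
  base 85% responder fraction retained, $80.7 B with it removed; neither
  matches.
- **Worst case → $2.3 M**: the stated overrides give $7.8 M, 3.4× the
  printed value, under every composition tried.

The scenario descriptions do not say whether the responder fraction
participates in the multivariate cases; the battery retains it (85%)
because nothing in the stated overrides touches it. These rows are
computed from the stated overrides, flagged in the scenario report with
the printed value and the relative difference, and no agreement is
asserted for them anywhere.

## Numerical choices and problem sizes

- Double precision throughout; totals are sums of per-stratum products,
  reported to the cent internally and rounded to $0.1 B for display.
- Shift fractions must sum to 1 within 1e-9 (absorbs float literals like
  thirds); the microsim renormalizes the fractions before sampling so
  that slack cannot bias allocation.
- Validation sizes were chosen so each check is decisively powered while
  the whole suite stays interactive: the oracle-equivalence battery runs
  the base case plus all 13 scenarios at n = 10⁶ individuals each
  (agreement asserted within 3 Monte Carlo SEs), the estimator validation
  uses 500 replicates of the 5-quintile design, and the SE calibration
  uses 50 seeds at n = 20,000.
- The probabilistic SA re-runs the full model per draw; at ~10 µs per
  evaluation, 10⁴ draws are instantaneous, so no response-surface
  approximation is used.

## Limitations

- Absolute dollar outputs depend on user-supplied denominators; only
  ratios are denominator-free.
- The per-gram reduction is a single national figure derived from one
  cohort of adult women; no age- or sex-specific dose–response is
  available, and applying it to children is an extrapolation.
- The cost inputs are sparse literature values inflated to 2012; the
  packaged CPI series is annual-average granularity only.
- The model is static: savings accrue in the single year modelled, and
  behaviour (sustained intake change) is assumed, not modelled.
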