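# Methods

## Model structure

The model is a four-state Markov cohort simulation: normal glucose
tolerance (NGT), impaired glucose tolerance (IGT), diagnosed type 2
diabetes (T2D), and an absorbing Dead state.  Cycles are one year; the
cohort ages one year per cycle and is followed from its entry age
(default scenarios: 30, 50, 70, per sex) to a maximum age of 100.  The
Markov property is strict: no tunnel states, no complication sub-states,
no memory of time spent in a state.

Transitions among alive states are NGT↔IGT, IGT→T2D and a small
T2D→IGT remission; NGT→T2D and T2D→NGT are structural zeros.  Only the
four free probabilities are configured — staying probabilities are row
residuals, so rows sum to one by construction.  (The published staying
probabilities are internally inconsistent with their row sums at the
third decimal; the residual convention resolves this and matches the
worked occupancy arithmetic.)

## Intervention effect and costs

The intervention arm uses its own transition matrix at full strength in
model year 1.  Under the default linear decay with horizon H = 7, the
effective matrix in year *y* is the elementwise blend
p_ctrl + w·(p_int − p_ctrl) with w = max(0, (H − y)/(H − 1)): the effect
declines over years 2–6 and both arms coincide from year 7 on.  This
resolves the six-versus-seven-year wording ambiguity in the source
material by satisfying both readings: six years with an effect, none in
the seventh.  A step profile (`decay: none`) is available.

Programme costs run for the five participation years: EUR 390.43 in
year 1 (screening EUR 113.32 + course incl. transport EUR 133.16 +
three quarters of a mentoring year incl. event transport EUR 143.95) and
EUR 189.93 in years 2–5.  The itemised build-up stores unit costs and
multiplicities and rounds each line to the cent (half away from zero);
two lines deserve note: the "four events" mentoring line is 4 ×
EUR 45/10 persons = EUR 18.00, and the prevention-manager follow-up time
is 41⅓ h × EUR 32/10 persons = EUR 132.27 (the exact third is needed to
reproduce the printed cent).  The programme cost is paid by the alive
fraction of the cohort only.

## Rewards, discounting, conventions

Costs (annual state costs; dead costs nothing) and QALYs (sex-specific
state utilities; dead is 0) accrue at cycle start on the occupancy
entering the cycle, with discount factor (1 + r)^(−t), t = 0 for the
first cycle, r = 3%/year for both costs and QALYs by default.  No
half-cycle correction is applied.  The residual alive mass at age 100
contributes its final-cycle rewards and is then dropped.  These
conventions are deliberate fixed choices — the source material does not
state its own — and lifetime totals (e.g. "QALYs gained" columns) are
lifetime discounted totals per person from cohort entry, not increments.

Internal arithmetic is full precision; rounding to 2 decimals (EUR) and
3 decimals (utilities) happens only at report time.

## Mortality

Mortality is banded: <35, 35–64, 65–74, 75+ per sex, with boundary ages
in the upper band and ages beyond the table reusing the 75+ values.
From a life table (columns age, sex, population, deaths_total,
deaths_diabetes) the background probability is
mr = Σ(deaths_total − deaths_diabetes)/Σpopulation per band.  NGT and
IGT share mr (no IGT excess mortality); the T2D state dies with
mr + t2d2d.

Two conventions are implemented for t2d2d.  The dimensionally strict one
divides the attributable share of the all-cause rate by the band's
diabetes prevalence, yielding a per-person-with-T2D excess.  The direct
one uses the attributable share of the all-cause rate itself as the
excess.  The direct convention is the package default and is used by the
`paper-base` preset: it is the only reading that reproduces the published
incremental results (with prevalence division the incremental QALY gains
roughly double and every published ICER is missed by 40–70%; with the
direct reading the age-30/50 ICERs agree to within 0.5–12%).  Explicit
per-band t2d2d overrides are accepted either way, and t2d2d is always
capped at 1 − mr.

Death competes first within a cycle: each alive row of the 3×3 glycaemic
matrix is scaled by (1 − d_state) and d_state fills the Dead column, so
the embedded 4×4 matrix stays row-stochastic exactly.

## Synthetic life tables

Real national life tables and diabetes-attributable death fractions are
inputs the package does not ship.  The generator produces
expectation-valued tables from a Gompertz–Makeham hazard,
q(a) = 1 − exp(−(A + B·e^{C·a})) per sex, with a stationary population
(survivors of a nominal 100,000 births) and diabetes deaths carved out
by band-level attributable fractions.  The `german-like-2006` preset's
hazard parameters were least-squares calibrated (on log band crude
rates) to round-figure targets representing mid-2000s German period
mortality; the preset stores those targets and a self-check asserts the
generated band rates stay within 20% of them.  The implied life
expectancies (e0 ≈ 77.3/82.5 years, e70 ≈ 13.6/16.4 for men/women) sit
within half a year of the real 2006 German values.  Attributable
fractions follow the hump-shaped age profile reported for low-mortality
European populations (peaking around retirement age, higher in women);
band diabetes prevalences are plausible German-survey magnitudes.  All
of these are synthetic stand-ins, chosen once for realism — the presets
are for testing and reproduction, not inference about Germany.

What the generator does not emulate: cohort effects and period shocks in
real mortality, within-band age gradients (the model is band-constant by
design), sex-specific diabetes-death recording artefacts, and any
correlation between diabetes prevalence and mortality.  Tests passing on
synthetic tables therefore validate the pipeline's arithmetic and
qualitative behaviour, not any specific national estimate.

## Probabilistic sensitivity analysis

Uncertain parameters get independent distributions: Betas for the
control-arm transition probabilities and the utilities, unit-shape
Gammas (SE = mean) for the three state costs and the annualised
programme cost (EUR 230.03, which rescales the whole payment schedule).
Beta parameters come from the method of moments,
ν = m(1 − m)/se² − 1, α = mν, β = (1 − m)ν, which round-trips the stated
mean and SE exactly; published shape values that disagree with this
formula can be forced via config overrides.  The IGT→T2D sampling mean
is 0.062 (its distribution's stated mean) while the deterministic base
case uses 0.060; both stated values are kept.

Intervention-arm transitions have no published distributions.  By
default each is tied to its control draw by the deterministic relative
effect (e.g. IGT→T2D halved), preserving the treatment effect while
propagating baseline uncertainty; optionally the arms are sampled
independently.  Mortality is not sampled.  Within a draw, both arms
share one sampled bundle (common random parameters), which the CEAC
interpretation requires.  Transition rows whose sampled exits exceed one
are redrawn as a block.  The generator is `numpy.random.default_rng`
seeded explicitly; identical seed and configuration reproduce the draw
set bitwise.  Default 10,000 draws.

## Economic outputs

ICERs are reported as signed ratios together with a cost-effectiveness
plane quadrant flag; with ΔQALY = 0 the ratio is undefined and flagged
rather than returned as a number.  The CEAC counts strictly positive
incremental net benefit (ties are not cost-effective) over a default
willingness-to-pay grid of EUR 0–50,000 in steps of 1,000.  One-way
sensitivity analyses move either the discount rate (costs and QALYs
together) or the effect horizon, holding everything else at base case.

## Verification

The cohort engine is cross-checked against an independent individual-
level microsimulation (50,000 sampled state paths with identical
conventions): the cohort result is the exact expectation of the sampled
quantity and must agree within three Monte-Carlo standard errors.
Structural properties — occupancy conservation to 1e-12, monotone dead
share, the discounted-annuity closed form for immortal constant-reward
cohorts, collapse of the degenerate-distribution PSA onto the
deterministic pipeline, CEAC monotonicity when all draws gain QALYs —
are asserted in the test suite, partly as seeded property-based tests.

## Known limitations

* The published age-70 results imply far heavier old-age mortality
  (a discounted life expectancy of ≈7.8 years at 70, i.e. roughly a flat
  10%/year death probability) than any realistic mid-2000s German life
  table supports.  On realistic synthetic mortality the model reproduces
  the published age-30/50 ICERs closely but yields age-70 ICERs of about
  EUR 15,700 (men) and EUR 9,300 (women) against the published 27,546
  and 19,433 — same sign, same ordering (women below men), smaller
  magnitude.  The qualitative conclusion (cost-saving at 30/50,
  cost-effective at 70) is robust to ±25% hazard scaling.
* No diabetes complication sub-states, production gains, screening
  utility, or hyperglycaemia mortality extension; two comparators only.
* Parameter independence in the PSA; no correlation structure and no
  uncertainty on mortality or on the relative treatment effect beyond
  the options described above.
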