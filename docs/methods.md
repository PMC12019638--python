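# Methods

This note documents the models implemented in `carecast`, the
assumptions behind them, the parameters that matter, and the design
choices made where the published description left the design open.

## Symptom states and analysis variables

Depressive symptoms are measured by the 8-item CES-D battery: six
negative statements and two positive statements, each answered yes/no.
The score counts symptom-consistent answers (yes to a negative item,
no to a positive one), range 0–8. Severity bands: 0 → none, 1–2 →
mild, 3–5 → moderate, 6–8 → severe. A part-missing battery yields no
score and the person-wave is excluded from estimation (no imputation;
the handling of partial batteries in the source survey is not
documented, so exclusion is this package's choice).

Functional difficulty has four levels derived from ADL/IADL counts:
none; IADL difficulties only; 1–2 ADL difficulties; 3+ ADL
difficulties. Care mode is the four-way cross of the two receipt
flags: none, unpaid only, home only, both. Equivalised income divides
household income by 1.0 for the first adult + 0.5 per further person
aged 14+ + 0.3 per child under 14. Housing quality is a 0–12 count of
problem types; counts above 12 are rejected as instrument errors.

## Transition model

A multinomial logistic regression of severity at wave *T*+1 (base
outcome: none) on wave-*T* covariates: housing-problem count, current
severity indicators, age (continuous), female, rented tenure, two
education indicators, and equivalised income in £/week (unscaled — the
published per-£ relative risk ratio of 0.99 with SE 0.0001 indicates a
per-pound coefficient). Consecutive wave pairs are pooled;
estimation is by maximum likelihood (statsmodels `MNLogit`),
unweighted (survey weights are out of scope).

**Annualization.** The survey is biennial, so predicted probabilities
are two-year ones. Under a constant instantaneous rate, *p₁ = 1 − (1 −
p₂)^½*. The published formula is scalar; in a 4-destination row we
apply it per off-diagonal destination and restore the stay probability
as the complement (if annualized moves exceed 1, they are rescaled
proportionally and the diagonal set to 0; in practice this never
triggers at realistic coefficients). This elementwise rule is an
approximation — the exact multi-state half-step is a matrix square
root, which can produce negative entries — and is exact in the
two-state case: two annual steps reproduce the two-year leave
probability to machine precision, a property the tests pin down.
Whether the original analysis renormalized after elementwise
conversion is not stated; the complement rule here is a choice.

**Matrix assembly.** One 5×5 annual matrix per single year of age and
gender. Housing enters as a stratum-level mixture: the living-state
row is Σ_h w(h) · row(h) over the housing-problem distribution w,
because a cohort model cannot carry individual housing counts.
Tenure, education and income are held at stratum means (predictions
are conditioned on age, gender and housing only); age is continuous in
estimation but matrices are materialized per single year of age.
Death is resolved first within each annual step: the death probability
from living state *s* is *q·m_s / Σ_k w_k m_k*, with marginal rate *q*
from the (age, gender) mortality schedule, state multipliers *m* =
(1.0, 1.1, 1.3, 1.6) by default and state shares *w*; the normalizer
preserves the stratum's marginal rate. The multipliers are
configuration inputs because the survival estimates behind
state-specific mortality are not published. Survivors then transition
among living states; the ordering of death vs morbidity within a year
is unstated in the source and is this package's convention.

**Scenarios.** The no-intervention base case uses the observed housing
distribution; intervention scenarios relocate all mass above a cap
(2, 1 or 0 problems) onto the cap. With all housing RRRs > 1, lower
caps never increase worsening probabilities (tested).

## Cohort projection

The projection starts from base-year (2022) population counts by
single year of age 45–100+ and gender, split across living states by
the base-year prevalence, and iterates annual steps to 2042 under
time-constant matrices (homogeneous chain): multiply each (age,
gender) state vector by its matrix, advance survivors one year of age,
pool the open 100+ group, accumulate deaths, and inject 45-year-old
entrants carrying the base-year age-45 state mix (the youngest-age
boundary rule is unspecified in the source; constant entrants at the
modelled floor is the simplest closure). Counts are expected values
(real numbers), not simulated agents. Accounting is exact: living +
cumulative deaths − cumulative entrants is conserved to machine
precision every year. Prevalence is reported by gender and age bands
65–69 … 90+.

## Care and cost macrosimulation

Three parts. (1) The 65+ population with symptoms is decomposed into
cells by age band, gender, functional difficulty and severity; the
functional distribution conditional on severity is estimated from the
base-year cross-section and held fixed across projection years (the
projection evolves symptom states only). (2) Cell-level care-mode
probabilities come from a multinomial logit on the 65+ cross-section
(severity, age, female, functional level; base outcome no care);
unpaid users = P(unpaid only) + P(both), home users = P(home only) +
P(both). Weekly hours come from per-care-type OLS on recipients (a
two-part model: participation × conditional hours); negative
predictions are floored at 0. Banded cells use the band midpoint age
(92.5 for 90+). (3) Annual hours = users × weekly hours × 52.14 weeks,
costed at the year's unit cost. Severity components sum exactly to
totals before any presentation rounding.

**Unit costs.** Home care £23/hour in 2022 prices. Unpaid care is
valued at replacement cost (£23, the price of its closest market
substitute) by default, or at opportunity cost (£14.8/hour, 2022
prices) — switching multiplies unpaid costs by 14.8/23 ≈ 0.6435
exactly, about 36% lower. Real unit costs grow at 1.2%/year with a
one-off ×1.05 uplift in 2024 for the planned living-wage rise; the
exact forecast growth rates behind the published projections are not
printed, so these are configurable defaults chosen to sit in the range
of recent UK productivity/wage forecasts. Costs are reported in
constant 2022 prices with real growth applied; no discounting.
Symptom-free people are excluded from cost tables by default (a flag
includes them for completeness analyses).

## Sensitivity analyses

*Progression perturbation*: worsening (toward more severe) annual
probabilities ×1.05 and improving ones ×0.95 ("accelerated"), or the
reverse ("delayed"); multiplicative scaling of annual probabilities,
diagonal restored, death column untouched. *Intervention
effectiveness*: scenario matrices become base + f·(scenario − base)
entrywise with f = 1.05 or 0.95, clipped and renormalized via the
diagonal. *Monte Carlo*: every regression coefficient across all
three fits is drawn independently from a normal on its estimation
scale (log-RRR or linear); each of the 1,000 draws reruns matrices →
projection → costs, and the 2.5th/97.5th percentiles across draws form
the 95% credible interval. Independence across coefficients is an
approximation — published tables carry SEs but no covariances — and
can widen or narrow intervals relative to the true joint. Each draw
uses the deterministic substream `default_rng([seed, draw])`, so
results are reproducible and invariant to draw order.

## Synthetic cohort generator

The generator emulates the survey structure the estimators assume:
~10,600 adults aged 50+ observed over four biennial waves. Individual
covariates are drawn from the published wave-6 marginals (55.2%
female, 16% rented, education 37.8/30.9/31.3%, income lognormal with
mean ≈ £392/week, housing bands 71.7/18.2/6.3/3.8% with the 3+ band
spread geometrically over 3–12, age from a Beta profile with mean ≈
67). Housing problems are drawn once per individual and held fixed
across waves — the published analysis treats them as a wave-T
covariate and its descriptive marginals are stable, but within-person
evolution is unobserved, so persistence is an assumption. Wave-1
severity follows the published baseline (48.0/31.9/14.3/5.8%);
subsequent waves follow the lagged multinomial process with the
published RRRs as truth. CES-D items are drawn score-first within the
state's band (items exist to exercise scoring, not as a latent item
model). Functional difficulty is drawn from a 4×4 conditional table
given severity (association is established but no generative law is
published; the default table has a plausible monotone gradient). Care
modes and hours follow the published care coefficients; hours are
normal residuals truncated at 0.5 h/week for recipients. Mortality is
Gompertz (q = a·e^{b·age}; defaults a = 2.3e-5, b = 0.095 for men,
a = 1.35e-5, b = 0.097 for women, giving life-table-like rates);
attrition is missing-at-random at 12%/wave, loosely matching the
observed panel decline. All randomness flows from one seeded
generator; identical config + seed gives byte-identical output.

Unpublished intercepts (transition, care mode, hours) were calibrated
once so the generator's stationary behaviour matches the published
wave-6/7 marginals — wave-to-wave severity near 45/36/14/5% and 65+
care use near 12.5% unpaid / 6.5% home — and are frozen in
`config.py`.

**What the synthetic world does not emulate:** the survey's sampling
design, household clustering and weights; state-dependent attrition;
within-person housing dynamics; cohort trends in education and income;
any correlation between income and housing quality. Passing tests
therefore demonstrate that the estimators recover a known
data-generating process of the assumed form and that the projection
arithmetic is exact — not that the synthetic levels equal the levels
estimable from the restricted microdata. Orderings (scenario effects,
perturbation directions, costing ratios) are structural and carry
over; absolute levels do not.

## Numerical choices and problem sizes

Probability vectors are validated to sum to 1 within 1e−9; emitted
matrices are row-stochastic to machine tolerance. Degenerate inputs
(empty outcome categories, rank-deficient hours designs, out-of-range
probabilities, negative counts) raise informative errors rather than
propagating NaNs. The test suite runs the full pipeline on small
worlds (flat populations, toy matrices) plus five 50,000-person panels
for parameter recovery; the acceptance script uses the survey-scale
panel (10,601 individuals), the full 45–100+ England-like age profile,
and 1,000 Monte Carlo draws.

## Known limitations

No care-home or health-care costs; no migration; no time-varying
transition probabilities; no survey weighting; no covariances in the
Monte Carlo; elementwise (not matrix-root) annualization; the cost
side of housing remediation itself is out of scope.
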