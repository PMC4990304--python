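# Methods

## The dose-response model

`cadbmd` treats each dose band as an independent binomial experiment:
`y_i ~ Binomial(n_i, P(d_i))` with the dichotomous log-logistic response

    P(d) = g + (1 - g) / (1 + exp(-a - b ln d)),    P(0) = g.

`g ∈ [0, 1]` is the background probability of an abnormal biomarker,
`a` the intercept and `b > 0` the slope per unit natural-log dose. The
dose-0 reference band enters the likelihood through `P(0) = g`; no log of
zero is ever evaluated. The natural logarithm of dose is load-bearing: with
log10 the same data imply a different `(a, b)` scale and different BMDs.

Assumptions worth stating: subjects are exchangeable within a band (the
band's geometric-mean dose stands in for every member), abnormality is a
fixed threshold exceedance, and the response is monotone in dose. The model
is fit to grouped counts, not subject-level covariates — age, for example,
influences the biomarkers but is deliberately not a fit covariate; its
effect is absorbed into the percentile cut-offs and the band prevalences.

### Estimation

The negative binomial log-likelihood is minimized over
`(g, a, b) ∈ [0,1] × R × [b_min, 25]` with analytic gradients, by L-BFGS-B
from a fixed lattice of 8 deterministic starts
(`g ∈ {0.02, 0.08} × a ∈ {-5, -2.5} × b ∈ {b_min, b_min+1}`), followed by a
Nelder-Mead polish of the best point; the convergence tolerance is below
1e-8 in negative log-likelihood. Probabilities are clipped at 1e-12 so a
degenerate `P → 0` with observed positives yields a large finite barrier
value rather than an overflow.

`b_min = 1` by default (`restrict_slope=True`), the usual regulatory
restriction that keeps the response from being supralinear at low dose.
When the data prefer a shallower curve the slope pins at 1 exactly and the
fit is flagged (`slope_at_bound`).

### Parameter counting at bounds

AIC is `2k − 2 ln L̂` and the Pearson goodness-of-fit chi-square uses
`df = groups − k`. By default `k` counts only parameters *not* pinned at a
constraint bound — the convention of the standard benchmark-dose software
this package interoperates with: a slope sitting on `b = 1` was not really
estimated. `count_boundary_params=True` restores the fixed `k = 3`
accounting. The packaged male NAG table exercises this path: its slope pins
at 1.00 and its AIC/GOF reproduce the published row only under the
boundary-aware convention.

### BMD and BMDL

The benchmark response `q` (default 0.10 and 0.05) is defined as *extra
risk*, `(P(BMD) − g)/(1 − g) = q`, not added risk. The inversion
`BMD = exp((logit(q) − a)/b)` is closed form and independent of `g` — a
property the test suite asserts to 1e-10. Extra risk also makes the
published BMD columns recomputable from the published `(a, b)` alone, which
the acceptance tests exploit.

The BMDL is a one-sided 95% profile-likelihood limit. Under extra risk,
fixing `BMD = D` is the linear constraint `a = logit(q) − b ln D`, so the
inner problem is a 2-parameter bounded optimization over `(g, b)`, warm
started along the search. The BMDL is the smallest `D` whose profiled
negative log-likelihood stays within `χ²₁(2·0.95 − 1)/2 ≈ 1.35277` of the
minimum; the crossing is bracketed geometrically (factor 0.7) and solved by
Brent's method (`xtol` 1e-9). A profile that never crosses raises an error
carrying the inspected trace. A dense-grid profile oracle in the tests
confirms the bisection to within grid resolution, and a 500-replicate
simulation puts the one-sided coverage of the true BMD at ~93–95% for
five bands of 200 subjects — slightly conservative-to-nominal, as expected
for profile limits at moderate `n` with an active slope restriction in part
of the replicates.

## Cut-offs, classification, grouping

Cut-offs are empirical upper percentiles (90th/95th) of each sex's
biomarker distribution over all subjects with a non-missing value. The
percentile convention is linear interpolation between order statistics
(numpy's default), exposed as an option because conventions differ at these
sample sizes; under linear interpolation a duplicated sample can shift the
cut-off within one order-statistic gap (the inverted-CDF convention is
exactly duplication-invariant). Classification is strict: a value exactly
at the cut-off is normal. Missing biomarkers propagate as missing and leave
the denominator.

Dose bands default to `≤0.49, 0.50–0.99, 1.00–1.49, 1.50–1.99, ≥2.00`
µg/g Cr, interpreted on values rounded to 2 decimals so the printed labels
partition the line (internally half-open intervals). Each band is
summarized by the geometric mean of its UCd values; a band whose positive
fraction falls below 0.5 (dominated by non-detects recorded as 0) reports
GM 0, which is how an all-non-detect lowest band can carry dose 0 into the
fit while contributing through `P(0) = g`.

## Trend and association statistics

The linear trend test is the Cochran–Armitage-type chi-square (1 df) with
integer rank scores 1..k by default and geometric-mean-dose scores as an
option; the normalization is the linear-by-linear `(N−1)` form by default
with the classical `N` form available. The statistic is affine-invariant in
the scores, reduces to the 2×2 Pearson chi-square for two bands, and is
cross-checked against `statsmodels` ordinal association on every packaged
table. Score and normalization choices are explicit because printed trend
statistics are not recoverable without the raw data; with rank scores and
the `(N−1)` form several published values reproduce exactly and the rest
agree to within a few percent.

Stepwise regression is forward selection (entry p ≤ 0.05) with backward
removal (p > 0.10) on OLS fits, with a design-rank guard so a predictor
collinear with the current model can never enter. Pearson correlations use
the exact t-distribution p-value.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
data set: two sexes (defaults 469 males, 465 females) with the enrolled
age-class frequencies (8 bins, open top bin capped at 85 years; ages
uniform within bin); per-sex log-normal UCd floored to 0 below a detection
limit (default 0.05); and biomarkers
`intercept + β_age·age + β_ucd·UCd`, with multiplicative log-normal noise
by default (biomarkers are nonnegative and right-skewed) or additive
Gaussian noise as an option, truncated at 0. One global seed drives
independent per-sex, per-stage substreams, so any stage regenerates in
isolation.

Default parameters: the age and UCd slopes are the published
stepwise-regression estimates (RBP 1.172 and 20.89; β2-MG 0.003 and 0.118;
NAG 0.072 and 1.143). The UCd distribution parameters are not published;
the defaults (male meanlog ln 0.6, sdlog 0.8; female meanlog −0.40, sdlog
0.9) were chosen once to mirror the observed five-band occupancy (roughly
39/31/15/6/9% of males from the lowest to the highest band) and a slightly
heavier female upper tail. Biomarker intercepts (60 µg/g, 0.15 mg/g,
4.0 U/g) and noise sdlogs (0.55, 0.70, 0.50) were likewise chosen once to
give plausible marginal scales (e.g. male RBP 90th percentile near
270 µg/g Cr). Per-biomarker missingness defaults (13/9/8%) mirror the
published per-biomarker denominators. What passing tests on this cohort
do **not** show: robustness to covariate-dependent (non-MCAR) missingness,
assay floor effects in the biomarkers themselves, or confounding beyond
age — none of which the generator emulates.

## Numerical and reporting choices

- Percentile method, trend scores/normalization, slope restriction and AIC
  parameter counting are all explicit keyword options; defaults are the
  conventions that reproduce the packaged reference tables.
- Fitted parameters on a quantal table with few bands are weakly
  identified along a likelihood ridge (near-equal likelihood for trades
  between `a` and `b`); the BMD is the stable functional of the fit and is
  what downstream consumers should compare. Inputs rounded to printed
  precision can move `(a, b)` by a few hundredths while moving the BMD by
  less than 0.01.
- Pipeline outputs are written at full precision; determinism is
  byte-level for fixed config and seed, and every table cross-foots before
  writing.
- Simulation sizes in the test suite (cohorts of 2×2500, five bands of
  200 subjects × 500 replicates for coverage) were chosen as the smallest
  sizes at which the checked statistical properties are stable.

## Known limitations

- Only the log-logistic quantal model is implemented — no gamma, probit,
  Weibull or dichotomous-Hill alternatives, no model averaging, and no
  continuous-endpoint ("hybrid") BMD.
- Group-level fitting discards within-band dose variation; the BMD
  inherits any bias from the band partition and its GM summary.
- The profile BMDL assumes the chi-square calibration of the likelihood
  ratio; at very small counts (bands with 0–2 positives) its one-sided
  coverage can drift a few points below nominal.
- Stepwise selection inherits the usual post-selection inference caveats;
  reported coefficient p-values are not selection-adjusted.
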