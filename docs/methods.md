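# Methods

## Data model and conventions

A capture record carries total length `TL` (cm, snout to caudal-fin tip,
required, > 0), wet mass `W` (g, optional), fractional age (yr, optional,
in (0, 12]), survey year, river tract, gear, transect id, and an optional
pointer to an earlier capture of the same pit-tagged fish.

* **Age classes** are 1-year intervals, right-closed: class `k` covers
  `(k, k+1]`, so a fish aged exactly 1.0 yr is still in class 0. Ages are
  stored fractional and binned lazily; nothing is ever stored rounded.
* **Recaptures** form chains (`recapture_of` links); each chain collapses
  to its earliest capture. The earliest record is the least
  growth-confounded measurement of the individual; circular links are a
  data error. The operation is idempotent.
* **Analysis subsets**: the length–weight fit uses records with a measured
  (never imputed) mass; length-at-age analyses use records with a
  determined age; density uses electrofishing records on transects with a
  known length. The single lake-caught record is carried under a LAKE
  tract code and folded into the lower-river tract for tract-level
  summaries.

## Length–weight allometry

`log10 W = b·log10 TL + log10 a` by OLS (statsmodels), with t-based 95%
CIs at `n − 2` df and adjusted r². Back-transformation is the raw inverse
`W = 10^(b·log10 TL + log10 a)` with **no** lognormal bias-correction
factor: imputed masses feed biomass-density sums that should sit on the
fitted line, not above it. Imputed masses are flagged and excluded from
any refit, which removes the circularity a naive impute-then-refit loop
would create.

## Growth trajectories

Nonlinear least squares (scipy `least_squares`, Levenberg–Marquardt,
analytic Jacobians, parameter tolerance 1e-8, ≤ 1500 function
evaluations). Starting values are data-driven: `TL∞⁰ = 1.1·max(TL)`, and
the rate and `t0` from an OLS line through the family's own
log-linearisation (e.g. `ln(−ln(TL/TL∞⁰)) = −G·t + G·t0` for Gompertz).
This is reproducible and needs no hand-tuned inputs.

Standard errors come from `σ̂²(JᵀJ)⁻¹` at the optimum with
`σ̂² = RSS/(n − 3)`; 95% CIs are `estimate ± t(0.975, n−3)·s.e.`. AICc uses
`n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` with `k = 4` (three curve parameters
plus the error variance), the convention of the standard model-selection
tooling for least-squares fits; Akaike weights are `exp(−Δᵢ/2)`
normalised, invariant to a common shift. A perfectly interpolating fit
(RSS = 0, possible on noiseless synthetic data) is kept finite by flooring
RSS at `n` times the smallest positive float.

Two diagnostics are deliberate behaviour, not errors: a non-converged fit
is returned with `converged=False` and a warning (on strongly sigmoid data
the von Bertalanffy asymptote genuinely diverges — that result is
information), and any fitted asymptote above a configurable plausibility
bound (default 140 cm, the species' maximum length record) fires a
warning while still being reported.

The sensitivity refit drops the `k` longest fish (default 3) and reports
the relative shift of `TL∞` against a 10% threshold; it guards the
asymptote against sparse coverage of old, large fish.

## Catch-curve mortality

Catch-at-age is tabulated over all 1-year classes (empty interior classes
kept as zeros). The descending limb by default starts **above** the modal
(first fully-recruited) class and stops at the first empty class: isolated
very old fish beyond a gap violate the constant-Z geometric-decline
assumption more than they inform it. An `include_peak` mode and an
explicit upper class bound are available.

With recoded ages `x = class − first_included_class`, `n` fish and
`T = Σx`, the Chapman–Robson estimator is `S = T/(n+T−1)` (the unbiased
estimator; the geometric MLE is `T/(n+T)` and the two coincide only as
`n+T → ∞`). The default mortality estimate applies the Hoenig bias
correction `Z = −ln S − (n−1)(n−2)/(n(T+1)(n+T−1))` with variance
`(1−S)²/(nS)`; `corrected=False` gives raw `−ln S` with the delta-method
variance from `se(S) = sqrt(S(S − (T−1)/(n+T−2)))`. CIs are normal-based.
The correction always shrinks `Z` downward.

`M = 5.109/t_max` is the one-parameter longevity estimator of natural
mortality; `t_max` defaults to 11 yr (the species' maximum recorded age in
the study region). `F = Z − M` is floored at zero with a warning when the
empirical `M` exceeds `Z` — possible because `M` is a rough cross-species
rate — and the flag is surfaced in reports. `E = F/Z` and
`A = 1 − e^(−rate)` are exact identities. Reports round half-to-even at 3
decimals; all computation is full precision.

## Reference points and harvest policies

The two empirical log10-linear relations (maturity: slope 0.8979,
intercept −0.0782, residual s.e. 0.127; optimum length: 1.0421, −0.2742,
s.e. 0.073) are applied to the selected model's `TL∞`. Their 95%
prediction intervals exponentiate `log10(point) ± c·s.e.` with `c = 1.96`
(infinite df) by default; the df is configurable, but the source
regressions' sample sizes are not published, and the normal quantile
reproduces the published intervals to within the rounding of the printed
standard errors (~0.1 cm on the endpoints). The optimum slot is
`TLopt ± 10%`; the megaspawner threshold is the slot's upper bound.

Policy conventions, fixed and documented because the regulations do not
state them: a fish exactly at the MLL is retainable (≥), slot bounds are
inclusive, "immature" means `TL < TLm` (point estimate; classification at
the PI bounds is available through a custom `ReferencePoints`). The three
primary retained categories (immature / within slot / mature outside
slot) partition the retained catch; the megaspawner flag is a subset of
mature-outside-slot and is reported separately as well. When nothing is
retainable, fractions are defined as 0 with an explicit flag.

## Density

A transect of length `L` m samples `2L` m³ (the electrofishing field is
~1 m³ swept along both sides of the path). Numerical density is fish per
m³ and biomass density g per m³ with imputed masses included (and
flagged). Between-tract comparisons: Kruskal–Wallis omnibus plus pairwise
Mann–Whitney with Bonferroni multiplication capped at 1; exact pairwise
p-values when both groups have ≤ 20 values and no ties, the tie-corrected
normal approximation otherwise.

## Synthetic populations

The generator emulates exactly the cross-sectional assumptions of the
estimators, with defaults set to the assessed population's conditions:

| parameter | default | meaning |
|---|---|---|
| `n` | 295 | aged-fish sample size |
| `Z_true` | 0.924 yr⁻¹ | constant total mortality; classes geometric with `S = e^(−Z)` |
| `t_max` | 11 yr | age truncation (oldest class 10) |
| `full_recruit_age` | 2 | first fully-vulnerable class |
| `ascending_catchability` | (0.2, 0.6) | relative capture probability of classes 0 and 1 |
| growth | (105.0 cm, 0.216 yr⁻¹, 3.99 yr) | Gompertz mean length-at-age |
| `sigma_TL` | 5 cm | additive Gaussian length noise, matching the ~5 cm residual scatter of the length-at-age fit |
| allometry | (log10 a = −2.100, b = 3.055) | mass power law |
| `sigma_log10W` | 0.05 | lognormal mass noise; yields adj. r² ≈ 0.99 for the length–weight fit, as observed |
| `missing_mass_frac` | 0.27 | fraction of unweighed fish (124/458 in the density subsample) |

One `numpy.random.Generator` seeded from the config drives everything, so
a fixed seed gives bit-identical datasets. The uniform (0, 1] fractional
age offset is chosen so right-closed binning returns the drawn class
exactly. Length noise is additive Gaussian (the error model of the
nonlinear growth fit) while mass noise is lognormal (the error model of
the log-scale regression) — each estimator is tested under its own
assumed error structure.

What the generator does **not** emulate: spatial structure and movement
between tracts, multi-year cohort dynamics and recruitment variability,
gear-specific length selectivity beyond the ascending-catchability ramp,
and measurement error in ages. Passing tests therefore demonstrate that
the estimators recover the truth when their assumptions hold, not that
those assumptions hold in any particular river.

## Problem sizes and test design

Simulation-based checks use sizes chosen to make sampling error small
relative to the asserted tolerances while keeping the suite quick:
parameter-recovery fits at n = 2000–5000, geometric-ratio checks at
n = 1e5, and CI-coverage runs with 200 replicates of n = 300–400 (binomial
slack on a 95% coverage estimate at 200 replicates is about ±0.03, hence
the ±0.04 acceptance band). The end-to-end pipeline test runs at n = 2000,
where the reference points land within a few cm of their generating
values.

## Known limitations

* The Chapman–Robson variance is the Hoenig form; variance-inflation
  (overdispersion) adjustments recommended for heavily overdispersed
  catch curves are not implemented.
* No regression-based catch-curve alternatives, no tag-based survival
  models, no depletion/capture-efficiency correction for density — raw
  catch per sampled volume only.
* The empirical reference-point relations are cross-species borrowing;
  their prediction intervals are honest about that (a factor of ~1.8 wide
  for maturity).
* One pooled allometry; no tract-specific or seasonal variants.
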