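# Methods

## Scope

`ecostoich` analyses plot-level vegetation, litter, and soil tables from
gradient studies of community stoichiometry. It computes community-weighted
leaf nutrients and diversity, mass-loss-corrected nutrient resorption
efficiencies, the resorption control-strategy test, the stoichiometric
homeostasis index, N:P limitation calls, and polynomial elevation trends.
A synthetic-community generator with fully known ground truth backs the test
suite, so every estimator is validated by closed-form checks and parameter
recovery rather than against unpublishable field data.

## Community aggregation

Community leaf C, N, P (LTC/LTN/LTP, g/kg) are community-weighted means:
CWM_t = Σᵢ tᵢ wᵢ with wᵢ the biomass proportion of species i. Species with a
missing concentration are excluded from the CWM (warned, never silent) but
retained for diversity, which needs only abundance. Diversity is
Shannon–Wiener H′ = −Σ pᵢ ln pᵢ (nats) and Pielou E = H′/ln S; E is flagged
undefined (NaN) for single-species plots rather than raising. Abundance for
diversity defaults to individual density when the survey provides it and
falls back to biomass share (`diversity_weight` switch); density is the
conventional weighting in the diversity literature, while biomass is what
the nutrient CWMs use.

## Resorption and control strategy

Resorption efficiency for nutrient X is
`NuRE = (1 − senesced/green · MLCF) · 100`, with the mass loss correction
factor MLCF defaulting to 0.762 (global broadleaf value; configurable
globally since growth-form-specific factors exist). Without MLCF, the dry
mass lost during senescence concentrates the remaining nutrients and
resorption is underestimated.

Community senesced concentrations come either from a pooled litter row
(token `__community__`, the herbaceous field protocol where senesced
material cannot be sorted to species) or as the biomass-proportion weighted
mean of species-level rows (shrub protocol). When a litter species lacks a
survey biomass share, the package falls back to an unweighted mean and flags
the plot.

The absolute resorbed ratio
`resorbed_NP = (LTN − LTN_s·MLCF) / (LTP − LTP_s·MLCF)` is undefined (NaN,
flagged) when either resorbed amount is non-positive — apparent nutrient
accretion — and such plots are excluded from both strategy fits with the
exclusion counted and reported.

The control-strategy test fits (a) a power law
`resorbed_NP = ω·(LTN:LTP)^λ` by OLS on log10–log10 axes (λ = slope,
ω = 10^intercept) and (b) a plain linear regression of resorbed_NP on
LTN:LTP, each with a t-based 95% CI on the slope. Labels: *stoichiometric
control* when both CIs contain 1; *nutrient limitation control* when the
power-law CI excludes 1; *joint regulation* when only the linear CI excludes
1. The power-law test takes precedence because the exponent is the quantity
with a mechanistic interpretation (preferential resorption of the scarcer
element); the precedence order is a package convention. The base-10
linearised fit (rather than nonlinear least squares) matches how such fits
are reported and displayed in this literature.

## Homeostasis and limitation

The homeostasis model is `log10 y = log10 c + log10 x / H` with x the soil
stoichiometry and y the paired plant stoichiometry; H is the inverse OLS
slope. Any fixed log base gives the same H (both axes rescale by the same
constant; asserted by a change-of-base test). Classification follows the
Persson bands: significant regression (p < α, default 0.05) with H ≥ 4
steady state, 2 ≤ H < 4 weak steady, 1.33 ≤ H < 2 weak sensitive, H < 1.33
sensitive; a non-significant regression is an *absolute steady state* (the
plant side does not track the soil side at all), and a non-positive fitted
slope is treated the same way. Band edges are inclusive on the left.
Pairing is plot-level soil against plot-level community values by default
(site-mean option in config).

Limitation calls use leaf N:P thresholds — Güsewell 10/20 (default) or
Koerselman–Meuleman 14/16 — with the interval closed on both ends, so a
ratio of exactly 10 or 20 is co-limited.

## Elevation trends and correlations

First- to third-order polynomials of each response on elevation are fitted
by least squares on centred/scaled elevation for conditioning, with
coefficients mapped back to the metre scale (verified to reproduce fitted
values to 1e-8). Model choice uses AICc (small-sample form, k counting the
residual variance) because gradient designs of this kind have only a few
dozen plots. Selection follows the standard parsimony convention: the
lowest-order model within 2 AICc units of the minimum, so a higher order
must earn its extra parameters; with strict arg-min selection a cubic term
captures replicate noise in roughly one replicate in nine regardless of the
noise scale. Adjusted R² is available as an alternative criterion. The
residual sum of squares is floored at numerical noise (n·(1e-12·scale)²) so
that interpolating fits of noiseless data compare by parameter count rather
than rounding error. The correlation screen (Pearson or Spearman) uses
pairwise-complete observations, flags cells with fewer than 3 pairs, and
reports Benjamini–Hochberg adjusted p-values alongside raw ones.

## Synthetic data generator

The generator emulates a six-site, four-plot montane gradient (1960–3548 m
evenly spaced) with shrub protocol (species-level litter) at the two lowest
sites and herbaceous protocol (pooled litter) above, and these latent
models:

* biomass shares per plot: symmetric Dirichlet; species green C and N:
  lognormal (σ = 0.2) around site means with linear elevation trends
  (defaults 445/24/1.85 g/kg C/N/P at the lowest site, N rising
  2 g/kg·km⁻¹);
* soil: TN rising 0.5 → 2.4 g/kg over the gradient, TP flat at 0.55 g/kg,
  both with lognormal noise (σ = 0.25), so soil N:P spans roughly 1–5;
* community leaf N:P through the homeostasis law
  y = c·x^(1/H_true)·lognormal(0.09), H_true default 16.34, c anchored so
  the mean community sits at the configured green-leaf N:P (≈13); species
  leaf P is rescaled within a plot so the community ratio equals y exactly.
  The residual σ = 0.09 reproduces a plot-level leaf N:P span of roughly
  10.5–16.5, the magnitude reported for arid montane shrub/steppe
  communities, and keeps the default communities inside the 10–20
  co-limitation band;
* senesced N and P back-solved so the plot's NRE equals a
  Normal(78, 4)% draw and its resorbed N:P equals
  ω·(leaf N:P)^λ·lognormal(0.05), λ default 0.912. ω defaults to the
  anchored value np_ref^(1−λ), which makes resorbed N:P equal green N:P at
  the mean community — the regime where N and P efficiencies are comparable
  — and keeps senesced P positive for any exponent. The NRE draw is
  truncated at the physical cap (95% of the value at which senesced P
  reaches zero); a configuration whose cap falls more than 3 SD below the
  requested NRE mean raises a generation error instead of silently
  distorting the distribution.

Each table draws from its own random stream split deterministically from
the master seed, so identical seeds give byte-identical tables and adding a
table never perturbs another's draws. The truth record stores every latent
(per-plot leaf N:P, NRE and resorbed-ratio targets, back-solved senesced
values) for recovery tests.

What the generator does **not** emulate: spatial autocorrelation between
plots, species shared across sites with correlated traits, within-species
trait plasticity, measurement error on concentrations, seasonal dynamics,
or climate beyond site-constant MAT/MAP columns. Passing recovery tests
therefore demonstrates that the estimators are correct for the stated
statistical models at the stated design size, not that field data of this
kind will satisfy those models.

## Known limitations and trade-offs

* With H_true = 16.34 and the realistic leaf N:P dispersion above, only
  about 2% of the leaf N:P variance is soil-driven, so the N:P homeostasis
  regression on a single 24-plot dataset is significant in only roughly
  half of random seeds — strong homeostasis is intrinsically hard to
  distinguish from no coupling at this design size. Recovery tests
  therefore target H = 4, where detection is robust.
* At the default design (n = 24) the SE of the power-law exponent is
  ≈ 0.10–0.15; λ estimates are unbiased but individual-study values scatter
  accordingly. Calibration and recovery are assessed over hundreds of
  seeded replicates (500 for CI coverage, 200 for detection/recovery
  rates) — sizes chosen so the suite runs in well under a minute per check.
* The NRE:PRE ratio is a plain ratio of percentages, undefined (flagged)
  when PRE ≤ 0.
* The strategy fit uses plot-level points by default; a site-mean option
  exists but with 6 sites the CIs are wide.
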