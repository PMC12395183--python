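# ecostoich

Community-level stoichiometry analysis for gradient studies in plant
ecology: community-weighted leaf C:N:P, nutrient resorption efficiency with
mass-loss correction, the resorption control-strategy test, stoichiometric
homeostasis, N:P nutrient-limitation classification, and polynomial
elevation-trend fitting — plus a synthetic-community generator with known
ground truth so every estimator is testable end to end.

It is aimed at ecologists working with plot-level survey/litter/soil tables
(e.g. from montane or other environmental gradients) who want the standard
community-stoichiometry quantities computed reproducibly from delimited
text files, and at methodologists who want the statistical behaviour of
those quantities (CI calibration, parameter recovery, model selection)
checked against simulations.

## The quantities

For a plot with species biomass proportions wᵢ and leaf concentrations tᵢ
(g/kg), community leaf nutrients are community-weighted means
CWM_t = Σᵢ tᵢ wᵢ (LTC, LTN, LTP), with diversity H′ = −Σ pᵢ ln pᵢ and
evenness E = H′/ln S.

Resorption efficiency with mass-loss correction (MLCF = 0.762 by default):

    NuRE = (1 − senesced/green · MLCF) × 100 %

The resorption control strategy contrasts the resorbed nutrient ratio
`resorbed_NP = (LTN − LTN_s·MLCF)/(LTP − LTP_s·MLCF)` with green-leaf
LTN:LTP through a power law `resorbed_NP = ω·(LTN:LTP)^λ` (log10–log10
OLS) and a linear fit; 95% CIs on both slopes decide between
*stoichiometric control* (both ≈ 1), *nutrient limitation control* (λ ≠ 1),
and *joint regulation*.

Stoichiometric homeostasis fits `lg y = lg c + lg x / H` for paired
soil (x) and plant (y) stoichiometry; H ≥ 4 steady state, 2–4 weak steady,
1.33–2 weak sensitive, < 1.33 sensitive, and a non-significant fit is an
absolute steady state. Leaf N:P limitation uses the Güsewell 10/20 or
Koerselman–Meuleman 14/16 thresholds.

See `docs/methods.md` for assumptions, numerical conventions, and the
generator's statistical model.

## Worked example

```python
from ecostoich import (SimulationConfig, generate_dataset,
                       aggregate_communities, fit_homeostasis)
from ecostoich.resorption import resorption_table, control_strategy

ds = generate_dataset(SimulationConfig(seed=42))   # 6 sites x 4 plots
traits = aggregate_communities(ds.survey, ds.soil)

resorp = resorption_table(ds.survey, ds.litter)
strat = control_strategy(resorp["ratio_NP"], resorp["resorbed_NP"])
print(f"NRE {resorp.NRE.mean():.1f}%  PRE {resorp.PRE.mean():.1f}%")
print(f"lambda = {strat.lambda_hat:.3f} "
      f"(95% CI {strat.lambda_CI[0]:.3f}-{strat.lambda_CI[1]:.3f})")
print(f"linear slope = {strat.linear_slope:.3f}  label: {strat.label}")

h = fit_homeostasis(ds.soil.TN / ds.soil.TP, traits.ratio_NP)
print(f"H = {h.H:.2f}  p = {h.p_value:.4f}  label: {h.label}")
```

prints

    NRE 77.3%  PRE 75.9%
    lambda = 0.959 (95% CI 0.773-1.145)
    linear slope = 0.979  label: stoichiometric control
    H = 8.76  p = 0.0015  label: steady state

Both slope CIs contain 1, so N and P resorption track green-leaf
stoichiometry (stoichiometric control); the community N:P barely responds
to the four-fold soil N:P variation (H ≈ 8.8 with a significant fit:
steady state). With this seed the dataset was generated with λ = 0.912 and
H = 16.34; at 24 plots the exponent is recovered within its CI, while H is
estimated with the wide spread that is intrinsic to strong homeostasis at
this design size (see the limitations section of `docs/methods.md`).

The same pipeline runs from the command line on CSV/TSV inputs:

    ecostoich run-all --simulate --seed 42 --out results/
    ecostoich run-all --config my_study.yaml --out results/

writing `community_traits.csv`, `resorption.csv`, `control_strategy.csv`,
`homeostasis.csv`, `limitation.csv`, `gradient_fits.csv`, `warnings.csv`,
and a JSON run manifest.

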