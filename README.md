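# firetraits

Continental-scale analysis of how plant fire-response strategies relate to
the fire regimes species actually experience. The package is for fire
ecologists and macroecologists who want to (a) estimate, for each species,
the mean fire frequency across its range by overlaying occurrence records
on a gridded burnt-area history, (b) classify species as resprouters and
postfire seeders from long-format trait observations, and (c) model how
the probability of each strategy changes along the fire-frequency
gradient.

## The model

For species *i* with mean fire frequency *F<sub>i</sub>* (fires per
century, averaged over the grid cells its occurrence records fall in over
an observation window of *T* years, assuming a constant event rate), let
*x<sub>i</sub>* = log₁₀ *F<sub>i</sub>*. A binary strategy
*Y<sub>i</sub>* (resprouts / does not) follows a binomial GLM with a
quadratic logit:

logit P(*Y<sub>i</sub>* = 1) = β₀ + β₁ *x<sub>i</sub>* + β₂ *x<sub>i</sub>*² ( + growth-form main effect and interactions )

with treatment coding (herbaceous as reference), so β₀ is the herbaceous
logit at *F* = 1 fire per century. When β₂ < 0 the strategy peaks at
*F*\* = 10^(−β₁ / 2β₂). Model quality is summarised by the Tjur
coefficient of discrimination, and each coefficient is reported with its
Wald 95 % CI and odds ratio e^β. Leaf traits (LMA, leaf N) are modelled by
OLS of the log₁₀ species mean on strategy × growth form, with
estimated-marginal-mean contrasts (Tukey or Bonferroni adjusted).

A comparison estimator of fire frequency fits a Weibull distribution to
the pooled inter-fire intervals of a species' cells by censored maximum
likelihood (closed intervals contribute the density, open window-edge
intervals the survival term) and converts the median fire-return interval,
λ(ln 2)^(1/k), to 100/median fires per century.

Every stage is backed by a synthetic generator — Poisson fire histories on
a rate gradient, block-shaped virtual ranges, trait observations drawn
from logistic-quadratic curves, and labelled occurrence contaminants — so
the whole pipeline is testable by closed-form oracles and parameter
recovery.

## Worked example

```python
from firetraits.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="scratch/readme_example", seed=42, simulate=True,
                     n_species=2000, grid_rows=150, grid_cols=150)
bundle = run_pipeline(cfg)      # simulate -> clean -> firefreq -> classify -> fit
fit = bundle["resprout_fit"]
print(fit.summary().round(3).to_string())
print("n =", fit.nobs, " Tjur R2 =", round(fit.tjur_r2, 3))
print("peak fire frequency:",
      round(fit.peak()["peak_fires_per_century"], 2), "fires/century")
```

prints

```
                coefficient  ci_low  ci_high  odds_ratio  or_ci_low  or_ci_high    p
intercept             0.881   0.752    1.009       2.413      2.122       2.743  0.0
log10_fires           0.565   0.300    0.830       1.759      1.349       2.294  0.0
log10_fires_sq       -1.060  -1.295   -0.825       0.346      0.274       0.438  0.0
n = 2000  Tjur R2 = 0.063
peak fire frequency: 1.85 fires/century
```

The simulation drew each species' resprouting status from a
logistic-quadratic curve with coefficients (0.88, 0.70, −1.17); the fit
recovers them within sampling error. The negative `log10_fires_sq`
coefficient means resprouting probability is hump-shaped in fire
frequency, peaking here at ≈1.9 fires per century; the odds-ratio column
is exactly e^coefficient.

The same stages are available from the shell:

```sh
firetraits run --n-species 2000 --seed 42 --out-dir out/
firetraits clean occurrences.csv --out-dir out/
firetraits fit out/model_table.csv --response resprouter
```

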