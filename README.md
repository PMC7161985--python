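# sdmfuse

Delta-GAM species distribution models for bottom-trawl biomass, climate
ensemble delta-downscaling, and a Bayes-theorem fusion of model projections
with expert climate-vulnerability votes — implemented end to end on a
synthetic analogue of a Northeast-US-shelf study system, so the whole
analysis runs and is testable without restricted survey or climate-model
data.

## Who this is for

Quantitative fisheries ecologists and climate-impact modellers who want to
(a) project species relative biomass under future sea-surface temperatures,
(b) translate those projections into the sensitivity/directional ranks used
by expert climate vulnerability assessments so the two can be compared, and
(c) blend an expert elicitation's multinomial vote data into a fitted SDM.

## The model

For each species and season (spring = MAM, fall = SON), relative biomass at
a location with seasonal SST `t` and depth `d` follows a two-stage delta
(hurdle) GAM:

    stage 1:  logit P(presence)      = a₁ + f₁(t) + g₁(d)
    stage 2:  E[log biomass | pres.] = a₂ + f₂(t) + g₂(d)
    relative biomass B(t, d)         = P(presence) · exp(stage-2 prediction)

with penalized cubic spline smooths (k = 10, shrinkage so either smooth can
drop to ~0 effective degrees of freedom, smoothing parameters by REML).
Future SSTs come from an ensemble of climate-model members, delta-downscaled:
member anomalies relative to each member's own baseline climatology are
added to the *observed* climatology (removing member mean bias), and the
ensemble is summarised by its mean, second-coldest (p5) and second-warmest
(p95) member fields.

Projections are compared with expert ranks via

    SensWeight = Σₖ |Baselineₖ − Futureₖ| / Σₖ Futureₖ      (over grid cells k)

percentile-ranked across species into {low, moderate, high, very high}, and
the season-averaged percent change thresholded at ±25% into
{negative, neutral, positive}.

The fusion step draws n = 1000 candidate stage-2 coefficient vectors
θ ~ MVN(β̂, V̂), scores each by

    log posterior(θ) = log MVN(θ; β̂, V̂)
                     + log Multinomial(sensitivity votes | bin probs(θ))
                     + log Multinomial(directional votes | bin probs(θ))

where the bin probabilities are Normal(F_mn, F_SD) masses (moments of the
candidate's future per-cell projections) between percentiles of its baseline
projections — {0,20,40,60,80,100} mapped symmetrically onto the four
sensitivity bins (tails → very high), {33,67} onto the three directional
bins — and keeps the maximum-a-posteriori candidate as the "combined" model.

## Worked example

```python
from sdmfuse import RunConfig, run_pipeline, summarize_run

cfg = RunConfig(outdir="results/demo", seed=7)
run_pipeline(cfg)          # generate → downscale → fit → validate →
print(summarize_run(cfg))  # project → compare → fuse  (~30 s)
```

prints (numbers from this exact seed):

```
sdmfuse run digest
========================================
species with AUC >= 0.70 in both seasons: 8/8
mean held-out AUC: 0.822; mean correlation: 0.480
spring/p5: mean shelf-wide change +15.2%
spring/mean: mean shelf-wide change +29.6%
spring/p95: mean shelf-wide change +41.4%
fall/p5: mean shelf-wide change -15.1%
fall/mean: mean shelf-wide change -27.3%
fall/p95: mean shelf-wide change -33.9%
sensitivity rank matches: 4/8; directional matches: 7/8
combined vs SDM (mean over models): d_r=+0.0010, d_crmse_norm=-0.0008, d_sd_ratio=+0.0010
```

Reading it: all eight synthetic species clear the AUC ≥ 0.7 inclusion
filter; held-out biomass correlations average 0.48 while the SD ratio
(~0.37 in `validation.csv`) shows predictions are smoother than
observations; cold-adapted species decline (most under the warmest p95
SSTs) while warm-adapted coastal species increase, more strongly in
spring; and the vote-fused MAP model performs essentially identically to
the SDM alone — expected when the fitted model is already well
constrained.

The same stages can be run piecewise as numbered scripts
(`python analysis/01_generate_data.py --outdir results/analysis` …) or via
the CLI (`sdmfuse all --seed 7 --outdir results/demo`); each script prints
a short narrative of what it found and leaves its tables under the run
directory.

## Layout

    src/sdmfuse/      library: synthetic data, climate fields, spline GAM
                      engine, delta GAM, validation, projection,
                      vulnerability comparison, fusion, pipeline, CLI
    analysis/         numbered narrative drivers over the pipeline stages
    tests/            pytest suite (unit, property and acceptance tests)
    scripts/          acceptance script
    docs/methods.md   modelling and design notes
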