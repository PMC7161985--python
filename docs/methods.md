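# Methods and design notes

This note documents the models, the synthetic study system, the numerical
choices, and the places where the design was genuinely open. Everything
quantitative stated here is computed by the test suite or the acceptance
script at run time.

## The study system being emulated

The analysis pattern is that of a temperate continental-shelf ecosystem
sampled by a stratified-random bottom-trawl survey, with species relative
biomass driven by depth and seasonal sea-surface temperature (SST), a
multi-decadal warming trend, an ensemble of climate-model SST projections,
and an independent expert climate-vulnerability elicitation for the same
species. All inputs are synthesized (`sdmfuse.synthetic`):

- **Domain**: a 20×20-cell grid over 10° of longitude and latitude
  (cell-centre coordinates), with a static positive depth field increasing
  smoothly offshore (15–300 m) and mild meridional structure.
- **SST**: monthly fields = latitudinal gradient (−0.8 °C per degree
  north) + seasonal cycle (±6 °C, warmest in August) + linear trend
  (0.03 °C yr⁻¹, the rapid-warming regime of the emulated shelf) + seeded
  smooth spatial noise (SD 0.4 °C). Observed years 1982–2015; seasonal
  values are MAM (spring) and SON (fall) means.
- **Ensemble**: 27 members on a 2×-coarser grid, each the observed-analogue
  baseline climatology plus a member bias (mean +1.5 °C — the analogue of
  the warm bias that motivates delta downscaling — SD 0.75 °C), a member
  trend (0.035 ± 0.008 °C yr⁻¹), smooth noise (SD 0.3 °C), and six missing
  coastal cells to exercise gap-filling. Years 1982–2055.
- **Survey**: per season and year, 300 stations allocated to 12 latitudinal
  strata by a multinomial draw proportional to stratum area, with a
  two-station minimum enforced by reassigning stations from the largest
  allocations. Species presence is Bernoulli(max presence probability ×
  product of Gaussian kernels in SST and depth); positive biomass is
  lognormal with median equal to the same response surface; absences record
  zero biomass. Bimodal thermal responses are available by mixing two SST
  kernels.
- **Expert votes**: 12 sensitivity attributes × 25 votes (5 experts × 5
  tallies) over four bins, and 12 directional votes (3 experts × 4 tallies)
  over three bins. Vote probabilities are a Dirichlet perturbation of a
  one-hot vector on the species' true bin (α = concentration·one-hot + ½,
  default concentration 8) — one tunable dispersion knob; the elicitation's
  real vote-dispersion behaviour is unknown, so this is a modelling choice.
  Overall expert ranks are consumed as given (the species' true ranks); the
  elicitation's internal logic rules are out of scope.

What the generator deliberately does **not** emulate: realistic bathymetry
or stratification by habitat type, gear catchability and vessel calibration,
species interactions, spatial autocorrelation of catches beyond the smooth
environmental response, and inter-annual recruitment variability. Passing
tests therefore demonstrate that the *methods* behave correctly under their
own assumptions, not that the ecological conclusions transfer to real
survey data.

## Delta GAM

Stage 1 is a binomial-logit penalized GAM of presence/absence on
s(SST) + s(depth); stage 2 is a Gaussian GAM of log positive biomass on the
same smooths over positive tows only (minimum 30 tows and 15 presences;
single-class responses are refused). Overall prediction is
P(presence)·exp(stage-2 prediction) — the direct exponentiation, with no
lognormal retransformation (smearing) correction, so conditional-mean
biomass is underestimated by the factor exp(σ²/2); comparisons are
consistent because both baseline and future projections carry the bias.

**Spline engine** (`sdmfuse.splines`, `sdmfuse.gam`): cubic B-spline bases
with k = 10 functions, interior knots at covariate quantiles, exact
integrated-squared-second-derivative penalties (2-point Gauss–Legendre per
knot span, exact for the piecewise-linear second derivative), and a
sum-to-zero constraint absorbed by a Householder rotation. Shrinkage uses a
single smoothing parameter per term with the penalty's null (linear) space
folded in at one tenth of the smallest strictly positive penalty eigenvalue
— small enough not to distort ordinary smoothing, while a very large
smoothing parameter can still remove the term entirely (below 1 effective
degree of freedom). Smoothing parameters minimize the REML criterion
(Laplace-approximate for the binomial family; GCV selectable by config) by
a bounded Powell search over log λ ∈ [−10, 28] from two starts (an
unpenalized-ish and a heavily penalized one), because the criterion surface
can hold a single start in an under-smoothed basin. The reported
coefficient covariance is the Bayesian posterior covariance
(X'WX + S_λ)⁻¹·φ̂ — the quantity the fusion's candidate sampling requires.
Tests cross-check predictions against hand-built design rows, statsmodels
GLM in the unpenalized limit, and an mgcv REML fit on common data.

Predictions at covariate values outside the training range are held at the
boundary value (constant extrapolation) and flagged with a warning; this
keeps exp(·) of unconstrained spline tails from exploding in future
scenarios and is the conservative choice for projection.

## Climate fields

Delta downscaling follows the standard anomaly method: per member, monthly
anomalies from the member's own 1982–2011 climatology are bilinearly
regridded to the observed grid and added to the observed climatology, which
removes member mean bias by construction. Member fields are gap-filled
*before* anomaly computation (the alternative ordering is a one-line change
in the pipeline stage); coastal gap-filling replaces each missing in-domain
cell by the mean of its non-missing 8-neighbours (queen adjacency — the
reading of "all bordering cells" that maximizes fillable cells), iterated
until convergence, so multi-cell gaps fill outside-in; isolated regions are
reported unfillable. Ensemble percentiles are order statistics — p5/p95 are
the second-coldest and second-warmest of the 27 members — not interpolated
quantiles. Cells the bilinear regridding cannot reach (outside the coarse
hull) are treated as coastal-fillable.

## Validation

AUC is the Mann–Whitney statistic (ties ½). Taylor statistics use
population (divide-by-n) standard deviations, the centered RMSE, and the
SD ratio; normalized forms divide by SD(obs) so species share one diagram.
The law-of-cosines identity crmse² = sd_p² + sd_o² − 2·sd_p·sd_o·r is a
test invariant. Validation pools all held-out tows (years after the 2011
split) shelf-wide. Species enter downstream analyses only with AUC ≥ 0.7
in both seasons.

## Projection and ranking

Shelf-wide percent change is the percent change of domain-total biomass
(per-cell-mean is kept as an alternative output, and the two are linked by
an exact cell-count-weighted identity used in tests); regional summaries
(a north/south split at 41.5° N as the two-subregion analogue) average
per-cell percent changes; baseline-zero cells are flagged and excluded from
per-cell means. Grid cells are equally weighted (cell areas vary by < 15%
across the domain's latitudes; an area-weighting flag would be the first
addition for a wider domain). The +500% reporting cap applies only to
displayed/capped columns, never to SensWeight or fusion inputs. Percentile
ranks use (rank−1)/(N−1)·100 with ties sharing the minimum percentile;
−25% and +25% fall in the neutral directional bin (closed interval).

## Fusion

Candidates θ ~ MVN(β̂₂, V̂₂) (Cholesky after escalating jitter if needed;
an exactly-zero covariance degenerates to the mean). The stage-1 model
never varies. Per candidate, F_mn and F_SD are the mean and SD of its
future per-cell projections, and the baseline percentiles are its own
baseline per-cell projections (both per candidate across grid cells; the
per-cell-across-candidates reading would confound parameter uncertainty
with spatial structure and is rejected). Percentiles interpolate linearly
between order statistics; p0/p100 are the sample min/max. The six
sensitivity percentiles induce seven Normal(F_mn, F_SD) interval masses
mapped symmetrically onto four bins (beyond min/max → very high, outer
flanks → high, inner flanks → moderate, centre → low); the construction
telescopes, so the four probabilities sum to one exactly. Sensitivity votes
enter as the four attribute-summed totals (Σ = 300). The posterior adds log
prior and the two multinomial log likelihoods (a bin holding votes at zero
probability scores −∞); a config flag exposes the literal
"multiply-the-logs" reading for comparison only, since it is
sign-pathological. Selection is the unnormalised argmax, ties to the lowest
index. Across a species' two seasonal fits the default pairs same-index
draws and sums seasonal log likelihoods and priors into one joint MAP
(per-season selection is a config switch).

**Identifiability regimes.** The bin-probability map is invariant to any
common rescaling of a candidate's projections: a stage-2 intercept shift
rescales baseline percentiles, F_mn and F_SD by the same factor and cancels
in the Normal CDF. Since the intercept direction carries most of a fitted
covariance's variance, candidates from a well-estimated fit differ in bin
probabilities by ~0.01 — below the sampling noise of a 312-vote sheet
(~0.025) — and the votes cannot single out a candidate; the combined model
then tracks the SDM, which is exactly the behaviour the full pipeline
shows. The behavioural tests therefore probe three distinct regimes: vote
self-consistency recovery on a fit whose coefficient uncertainty is
concentrated in response-shape directions (where candidates are
distinguishable, using expected rather than sampled vote counts);
directional pull on a truly declining species with a data-limited fit
(likelihood strong enough to rerank candidates, but not so strong that the
300 "very high" votes — which reward *both* tails — overwhelm the 12
directional votes); and prior dominance under evenly split votes on the
well-estimated fit. No single fit exhibits all three behaviours.

Combined-vs-SDM evaluation reuses the validation statistics on identical
held-out tows; AUC is shared by construction (stage 1 fixed). The
certainty-stratified summary bins SDM certainty by AUC ∈ [0.7, 1] in four
equal-width bins and expert certainty by the modal vote share
(< 0.40 low, < 0.55 moderate, < 0.75 high, else very high).

## Pipeline

One master seed fans out to fixed per-stage RNG streams
(`default_rng([seed, k])`), so reruns are byte-identical; CSVs are written
with a fixed float format. Stages communicate only through files under the
run directory (survey and vote CSVs, NetCDF fields via xarray's NetCDF-3
backend, fits as JSON with β and V), so any stage can be rerun from its
predecessors' artifacts and the digest is rebuilt from artifacts alone.
Default problem sizes — 20×20 grid, 8 species, 34 survey years × 2 seasons
× 300 stations, 27 members, 1000 candidates per species-season — run the
full pipeline in about half a minute on one CPU; the test suite scales its
private fixtures down (fewer years, 9 members) but keeps these defaults for
the end-to-end determinism check. The match/mismatch random forest
(500 trees, OOB error, permutation importance, per-level marginal mismatch
probabilities) needs at least 20 sufficiently certain species and therefore
does not run in the 8-species default pipeline; it is exercised on
50–60-species synthetic panels in the tests.

## Known limitations

- Constant (clamped) extrapolation beyond the training covariate range
  flattens responses under strong warming; mgcv would extrapolate linearly.
- No smearing correction for the lognormal back-transform (matches the
  projection convention, biases absolute biomass low).
- The overall-prediction convention is P(presence)·exp(log biomass)
  throughout; the alternative p·logB convention that sometimes appears in
  validation contexts is not used.
- Equal cell weights in domain summaries; no area weighting.
- The fusion's vote likelihood is nearly scale-invariant (see above), so
  for well-estimated models the expert data cannot move the projections
  much — a structural property of the method, not an implementation limit.
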