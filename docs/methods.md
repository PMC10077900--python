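# Methods

`nullcomm` implements an observational inference framework for asking
whether a focal guild of plants — root hemiparasites are the motivating
case — is associated with more even or more species-rich plant
communities than equally-rare non-guild plants are. The framework has
three statistical ingredients: per-plot community metrics, a
rank-abundance-matched empirical null, and Gaussian linear mixed
models. A synthetic-data generator reproduces the statistical structure
of a continental vegetation survey so that every stage is testable with
known ground truth.

## Community metrics

For each plot and growth form (all / herbaceous / woody, classified
from growth-habit labels; hemiparasites always count as herbaceous),
the package computes richness S, summed percentage cover A, and Pielou
evenness E = H / ln S with H = −Σ pᵢ ln pᵢ over relative covers.
Natural logarithms throughout. E is undefined for S < 2; such plots
keep their richness and drop out of evenness models only, so evenness
and richness sample sizes differ. Covers of one species recorded in
several strata are summed into a single (plot, species) value before
any metric — the analysis has one abundance per taxon per plot and no
downstream use of stratum. Cover is not capped at 100% (strata
overlap).

Model-scale transforms: ln for richness (plots with S = 0 cannot be
transformed and are dropped from that model, with the count reported),
logit for evenness. Exactly even plots (E = 1, possible with tied
covers) are clamped into (ε, 1−ε) before the logit, ε = 1e−6 by
default and configurable; clamping (rather than exclusion) keeps those
plots in the model and is flagged here because boundary handling is a
genuine free choice.

## Rank-matched null sets

Global abundance is a species' cover summed over all retained plots;
ranking by descending abundance (ties broken lexicographically, for
determinism) gives the rank-abundance curve. The guild's ranks span a
window [min, max]; each null replicate draws, uniformly without
replacement, an equally sized set of non-guild species whose ranks fall
in that window. "Equally sized" means the number of guild species
actually observed in the data: catalog members recorded in no plot
carry no cover and must not inflate the matched set, which would bias
the null coefficients tight relative to the guild's. Uniform (not occupancy-stratified) sampling is the
default because it is what the original analysis did; a rank-window
recomputation is applied after any guild subsetting (top-k, rank band,
genus), mirroring subset reruns. Each replicate draws a fresh set from
its own seed substream spawned from the master seed, so ensembles are
reproducible and order-independent.

## Spatial pairing (presence contrast)

Within each Level IV ecoregion, every plot's nearest neighbour is found
by great-circle (haversine) distance on a sphere of radius 6371.0088 km.
Only mutual nearest-neighbour pairs are kept, in a single pass;
non-mutual plots, pairs at identical coordinates (distance 0), and
singleton ecoregions are discarded with reasons reported.
Nearest-neighbour ties break lexicographically by plot id so that
gridded data pair deterministically. Pairing is unconditional on guild
presence, as the source procedure describes.

## Mixed models and inference

Presence models: transformed response ~ presence (plot holds ≥ 1 set
member), random intercepts for pair identity and survey year.
Abundance models: restricted to plots holding ≥ 1 set member,
transformed response ~ ln(summed set cover), random intercepts for
year, park and ecoregion. Intercept-only random effects; no random
slopes. Grouping factors with a single level are dropped with a
warning; a predictor with no contrast raises a constant-predictor
error.

Fitting is profiled REML (reported coefficients, variance components)
with ML refits of the full and intercept-only models for the AIC screen
— REML criteria are not comparable across fixed-effect structures.
ΔAIC = AIC(reduced) − AIC(full), with ΔAIC ≥ 2 read as support for the
focal term; both fits must use identical observations (enforced).
Variance explained is partitioned in the Gaussian variance-component
form: marginal R² = v_f / (v_f + Σ v_random + v_resid) with v_f the
variance of the fixed-effect predictions; conditional R² adds the
random-intercept variances to the numerator.

The fitter itself (`nullcomm.lmm`) is an in-house profiled
REML/ML implementation for crossed random intercepts: the grouping
factor with the most levels is absorbed analytically (its contribution
to V is block-diagonal rank-one, with a closed-form inverse) and the
remaining factors enter through a small Woodbury system, so one
objective evaluation costs O(L₀ q²) on precomputed cross-products.
Variance ratios are optimised on the standard-deviation scale with
L-BFGS-B bounded at zero; boundary estimates (zero variance) are
reached exactly, which is why the model collapses to OLS on data with
no group structure. The implementation is validated against statsmodels
MixedLM (coefficients to ~1e−6, log-likelihood to ~1e−8) in the test
suite; the speed (≈3 ms per warm-started fit on a few hundred
observations) is what makes 1,000-realisation calibration studies with
50 null replicates each feasible on one CPU.

Significance is empirical and one-sided, exactly as the procedure words
it: p = #{null β₁ ≥ observed β₁} / n_converged. Replicates that fail to
fit or converge are dropped and counted, and p uses the converged
denominator; when no null reaches the observed value the report notes
the resolution bound p < 1/n. A two-sided option exists but is off by
default. Every null replicate runs through literally the same code path
as the observed fit — a shared pilot fit supplies the optimizer start
for the observed refit and all null refits, and a test injects the
guild itself as a null set and asserts bit-identical output.

## The synthetic generator

The generator emulates: a heavy-tailed global SAD over (by default)
2,000 species; hierarchical grouping 20 ecoregions × 2 parks × 50 plots
(= 2,000 plots) with group-level intercepts; survey years 1997–2012
with a year intercept; a 78-taxon herbaceous focal guild occupying ~13%
of plots across a wide rank window (10th–97th percentile of ranks); an
independently generated woody stratum; and a tunable evenness effect
with zero richness effect. These sizes are the package's default study
conditions; the effect-recovery study scales to 20 × 4 × 160 = 12,800
plots so that ~1,600 plots hold the guild at the same occupancy.

Mechanism (core–satellite). Each flora splits at an occupancy knee
(rank ≤ 10% of species) into a common core and a satellite pool. Core
species present in a plot receive dominance-decay covers — weight
mᵢ(1−δ)^(k−1) at local commonness position k, with lognormal size
scores mᵢ (σ = 0.7) — normalised to a lognormal plot total (~70%
herbaceous). Satellite species occur rarely (occupancy a shallow
power-law in rank, its level anchored so a guild-sized rank-window set
is expected to occupy the 13% target) and their cover-given-presence is
an iid lognormal draw (mean 0.1%, σ_ln = 0.8) independent of rank and
of the plot's dominance. The evenness metric is computed over all
species, core and satellite.

Dominance is causal on evenness:

    logit(δ_plot) = logit(δ₀) + u_eco + u_park + u_year + e
                    − γ · [ln(1 + F/h) − ln(1 + c₀/h)]

with F the plot's summed focal cover, half-scale h = 0.1% (effect
leverage at realistic sub-percent guild covers) and centring constant
c₀ = 0.1% (so γ spreads dominance around δ₀ = 0.2 instead of shifting
its mean into the saturated, ceiling region of the evenness response).
Group intercept sds default to 0.30 / 0.20 / 0.10 (ecoregion / park /
year) and plot-level residual 0.20 on the logit-dominance scale; park
suitability multipliers on occupancy are drawn independently per
stratum and per pool, so focal cover is uncoupled from core richness
and from the woody stratum even at park level. Richness is untouched by
γ; a separate knob (`effect_richness`) adds species with focal cover
for sensitivity studies and defaults to zero.

Two properties of this construction carry the statistical weight.
First, at γ = 0 focal cover is causally independent of the dominance
series, so its only link to measured evenness is the guild's own small
contribution to the metric (a within-ecoregion correlation of ~0.03,
which is why the decorrelation check uses the mean over several
realisations — a single 5,000-plot realisation estimates r with
Monte-Carlo sd ~0.04). Second, the guild is exchangeable with
uniformly drawn rank-window null sets: guild and null species are
satellites with identical cover-given-presence distributions, matched
expected plot occupancy, and — by default — uniformly placed guild
ranks. This last point is a deliberate design choice: with guild ranks
clustered toward the common end of the window (the pattern real
hemiparasites show, available via `focal_rank_concentration`), uniform
null draws are a biased comparison — the method's known rank-weighting
caveat — and the type-I error of the empirical p leaves the calibrated
range. The default conditions are therefore the exchangeable ones, and
the clustering knob exists to reproduce the biased regime on purpose.

The generator's true coefficient (`true_effect`) is the large-sample
regression slope of logit herbaceous evenness on ln focal cover with
all group and residual noise switched off, computed on ~12,000
noiseless plots; it has no closed form because the logit-evenness
response to δ runs through the geometric series and the realised
community composition. It includes the guild's own metric contribution
(hence slightly positive even at γ = 0, ~0.02) and is independent of
the dataset seed. At the defaults, γ = 0.8 gives a truth of ≈ 0.19 on
the logit-evenness scale at the effect-study size.

What the generator does not emulate: spatial autocorrelation of species
composition (coordinates are independent jitter around park centres),
phylogenetic structure, host–parasite dynamics at the individual level,
observer and cover-class measurement error, and real surveys' uneven
plot areas (all plots are generated at the retained area, 400 m²).
Passing tests therefore show the inference machinery is correct and
calibrated under the stated structure, not that the ecological result
of any real survey is reproduced.

## Numerical and procedural details

- Tolerances: REML/ML optimisation ftol 1e−7 on the deviance, bounds
  [0, 1e4] on sd ratios; evenness oracle agreement asserted to 1e−12;
  logit clamp ε = 1e−6.
- Tie-breaks: abundance ties by species id; nearest-neighbour ties by
  plot id; both documented and deterministic.
- Degenerate inputs: empty focal sets, unknown fixture names, single
  survivor filters, singleton grouping factors, constant predictors and
  empty null ensembles all raise typed errors with context.
- Determinism: one master seed per run; per-analysis and per-replicate
  substreams via `numpy.random.SeedSequence.spawn`; rerunning a config
  reproduces every artifact byte-for-byte.
- Problem sizes used by the shipped studies: metric and pairing oracles
  at ≤ 300 plots × 100 instances; null calibration at 1,000 generator
  realisations × 50 replicates (2,000 plots each); effect recovery at
  100 realisations of 12,800 plots. All run on a single CPU. With 50
  null replicates the exchangeable expectation of P(p ≤ 0.05) is
  3/51 ≈ 5.9% (the rank of the observed coefficient is uniform over 51
  positions), not 5% exactly; the calibration band is asserted around
  that discrete reality.

## Known limitations

- The empirical p is one-sided by construction; two-sided inference is
  exposed but unexercised by the shipped studies.
- Woody richness models drop plots with no woody species (ln 0); the
  count is reported but no zero-inflation handling is attempted.
- The fitter covers random intercepts only — by design, matching the
  analysis — and profiles a single residual variance (no
  heteroscedasticity).
- Presence models with many thousands of pairs are the slowest path
  (the pair factor is absorbed analytically, but the remaining Woodbury
  system still grows with the year count only — cost is linear in n).
- `true_effect` is itself a Monte-Carlo quantity (large-sample fit);
  its residual wobble is well under the ±25% recovery band it anchors.
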