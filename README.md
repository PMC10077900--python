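# nullcomm

Rank-abundance-matched null models for asking whether a focal guild of
plants is associated with more even or more species-rich communities
than equally-rare plants are.

## The problem

Root hemiparasitic plants (Castilleja, Pedicularis, Krameria,
Comandra, ...) photosynthesise but also tap the roots of neighbouring
plants, preferentially the belowground dominants. Experiments show they
can suppress dominants and release subordinate species, flattening the
community — but most such evidence comes from manipulations of a few
taxa in grasslands. In a large observational vegetation survey one can
ask whether that signature is visible at scale: are plots where
hemiparasites are present, or abundant, more even or more species-rich?

The statistical trap is that hemiparasites are uncommon. Uncommon
plants of *any* kind may associate with even or rich communities simply
because of where they sit on the rank-abundance curve. `nullcomm`
implements the defence against that trap: every analysis run for the
guild is rerun, identically, for many random sets of non-guild species
drawn from the same window of the global rank-abundance curve, and
significance is the proportion of those null coefficients at least as
large as the guild's.

## What it computes

For a plot × species cover table, a species-attributes table, and a
plot-metadata table (three CSVs):

- **Metrics** — per plot and growth form (all / herbaceous / woody):
  richness S, summed cover A, and Pielou evenness E = H/ln S
  (undefined for S < 2). Models use ln S and logit E.
- **Presence contrast** — mutual-nearest-neighbour plot pairs within
  Level IV ecoregions (haversine distance, single pass, zero-distance
  pairs discarded); LMM of each response on guild presence with pair
  and year random intercepts.
- **Abundance models** — on plots holding the guild: LMM of each
  response on ln(summed guild cover) with year, park and ecoregion
  random intercepts; the guild term is screened by ΔAIC =
  AIC(reduced) − AIC(full) under ML refits, with ΔAIC ≥ 2 as support.
- **Empirical null** — n (default 1000) rank-matched null species
  sets, each pushed through the identical modelling path; one-sided
  empirical p = #{β_null ≥ β_observed}/n; marginal and conditional R²
  in the Gaussian variance-partition form.
- **Synthetic data** — a generator with the survey's statistical
  structure (heavy-tailed SAD, ecoregion > park > plot intercepts,
  year effects, a 78-taxon guild on 13% of plots) and a *known,
  tunable* evenness effect γ, whose ground-truth coefficient
  `true_effect()` anchors recovery tests.

The mixed models are fitted by an in-house profiled REML/ML routine for
crossed random intercepts (validated against statsmodels MixedLM, ~30×
faster), which is what makes 1,000-realisation calibration studies
practical on one CPU. See `docs/methods.md` for the model, the
generator mechanism, and every numerical choice.

## Worked example

Run the whole pipeline on a synthetic survey with a known positive
evenness effect (γ = 0.8, generator truth β₁ ≈ 0.19):

```python
import yaml
from nullcomm.pipeline import run

config = {
    "seed": 1,
    "output_dir": "out",
    "synthetic": {"effect_evenness": 0.8,
                  "parks_per_ecoregion": 4, "plots_per_park": 160},
    "analyses": [
        {"name": "abundance", "kind": "abundance",
         "focal": {"guild": True}, "n_replicates": 200},
    ],
}
open("config.yaml", "w").write(yaml.safe_dump(config))
run("config.yaml")
```

or equivalently `nullcomm run -c config.yaml`. The artifact directory
holds `metrics.csv`, `rank_abundance.csv`, `results.csv`,
`null_coefficients.csv` and a run log with all seeds. With this seed,
`results.csv` reads (abridged):

| response | growth form | n | β₁ | ΔAIC | empirical p |
|---|---|---|---|---|---|
| evenness | herbaceous | 1682 | 0.1906 | 105.7 | 0.000 (p < 0.005) |
| evenness | woody      | 1682 | −0.0098 | −1.29 | 0.82 |
| richness | herbaceous | 1682 | 0.0212 | 2.97 | 0.045 |

Read: across the 1,682 plots holding the guild, each unit of ln guild
cover raises logit herbaceous evenness by 0.19 — matching the
generator's truth of 0.186 — and the AIC screen is decisive
(ΔAIC ≈ 106), while none of the 200 rank-matched null sets reached the
guild's coefficient (p < 1/200). The woody stratum, causally untouched
by construction, shows nothing. Herbaceous richness, whose true effect
is zero, lands this seed at the 5% boundary (ΔAIC 2.97, p = 0.045) —
a useful reminder that single borderline screens are exactly what the
null ensemble is there to contextualise.

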