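# foramsize

Macroecology of intraspecific shell size in planktonic foraminifera —
unicellular marine zooplankton whose calcite shells accumulate in
seafloor sediments.  A recurring claim in this field (the
"optimum-size hypothesis") is that a species grows largest where
conditions are optimal, e.g. at its thermal optimum or where it is most
abundant.  Testing the claim at biogeographical scale requires
population-level size statistics that survive the quirks of
hand-picked museum collections, environmental covariates matched to
georeferenced sediment samples, and a disciplined multimodel
comparison.  `foramsize` implements that pipeline end to end, together
with a seeded synthetic-data generator so every stage runs and is
testable with no external downloads.

## What it computes

**Population size statistics.** Individual shell cross-sectional areas
(µm²) are natural-log transformed and summarized per species × site
population by five metrics: mean, median, 75th percentile, 95th
percentile (P95) and maximum.  Quantiles interpolate linearly between
order statistics (R's default type 7).

**Collector-bias audit.** A hand-picked collection is compared with a
resampled bulk-sediment baseline over the populations present in both.
For each metric the residual from the 1:1 line,
r = metric(collection) − metric(baseline), is computed per paired
population; metrics are ranked by mean squared error (MSE) of those
residuals.  The argmin-MSE metric — typically an upper quantile, which
is less outlier-sensitive than the maximum and less truncation-
sensitive than the mean — becomes the response variable of the
analysis.

**Geodesic covariate matching.** Each site is matched to mean annual
sea-surface temperature (SST, °C) and net primary productivity
(NPP, mg C m⁻² day⁻¹) at the nearest grid node, and to species
relative abundances from an assemblage compilation both at the nearest
record and as the per-species median over all records within a 300 km
radius (the maximum postmortem drift of settling shells).  Distances
are WGS-84 ellipsoidal geodesics (Vincenty's inverse iteration, with a
numerical boundary-value solver near the antipode), implemented and
cross-checked in-package.

**AICc multimodel inference.** Per species, the log-P95 response is fit
by Gaussian maximum likelihood to ten candidate models in SST, NPP and
relative abundance:

    null, sst, sst2, pp, abund, sst+pp, sst+abund, sst:pp, sst2+pp, sst2:pp

where `sst2` adds SST², interaction labels include their main effects,
and each model's parameter count k counts the residual variance
(so df runs 2…6).  Models are compared by

    AICc = −2 logL + 2k + 2k(k+1)/(n−k−1),

with Akaike weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2) over the fitted
set, adjusted R², and an "equally plausible" set defined by
ΔAICc < 2 (strict).  A random-intercept (species) linear mixed model,
fit by ML, provides a χ²₁ likelihood-ratio test of the abundance
effect across species.

**Synthetic data.** The generator draws tropical/subtropical sites
(±40° latitude), a zonal SST field, NPP correlated with SST
(target Pearson r = 0.4), Gaussian thermal niches producing relative
abundances, lognormal individual sizes whose population P95 responds
linearly/quadratically to SST and NPP, and a logistic size-selective
collector retention applied to an independently drawn collector pool.
One root seed fans out into per-stage PCG64 streams, so outputs are
byte-identical under a fixed seed.

## Worked example

Simulate the default study system (9 species, 50 sites, 40 measured
individuals per population) and run every stage:

```
$ foramsize run-all --sim-config config.yaml --seed 42 --outdir demo
foramsize pipeline report
==========================

bias audit over 450 paired populations:
    mean: MSE 0.0851  mean residual +0.2694
  median: MSE 0.0890  mean residual +0.2680
     p75: MSE 0.0727  mean residual +0.2291
     p95: MSE 0.0768  mean residual +0.1999
     max: MSE 0.1604  mean residual +0.2412
  selected metric: p75

response variable: log p75 of shell area per population
populations analyzed: 450

species_00: best sst (AICc -88.62, R2_adj 0.68); plausible: sst, sst+abund, sst+pp, sst2
species_01: best sst (AICc -84.88, R2_adj 0.73); plausible: sst, sst+abund, sst+pp
species_02: best abund (AICc -61.71, R2_adj 0.63); plausible: abund
...
mixed-model abundance LRT: abundance effect +0.0078, chi2(1) = 0.00, p = 0.949
```

Reading the report: every metric's mean residual is positive — the
simulated collector is biased toward large specimens — and the upper
quantiles transfer most faithfully between collections (lowest MSE),
while the maximum transfers worst.  The generator gave each species a
pure linear SST effect on size, and SST-containing models dominate the
plausible sets; `abund` sometimes stands in for SST because abundance
is itself a (Gaussian) function of SST through the thermal niche —
exactly the confounding the multimodel comparison is meant to expose.
The mixed-model test correctly finds no abundance effect on size
beyond that confound.  The output directory holds every intermediate
table (summaries, audit, matched covariates, per-species AICc tables,
plausible sets) plus a `manifest.json` recording parameters, seed,
per-stage row counts and every dropped population.

Other subcommands: `simulate`, `audit-bias`, `match`, `select-models`,
and `sensitivity` (base vs filtered rerun with a per-species diff of
plausible sets).

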