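# paimpact

Estimation of protected-area (PA) effectiveness at reducing forest loss on
gridded landscapes, with explicit treatment of the two things that most
often distort such estimates: confounded PA siting and spatial
autocorrelation in loss rates.

The package implements an end-to-end, fully reproducible pipeline:

1. **Synthetic landscapes** (`paimpact.synthetic_landscape`) — Gaussian
   random field covariates (exponential covariance), contiguous Voronoi
   region/municipality tessellations, logistic PA siting biased by
   covariates (with optional spatial clumping and regional heterogeneity),
   forest-loss outcomes with a known protection effect plus spatially
   autocorrelated noise, and MCAR missingness. Ground truth is recorded
   for parameter-recovery tests.
2. **Forest change** (`paimpact.forest_change`) — temporal gap-filling of
   missing classifications (a missing year becomes forest/nonforest only
   when both temporal neighbors agree; single pass; endpoints untouched),
   block aggregation of fine rasters to forest fractions, net-loss tables
   (gain kept as negative loss), and group summaries with 95% CIs.
3. **Matching** (`paimpact.matching`) — logistic propensity scores,
   greedy 1:1 nearest-neighbor matching without replacement under a
   0.25-SD caliper, plus the three regional procedures: *subsetting*
   (partition national pairs), *exact subsetting* (national scores,
   controls restricted to the treated cell's region) and *submatching*
   (independent fit-and-match per region).
4. **Balance** (`paimpact.balance`) — normalized differences
   (100·(m̄ₜ−m̄꜀)/√((s²ₜ+s²꜀)/2)), dummy-by-dummy for categoricals, with
   the |ND| > 25% imbalance flag.
5. **Autocorrelation** (`paimpact.autocorrelation`) — distance-band
   Moran's I, permutation-envelope correlograms on residual subsamples,
   and the first non-significant distance.
6. **Spatial models** (`paimpact.spatial_models`) — four outcome models on
   matched data: (1) Gaussian mixed model with crossed municipality and
   pair random intercepts (profiled REML, implemented in
   `paimpact.lmm`); (2) model 1 + mean neighborhood loss within one
   buffer; (3) two buffers; (4) an ML spatial error model with
   row-standardized distance-band weights on a subsample. Buffer radii
   are selected iteratively: radius = (first non-significant correlogram
   distance of the previous model's residuals) − 5 km.
7. **Effectiveness** (`paimpact.effectiveness`) — national / regional /
   per-PA / per-category loss contrasts, percent reduction
   (100·(control−PA)/control), and model coefficients in one report.

## CLI

Every stage is exposed under the `pa-impact` entry point; `run` executes
the whole pipeline into an output directory with a hash manifest, and a
rerun with the same master seed reproduces every CSV bitwise:

```sh
pa-impact run --grid 60 --seed 7 --out-dir runs/demo
pa-impact simulate --seed 1 --out landscape.csv
pa-impact match --landscape landscape.csv --procedure submatching --out pairs.csv
pa-impact balance --landscape landscape.csv --pairs pairs.csv --out balance.csv
pa-impact fit --landscape landscape.csv --pairs pairs.csv --model 3 --buffers 30,5 --out fit.csv
pa-impact correlogram --residuals fit.residuals.csv --landscape landscape.csv --out corr.csv
```

## Acceptance

`tests/test_acceptance.py` holds one test per acceptance criterion
(matching/Moran's-I/buffer oracle equivalence, balance recovery and the
submatching ≥ exact-subsetting ≥ subsetting ordering, parameter recovery,
type-I inflation of the uncorrected model, residual-autocorrelation
ordering across models, gap-fill worked examples, and the buffer-selection
rule). The underlying experiments live in `paimpact.experiments`.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The script re-runs the property experiments from scratch (logging their
statistics to stderr) and writes the target JSON; no numeric headline
targets are defined for this artifact, so the JSON object is empty.
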