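# ecoturnover

Temporal turnover analysis for assemblage time series.

Long-running community monitoring programmes — the motivating system is a
three-decade series of estuarine fishes sampled at a power-station intake —
pose two linked questions:

1. **Do species fluctuate asynchronously?**  If species rise and fall
   independently around their mean abundances, aggregate assemblage
   properties can stay stable while individual populations churn (the
   portfolio/insurance view of diversity).
2. **Which turnover regimes reproduce the observed assemblage?**  Writing
   each species' abundance as an AR(1) process
   `Y_t = α·Y_{t−1} + Z_t` with `Z_t ~ N(0, σ_i)` (σ_i the species'
   empirical s.d., output recentred on its empirical mean), how does the
   within-species year-to-year autocorrelation α shape annual diversity
   and year-to-year composition change?

`ecoturnover` implements the full workflow for both questions:

- **Metrics** — Hill diversity numbers per year (`N0` richness,
  `N1 = exp(Shannon)`, `N2 = 1/Simpson`, `N∞ = ΣN/max N`, the reciprocal
  Berger–Parker dominance) and identity-tracking turnover between
  consecutive years (mean rank shift with mid-rank ties over the union of
  present species, and Bray–Curtis dissimilarity `Σ|x−y|/Σ(x+y)`).
- **Asynchrony test** — median pairwise Pearson correlation across years
  versus a null built by independently shuffling each species' abundances
  among years (1000 replicates by default).
- **Turnover simulator** — the AR(1) model above, run 50 years with the
  last 30 kept, swept over α from −1 to +1 in steps of 0.05 with 1000
  replicates per α.
- **Envelope comparison** — per-α predicted metric means against 95%
  confidence limits built from the observed annual values, plus OLS trend
  fits of each annual metric series.
- **Synthetic data** — a generator that emulates the study system
  (81 species, 30 years, 15 ever-present core species holding ≥98% of
  abundance, flickering occasional species, generating autocorrelation
  0.5) with full ground truth, so the whole pipeline is testable without
  the original (undeposited) monitoring data.

## Worked example

```python
from ecoturnover import (
    SyntheticConfig, generate_assemblage, select_core, asynchrony_test,
)

matrix, truth = generate_assemblage(SyntheticConfig(seed=1))
report = asynchrony_test(select_core(matrix), n_replicates=1000, seed=1)
print(f"observed median r = {report.observed_median_r:+.4f}")
print(f"null 95% interval = [{report.null_q025:+.4f}, {report.null_q975:+.4f}]")
```

prints

```
observed median r = +0.0089
null 95% interval = [-0.0200, +0.0191]
```

The observed median pairwise correlation of the core species sits inside
the shuffle null's 95% interval: no detectable cross-correlation, i.e. the
species fluctuate asynchronously (as they should — this synthetic
assemblage was generated with independent species dynamics).  The
`examples/` directory has one short script per capability: generation,
annual metrics and trends, the asynchrony test, and the α sweep with
envelope comparison; `examples/04_alpha_sweep_envelope.py` reproduces the
characteristic contrast in which diversity metrics match the observed
assemblage over nearly the whole α range while the identity-tracking
metrics match only a narrower band around the generating autocorrelation.

## Command line

```sh
ecoturnover generate --out assemblage.csv --truth truth.json --seed 1
ecoturnover metrics assemblage.csv --out metrics.csv
ecoturnover analyze assemblage.csv --outdir results --seed 1 \
    --n-replicates 200 --alpha-step 0.1
```

`analyze` runs the full workflow for both the entire assemblage and the
core (majority-occupancy) subset and writes `asynchrony.json`,
`trends.csv`, `sweep.csv`, `envelope.json` and a reproducibility
`manifest.json`.

Input format: wide CSV, first column `species`, remaining column headers
consecutive integer years, cells non-negative abundances.

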