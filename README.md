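# bymap

Small-area disease-risk mapping in Python: allocate facility-level
consultation counts to census areas, prepare spatially structured
covariates, fit a Bayesian Poisson regression with paired unstructured
and intrinsic-CAR (BYM) spatial random effects, and turn the posterior
into relative-risk maps, exceedance probabilities and hotspot labels.

Everything runs on synthetic cities with known ground truth, so each
pipeline stage is testable end to end without any external data.

## What's inside

| module | purpose |
| --- | --- |
| `bymap.spatial_lattice` | polygon lattices, queen/rook/knn/distance-band/second-order adjacency, Moran's I with permutation test, GeoJSON / edge-list / matrix-market I/O |
| `bymap.synthetic_city` | Voronoi cities: populations, ICAR-correlated covariates, pollutant stations, tiered health services, Poisson counts from known parameters |
| `bymap.rate_allocation` | service zones (home area + graph neighborhood by complexity tier), population-proportional weights, case allocation, per-100 rates incl. the migrant-service rate |
| `bymap.covariate_prep` | IDW interpolation of station PM10, per-area averages, quintile codes, VIF screening |
| `bymap.bym_inference` | the hierarchical Poisson/BYM model with logGamma hyperpriors, fitted by a built-in NUTS sampler (mode-initialised, Laplace-preconditioned); DIC, split-R-hat, spatial variance fraction |
| `bymap.risk_mapping` | per-area relative risk `exp(u_i + st_i)`, Pr(RR > 1.5), high-high hotspot / low-low coldspot labels |
| `bymap.model_selection` | DIC comparison of candidate priors/adjacencies, backward elimination of non-credible covariates with combination re-addition |
| `bymap.cli` | `bymap` command: simulate / allocate / covariates / screen / fit / map / select / run, config-driven, with a reproducibility manifest |

## Quick start

```bash
# simulate a 100-area city and run the whole pipeline
bymap run --seed 7 --output-dir out/
cat out/manifest.json            # stages, seed, versions, checksums
head out/risk.csv                # rr_mean, CI, prob_exceed, label
```

or with a config file:

```yaml
# config.yaml
seed: 7
output_dir: out
paths:
  areas: inputs/areas.geojson      # features need area_id + population
  services: inputs/services.csv    # service_id,x,y,complexity,consultations,migrant_exclusive
  stations: inputs/stations.csv    # station_id,x,y,pm10
  covariates: inputs/covariates.csv
adjacency: {scheme: queen}
model:
  covariates: [migrant_rate, pm10, pea, imp, pop_under15, pop_over65]
  n_chains: 4
  n_draws: 1000
thresholds: {exceedance: 1.5, probability: 0.8, vif: 5.0, dic_equivalence: 2.0}
```

```bash
bymap run --config config.yaml
```

All geometry is assumed to be in one projected planar CRS (metres);
no reprojection is performed.

### Python API

```python
from bymap import (generate_city, BYMData, BYMModelSpec, fit,
                   summarize_fixed_effects, risk_summary)

city = generate_city(n_areas=460, seed=1)
names = list(city.covariates.columns)
data = BYMData(city.cases, city.populations,
               city.covariates.to_numpy(), city.lattice, names)
post = fit(data, BYMModelSpec(covariate_names=names), seed=1)
print(summarize_fixed_effects(post))          # exp(beta) with 95% CI
print(risk_summary(post, city.lattice))       # RR, Pr(RR>1.5), labels
```

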