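# ducksel

Bayesian resource-selection analysis for GPS-tracked waterfowl using mixed
(random-effects) conditional logit discrete choice models.

## The scientific problem

Wintering ducks choose where to sit on a landscape that mixes food (flooded
agriculture, supplemental feed), cover (marsh, open water), and risk (public
hunting land versus sanctuaries). Given GPS telemetry, the question is which
landscape attributes drive those choices, at the scale of movements *within*
a home range, and how strongly preferences differ between individuals,
between day and night, and across phases of the hunting season.

`ducksel` implements the full chain from raw fixes to ranked selection
models:

1. **Movement filter.** Fixes from the first 4 days after marking are
   censored (capture effects; animals whose transmitters fail inside that
   window are dropped). Each step between consecutive fixes is classified by
   length into *fine* (< 0.33 km, within-unit jitter), *local* (0.33–25 km,
   the selection scale of interest), or *relocation* (> 25 km). Every count
   is tracked in a `FilterLedger` whose conservation identities are checked.
2. **Diel and season labels.** Diurnal means sunrise − 30 min to
   sunset + 30 min (legal shooting time), computed with the standard NOAA
   solar-position algorithm. Dates map to four hunting-season phases (PRE,
   FIRST split, SECOND split, POST) over two winters.
3. **Choice sets.** The landscape raster is aggregated to an analysis grid
   of 2.12 km cells ("resource units", covariates in hectares per unit). For
   each retained local movement, the choice set is the used unit plus all
   units whose centers fall within the availability radius — the 97.5th
   quantile of local step lengths (9.6 km under the defaults, giving at most
   69 units per set).
4. **Covariates.** Fourteen land-class × ownership crossings (e.g.
   private-land marsh, public water, flooded agriculture, 400 m supplemental
   feeding refuges). Pairwise Pearson screening (|r| ≥ 0.8) removes the
   lower-priority member of correlated pairs; survivors are standardized to
   mean 0 / SD 0.5 (the 2-SD convention, so continuous and binary effects
   are comparable).
5. **Models.** Four candidate structures per season × diel stratum — random
   (no covariates), risk (hunting-risk tiers), resource (land-class sums),
   and full (all retained crossings) — each a mixed conditional logit:

   P(unit j | set Cₙ, βᵢ) = exp(xⱼ′βᵢ) / Σ_{l∈Cₙ} exp(x_l′βᵢ),
   βᵢₖ ~ Normal(μₖ, σₖ²), μₖ ~ Normal(0, 2.786), σₖ ~ half-t(scale 2, df 3),

   fit by adaptive random-walk Metropolis-within-Gibbs, with convergence
   judged by the Brooks–Gelman–Rubin statistic (R̂ < 1.1) and models ranked
   by DIC (ΔDIC ≤ 5 treated as competitive). A variable is called important
   when its 95% credible interval excludes zero.

Because real telemetry of this kind is rarely shareable, the package also
ships a full synthetic-data generator (`ducksel.synthetic`): a random
land-class mosaic crossed with Voronoi ownership parcels, plus trajectory
simulation from the very movement-and-selection process the estimator
assumes, with the ground-truth coefficients saved alongside the fixes.

## Worked example

Simulate a small study, run the whole pipeline, and inspect the results
(deterministic under the seeds shown):

```python
import pandas as pd
from ducksel import pipeline
from ducksel.config import Paths, RunConfig, Thresholds
from ducksel.dcm import McmcConfig
from ducksel.synthetic import SimConfig, generate_landscape, simulate_trajectories

cfg = SimConfig(seed=11, n_rows=250, n_cols=250, radius_km=3.0, n_animals=6)
bundle = generate_landscape(cfg)
fixes, truth = simulate_trajectories(cfg, bundle)

rc = RunConfig(
    paths=Paths(output_dir="results/demo"),
    thresholds=Thresholds(radius_km=3.0),
    mcmc=McmcConfig(chains=2, iterations=400, burn_in=150, max_doublings=0, seed=7),
)
res = pipeline.run_analysis(rc, fixes=fixes, landscape=bundle.landscape)
print(res["ledger"].as_dict())
```

prints the movement-filter accounting

```
{'total': 6755, 'censored_initial': 176, 'fine': 4830, 'relocation': 20,
 'local': 1905, 'out_of_extent': 90, 'final': 1815,
 'animals_marked': 6, 'animals_censored': 0, 'animals_analysed': 6}
```

so 1,815 choice sets enter the models. The DIC ranking for the
FIRST-split / diurnal stratum (`results/demo/dic_table.csv`):

```
   model         DIC  delta_DIC  competitive
    full 1001.436305   0.000000         True
resource 1112.754556 111.318251        False
    risk 1223.868230 222.431924        False
  random 1304.703193 303.266887        False
```

The full model wins, as it should — the trajectories were simulated from
it. Its posterior summary (`results/demo/caterpillar.csv`, first rows):

```
  variable   mean  cri_lo  cri_hi  important
  MICH-DNR -0.216  -0.667   0.207      False
 PUB-WATER -0.271  -0.625   0.155      False
 PRI-WATER  0.175  -0.134   0.468      False
 WAL-WATER -0.503  -0.949  -0.119       True
MICH-WATER  0.412  -0.187   1.027      False
 PUB-MARSH -0.630  -1.999   0.230      False
```

The same pipeline is available on the command line:

```sh
ducksel simulate --seed 4 --n-animals 2 --size 500 --out data/sim
ducksel prepare  --fixes data/sim/fixes.csv --out results/prep
ducksel recovery --replicates 2 --animals 20 --sets 60 --alternatives 8 \
                 --seed 1 --iterations 1500 --burn-in 500 --out results/rec
# -> coverage 1.00, mean bias -0.011 over 2 replicates
```

(`ducksel run` drives the full analysis from a YAML config; `ducksel fit`,
`rank`, and `report` operate per stratum.)

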