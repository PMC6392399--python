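# Methods

This document records the statistical model, the defaults and their
rationale, the numerical choices, and the limits of what the package claims.
It makes no empirical claims beyond what the test suite and
`scripts/acceptance.py` actually compute.

## 1. Data model

A **fix** is one GPS location: animal id, UTC timestamp, planar coordinates
in km (easting/northing; any local projected CRS works, the package never
re-projects). A **step** joins consecutive fixes of one animal; timestamps
must be strictly increasing per animal.

The **landscape** is a square raster of integer class codes (ESRI ASCII grid
on disk), with a catalog mapping codes to the fourteen analysis variables.
Cell membership everywhere in the package uses half-open cell squares and
cell *centers* (a raster cell belongs to whichever analysis unit contains
its center), so areas are conserved up to one raster cell.

## 2. Movement filter

- **Censoring.** The first `censor_days` (default 4) after each animal's
  first fix are removed to avoid capture effects. Animals with no fixes
  after the window count as censored; the rest are analysed.
- **Diel label.** Diurnal = [sunrise − 30 min, sunset + 30 min], inclusive
  at both ends, with sunrise/sunset from the NOAA solar-position equations
  (zenith 90.833°) at a configurable study-area latitude/longitude. Polar
  day/night raises an error rather than guessing.
- **Season label.** Eight inclusive date windows (PRE/FIRST/SECOND/POST in
  each of two winters); fixes outside every window are labelled
  `out_of_window` and leave the analysis (and the ledger) before choice-set
  construction.
- **Step scales.** fine < 0.33 km; local ∈ [0.33, 25] km (closed — boundary
  values are local); relocation > 25 km. The fine cutoff is ~8.5 raster
  cells of within-unit jitter at 38.7 m resolution; 25 km separates
  within-home-range movement from site abandonment.
- **Ledger.** `total = fine + relocation + local` and
  `final = local − out_of_extent` are enforced identities, not reports.

The descriptive table reports, per season × diel stratum, the number of
animals, fixes, mean fixes per animal (= N/IDs, displayed with trailing
zeros trimmed after round-half-even to 2 decimals), SD, min and max.

## 3. Choice sets

The analysis grid has 2.12 km spacing (about 4.5 km² units — large enough
that consecutive local steps usually change units, small enough to resolve
ownership boundaries). The availability radius defaults to the 97.5th
quantile (linear interpolation) of observed local step lengths; a fixed
radius can be configured instead. A choice set is the used unit plus every
unit whose center lies within the radius of the used unit's center
(Euclidean, closed disc) and inside the landscape extent. At 2.12 km
spacing and 9.6 km radius the lattice enumeration gives exactly 69 units —
the package's hard upper bound for that geometry. The used unit always sits
at alternative index 0.

Covariates are hectares of each of the fourteen land-class × ownership
crossings per unit, computed once on the aggregated grid. Ownership
rasterization uses a fixed priority (CWS > Walpole > MICH-DNR > Michigan >
private > public) so overlapping parcels resolve deterministically. The
400 m supplemental-feed buffer changes only the land-class component of a
cell, never its ownership; flooded-parcel recoding applies to agriculture
cells only.

## 4. Screening and standardization

Within each stratum, variables with zero variance are dropped first; then,
while any pair of remaining variables has |Pearson r| ≥ 0.8, the
lower-priority member of the worst pair is removed (marsh variables outrank
water within an ownership, so e.g. CWS-MARSH survives a CWS-WATER
collision). Survivors are standardized as (x − mean)/(2·SD), giving mean 0
and SD 0.5, which puts continuous effects on the scale of a binary
contrast. Standardization parameters are retained so coefficients can be
mapped back to hectares.

## 5. The discrete choice models

Per stratum, four candidate structures share the same choice sets:
**random** (no covariates — each unit equally likely), **risk** (areas
summed into high/intermediate/no hunting-risk tiers), **resource** (areas
summed by land class), and **full** (all retained crossings). Each is a
mixed conditional logit:

- P(j | Cₙ, βᵢ) = exp(xⱼ′βᵢ) / Σ_{l∈Cₙ} exp(x_l′βᵢ)
- βᵢₖ ~ Normal(μₖ, σₖ²) per animal i
- μₖ ~ Normal(0, 2.786) — a weakly informative prior: on 2-SD standardized
  covariates, variance 2.786 keeps implied choice probabilities from piling
  onto 0/1
- σₖ ~ half-t(scale 2, df 3) — heavy-tailed but proper, shrinking small
  heterogeneity toward 0 without forbidding large values

`Priors.mu_var_is_variance` records explicitly that 2.786 is a variance
(set it False to read the number as an SD).

### Sampler

Adaptive random-walk Metropolis within Gibbs, vectorized across animals:

- per-animal β blocks updated jointly by a spherical Gaussian proposal with
  a per-animal scalar step size;
- μ drawn exactly from its conjugate normal conditional;
- log σ updated by RWM with the Jacobian correction.

Step sizes adapt toward 0.3 acceptance during burn-in only (so the retained
chain is a valid fixed-kernel Markov chain). Chains (≥ 2 required, default
3) are seeded independently via `default_rng([seed, chain])`, making every
fit reproducible. Convergence = classic Brooks–Gelman–Rubin
R̂ = √(V̂/W) < 1.1 for every μ and σ; if any parameter fails, the run
length doubles (up to `max_doublings`) and the fit is re-run, with the
final flag reported honestly either way.

### DIC and ranking

DIC = D̄ + pD with pD = D̄ − D(β̄ᵢ), the plug-in deviance at the posterior
means of the *individual* coefficients (the focus of inference is
animal-level selection). For the random model DIC = 2·Σₙ ln|Cₙ| exactly —
no sampling. Models are ranked by DIC; ΔDIC ≤ 5 is flagged competitive.
Ranking refuses to compare fits whose underlying choice-set data differ
(checked by fingerprint). A variable is "important" when its pooled 95%
percentile credible interval for μₖ excludes zero.

## 6. Synthetic data generator

The generator's defaults *are* the study conditions: 57 animals, 6–8 fixes
per day from 27 August to 31 January, a 38.7 m raster, step-scale mixture
(fine 0.7232, local 0.2744, relocation 0.0024), 2.12 km analysis grid and a
9.6 km radius.

- **Landscape**: nearest-seed (Voronoi) mosaic of land classes at
  configurable frequencies, crossed with Voronoi ownership parcels; feed
  sites fall on private land; flooded parcels recode private agriculture.
- **Trajectories**: each animal draws βᵢ from the true hierarchy and, at
  each scheduled fix, makes a fine jitter, a rare relocation, or — at the
  local scale — picks its next unit by conditional-logit probabilities over
  the availability disc of its current unit, using globally 2-SD
  standardized covariates. The landing point is jittered inside the chosen
  unit while keeping the step in the local band. Ground truth (μ*, σ*, every
  βᵢ, each model-driven choice, and the standardization constants) is saved
  for verification.
- **Direct choice-set simulator** (`simulate_choice_data`): i.i.d.
  Normal(0, 0.5) covariates and Gumbel-max choices straight from the
  hierarchical logit — the workhorse for parameter-recovery studies, since
  it isolates the estimator from the geometry pipeline.

What the generator does **not** emulate: real land-cover spatial
autocorrelation beyond patch structure, GPS measurement error, missed
fixes, behavioural state switching, or attraction to conspecifics.

## 7. Numerical choices

- Log-sum-exp everywhere a softmax denominator appears; likelihood is exact
  to ~1e-15 relative against direct enumeration (asserted at 1e-10).
- DIC's D̄ uses at most 1,500 evenly spaced posterior draws, evaluated in
  vectorized batches; with typical chain lengths this is an exhaustive or
  near-exhaustive thinning, not an approximation knob.
- Quantiles use linear interpolation (NumPy default); correlations are
  Pearson on raw hectares; SDs are sample (ddof = 1) except single-animal
  strata, reported with ddof = 0.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give byte-identical outputs.

## 8. Resolved design ambiguities

- The analysis-unit size is implemented as 2.12 km **spacing**; that is the
  reading under which the 9.6 km radius yields exactly 69 available units.
- The μ-prior constant 2.786 is treated as a **variance** (switchable).
- Season windows are applied verbatim in both winters; window endpoints and
  the diel boundaries are inclusive.
- Screening priority places marsh above water within each ownership, then
  follows the catalog order.

## 9. Problem sizes and limitations

The test suite runs on reduced problems chosen for CI budgets (e.g. a
250×250-cell landscape with 6 animals and a 3 km radius; recovery studies
with 40 animals × 150 sets × 10 alternatives and 3 chains × 3,000
iterations). These sizes are the package's own verification choices, not
claims about any particular field study. Known limitations: the sampler is
plain RWM-within-Gibbs (adequate at these scales, slower mixing for large
K); coordinates are assumed planar km (no geodesy); rasters must fit in
memory; and real-data coefficient values are inherently study-specific —
the package verifies its arithmetic, its estimator, and its accounting, not
any particular ecological conclusion.
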