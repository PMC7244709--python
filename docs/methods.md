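# Methods

## Scope

`macrogen` re-implements, as a tested library, the analysis chain used to
map intraspecific genetic diversity (GD) of terrestrial vertebrate
assemblages and to weigh its candidate drivers: interspecific diversity
(species richness SR and Faith's phylogenetic diversity PD), Late
Quaternary climate stability, and human land use.  Real-data acquisition
(sequence databases, range shapefiles, published tree posteriors,
paleoclimate extractions) is out of scope; a synthetic-data module
generates statistically analogous inputs with known ground truth so every
stage is verifiable.

## Genetic diversity

Per species, nucleotide diversity is

    Pi = mean over valid pairs (i, j) of k_ij / m_ij

where `m_ij` counts aligned positions at which both sequences carry an
unambiguous base (A/C/G/T — gaps and N are skipped) and `k_ij` counts the
subset of those positions at which the bases differ.  A pair is *valid*
when the two sequences overlap in at least 50% of the unambiguous length
of the longer sequence.  Two interpretation choices are deliberate:

* invalid pairs are removed from both numerator and denominator (treating
  them as zero differences would bias Pi downward);
* the 50% overlap is measured against the count of unambiguous bases, not
  alignment columns, because gaps and N carry no information;
* a species with a single sequence in a spatial unit contributes nothing
  (Pi is undefined at n = 1, not zero).

Assemblage GD of a unit is the unweighted mean of the defined Pi values of
the species sampled there; sequences are pooled strictly within the unit.

## Spatial units

All geometry lives on the Behrmann cylindrical equal-area plane (standard
parallel 30°, authalic radius 6,371,007.181 m).  The grid has square
half-open cells of 385,900 m (≈148,953 km² each), indexed from the
projected origin; boundary points belong to the east/north cell.  Region
polygons are supported as an alternative grain.  The sequence-to-range
distance filter (keep ≤ 385,945.1 m, one cell edge) uses planar distance in
this same projection; relative to geodesic distance the distortion is a few
percent below ~60° latitude, which we accept because the threshold itself
is defined as a projected cell edge.

## Sequence filters

1. sequences containing IUPAC ambiguity letters (R Y S W K M B D H V U) are
   removed; `-` and `N` survive because the Pi computation skips them;
2. range polygons coded presence 3/6 or origin 3/4 are unusable;
3. a synonym table (old name → accepted name) may merge taxa before
   filtering;
4. sequences farther than one cell edge from their species' usable range
   (strict `>`) are dropped; species without a usable range are dropped and
   logged.

## SR and PD

SR counts species whose usable ranges intersect a unit *and* that are tips
of the phylogeny, so SR and PD cover the same pool.  Faith's PD is the
branch-length sum of the minimal subtree connecting the selected tips.  The
default convention is root-exclusive: branches between the tips' most
recent common ancestor and the tree root are not counted, and a single tip
contributes its terminal branch only.  `include_root=True` switches to the
root-inclusive convention used by several other implementations.  PD is
averaged over a posterior sample of trees when one is supplied.

## Climate stability

Annual series (temperature in °C, precipitation totals in mm/yr;
annualisation is upstream of this package) are summarised by 100-year
sliding windows with a 1-year step.  Window fits default to generalized
least squares with AR(1) errors via Cochrane–Orcutt iteration (tolerance
1e-8 on rho, at most 50 iterations); iterations that fail to converge or
stall near the unit root (|rho| ≥ 0.97, where the quasi-differenced design
degenerates) fall back to OLS and are logged.  `method="ols"` bypasses GLS.
Residual variability is the population SD (ddof = 0) of the residuals about
the fitted local line, always measured on the untransformed scale.

*Extreme centuries* are windows of the global mean temperature series whose
slope is strictly greater than the 90th percentile (linear-interpolation
quantile) of all window slopes; a guard of 1e-8 times the slope magnitude
protects the strict comparison from floating-point jitter so a degenerate
all-equal slope distribution selects nothing.  The extreme windows are
identified once, from temperature, and reused for the precipitation
metrics.  Per climate cell we take the median slope and median residual SD
across the extreme windows (windows are used as selected, without
deduplication), and per spatial unit the unweighted mean over the climate
cells whose outline intersects the unit.

## Human land use

Per ALCC cell, the historical predictor is the oldest year BP at which the
anthropogenic land-cover-change fraction strictly exceeds 20% (0 when the
threshold is never crossed; the first crossing stands even if the series
later dips).  The static human-footprint raster (0–50) and the exceedance
times are aggregated to units by unweighted means over intersecting cells.

## Driver statistics

* **Data-rich cells** — retained when taxonomic coverage ≥ 7% *or* the
  cell's sequence count reaches one standard deviation (sample SD,
  ddof = 1) of the count distribution over the full cell set; the union rule
  reflects that either criterion marks a cell as informative.
* **Transform** — grid-scale GD is square-root transformed before all
  regression work; region-scale GD is left untransformed.
* **OLS/AICc** — Gaussian ML log-likelihood with
  AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1), K counting slopes + intercept +
  residual variance.  An exact fit's likelihood is floored so model
  comparison degenerates gracefully to the parameter penalty.
* **Hierarchical partitioning** — the independent contribution (IC) of a
  predictor is its R² increment averaged over all orderings in which
  predictors can enter (a Shapley value over subsets); the joint
  contribution is the remainder of its simple-regression R².  The ICs sum
  to the full-model R² exactly (checked to 1e-10).  All-subset R² values
  come from the correlation matrix (solve per subset), which is what makes
  the randomisation test affordable: permuting one column changes only its
  correlations, so each subset updates by a rank-one formula, vectorised
  over permutations.
* **IC significance** — each column permuted `n_rand` times (default
  1000); significant iff the observed IC strictly exceeds the 95th
  percentile of its permuted ICs — a 5%-level test per variable, which
  bounds how often a pure-noise predictor survives (see Limitations).
* **Iterative exclusion** — drop the insignificant variable with the
  smallest IC (ties: the later column, logged) and repeat until all
  retained variables are significant; the retained set may be empty.
* **Multimodel inference** — all non-empty subsets of the retained
  variables, minus any containing a pair with |Pearson r| > 0.7; AICc
  ranking; models with ΔAICc > 5 dropped; Akaike weights renormalised over
  the survivors; SAW per variable is the summed weight of retained models
  containing it.
* **Spatial diagnostics** — Dutilleul/Clifford-Richardson modified t-test
  with 13 equal-width distance classes spanning (0, max pairwise distance]:
  the correlation r is referred to F(1, M̂−2) with the effective sample
  size M̂ = 1 + 1/v, v = (n + Σ_k h_k ρ̂x(k) ρ̂y(k))/n² over ordered pair
  counts h_k.  Moran's I uses row-standardised weights (kNN with k = 4 on
  projected centroids at the grid scale, shared-boundary contiguity for
  regions), null expectation −1/(n−1), and a two-sided permutation p-value
  with the +1 correction (10,000 permutations by default).
* **Prediction** — the most parsimonious model (minimal AICc; ties to
  fewer variables, then name order) is evaluated at every cell with
  complete predictors; sqrt-scale predictions are clipped at zero and
  squared.  No smearing correction is applied for the retransformation
  (`square_backtransform=False` returns the sqrt-scale surface instead).

## Synthetic world

The generator's defaults are the study conditions; every draw descends from
one root seed through `SeedSequence(seed, spawn_key=(component, index))`.

* **Phylogeny** — Yule trees (birth rate 0.1/My, default 40 species,
  posterior sample of 10 trees).  The simulator stops at the n-th birth,
  which would leave two zero-length tips; the clock is run on by the
  waiting time to the next (uncommitted) birth so all branches are positive
  and the tree stays ultrametric.
* **Ranges** — 64-gon circles (default radius 1500 km) centred uniformly
  in the map extent, drawn on the projected plane (area within ~0.2% of
  πr²).  Decoy polygons with excluded presence/origin codes can be added
  for filter tests.
* **Sequences** — star genealogy: n sequences (default 12) derive
  independently from one random ancestral sequence of 800 bp; each site
  mutates with probability p = 0.01 to a uniformly chosen different base.
  Two lineages then differ per site with probability 2p(1−p) + (2/3)p²,
  the closed-form oracle for Pi.  Coordinates are uniform inside the
  species' range.  A star genealogy is deliberately unrealistic (no shared
  coalescent history): the point is an analytic expectation, not realism.
* **Climate** — per cell, value_t = trend·t + ε_t with
  ε_t = a·ε_{t−1} + N(0, sd²), stationary initialisation, default a = 0.5
  on a 2.5° grid over 600 years; the global series is the unweighted cell
  mean.  The pipeline draws per-cell trends and innovation SDs around the
  configured values (±50%/±40%) so both stability predictors carry genuine,
  mutually independent spatial signal.
* **Human** — per-cell logistic ALCC growth curves with random onset,
  rate and ceiling (≤0.6) over 8000–100 BP; static footprint uniform on
  [0, 50].
* **Response** — sqrt-scale linear model y = Xβ + N(0, σ²), GD = y², so
  the pipeline's sqrt transform faces an exactly linear truth.  Effects are
  specified per SD of each predictor; the recovery configuration puts
  +0.05/SD on PD and +0.04/SD on precipitation variability against
  σ = 0.06, i.e. the true drivers explain roughly half the variance,
  matching the explanatory power such assemblage models typically reach.

### Recovery study design

Variable-recovery experiments use a 60-species world on a ±70° lon × ±40°
lat extent (≈930 grid cells with complete predictors), a 3-tree posterior
and 300 climate years, and analyse 200 "data-rich" cells taken as a
spacing-2 lattice.  Scattered cells mirror how data-rich cells are
distributed in practice, and the lattice guarantees that no two analysed
cells share a climate cell, so the row-permutation null of the IC test is
not distorted by aggregation-induced spatial correlation.  The problem
sizes (cells, years, posterior size) are desk-scale choices; the procedure
is identical at any scale.

## What the synthetic tests do and do not show

Passing tests demonstrate that the implementation computes the stated
quantities correctly (exact oracles), that the statistical procedures hold
their nominal levels under their null assumptions, and that the full stack
recovers a known linear signal.  They do not demonstrate robustness to the
features real data add: coalescent (non-star) genealogies, sequencing and
georeferencing error, phylogenetic signal in sampling effort, non-linear
driver effects, or strong residual spatial autocorrelation — the latter is
precisely what the Moran's I diagnostic is there to flag.

## Numerical choices

* Window OLS is computed on centred windows with explicit residuals (no
  catastrophic cancellation; a noiseless line yields residual SD ~1e-16).
* Cochrane–Orcutt runs vectorised over windows with an active set;
  convergence is non-sticky (a window re-enters if rho drifts).
* Permutation p-values always use the (1 + #extreme)/(n_perm + 1) form.
* The degenerate denominator in the rank-one R² update (permuted column
  collinear with a subset) contributes a zero increment.
* kNN ties are broken by unit order; contiguity counts a shared vertex.

## Known limitations

* The per-variable 5% level of the IC randomisation test means that with
  several pure-noise predictors the iteratively retained set contains at
  least one false positive in roughly 1 − 0.95^m of runs (m noise
  variables); this is a property of the prescribed test, not of the
  implementation, and such variables typically carry small ICs and may
  also enter the AICc-best model because the same chance correlation that
  passed the permutation bar also improves the likelihood.
* The modified t-test is mildly conservative at small n (empirical level
  ≈0.04 at n = 30, ≈0.05 by n ≈ 80).
* Planar distances overstate/understate geodesic distances at high
  latitude; ranges crossing the antimeridian are not handled.
* Back-transforming sqrt-scale predictions by squaring is biased low for
  noisy fits (no smearing correction).
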