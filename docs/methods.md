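# Methods notes

This note records the models, parameter choices and numerical policies
behind `elasmodiv`, in the spirit of a package vignette: what is
computed, under which assumptions, and where the genuinely open design
choices were resolved.

## Trait space

**Dissimilarity.** Species are compared over seven traits of four
kinds. Per-trait dissimilarities are: continuous — absolute difference
divided by the pool range, with maximum body size log10-transformed
first (sizes span roughly 20 cm to 20 m; without the log transform the
largest species would dominate the contrast among everything below a
metre); nominal and binary — simple matching (0 if equal, 1
otherwise; neither state of the binary traits is an "absence", so an
asymmetric coefficient would be wrong); multichoice — Jaccard
dissimilarity of category sets, so a coastal-and-oceanic species is at
distance 0.5 from a strictly coastal one. Traits receive equal
weights; a trait with zero pool range contributes nothing and is
logged. The combined value is the square root of the per-trait mean,
which moves the matrix substantially closer to Euclidean (fewer and
smaller negative PCoA eigenvalues). Both the log transform and the
square-root combination are switches on `trait_gower_matrix`.

**Embedding.** Classical PCoA: double-centre the squared
dissimilarities, eigendecompose, scale eigenvectors by the square
roots of positive eigenvalues. If the most negative eigenvalue
exceeds 1e-8 of the largest, the Lingoes correction (add a constant to
all squared off-diagonal dissimilarities) is applied; otherwise
negative axes are simply truncated. Axes are signed so the
largest-magnitude coordinate on each axis is positive, making outputs
deterministic. Three retained axes are the pipeline default; the mSD
quality (mean squared deviation between max-scaled original and
embedded pairwise distances) is reported for 2–6 axes so the
dimensionality trade-off is visible in every run.

## Species scores

FUn is the mean Euclidean distance to the five nearest other species
(ties at the fifth neighbour break by species order, logged); FSp the
distance to the pool centroid (the PCoA origin); FRic the convex-hull
volume of a subset as a percentage of the pool hull. Subsets smaller
than m+1 points in m dimensions, or lying on a lower-dimensional flat,
yield NA with a reason code rather than a degenerate volume.

FUSE combines min–max–scaled FUn and FSp with the species' 100-year
extinction probability GE as `ln(1 + FUn01·GE) + ln(1 + FSp01·GE)`.
The composition is isolated in one function (`species_scores.fuse`) so
an alternative standardisation can be swapped without touching
anything else; the pipeline's own checks avoid FUSE magnitudes and
rely only on its ordinal behaviour (zero at GE = 0, strictly
increasing in GE, rank-invariant to common axis rescaling).

GE comes from an explicit `ExtinctionProbabilityMap`; the shipped
preset `IUCN100-Mooers2008` (LC 0.001, NT 0.01, VU 0.1, EN 0.667,
CR 0.999) is the 100-year transformation standard in the
HED/EDGE-style literature. Scoring refuses to run on DD/NE statuses —
impute first — and there is deliberately no silent default map.

## Phylogenetic scores

PD uses the rooted convention (the spanning subtree includes the root
path, so a singleton's PD is its distance to the root). ED2 for tip i
sums, over the edges on i's root path, the edge length times the
probability that every other tip descending from that edge goes
extinct; with everyone else extinct it equals the root-path length,
with everyone safe the terminal branch. This path-product form is
checked against an exhaustive-enumeration oracle
(`ed2_by_enumeration`, expected PD gain over all 2^(n−1) survival
outcomes) — the two agree to 1e-9 on hundreds of random small trees.
EDGE2 is the point-probability product ED2 × GE (the protocol's full
probability-distribution variant is out of scope). All per-species
phylogenetic quantities are averaged over a tree sample (100 trees at
real scale; 3–10 in tests) with per-tree values retained.

## Spatial metrics, hotspots, congruence

Cells are half-open [west, east) × [south, north) on a 0.5° default
lattice, id'd by integer (col, row) from the (−180, −90) origin. Cell
assignment is exact on representable boundaries and within one float
rounding elsewhere. Assemblage FUn uses the single nearest neighbour
so that four-species cells remain comparable; FRic is NA below four
species and uses the *global* pool hull as denominator; per-cell FSp
keeps the global centroid. Top-quartile membership is
`score >= empirical 75th percentile` with boundary ties included
(logged). The FRic~SR residual map is an OLS fit over cells with
defined FRic.

Hotspots are cells at or above the empirical (1−q) quantile of a
layer (default q = 2.5%), NA cells excluded throughout, boundary ties
included. Congruence between two layers: restrict to common defined
cells, compare the observed hotspot overlap Oo with the independence
expectation Oe = Ni·Nj/NT, and permute one layer's values 999 times.
Because a permutation of the values over the same cells leaves the
detection threshold unchanged, the implementation permutes the hotspot
mask — provably the same distribution, at a fraction of the cost. The
overlap percentage uses min(Ni, Nj) as denominator (with equal-sized
top-q masks the candidate denominators coincide anyway).

The headline p-value is the one-sided add-one permutation p with ties
counted as extreme. The overlap count is a heavily tied discrete
statistic, so this p is conservative (super-uniform) under the null —
correct for inference, but a naive uniformity check on it would fail.
`CongruenceResult` therefore also carries `p_value_randomized`, the
standard tie-randomized construction that is exactly uniform under
the null; calibration experiments use that one.

## Imputation

`impute_once` follows the missForest recipe: initialise missing cells
with the column mean/mode, revisit variables in increasing-missingness
order, fit a 100-tree random forest per variable on the currently
completed data, and stop the first time the change in imputed values
increases (continuous and categorical tracked separately; the
previous iterate is returned), or after 10 iterations. Predictor
sets: traits+taxonomy, geography+taxonomy, or all (the default).
Family/order enter as one-hot indicators; geography as range size in
cells and range centroid latitude; multichoice predictors are encoded
as per-category membership indicators so category-level signal is
visible to the trees, while multichoice *targets* are imputed as
combination-level categoricals ("coastal;oceanic" is one label,
matching the coastal/oceanic/both encoding). IUCN status is imputed
as a 5-level categorical with DD/NE treated as missing.

Ten replicates are aggregated by modal value (median for the single
continuous trait, where a mode is not meaningful; categorical ties
break to the lexicographically smallest label, logged). Recovery
error is measured by artificial masking of known values —
incorrect/total × 100 for categorical variables, NRMSE for continuous
— since out-of-bag error is not well defined across the modal
aggregation.

## Fishing pressure and protection

Effort records are summed per 1° cell over the gear types that can
target elasmobranchs (pole and line; drifting longlines; tuna and
other purse seines; trollers; other seines; set gillnets and
longlines; trawlers); other gears are counted and ignored. Ordinary
kriging interpolates to the analysis grid: an exponential variogram
with nugget is fitted to the binned empirical semivariogram by
weighted least squares (Cressie weights); predictions use data cells
within a 3° radius (NA below five neighbours), weights sum to one by
the ordinary-kriging constraint, and predictions are clipped at zero.
If the variogram fit fails the field falls back to inverse-distance
weighting, flagged per cell. An optional log1p transform of effort is
off by default. The kriging is written in-package (no geostatistics
dependency is declared) and is validated by exactness at data
locations, constant-field reproduction, and hold-out comparison
against IDW.

MPAs are consumed pre-gridded (one row per covered cell). The filter
keeps categories Ia/Ib/II/III and drops designations matching a
configurable keyword list (bird, seabird, turtle, seal, flora, plant,
wetland by default); a cell is protected if any retained MPA covers
it (binary, no area weighting). Gap analysis reports the percentage
of hotspot cells inside/outside the network and the cumulative
protection curve (protected cells ranked least to most diverse
against the cumulative percentage of protected cells).

## Pool filtering

Before any metric: exclusively freshwater species are dropped;
species absent from the grid or from any tree in the sample are
dropped (with counts per reason); cells with fewer than four species
are flagged as excluded from FRic; species occurring *only* in such
cells are dropped. The "exclusively in sparse cells" reading (rather
than "anywhere in a sparse cell") keeps the pool maximal and makes the
filter a well-defined fixed point, which is iterated so the operation
is idempotent.

## Synthetic benchmark

The generator emulates the statistical structure the analysis assumes,
not the geography of the real ocean:

* **Trees** — pure-birth trees (birth rate 1, configurable), 10 per
  bundle by default.
* **Traits** — log10 size by Brownian motion (variance 0.5 per tree
  height, root at 100 cm); nominal/binary traits by symmetric Mk
  (0.7 expected transitions per tree height); each multichoice
  category by an independent two-state Mk with at least one category
  forced present. Taxonomy is read off the clade structure
  (superorders at the basal split, orders/families at fixed depth
  fractions).
* **Statuses** — a logistic threat model with positive log-odds
  couplings on standardised log size (0.8), coastal habitat (0.7),
  freshwater incursion (0.9) and plankton diet (0.8); covariates are
  centred so the configured base rate (0.37, the assessed threatened
  fraction of the real pool) is the marginal rate. Threatened species
  draw VU/EN/CR at 0.45/0.35/0.20, the rest LC/NT at 0.8/0.2; 17% are
  relabelled DD/NE to exercise imputation.
* **Missingness** — MCAR at per-trait rates mirroring the real
  dataset's missingness (diet 0.35, habitat 0.007, terrestriality and
  size 0.001), with a hidden truth table for exact recovery scoring.
* **Ranges** — contiguous blocks with lognormal areas (μ = 6, σ = 1 in
  log cells) around centroids whose latitude density decays as
  exp(−4·(lat/half-span)²), giving the equatorial richness peak; the
  default domain is a 60°×120° basin of 0.5° cells (28,800 cells),
  large enough for stable hotspot tails at q = 2.5% while keeping an
  end-to-end run around a minute.
* **Fishing** — exponentiated smoothed Gaussian noise at 1° (Gaussian
  correlation length 2 cells), split across target gears with
  occasional non-target-gear records.
* **MPAs** — random rectangular patches to ≈6% coverage, categories
  across Ia–VI, with decoy designations (seabird sanctuaries and the
  like) so the designation filter is exercised.

All sub-generators draw from seeds spawned from the master seed, so a
bundle is byte-identical across runs and adding a generator does not
shift the other streams. Because ranges are single rectangles and
traits/ranges are generated independently, the benchmark does *not*
emulate range fragmentation, coastline geometry, species
interactions, or trait–range covariation; passing tests demonstrate
the correctness and calibration of the machinery, not real-world
effect sizes. A MAR missingness mode and regional FRic pooling are
deliberate non-defaults.

## Degenerate inputs and edge policies

Constant hotspot layers raise (no meaningful upper tail); empty
hotspot masks raise in the protection overlap; singleton assemblages
get NA MNTD; all-identical trait columns contribute zero
dissimilarity; kriging cells with fewer than five neighbours stay NA;
an analysis pool that filters to empty raises. Every NA carries a
reason code where downstream consumers need to distinguish causes
(FRic: too few species vs degenerate vs excluded cell).

## Problem sizes

Tests and the acceptance script run the pipeline at a 300-species /
10-tree / 28,800-cell scale and the calibration experiments at the
sizes their statistics require (500 null simulations × 999
permutations on 10,000 cells; 200 small trees for the ED2 oracle; 50
pools for the hull oracle; 1,000 species for imputation recovery).
These sizes were chosen as the smallest at which the respective
checks are statistically meaningful; the machinery itself is
scale-free and has been run unchanged at the full 0.5° global lattice
geometry.

## Known limitations

* FUSE's exact standardisation varies across the literature; the
  log1p-of-scaled-product form here is one defensible choice, kept
  behind a single function.
* EDGE2 uses point extinction probabilities, not the full
  probability-distribution protocol.
* The congruence null permutes cells freely; spatially structured
  (autocorrelation-preserving) nulls are a possible extension.
* Kriging fits one global variogram; strongly non-stationary effort
  fields would warrant local refitting.
* The imputation error estimate is an artificial-masking estimate,
  which can differ from out-of-bag error under informative
  missingness.
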