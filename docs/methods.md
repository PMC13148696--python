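# Methods

This note documents the models and procedures implemented in `nichescape`,
the choices made where the design was genuinely open, and what the
synthetic scenarios do and do not establish.

## Occurrence cleaning

Records pass three filters in a fixed order: (1) coordinate precision —
both coordinates must carry at least two decimal digits *as written*, so
raw coordinate text is preserved through the cleaning chain rather than
round-tripped through floats; (2) per-pixel deduplication — one record per
raster cell, first in input order; (3) distance thinning — greedy removal
of the record with the most neighbours within 5 km, ties broken by a seeded
RNG, with a coordinate-sort canonicalization pass so the result is
independent of input order. The order precision → dedup → thin is a
documented convention; each filter is idempotent. Species are modelled only
if they retain ≥ 5 unique localities. Ocean or otherwise out-of-area
records are handled by the study-area mask rather than a dedicated
gazetteer check.

## Environmental space

PCA is computed on standardized variables (correlation matrix), because
climate layers have incommensurate units (°C, mm); the per-layer means and
standard deviations are stored so projection is exactly reproducible.
Component signs are fixed by making the largest-|loading| entry of each
component positive, which removes eigen-solver sign ambiguity. Because the
PCA is centered on the study-area cells, the study-area mean climate is the
origin of component space; multivariate marginality is measured to that
origin.

## Minimum-volume ellipsoid niches

Exact MVE over "best h of n" subsets is combinatorial, so the fitter uses a
seeded multi-start concentration heuristic in the spirit of robust
minimum-covariance-determinant estimation: draw a random h-subset
(h = ⌈coverage·n⌉, default coverage 0.95), then iterate "compute subset
mean/covariance → reselect the h smallest squared-Mahalanobis points" to a
fixed point. *Every* subset examined along every concentration path is a
candidate, and the minimum-volume candidate over ≥ 50 starts is returned;
tracking intermediate iterates matters because the optimal subset need not
be a fixed point of the concentration map. The returned radius² is the h-th
smallest squared Mahalanobis distance of the fitting points under the final
centroid/covariance, which makes "exactly h points inside" an exact,
testable contract (up to distance ties, which have measure zero for
continuous data). Volume is V_d·√det(Σ)·c^d. The fitter refuses
rank-deficient point sets (suggesting dimension reduction) and n < d + 2.

Accessible areas are convex hulls of the occurrences buffered by 25 km in
the planar frame; geodesic buffering is out of scope, so real-data inputs
must already be in an equal-area projection. Ranges are presence cells
whose centers fall in the accessible area.

## Assemblages

The PAM grid is axis-aligned with the raster bounding box; a species
occupies a coarse cell iff at least one fine range-cell center falls in it.
Coarse cells containing no valid fine cell are dropped; valid-but-empty
cells are retained as zero rows (they define the null-model domain).
Property maps are arithmetic means over the species present in each cell;
empty cells are missing. Synthetic scenarios use 1-km fine cells and 10-km
PAM cells, a scaled-down analogue of ~5-km climate pixels aggregated to
~110-km (one-degree) assemblage cells.

## Trait evolution

All four models are Gaussian on the tips with mean z₀·1 and covariance
σ²·V₀(·) built from shared path lengths C:

* BM: V₀ = C;
* OU (stationary, root at the optimum): V₀ᵢⱼ =
  e^{−α(tᵢ+tⱼ−2Cᵢⱼ)}(1−e^{−2αCᵢⱼ})/(2α), the familiar ultrametric form
  when all tip depths are equal; non-ultrametric trees use this general
  form with a warning;
* Early Burst: V₀ᵢⱼ = (e^{rCᵢⱼ}−1)/r with r < 0;
* rate trend: the evolutionary rate changes linearly in time,
  σ²(t) = σ²(1+bt), so V₀ᵢⱼ = Cᵢⱼ + bCᵢⱼ²/2. The alternative mean-drift
  "trend" is not identifiable on ultrametric trees, which is why the rate
  reading was adopted.

Given the structure parameter, z₀ and σ² have closed-form ML solutions
(GLS mean and scaled quadratic form), so each fit is a one-dimensional
profile-likelihood search: a deterministic coarse grid over documented
bounds (α ∈ [10⁻⁸, 50]/T, r ∈ [−10, −10⁻⁸]/T, b ∈ [−0.99, 10]/T with T the
tree height; the α grid is log-spaced) followed by bounded scalar
refinement. A deterministic grid of 40 points provides the multi-start
robustness that random restarts would, without RNG dependence. Parameter
counts for AIC: BM 2, others 3. AIC weights are exp(−Δᵢ/2) normalized;
ties go to the fewest-parameter model.

Root reconstruction is the GLS estimate ẑ₀ = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹z under the
*fitted* covariance of the selected model, with standard error
√(σ̂²/(1ᵀV₀⁻¹1)). Multivariate centroids are reconstructed trait-by-trait
(pc1, pc2, pc3 independently); each trait selects its own best model.
Phylogenetic position is the Mahalanobis distance (through the species'
own ellipsoid covariance) from the species centroid to the ancestral
centroid in component space, or the absolute per-variable difference in
the univariate approach. The same species-ellipsoid covariance choice is
used for marginality; a background-covariance variant can be obtained by
passing a different ellipsoid.

## Spatial regression

Weights: neighbours are centroid pairs within a distance band. The two
distance classes default to the largest first-nearest-neighbour distance
("min", guaranteeing no island) and twice that ("max"); both are
overridable, as the class definitions are an interpretation of
under-specified practice. Schemes: row-standardized (W), globally
standardized to total weight n (C), and variance-stabilizing (rows scaled
by their L2 norm, then globally rescaled to total n; S). All three are
similar to symmetric matrices, so the spectrum of W is real and the
SAR Jacobian ln|I−λW| = Σ ln(1−λeᵢ) is computed from a symmetric
eigendecomposition — practical up to a few thousand cells, ample for the
grids used here.

The SAR error model y = Xβ + u, u = λWu + ε is estimated by maximum
likelihood concentrated over λ (50-point grid on the feasible interval
(1/e_min, 1/e_max), then bounded refinement); β and σ² are the GLS
solutions at λ̂, with asymptotic standard errors σ̂²(X*ᵀX*)⁻¹ where
X* = (I−λ̂W)X. AIC counts the regression coefficients plus λ and σ².
Cells with zero richness (or a missing property mean) are excluded from
fitting. Predictors are screened by pairwise Spearman |ρ| > 0.7 with a
greedy first-fit split into conflict-free models.

Moran's I uses the standard (n/S₀)·zᵀWz/zᵀz form with expectation
−1/(n−1) and a two-sided permutation p-value under the add-one rule.

## Null models

The spreading-dye null regrows each species' range as a cohesive random
blob of the observed size: a uniform seed cell, then uniform draws from the
frontier (the *set* of unoccupied domain neighbours — uniform over frontier
cells, not over neighbour multiplicity, which affects only blob shape
statistics) until the size is reached, restarting from a new seed if a
disconnected pocket stalls growth. Adjacency is rook by default, queen by
flag. Species count and all range sizes are conserved exactly.

The property-shuffle null keeps ranges fixed and permutes the species'
property rows jointly (each species' property tuple stays together), so
the species-level multiset is conserved while the geographic pattern of
assemblage means is randomized.

Each null replicate recomputes richness and the per-cell property means
and refits the same SAR specification (the observed best scheme and
distance class; re-selection per replicate is available behind a flag but
costs six fits per replicate). The test statistic is the slope magnitude:
p = (1 + #{|slope_null| ≥ |slope_obs|})/(n_reps + 1).

## Synthetic scenarios

`make_landscape` builds layers as a latitudinal gradient plus a Gaussian
random field (white noise smoothed with a squared-exponential kernel of
the stated range, centered and scaled to unit variance): a strong-gradient
"temperature" layer (default 15 °C across the domain, warm edge =
"tropics") and a patchy, bimodal "precipitation" layer (wet/dry regimes
around 1500/600 mm), emulating the bimodal environment distribution that
complicates the interpretation of marginality. Trees are exact Yule
simulations scaled to height 1, with a final waiting interval so no
pendant edge is zero. Niche centroids evolve per-axis under exact OU
branch transitions; ellipsoid covariances are diagonal with log-normal
axis scales. The `breadth_gradient` preset pulls centroids toward the
warm-climate pole of component space and couples log niche *volume* to the
distance from that pole (slope 3.5 per component unit, spread evenly over
the axis scales, with the independent log-normal scatter tightened to
σ = 0.1 so the coupling dominates), building a negative richness–breadth
association. The coupling acts on log volume rather than on every axis
standard deviation because an all-axes shift cubes into the volume and
produces an extremely heavy-tailed breadth distribution, whose largest
values dominate assemblage means and inflate the shuffle-null slope
variance. `conserved_position` uses a strong pull (α = 4) toward the root
centroid; `neutral` draws breadths independently of position (α = 0.5
wander).

Occurrence sampling is dispersal-limited by default (`dispersal_km` = 60 on
the 300-km domain): a range center is drawn uniformly among a species'
climatically suitable cells and occurrences are sampled around it under a
Gaussian kernel of that scale. Without this, broad-niche species occupy
essentially the whole domain; such wall-to-wall ranges act as variance
sinks when species-level properties are permuted (a large property value
assigned to an everywhere-species flattens the assemblage-mean map), which
inflates the null slope distribution of the property-shuffle test.
Dispersal limitation is also the biological situation the accessible-area
(hull + buffer) constraint exists for, so the generator and the analysis
assumptions match. Even so, the raw-slope shuffle test at this
scaled-down size (60 species) retains noticeable tail mass: across
scenario realizations the built-in breadth effect tests at p < 0.05
against the spreading-dye null essentially always, and against the
property-shuffle null in most but not all realizations; the per-cell
breadth-richness rank correlation is ≈ −0.8 throughout. A species whose
drawn niche
misses every realized climate has its radius² enlarged geometrically until
it intersects — biologically, marginal-centroid species get broad
tolerances — and the enlarged ellipsoid is recorded as the truth.

Default problem sizes were chosen as the smallest at which the built-in
effects are comfortably detectable: the headline breadth-gradient run uses
60 species on a 300×300-km landscape (30×30 PAM, ~900 cells) with 100 null
replicates per null type; calibration checks use 24 species on 150×150
(15×15 PAM) with 100 shuffle replicates across 20 scenario repetitions.
Occurrences default to 60 points per species, sampled with replacement
from suitable cells and jittered within the cell.

One subtlety of the neutral preset deserves emphasis: "no built-in
effect" cannot mean that every niche property is independent of richness.
Niche volume mechanically determines range size, so assemblages in
climatically marginal cells are composed disproportionately of broad-niche
species and the per-cell mean breadth is structurally associated with
richness even when species-level breadths are drawn i.i.d. The shuffle
null — which breaks exactly the species-to-property assignment — correctly
detects this real structure. Calibration of the null test is therefore
assessed with a *decoy* trait: a per-species value drawn independently of
the niches and ranges, mapped and tested through the identical pipeline.
For such an assigned-independent trait the null-test p-values are
approximately uniform (p > 0.05 in ≥ 18 of 20 scenario repetitions).

What the scenarios do *not* emulate: georeferencing error patterns,
taxonomic noise, sampling-effort bias, non-equilibrium range dynamics, or
real bioclim inter-layer correlation structure. Passing tests therefore
establish the *internal* correctness and calibration of the pipeline —
that it recovers effects its own generating model builds in and stays
quiet when none exist — not that any real richness gradient is driven by
niche properties.

## Numerical notes and limitations

* Ellipsoid covariances are Cholesky-factorized once per ellipsoid;
  positive-definiteness is enforced (eigenvalue floor 10⁻¹²).
* The MVE contract "exactly h inside" can be violated by exact distance
  ties; real-valued climate data make this a measure-zero event.
* The SAR eigendecomposition limits fits to n ≲ 5000 cells; the log-det
  could be swapped for sparse LU at larger n.
* Permutation and null-test p-values are never zero by construction
  (add-one rule); with 100 replicates the floor is 1/101.
* Trees must have strictly positive terminal branches for the Gaussian
  trait models; the tree simulator guarantees this, and external trees
  are validated on load.
* Real-data mode performs no reprojection: rasters, polygons and
  occurrence coordinates must share one planar equal-area frame with km
  units.
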