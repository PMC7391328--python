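# Methods

## Rectification model

Each sub-block photograph views a planar ground patch from (approximately)
overhead. For a planar scene the map from image pixels to ground
coordinates is exactly a planar projective transform (homography), a 3×3
homogeneous matrix H with 8 degrees of freedom; it is the minimal family
that corrects the perspective displacement ("parallax") of an off-nadir
camera. Lens distortion beyond the projective component is not modelled:
for near-nadir photographs of a 0.5 m cell it is second-order relative to
the ~1 mm digitization noise floor.

`fit_projective` estimates H from ≥ 4 control-point correspondences by the
direct linear transform with Hartley coordinate pre-normalization (via
scikit-image), least squares when over-determined, and reports the RMS
reprojection error. Control points carry absolute plot coordinates, so
each sub-block transform maps directly into the plot frame with no second
translation step, and the pixel v-axis flip (v increases downward, y
northward) is absorbed by the fitted matrix.

Cell membership is half-open — [low, high) on each axis — with the high
edge closed on the plot's outer east/north boundary, so every plot point
belongs to exactly one sub-block and plants sitting on a shared chopstick
edge are never double-counted. Points digitized twice across an edge
(within 1 mm after rectification) are merged to one and logged; rejected
points are logged with their overshoot distance, never dropped silently.

## Second-order estimators

All estimators condition on the observed count n and use translation edge
correction, which is exactly unbiased on rectangular windows: a pair with
displacement (dx, dy) in window W of sides (a, b) is weighted by the
reciprocal of the overlap area A = (a − |dx|)(b − |dy|), the area over
which that displacement could have been observed.

Ripley's K:

    K̂(r) = |W|² / (n(n−1)) · Σ_{i≠j} 1[d_ij ≤ r] / A_ij

The pair-intensity normalization uses n(n−1)/|W|² (not n²/|W|²); for the
fixed-n binomial process this makes E[K̂(r)] = πr² exact under CSR, which
the test suite verifies to Monte Carlo precision.

Pair correlation function, Epanechnikov kernel k_bw of half-width bw,
divisor-d (Stoyan) variant:

    ĝ(r) = |W|² / (n(n−1)) · Σ_{i≠j} k_bw(r − d_ij) / (2π d_ij A_ij)

Dividing each pair by its own distance d rather than by the bin centre r
avoids the (2πr)⁻¹ blow-up near the origin and makes ĝ exactly unbiased
under CSR at every bin with r ≥ bw. With the defaults — bw = Δr and a grid
starting at Δr — that is every reported bin; a user-supplied bw > Δr
leaves the bins below bw negatively biased, the usual behaviour of kernel
pcf estimators near zero. Coincident pairs (d = 0) have no well-defined
kernel contribution and are skipped. `stoyan_bandwidth` offers the
rule-of-thumb bw ≈ 0.2/√λ̂ as an alternative.

Distance grid default: Δr = 0.05 m, r = 0.05 … 2.5 m — 50 bins, which is
also why the g(r) reliability comparison has df = 49.

## Intensity surface and null models

The heterogeneous Poisson null needs a first-order intensity estimate.
`estimate_intensity` places a radially symmetric Epanechnikov kernel of
radius R (default 1.0 m, chosen to sit below the ~2 m scale of
environmental variation in typical steppe plots while smoothing over
plant-scale clumping) at each point, discretised on cells of R/10, and
renormalises each kernel by its mass inside the window; the surface
therefore integrates to n exactly, an edge correction that prevents
intensity leakage at the boundary.

Envelope tests simulate nsim null patterns conditioned on the observed n:
CSR draws n i.i.d. uniform points; the heterogeneous null draws n points
by rejection sampling against the intensity surface, which is estimated
once from the observed pattern (bandwidth R) and reused for all
simulations. Each simulated pattern is summarised with settings identical
to the observed estimate, and the envelope is the pointwise min–max over
simulations. Classification uses strict inequalities — aggregated above
the upper bound, regular below the lower, ties consistent — so by
exchangeability a bin of a true null pattern is non-consistent with
probability exactly 2/(nsim + 1): 0.01 at the default nsim = 199. The
"aggregated at 0–x m" summary is the largest r below which every bin is
aggregated (likewise for regular).

Seeding: simulation i of a run with master seed s uses the independent
stream `default_rng([s, i])`, making every envelope bit-reproducible.

## Replicates and reliability

Replicated plots are combined as ḡ(r) = Σ wᵢ ĝᵢ(r) with wᵢ = nᵢ²/Σnⱼ².
Pair-count weighting is the natural choice for a second-order statistic,
whose information content scales with the number of point pairs; wᵢ ∝ nᵢ
is available behind a flag. Envelope bounds are combined with the same
weights and the combined observed curve re-classified.

The reliability protocol pairs two measurements of the same plants by
greedy matching over candidate pairs within 5 cm, taken in
increasing-distance order with index tie-breaks — every accepted pair is
mutually nearest among the still-unmatched points, and the matching is
symmetric in its arguments. Paired t statistics (mean, sd, se, t,
df = n − 1, two-sided p) are computed for Δx, Δy over matched pairs and
for Δg over distance bins. Degenerate inputs follow fixed conventions:
all-zero differences give t = 0, p = 1; zero sd with nonzero mean is
flagged as an infinite statistic with p = 0 rather than raising.

## Synthetic data

The generators supply every regime the analysis distinguishes: CSR
(baseline), Thomas clusters (κ = 1 parent/m², μ = 8 offspring, σ = 0.05 m
defaults — an aggregated pattern of ~200 points on a 5×5 m plot, the
density scale of a bunchgrass stand), Matérn type-II hard core (the
overdispersed regime produced by competition), and a linear intensity
gradient λ = a + bx (habitat heterogeneity without interaction; the
default b = 4/m³ on a 5 m plot gives n ≈ 250). Thomas parents are
simulated on a 4σ-buffered window so clusters straddling the boundary are
not deficient.

The photo fixture assigns each true point to its sub-block, projects it
through a synthetic per-cell camera (~1000 px/m, random perspective
displacing image corners by up to 3%), and adds Gaussian pixel noise to
the digitized plant positions only — control-point pixels are exact, as
corner fiducials are located far more precisely than free-hand plant
clicks. Zero noise must round-trip exactly; σ_px = 1 corresponds to ~1 mm
ground error. What the fixtures do not emulate: actual raster imagery,
detection/identification errors (missed or double-counted plants), lens
distortion, and non-planar ground — so passing tests certify the
geometry and statistics of the pipeline, not the field protocol itself.

## Numerical and testing choices

- Monte Carlo checks compare empirical means/fractions within 3 standard
  errors. Where a protocol's expected pass rate is itself the nominal
  level (e.g. "non-significant in 95% of seeds" for an exactly level-0.05
  test), the check requires the observed fraction to lie within 3 binomial
  SEs of the expected rate rather than strictly above it, which a
  correctly calibrated test would fail a third of the time.
- Test problem sizes: calibration uses 500 repetitions of the 199-replicate
  envelope test at n = 100 on the unit square; power and contrast checks
  use 10–40 seeds at the 5×5 m plot scale with ~200–500 points,
  matching the density of the motivating field data.
- Homography fitting tolerances: exact 4-point fits reproject below
  1e−9 m; refitting a forward-applied known matrix recovers corners below
  1e−6 m.
- The envelope test's intensity surface is estimated once, not per
  simulation: re-estimation would inflate envelope width by adding
  estimator noise the observed curve does not carry.

## Limitations

- Only rectangular windows and univariate (single-species) statistics;
  no anisotropy, no cross-type functions, no global rank envelopes.
- The heterogeneous null uses the pattern's own kernel intensity, so at
  smoothing scales near the clustering scale it partially absorbs genuine
  aggregation; the R = 1.0 m default keeps a factor ~10 separation from
  the cluster scales of interest (≤ 0.3 m).
- Numerical equality with GUI point-pattern programs is not claimed; their
  exact estimator variants are undocumented.
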