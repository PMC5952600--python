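# Methods

This note records the models implemented in `coreud`, the parameter choices
behind the synthetic study, and the numerical decisions a maintainer would
otherwise have to reverse-engineer.

## Movement model

The continuous-time correlated random walk treats each planar coordinate as
an integrated Ornstein–Uhlenbeck process: velocity follows
`dv = −β v dt + σ dW`, position integrates velocity, and the two coordinates
share `β` (velocity autocorrelation rate, 1/h) and `σ` (velocity
stochasticity, km/h per √h). The stationary RMS speed of the 2-D process is
`σ/√β`. Observations are positions plus isotropic Gaussian error whose SD is
fixed per Argos location class; by default the class ladder
{3, 2, 1, 0, A, B} carries SDs {0.15, 0.35, 1.0, 1.5, 2.0, 3.0} km and LC Z
is unusable. Only the endpoints of that ladder correspond to published
accuracy bands (< 150 m at LC 3, > 1.5 km at LC B); interior values are
conventional nominal Argos errors and are fully configurable.

Fitting maximizes the exact Gaussian likelihood with a Kalman filter over
the irregular fix times, in log-parameter space with L-BFGS-B (Nelder–Mead
fallback), bounded to `β ∈ [10⁻³, 50] /h` — above ~50/h velocity is
indistinguishable from white noise at telemetry time scales, and unbounded
fits on dwell-heavy tracks can otherwise run away toward that degenerate
limit. Fits at a bound, or with `σ` below 10⁻³, are flagged
(`at_boundary`). The initial state is position ~ N(first fix, 10⁴ km²)
(diffuse) and velocity at its stationary distribution; because both
coordinates share all variances, one covariance recursion serves both
coordinate means.

Imputation draws whole path realizations from the smoothing distribution on
a regular 2-h grid (anchored at the first fix time, truncated at the last)
using the mean-correction simulation smoother: simulate an unconditional
state path and synthetic observations, smooth both, and shift by the
difference of smoothed means. The pointwise average of 500 draws is the
default output, converging to the analytic smoothing mean at the
Monte-Carlo 1/√n rate; the analytic mean itself is exposed separately
(`smoother_pseudolocations`). Pseudolocations that land on land — averaging
and genuine haulout residence both cause this — are moved to the nearest
water-cell center, which for coastal points keeps them within about one
cell of the haulout.

## Utilization distributions

Kernel density estimates use an isotropic bivariate Gaussian kernel
evaluated at the centers of 1 km × 1 km cells (not cell-integrated; at this
resolution the difference is negligible and center evaluation keeps the
brute-force test oracle exact), renormalized to integrate to 1. Grids are
row-major from the NW corner with half-open cells.

The bandwidth maximizes the leave-one-out log predictive density
(likelihood cross-validation). The search is a 60-candidate log-spaced grid
from `cell_size/2` to the diagonal of the point bounding box, refined by a
bounded scalar optimization around the best candidate; ties prefer the
smaller bandwidth. Zero-distance pairs are excluded from each point's LOO
sum so duplicated points cannot drive the bandwidth to zero; fully
degenerate input returns the lower bound with a warning. The upper search
bound is the full bounding-box diagonal because the LOO optimum for widely
separated sparse points (two points at distance d give exactly `h = d/√2`)
can exceed any small fraction of the diagonal.

The pooled, effort-corrected UD multiplies each cell of the pooled-sample
KDE by the fraction of distinct animals with at least one pseudolocation in
that cell, then renormalizes. Cells visited by no animal carry only kernel
spill-over and are left unweighted, which makes the correction an exact
no-op when every animal uses the same cells. The weighting direction and
normalization order are isolated in one function; the bandwidth for the
pooled UD is selected on the pooled point set.

## Home range and core space

The home range is the 95% volume isopleth: the smallest set of
highest-density cells whose cumulative probability reaches 0.95 (density
ties broken by cell index). Cell sets are polygonized as the union of their
square cell boxes rather than by tracing a marching-squares contour — the
raster-faithful polygons have area exactly equal to cell count × cell area,
so raster and vector measurements cannot disagree. Polygons are clipped to
exclude land; haulouts are counted as inside the home range when within one
cell of a polygon, since clipping removes the coastal cells the sites sit
on.

Core delineation fits `A(v) = a·e^{b·v/100}` by nonlinear least squares to
the isopleth-area profile evaluated at 1% steps (volumes 1–99), with both
axes normalized to [0, 1] — volume as v/100, area relative to the area at
the 99% level — so the residual standard error is dimensionless and
comparable across animals. The core boundary is where the fitted slope
equals 1, `v* = 100·ln(1/(ab))/b`. No core is declared when the fitted rate
is non-positive, when v* falls outside (0, 95), or when the profile itself
implies `I = v*/proportion < 1` at v* (a uniform UD, whose area grows
exactly as fast as volume, is the canonical case). The intensity index uses
the land-clipped home-range area in its denominator, consistent with
clipping preceding area calculation. Distances from core to haulout use
core-polygon centroids and planar Euclidean distance.

Bi-monthly bins (JF, MA, MJ, JA, SO, ND) partition the calendar year by
month of pseudolocation timestamp; a sample is eligible for a UD when it
has strictly more than 50 pseudolocations and a pseudolocation-to-raw-fix
ratio strictly below 3. When a track is split across bins the raw-fix count
is apportioned by the share of pseudolocations per bin.

## Model selection

Akaike weights are `exp(−ΔAIC/2)` renormalized over the candidate set. The
final model set keeps candidates with ΔAIC < 6 (strict) that are not nested
versions of a simpler model with equal-or-lower AIC. Nesting compares
interaction-expanded term sets: an interaction label (`Season:Sex`, with or
without a smooth wrapper `s(...)`) implies its main effects, so
`Region + s(Season)` counts as nested within `Region + s(Season:Sex)`.
Relative importance, by contrast, uses literal term membership — an
interaction does not transfer support to its main effects — matching how
published importance tables are usually tallied. Importance can be computed
from weights renormalized over the final set (default) or from supplied
weights passed through unchanged; with rounded published weights the
passthrough sum for a term present in every model can fall slightly below
1 (e.g. 0.99), which is reported as-is rather than corrected.

## Synthetic data: what it emulates and what it does not

The generator produces a single connected land mass with a smooth random
coastline on a planar equal-area grid (default 100 × 100 km, 1-km cells),
haulout/rookery sites on land–water boundary cells, and central-place
movement: stationary dwell bouts at a haulout alternating with at-sea trips
integrating the OU velocity at a 0.1-h internal step (finer than the 2-h
imputation grid, so discretization is negligible), reflected off the coast
by velocity reversal. Trips end with a deterministic ~6 km/h homing pull
toward the nearest haulout so paths stay continuous and concentrated use
forms where real pinniped cores form. Dwell and trip durations are
exponential; dwell draws are clipped at 3× their mean because animals must
return to sea to feed, and unclipped exponential tails would generate
multi-day transmission silences that the >4-day gap rule then amputates
mid-track.

Observation emulates a saltwater-switch duty cycle: fast fix repetition
while wet, slow while dry, and silence once continuously dry longer than
the 6- or 12-h preset. Location classes are drawn from a configurable
frequency table (the class mix of real deployments is not standardized), a
configurable fraction is relabelled LC Z, and multi-day outage gaps are
injected in the final third of a deployment — where failing batteries and
imminent tag shedding put them in real data, and where the truncation
rule's keep-the-front behaviour is the appropriate response.

Default dynamics (β = 1/h, σ = 4 km/h per √h, i.e. RMS speed 4 km/h; dwell
mean 18 h, trip mean 12 h) describe a strongly coastal, frequently
hauled-out juvenile otariid. The end-to-end smoke scenario uses an even
more anchored configuration (dwell 24 h, trip 6 h), under which every
core polygon forms within a few kilometres of a haulout.

Not emulated: prey fields and foraging decisions, tidal haulout
availability, behavioural-state switching, anisotropic or autocorrelated
observation error, and Argos error's heavy tails. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to everything field data can do. One known mismatch
is informative: CTCRW fits to dwell-heavy synthetic tracks inflate β and σ
(the single-process model must reconcile stationary dwells with at-sea
transit), occasionally to the β bound; parameter recovery is therefore
validated on tracks simulated from the state-space model itself, while the
pipeline treats the movement model as an interpolation device, as is
standard practice.

## Problem sizes

The test suite validates likelihood equality on ≤ 8-fix tracks (tolerance
10⁻⁶ against a joint-covariance Gaussian oracle), parameter recovery on 20
replicates of 2000-fix tracks (mean bias < 15%), KDE agreement with a
double-loop oracle on ≤ 500 points (10⁻¹⁰ relative), isopleth areas of
sampled Gaussians against closed forms (−2πσ²ln(1−p)), and an end-to-end
study of 6 animals × 60 days with 50-draw imputation. The analysis scripts
default to 8 animals × 120 days with the full 500-draw imputation.
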