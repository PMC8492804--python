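# Methods

`quorumdim` analyzes how combinations of two acyl-homoserine-lactone (HSL)
signals — C8HSL and 3OC6HSL in the *Vibrio fischeri* quorum-sensing
circuit — reshape the full statistical distribution of single-cell reporter
activity, not just its mean. The pipeline treats each measured
per-condition histogram as a point on a sphere, finds the low-dimensional
manifold those points occupy, collapses it to a single arc-length
coordinate S, and derives the input distribution to which the pathway is
maximally sensitive.

## Histogram embedding

All single-cell green-fluorescence values for one reporter (every input
condition pooled) define a 20-bin equal-occupancy binning: interior edges
sit at the k/20 empirical quantiles (linear interpolation between order
statistics) and the outer bins are unbounded, so a frozen scheme can
histogram any later value. Bins are half-open `[lo, hi)`; a value equal to
an edge falls in the upper bin. Each condition's histogram is a
probability vector p over those shared bins, and the square-root map
q_i = sqrt(p_i) places it on the unit sphere in bin space (Σ q_i² = 1).
On the sphere, Euclidean distance between two embedded histograms is the
chord distance and the great-circle angle `arccos(q_a · q_b)` is the
information-geometric distance; dot products are clamped to [−1, 1] before
`arccos` for floating-point safety.

Pipeline order is: aberrant-cell exclusion → area correction → edge
finding → per-condition histograms. Edges are therefore computed from the
cleaned, corrected values.

## Preprocessing

*Exclusion.* Within each condition, cells whose green fluorescence has
robust z-score `|x − median| / (1.4826·MAD)` above `z_max` (default 6) are
removed. The threshold is deliberately loose: it should catch only
grossly aberrant cells (well under 1% at realistic noise), not trim the
skewed tails that carry real signal. If the MAD degenerates to zero while
values still differ, an IQR rule (`|x − median| > z_max·IQR/1.349`) takes
over; an all-identical condition loses nothing. Exclusion is judged per
condition because the per-condition distributions differ by design.

*Area correction.* At conditions where reporter expression is very weak,
green fluorescence tracks cell size rather than promoter output. The
correction slope is fit by pooled ordinary least squares of green on area
over the conditions whose mean green lies in the lowest quintile
(`low_expression_quantile = 0.2`) of condition means, then `slope · area`
is subtracted from every cell's green value. The transformation is linear
and invertible; corrected values may go negative, which the binning
handles. The correction is exposed as a per-dataset switch since a
two-color reporter motivates it most directly.

## Linear PCA

PCA is computed on the mean-centered, unscaled q vectors, one point per
condition (unweighted by cell count), via SVD. Centering is adopted —
"variance explained" language presupposes it — and each loading's
largest-magnitude entry is made positive so signs are deterministic across
platforms. Scores, loadings and explained-variance fractions are emitted
per component.

## Hierarchical nonlinear PCA

The nonlinear analysis fits an autoassociative network in a d:h:n:h:d
configuration (d = 20 bins, h = 10 hidden units, n ≤ 5 bottleneck
components), tanh on the two hidden layers, linear bottleneck and output.
Hierarchy is enforced by component masking: the training loss sums, over
k = 0..n, the mean squared reconstruction error obtained with bottleneck
units k+1..n zeroed, plus a weight-decay penalty 0.001·Σw² (biases
undecayed). Because every prefix of components is trained to be the best
representation of its size, component i of an n-component model does not
change materially as n grows (stability), and explained variance is
non-decreasing in the number of active components (scalability). The
k = 0 term anchors the decoder's constant at the data center, making the
zero-component reconstruction a meaningful baseline (explained variance
≈ 0) instead of an untrained extrapolation.

Inputs are centered and rms-scaled as a whole (one global scale, so
relative bin shapes are untouched) before training; this gives the decay
coefficient a data-independent relative strength, and explained variance —
reported as 1 − SSE/SS_total in the original embedded space — is invariant
to it. Training is full-batch L-BFGS with analytic gradients from
multiple random initializations (default 20 restarts; autoencoder losses
are multimodal) and is deterministic given the seed. Varying the hidden
width between 5 and 20 leaves the explained variance within one percentage
point on the synthetic datasets; this ships as a regression test. With
linear activations the model recovers linear PCA's explained-variance
ladder, a useful sanity anchor.

## The S coordinate

The first nonlinear component traces a curve through histogram space: the
decoder image of a 512-point sweep over the span of the training latents,
renormalized onto the unit sphere (the raw network output need not lie on
it). Cumulative chord length along this polyline, rescaled to [0, 1],
defines S; each condition's S is the normalized arc length at its own
encoded latent (linear interpolation along the sweep). Equal increments
in S therefore correspond to equal distances between the underlying
histograms. Orientation is fixed so the zero-input condition sits at the
S = 0 end. Arc length is purely geometric: monotone re-indexing of the
sweep leaves S unchanged, and refining the sweep from 512 to 2048 points
moves no condition's S by more than 1e−3.

S is interpolated over the input plane bilinearly in transformed axis
coordinates u(c) = c/10 for c ≤ 10 and 1 + log10(c/10) above (threshold 10
in each axis's native unit, pM or nM; zero maps to u = 0 on the linear
segment). No extrapolation outside the measured grid.

## Maximum-information input prior

A deterministic response transmits the most information when all output
values are equally probable, so the sensitivity map is the input prior
whose pushforward through S is uniform. By the coarea formula, weighting
each cell of the S surface by |∇S| (gradient in the transformed
coordinates) concentrates mass where the response is steep; partitioning
cells into `n_s_bins = 20` equal-width S bins and renormalizing each bin
to carry mass 1/n_s_bins then flattens the output exactly. The per-bin
step is required in two dimensions, where level-set length varies.

Discretization: the surface is resampled at the centers of an equal-area
cell grid, and each cell's weight is split across the S bins its S-span
overlaps (span estimated from the local gradient — linear binning). This
makes the construction's pushforward uniform to machine precision and
meets the analytic benchmarks (uniform prior for a linear S; marginal 2x
for S = x²) to O(1/refine). Empty S bins hand their mass share to the
adjacent non-empty bins and are reported.

Two caveats are deliberate. Mutual information itself is not computed:
for a noise-free deterministic map it is unbounded, so the flat-pushforward
criterion is the operational definition. And the prior is *not* invariant
under non-affine monotone reparameterization of the output — flattening
g(S) reweights the prior by g′(S) — so S's arc-length normalization is
part of the definition; tests verify the affine invariance and the
Jacobian reweighting relation rather than a false general invariance.

## Two-reporter calibration

Two sensor strains with complementary HSL preferences are calibrated as
bilinear luminescence surfaces over the same transformed coordinates.
A pair of readings is inverted by grid search plus Nelder-Mead refinement
of the log-compressed objective Σ (log(1+r_i) − log(1+cal_i(c)))² —
luminescence spans orders of magnitude, so raw least squares would let the
bright surface dominate. Two monotone surfaces generically determine two
concentrations, but flat regions yield ridges: boundary-touching solutions
are flagged and local minima within 5% of the best residual are reported
rather than hidden. Exactly realizable readings are recovered with
residual ≤ 1e−9 and within one refined grid cell.

## Synthetic data

The generator emulates the structure the analysis assumes, with known
ground truth. A latent activation t(c1, c2) = clamp01(w1·h1 + w2·h2 +
w12·h1·h2) combines two Hill terms (the w12 cross term is the crosstalk);
defaults w1 = 0.5, w2 = 0.3, w12 = 0.2 keep t strictly below 1 so no two
conditions tie. Per-cell green fluorescence is gamma-distributed with
shape and scale linear in t, so mean, variance and skewness co-vary along
one curve — the one-dimensional family the NLPCA should recover. The qrr
preset (7×7 grid, C8HSL in pM) shuts off with rising t (shape 9→3, scale
30→12, mean ≈ 270→36 a.u.); the lux preset (7×8 grid) turns on (shape
2.5→6.5, scale 15→40). Hill constants sit mid-grid (qrr: K = 40 pM /
30 nM; lux: 60 / 40 nM) so the latent sweeps most of [0, 1). Cell areas
are lognormal (median 40 px, σ = 0.3) and a leak of 0.3 a.u./px enters the
green channel, giving the area correction something real to remove; a
constitutive red channel is included for the qrr-like preset. Defaults use
400 cells per condition, matching the measured datasets' scale.

What the generator does *not* claim: the real histograms are poorly fit by
standard families including the gamma, so passing recovery tests shows the
pipeline recovers a one-dimensional latent structure under realistic
sample sizes and skewness — not that real *V. fischeri* histograms are
gamma. An optional two-component gamma mixture provides non-gamma shapes
for robustness checks.

## Problem sizes and determinism

Default analysis settings reproduce the study conditions: 20 bins, 10
hidden units, 20 restarts, 512-point sweep, refine = 200, 20 S bins.
Tests and the acceptance script use 6–10 restarts for the synthetic
recovery runs — the fits are already stable there — and the full test
suite completes in about a minute on one CPU. One global seed fans out to
per-stage seeds through a fixed counter, so any stage can be rerun in
isolation; reruns are byte-identical.

## Known limitations

- One histogram per condition; duplicate histograms per condition are not
  modeled.
- No kernel density estimation or adaptive bin counts; 20 equal-occupancy
  bins are the fixed convention (configurable).
- The flat-output prior assumes a noise-free response surface; no
  channel-capacity estimation with explicit noise models.
- Fit-error-based cell exclusion (image-segmentation residuals) is outside
  the data model; exclusion uses fluorescence only.
- The inversion procedure for paired sensor readings is this package's
  declared choice; flat response regions make estimates there
  ridge-degenerate, which is reported, not resolved.
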