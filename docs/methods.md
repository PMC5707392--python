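# Methods

## The problem

Sub-pixel particle tracking estimates a spot's center from the intensities
of a handful of pixels around its brightest pixel.  When the refinement
window is small (a circular window of radius R, spanning W = 2R + 1
pixels), the estimate is systematically pulled toward the center of the
candidate pixel — *pixel locking*.  The diagnostic is the **meta-pixel**:
pool the fractional parts `frac(x̂) = x̂ − ⌊x̂⌋` of many localizations into
the unit interval, per axis.  If the true sub-pixel positions sample the
pixel uniformly and the estimator is unbiased, the meta-pixel is uniform;
locking shows up as density compressed toward 0.5.

## The SPIFF correction

Let F be the empirical CDF of the estimated fractional parts on one axis.
The corrected fractional part of an estimate x̂ is

    frac_corrected = F(frac(x̂)),        x̂_corrected = ⌊x̂⌋ + F(frac(x̂))

By the probability-integral transform the corrected fractional parts are
uniform for *any* continuous input distribution, and if the estimator's
bias is a monotone deterministic map g of the true fractional position
(with uniform truth), F = g and the correction recovers the truth exactly.
Relative to the pixel center the map reads F(x) − 1/2, which reduces to the
signed-integral form of the correction when the density is symmetric about
the center; the CDF form also handles the skewed meta-pixels that arise at
small interparticle separations.  Implementation choices:

- F is the empirical CDF with **linear interpolation between order
  statistics** (Hazen plotting positions, ties collapsed), pinned to
  F(0) = 0 and F(1) = 1.  No histogram binning enters the correction path;
  binning (default B = 20 equal-width bins) is used only by the chi-square
  uniformity diagnostic.  Corrected fractions are clipped below 1 so the
  integer pixel assignment is always preserved.
- Axes are corrected **independently** (x-map from x-fractions, y-map from
  y-fractions); the correction is one-dimensional per axis and no joint 2D
  map is attempted.
- By default all particles of a movie are **pooled** into one meta-pixel,
  which maximizes sample density; per-particle maps are available by
  passing per-particle subsets.  In the static two-particle benchmark the
  map is built from the mobile particle only, because the anchored
  particle's true sub-pixel position never varies and would violate the
  uniform-truth premise.
- `fit_spiff_map` refuses fewer than **min_samples = 500** points per axis
  (the sup-norm CDF noise ~ n^(-1/2) would rival the 0.2–0.4 px biases
  being corrected) and refuses a zero-width density outright: complete
  locking destroys the information needed to invert the map.
- A verdict of "locked" is declared when the chi-square p-value against
  uniformity falls below 10⁻³ on either axis.

## Trackers

The trackers implement the single-pass class whose locking the correction
targets.  Candidates are local intensity maxima above a percentile
threshold (default 99.5), pruned brightest-first to a minimum separation
(default 2R).  Refinement runs once, in a circular window (pixels with
integer offset norm ≤ R; R = 1 gives the five-pixel "Swiss cross"),
without iterative re-centering — iteration would alter the bias being
studied:

- **centroid** — background-subtracted intensity-weighted mean, with the
  background taken as the median of the window's perimeter pixels and
  negative residuals clipped.
- **gaussian_fit** — Levenberg–Marquardt least squares of a point-sampled
  symmetric 2D Gaussian plus constant offset (5 parameters), initialized
  at the centroid.  Fits that do not converge, or whose center leaves the
  window, fall back to the centroid result and are flagged.  On the R = 1
  window the system is exactly determined (5 pixels, 5 parameters), so a
  substantial fraction of noisy fits take the fallback path; this is the
  realistic behavior of tiny-window Gaussian fitting rather than a defect.

Coordinates follow the pixel-center convention: pixel (i, j) spans
[i, i+1) × [j, j+1) with center (i + 0.5, j + 0.5).

## Synthetic data

Every benchmark is generated internally so ground truth is exact.

- **Renderer** — each spot is an amplitude-A Gaussian of width σ_px
  integrated over each pixel's area (separable erf differences), so a spot
  at a pixel center is exactly reflection-symmetric and the total signal
  is A·2πσ² counts.  Noise: Gaussian background (mean 100, SD 4 counts)
  plus optional Poisson shot noise on the signal; intensities clipped at
  zero and quantized to 16-bit only on TIFF export.  Defaults: σ_px = 1.0,
  A = 43 (peak ≈ 10× the background SD), shot noise on.
- **Static pair** — particle 1 fixed at the center of its anchor pixel,
  particle 2 drawn per frame from an axis-independent normal centered 5 px
  away (σ_x = 2, σ_y = 1 px).  Frames are independent; this isolates the
  window-size vs. identification tradeoff.
- **Trapped pair** — two particles in independent harmonic traps,
  simulated as exact-discretization Ornstein–Uhlenbeck processes.
  Defaults: stiffness 1.63 µN/m per axis (stationary SD ≈ 0.7 px at 300 K
  and 72 nm pixels), friction 1.41 ns·N/m (Stokes drag of a 150 nm sphere
  in water), rest separation 6.5 px, 3,200 frames at 0.5 µs.  At this time
  step the per-frame displacement is ~0.02 px — deeply sub-pixel — while
  the trajectory diffuses across ~2–3 pixels over the run, so the
  meta-pixel is filled by the path rather than by independent draws.
  Optical interactions between the particles are not modeled; the
  surrogate reproduces only the positional statistics that matter to
  sub-pixel bias.
- **Transport** — drift–diffusion of a single emitter (defaults
  D = 10 px²/s, v = 5 px/s along x at 100 nm pixels, i.e. 0.1 µm²/s and
  0.5 µm/s), rendered at 2000 FPS and downsampled ×100 to 20 FPS by
  keeping every 100th frame and scaling the frame interval.

What the generator does **not** emulate: EMCCD gain statistics, astigmatic
or otherwise aspherical PSFs, motion blur within an exposure, stage drift,
and optical (light-mediated) interparticle forces.  Passing benchmarks
therefore demonstrate correctness of the estimators and of the correction
under idealized imaging, not performance on any particular camera.

## Metrics

- **MSD** uses time-averaged overlapping displacement pairs,
  MSD(τ) = ⟨|x(t+τ) − x(t)|²⟩_t, with gap frames excluded pairwise and the
  pair count reported per lag so non-overlapping estimates can be
  reconstructed.  MSD(0) = 0 by convention.
- **Pair series** report Euclidean separation and the ordered-pair angle
  atan2(Δy, Δx) in degrees in (−180°, 180°], with physical units via the
  pixel size.  Frames missing either particle are dropped.
- **Localization error** is the per-frame Euclidean distance between a
  tracked trajectory and its ground-truth particle, with identity fixed by
  nearest neighbor at the first common frame (ties broken by index).  In
  the benchmark scenarios, localizations are instead assigned to truth
  particles per frame, greedily in order of increasing distance, which is
  unambiguous at the ~6.5 px separations used.
- **Second-tier separation correction**: the residual separation error
  varies with the true separation (spot overlap grows as particles
  approach).  The mean (apparent − true) separation is binned in
  equal-count bins of true separation (default 20), fitted with a cubic
  polynomial, and subtracted at the apparent separation; evaluation
  outside the fitted domain clamps to the edge and warns.

## Benchmark scenarios and problem sizes

`run_scenario` chains simulate → render → track → correct → measure with
all randomness split deterministically from one seed, and reports carry a
config hash so any number can be regenerated.  The standard sizes are 10⁴
frames (static pair, 24×32 px), 3,200 frames (trapped pair), and 10⁴
frames (transport, 96×192 px); each completes in a couple of minutes on
one core, with the Gaussian fits dominating.

## What the correction can and cannot fix here

Two findings from the benchmarks are worth stating explicitly.

First, the correction is *distributional*: it restores a uniform
meta-pixel for any continuous input (measured KS distance to uniform drops
from ~0.06 to ~0.01 on the benchmarks, and below 0.02 for every analytic
bias shape in the test suite), and when the estimator error is a monotone
deterministic bias it recovers the true positions (the affine-compression
oracle: 0.15 px mean error → <0.01 px).

Second, at the default synthesis conditions the *mean localization error*
of the Gaussian-fit tracker is dominated by photon noise, not by bias.
With ~270 signal photons per spot the shot-noise-limited precision is
≈ 0.1 px per axis even for a full-frame estimator, and ≈ 0.17 (R = 2) to
0.29 px (R = 1) for windowed fits; a free-parameter least-squares Gaussian
fit is empirically unbiased on noiseless pixel-integrated data at any σ,
so its meta-pixel compression is mild.  CDF remapping cannot remove
independent per-frame noise, so the corrected mean error on the
trapped-pair benchmark stays near the windowed noise floor (~0.25 px
averaged over R = 1, 2) instead of dropping toward ~0.1 px, and the mild
locking never empties whole 1° bins of the interparticle-angle
distribution.  Deep, correctable locking requires bias-dominated error —
brighter spots or more strongly biased estimators (e.g. truncated moment
centroids at high SNR).  The distinction matters when interpreting the
trapped-pair numbers: before correction they match the severity expected
of small windows, but the error budget behind them is noise-heavy, and the
correction's mean-error gain is correspondingly small.

## Known limitations

- No correction for misidentification or undercounting: frames where a
  particle is missed stay missed (this is outside what a sub-pixel
  remapping can do).
- The greedy mutual-nearest-neighbor linker has no gap closing or motion
  model; it is adequate for the well-separated benchmark geometries only.
- Per-axis (separable) correction cannot repair a bias that couples x and
  y within a pixel.
- The uniformity verdict is a null-hypothesis test: with enough samples it
  flags even negligible non-uniformity; the KS distance should be read
  alongside it as an effect size.
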