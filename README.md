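# spifftrack

Sub-pixel particle tracking with meta-pixel diagnostics and SPIFF
pixel-locking correction.

## The problem

Single-particle tracking localizes spots — trapped nanoparticles, single
fluorophores — to a fraction of a pixel by refining intensities inside a
small circular window of radius R (window size W = 2R + 1).  When the
window is small, the image noisy, or particles closely spaced, the
estimated sub-pixel positions are biased toward pixel centers.  This
*pixel locking* corrupts every downstream quantity: interparticle
separations develop spurious spikes, some interparticle angles become
"forbidden", and mean-square displacements (MSD) are distorted.

The diagnostic and the cure both live in the **meta-pixel**: pool the
fractional parts {x̂ − ⌊x̂⌋} of many localizations into the unit interval,
per axis.  Unbiased tracking fills it uniformly.  The SPIFF (Single-Pixel
Interior Filling Function) correction maps each estimate through the
empirical CDF F of the meta-pixel,

    x̂_corrected = ⌊x̂⌋ + F(x̂ − ⌊x̂⌋),

which makes the corrected fractional parts uniform and, for a monotone
estimator bias, recovers the true sub-pixel positions.

The package provides, for anyone who tracks sub-resolution objects in
video microscopy:

- `synthdata` — ground-truth generators (static particle pairs,
  harmonically trapped pairs via Ornstein–Uhlenbeck dynamics,
  drift–diffusion transport) and a pixel-integrated Gaussian-PSF renderer
  with realistic noise, so every claim is testable against exact truth;
- `tracking` — the affected tracker class: percentile + local-maximum
  detection, centroid and Gaussian-fit refinement in circular windows,
  nearest-neighbor linking;
- `spiff` — meta-pixel construction, chi-square/KS uniformity diagnosis,
  empirical-CDF map fitting and application;
- `metrics` — MSD, separation/angle pair series, tracked-vs-true error,
  and a second-tier cubic fit of the separation-dependent residual bias;
- `scenarios` — end-to-end benchmarks gluing the above together, fully
  seeded and reproducible;
- a thin `spifftrack` CLI (`simulate | render | track | spiff | metrics |
  benchmark`) over the same functions.

## Worked example

`examples/meta_pixel_diagnosis.py` builds a biased estimator directly —
uniform true positions whose fractional parts are compressed toward the
pixel center by a factor 0.4 — then diagnoses and corrects it:

```
$ python examples/meta_pixel_diagnosis.py
meta-pixel of 10000 estimates: chi2_x = 15012 (p = 0.00e+00), KS_x = 0.300, verdict: locked
after SPIFF: chi2_x = 0 (p = 1.00), KS_x = 0.000, verdict: not locked
mean |error|: 0.149 px biased -> 0.004 px corrected
```

The chi-square statistic (20 equal bins, 19 dof) and the
Kolmogorov–Smirnov distance measure how far the meta-pixel is from
uniform; "locked" means chi-square p < 10⁻³.  The biased estimates are
0.15 px off on average (the analytic value for this compression); after
the correction the residual error is set by the finite sample alone.

`examples/two_particle_windows.py` runs the imaging pipeline end to end —
render two spots ~5 px apart, detect, Gaussian-fit — and shows the window
tradeoff:

```
$ python examples/two_particle_windows.py
R=1 (window 3x3): two particles identified in 88.1% of frames; meta-pixel locked (chi2_x=185, p=3.5e-29)
R=2 (window 5x5): two particles identified in 76.4% of frames; meta-pixel uniform (chi2_x=24, p=2.1e-01)
```

Small windows keep close pairs separable (more frames with both particles
found) at the price of sub-pixel bias; large windows invert the tradeoff.
The other examples (`trapped_pair_correction.py`,
`transport_frame_rate.py`) cover the trapped-pair error benchmark and the
frame-rate regime in which the correction does/does not improve the MSD.

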