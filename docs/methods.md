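# Methods

## Signal model and concentration conversion

DSC-MRI acquires rapid T2\*-weighted frames while a gadolinium bolus
transits the brain. Susceptibility effects raise the transverse relaxation
rate, so signal drops as contrast arrives:

    S(t) = S_base * exp(-TE * dR2*(t)),    dR2*(t) = -ln(S(t)/S_base) / TE.

TE is carried in milliseconds, so dR2\* is in 1/ms. dR2\* is proportional to
contrast concentration with an unknown tissue-dependent constant; since rCBV
normalizes by a white-matter reference, the constant (and the unit) cancels
and no absolute calibration is attempted. The baseline S_base is the
per-voxel *mean* over the pre-bolus window (no robust estimator: the window
is short and outlier-free after the saturated frames are dropped).
Negative dR2\* (signal above baseline, the T1 signature of leakage) is
deliberately retained — flooring it would destroy the very lobe the leakage
correction fits. Voxels with non-positive signal at any frame cannot be
log-transformed and are excluded from the analysis mask.

## Bolus delineation

The first-pass bolus is a dip in the brain-average signal–time curve. The
first 3 frames (default) are discarded as saturation-distorted. A continuous
wavelet transform with the Ricker (Mexican-hat) wavelet is computed at
scales 1–12 frames; local extrema of the coefficients at each scale are
linked across adjacent scales within ±2 samples, and ridges persisting over
at least 3 scales are retained. Extrema within one scale-width of the curve
ends, or weaker than 1e−6 of the curve range, are treated as numerical
noise — this makes a straight line feature-free, and makes detection
invariant to positive rescaling and constant offsets (the Ricker wavelet has
zero mean). The trough is the base position (smallest linked scale) of the
minimum ridge with the largest summed |coefficient| (ties break to the
earlier position), snapped to the minimum of the 3-frame-smoothed curve
within ±2 frames, since the ridge localizes only to a sample or two.

Entrance and exit are the nearest local maxima of the smoothed curve before
and after the trough. "Local maximum" is evaluated with a flatness
tolerance of 3× a robust noise scale (median absolute first difference of
the smoothed curve, scaled to SD), so the end of a flat, noisy pre-bolus
plateau is found instead of the search random-walking backwards through
plateau noise. The baseline window is [0, entrance−1].

Per-voxel integration bounds (optional) are re-located on each voxel's raw
concentration curve within ±3 frames of the global bounds: the entrance
takes the latest frame attaining the windowed minimum and the exit the
earliest, so the bounds hug the first pass. A voxel whose peak does not rise
3 baseline-SD above its baseline (flat or noise-only) keeps the global
bounds.

## Leakage correction and CBV

Where the blood–brain barrier is disrupted, extravasating contrast adds a
T1-driven negative (and a residual T2\*-driven positive) component to
dR2\*(t). The standard reference-curve linear model expresses a voxel curve
through the average curve of non-enhancing tissue:

    dR2*_voxel(t) ≈ K1 * ref(t) - K2 * cumint(ref)(t)
    corrected(t)  = measured(t) + K2 * cumint(ref)(t)

fitted per voxel by ordinary least squares from the bolus entrance to the
last frame (leakage expresses in the tail; pre-bolus frames carry no
information). The running integral uses cumulative trapezoids at the frame
spacing — the same quadrature as the CBV integral, so a generatively leaky
phantom voxel is recovered to machine precision without noise.

The non-enhancing reference mask is the brain mask minus the tumor ROI minus
voxels whose late tail (last quarter of the series, past recirculation)
deviates from zero by more than 2 baseline-SD **plus 2 % of the voxel's peak
|dR2\*|**. The 2 % floor exists because a noiseless curve has zero baseline
SD and would otherwise always "deviate"; 2 % sits an order of magnitude
above the residual recirculation tail of a healthy curve and well below the
accumulated K2 term of a leaky one.

CBV is the trapezoidal integral of the corrected curve between entrance and
exit, computed directly on the dynamic frames (no resampling, no
gamma-variate refit). Negative CBV values are retained in the maps —
clipping would bias downstream Bland–Altman comparisons — and only excluded
where a caller's mask excludes them.

## White-matter reference and rCBV

Automatic WM selection clusters the post-entrance concentration curves:
curves are z-scored per frame, reduced by PCA to the components explaining
95 % of variance (bandwidth estimation on ~30-dimensional raw curves is
unstable), and clustered with flat-kernel mean shift. The default bandwidth
is 0.5× the median pairwise distance of a seeded 500-voxel subsample,
keeping the automatic path parameter-free. The WM probability map (from any
population atlas, registered to the DSC grid by external tooling —
registration is deliberately out of scope) gates the result: among voxels
with probability ≥ 0.95 ("at least 95 %", inclusive), the cluster with the
largest count of such voxels wins (ties to higher mean probability), and
the ROI is that cluster's high-probability voxels outside the tumor ROI.
The automatic path excludes only the tumor ROI itself, not the whole
hemisphere. The manual path intersects a user-drawn label with the brain
mask and subtracts the tumor ROI.

rCBV divides the corrected CBV map by the mean corrected CBV over the WM
ROI; the WM mean rCBV is exactly 1 by construction. ROI summaries are the
mean and the 95th percentile with linear interpolation between closest
ranks (the rule is recorded in the output, because the hot-spot statistic is
sensitive to it).

## Tumor ROI

From a user-supplied generous boundary on the post-contrast T1-weighted
image (already on the DSC grid), the classic Otsu threshold is computed on a
256-bin histogram of the boundary's intensities; voxels at or above the
threshold are kept and the largest 3D connected component survives. The
result is invariant to affine intensity rescaling. Note the between-class
variance is flat across empty histogram bins, so the threshold position
within a bimodal gap is arbitrary while the partition is not; tests compare
achieved objective, not raw threshold. No necrosis exclusion is applied.

## Agreement statistics

Bland–Altman: bias = mean(a−b), limits of agreement = bias ± 2·SD (sample
SD, n−1); 2·SD rather than 1.96·SD is used throughout. ICC uses the one-way
random-effects model: ICC(1,1) = (MSB − MSW)/(MSB + (k−1)·MSW) from the
one-way ANOVA mean squares of a complete n×k table; the average-measure
form ICC(1,k) is available by flag. Degenerate tables (zero total variance)
raise rather than return an arbitrary 0 or 1.

## Synthetic phantom

The generator emulates a standard 1.5/3 T glioma DSC protocol: 40 frames at
2.2 s spacing, TE = 60 ms, the first 3 frames inflated by saturation factors
(1.5, 1.2, 1.05), baseline plateau, and a bolus appearing 25 s after
acquisition start. The first pass is a unit-area gamma variate
(α = 3, β = 1.5 s; peak ≈ 4.5 s after onset) scaled so the WM peak dR2\* is
0.010 /ms (≈ 45 % signal drop at TE 60 ms); a recirculation bump (25 %
amplitude, β = 3 s, delayed 12 s) follows, so a genuine exit maximum exists
between the passes. Geometry is a 32×32×8 grid: a 2-voxel gray-matter band
around a white-matter core with an embedded tumor sphere (radius 5).
CBV multipliers are WM 1, GM 2, tumor 3; baselines 400/500/450 signal units
(background 50); Gaussian noise SD 5 by default (baseline SNR 80–100; tests
use SD 20 and 13.3 for SNR 20 and 30 conditions). Tumor leakage is generated
with the same linear model the correction fits (K2 = 0.02 /s by default,
against the discrete trapezoidal cumulative of the sampled reference), which
makes noiseless K1/K2 recovery exact — a deliberate choice that sharpens the
oracles; a model-mismatch leakage is *not* the default and real leakage
kinetics are nonlinear.

What the phantom does **not** emulate: anatomy, partial-volume mixing,
motion, steady-state contrast retention in healthy tissue (the simulated
first pass returns fully to baseline, which is what lets the tail rule
separate leaky voxels so cleanly), arterial voxels, or vendor-specific
signal nonlinearity. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not clinical performance.

## Numerical and design notes

- Internal axis order is (t, z, y, x); NIfTI I/O transposes to/from the
  on-disk (x, y, z, t). Maps are written float32. Header frame spacing is
  trusted only when the header declares a time unit (sec/msec/usec).
- Grid compatibility = equal shapes and affines within 1e−3.
- When no brain mask is given, one is derived by Otsu on the temporal mean,
  keeping the largest connected component.
- Mean shift is run with bin seeding on the PCA-reduced features; all
  randomness (bandwidth subsampling) is seeded, so runs are bit-reproducible.
- Problem sizes in the test-suite and acceptance script (32×32×8 grids, 100
  detection replicates, 500 leaky voxels, 8-phantom cohorts) were chosen as
  the smallest sizes at which the measured rates are stable to a few
  percent across seeds.
- The ICC comparison of corrected vs uncorrected rCBV across a phantom
  cohort varies the tumor blood volume across subjects (multiplier uniform
  in [2, 4]); without between-subject variance a one-way ICC is dominated
  by the systematic method offset and is uninformative.

## Known limitations

- Exit detection needs a recirculation (or any post-bolus) local maximum; a
  pure monotone recovery to baseline yields a plateau-end exit that is less
  sharply defined.
- The leakage fit is plain OLS; heteroskedastic concentration noise (noise
  grows as signal drops) widens true coefficient variance beyond the naive
  OLS standard errors by up to ~2× at the bolus trough.
- DICOM input is a thin adapter for single-frame 2D+t directories; mosaic
  and vendor perfusion formats are unsupported.
- No AIF detection or deconvolution (by design: normalization-based rCBV),
  no percent-signal-recovery or mean-transit-time maps.
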