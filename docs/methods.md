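# Methods

This note records the models, conventions, numerical choices and known
limitations of the package, in the order the pipeline runs.

## Conventions

Axis order is (z, y, x) everywhere, indices are 0-based, and a pixel's
coordinate is its center. Default physical pixel size is
(0.97, 0.485, 0.485) µm, the sampling of the motivating light-sheet
datasets; movies are (T, Z, Y, X). The analysis window around a
candidate spot is 9×11×11 px.

## Synthetic spots

A spot voxel's mean field is an anisotropic Gaussian (default widths
σ = (1.5, 1.3, 1.3) px, reflecting the ~2:1 z-anisotropy of light-sheet
sampling) plus a constant offset plus an exponential gradient
`g·exp(−(r−r₀)·d̂/L)` with decay length L = 10 px and random unit
direction d̂; the gradient is normalized to value `g` at the voxel
center so it is directly comparable to the offset. Per-pixel Poisson
noise is applied to the mean field. The constant offset defaults to
100 photons, a realistic camera-background level chosen once for all
synthetic conditions.

Ground truth for accuracy assessment is the noiseless Gaussian summed
over the same 4×4×4 px integration ellipsoid the pipeline uses, so the
measured/true comparison isolates measurement error from aperture
choice.

Two observable coordinates parameterize difficulty: signal:background
(mean background-subtracted spot intensity over the ellipsoid divided by
the local background) and structuredness (variance-to-mean ratio of the
background shell pixels; 1 for flat Poisson background). A deterministic
calibration inverts the noiseless mean field to find the (spot
amplitude, gradient amplitude) pair that realizes a requested operating
point, averaging over a fixed set of gradient directions; the
experimental operating point used throughout is (0.35, 40).

## Detection

Bright non-tissue regions are masked by Gaussian blurring and
thresholding (an error is raised if the mask would cover the whole
volume). Candidates come from a Difference of Gaussians applied to each
2D z-slice independently (defaults σ_small = 1 px, σ_large = 3 px,
sized to a diffraction-limited spot at 0.485 µm/px), thresholding
(helper: a quantile of the filtered image, default 0.995), 3D
26-connectivity labeling — so a spot split across slices stays one
object — and component centroids. Candidates whose analysis window
would leave the volume are dropped.

## Classification

The voxel classifier is a small 3D CNN: two convolution layers of four
3×3×3 kernels (ReLU, 'same' padding), each followed by 2×2×2 max
pooling, a dense layer of 512 ReLU units with dropout 0.5 during
training, and one sigmoid output. Training: class-weighted binary
cross-entropy (weights = half the inverse class fraction), Adam at
lr 10⁻⁴, batch size 8, 100 epochs, 5-fold cross-validation, inputs
min-max scaled to [0, 1] per voxel, augmentation by random 90°
in-plane rotations and axis flips (arbitrary-angle 3D rotations would
interpolate anisotropic voxels, so the exact symmetry group is used
instead). The network is implemented directly on NumPy — forward,
backward, and the Adam update — which trains this architecture in a few
minutes on one CPU; gradients are verified against finite differences in
the test suite. Acceptance of a candidate requires probability ≥ 0.7.

Training voxels come from the generators: spot-class voxels across
signal:background 0.2–1.0 on structured backgrounds, non-spots the same
backgrounds without a spot (for libraries), or hard negatives — detected
false candidates — when labeling from a synthetic movie. A
logistic-regression fallback on simple features (DoG peak, fitted
widths, signal:background) is provided for fast pipeline runs; it is not
the reference method.

## Quantification

Both localizers run on a DoG-prefiltered voxel (3D, same σ as
detection): the structured background otherwise violates their
uniform-background assumption. The Gaussian fit runs on the voxel
interior (margins of 1 px in z, 2 px in y/x excluded — the band-pass
has edge artifacts there that can rival a dim spot on a steep gradient)
and includes a linear background plane; the center is initialised at the
voxel center (the window is extracted around a detected candidate) and
bounded to ±2.5 px. Fitted widths are deconvolved for the prefilter
(σ_raw = √(σ_fit² − σ_small²)) so they refer to the raw spot. The
radial-center method solves the weighted least-squares point nearest all
gradient-direction lines — the 3D analogue of radial-symmetry particle
localization — on the same interior. A failed or out-of-bounds fit
falls back to the radial center with a flag.

Background: mean of a cubic shell at Chebyshev distance (2, 3] px from
the rounded center (inner/outer widths 4/6 px). The fitted spot's own
tail is subtracted from the shell pixels first (amplitude re-estimated
in raw space by a linear fit with frozen center/widths and a background
plane); without this the tail inflates the background by several percent
of the spot amplitude and biases intensities low — the noiseless
integration error is −1.6% with the correction versus −11% without.
The correction is only applied when the fitted widths are spot-like
(all σ ∈ (0.3, 2.5] px) and is capped at half the shell mean, so
extended structure (e.g. a nucleus boundary) cannot masquerade as a
tail. Structuredness is always reported from the uncorrected shell,
matching how it is measured on real spots. The alternative
`gaussian_refit` background (offset of the fixed-shape refit) agrees
with the shell method at R² ≈ 0.97 across the library.

Integration: background subtracted from all pixels, negatives clipped
to zero, summed over the ellipsoid with 2 px semi-axes (full extents
4×4×4 px ≈ 2×2×4 µm) centered on the sub-pixel center; truncated
ellipsoids are flagged, not rejected.

Accuracy at desk scale (seeded, recomputed by `scripts/acceptance.py`):
maximum binned mean |relative error| ≈ 33–36% over the regime diagram
(signal:background 0.1–1.5 × structuredness 1–80), library-wide median
≈ 5%. At the operating point itself (0.35, 40) the median is ≈ 9%; the
residual is the difference between the background's mean over the shell
and over the ellipsoid for a steeply curved exponential — replacing the
estimate with the oracle background drives the error to ~0, so this is
a property of local background estimation on such backgrounds, not of
the integration.

## Traces

Spots inside a labeled nucleus are assigned to it; otherwise the nearest
labeled pixel within a 7×11×11 px (z, y, x) search cube. One spot per
nucleus per frame survives (highest classifier probability). Active
regions are frames where the 5-point moving average (zero-padded,
centered) exceeds 1 a.u.; zero points inside an active region with a
detected neighbor at an adjacent observed frame are re-examined by
extracting the voxel at the neighbor's position at the empty time and
re-running classification/quantification; a fill is accepted if the
classifier passes or all fitted widths lie in 0.5–3.0 px. This is
iterated to a fixed point (at most 10 iterations). Spatial filters drop
spots > 40 µm anterior of the last formed somite or > 50 µm off the AP
axis, and traces with ≤ 10 detected spots.

Per-point uncertainty: σ_I is the RMS residual of the spot's background
time series about a degree-4 polynomial trend (raw standard deviation,
flagged, below 6 points); then σ = √(σ_I²/(1−fp) + I²·fp/(1−fp)) for
detected points and σ = Ī·fn/(1−fn) for zeros, with fp = 0.04,
fn = 0.08 as defaults and Ī the mean over detected points only.

## Protein prediction and bursts

mRNA and protein follow dm/dt = r_m x − γ_m m, dp/dt = r_p m − γ_p p,
integrated with adaptive RK45 and linear interpolation of the MS2 signal
x(t) (zero where no spot), zero initial conditions, and the first
~1/γ_p flagged transient. γ_m = γ_p = 0.23 min⁻¹ by default for
prediction; the stochastic simulator uses γ_m = 0.231 min⁻¹ (both are
exposed). Note that with equal decay rates the initial condition decays
as t·e^(−γt), so "forgetting" takes ~10 decay times, not 5.

Bursts: contiguous runs where the 3-point moving average is ≥ 1 a.u.;
pulses merge unless separated by 3 zero frames. Bursts are assigned to
the next protein peak at or after their start (bursts before the first
peak to the first peak; after the last peak, unassigned). Protein peaks
use `find_peaks` with prominence 0.01 on the max-normalized signal —
normalization is this package's choice since units are arbitrary.

## Tissue scale

Per keyframe, ~10 manually placed anchors from the last formed somite
(origin) to the tailbud tip are interpolated with a degree-2 B-spline
resampled to 100 points; each point index is then interpolated linearly
in time. Arc length accumulates from the origin. Spots take the AP
coordinate of their nearest axis point. Kymographs sum intensity in 100
equal bins over [0, axis length] — the bin width is derived from the
axis, not hard-coded. The tissue period sums a fixed AP window
(default 240–315 µm), splits the signal into single-oscillation
sections at smoothed minima (a manual-section override exists; automatic
segmentation is used for reproducibility), fits a Gaussian per section,
and differences successive centers; uncertainties are bootstrapped over
spatial bins. Tailbud boundary projection is approximated by
extrapolating the spline toward a user-supplied tail-tip point rather
than projecting to a segmented tissue boundary.

## Feedback bursting model

States: promoter G ∈ {0, 1}, mRNA count M, protein count P. Reactions:
promoter on at k_on(p), off at k_off(p); transcription at r_m(p) while
ON, delivering M after a fixed delay τ; translation at r_p·M; decays
γ_m·M, γ_p·P. Regulation modes use Hill functions of P (coefficient
n = 3): amplitude r_m/(1+(p/K_D)ⁿ) with the promoter pinned ON and
τ = 7.5 min (K_D = 100); frequency k₊/(1+(p/K_D)ⁿ) with k₊ = 0.5,
k_off = 0.08, K_D = 80; duration k₋(p/K_D)ⁿ/(1+(p/K_D)ⁿ) with
k_on = 0.055, k₋ = 0.4, K_D = 1100; combined frequency+duration with
K_D,on = 80 and K_D,off = 1100. Unregulated: k_on = 0.055,
k_off = 0.4. Fixed: r_m = 10 mRNA/min, r_p = 4.5 /mRNA/min.

The simulator is an exact delayed-Gillespie scheme: propensities use the
current state; each transcription initiation pushes a delivery event
into a priority queue, and a pending delivery earlier than the sampled
next-reaction time interrupts the wait (the delivery changes the state,
so propensities are re-evaluated). Translation is instantaneous; only
transcription carries τ. Trajectories are recorded both at exact switch
times and on a 1/min grid. The core is plain Python/NumPy — at these
parameters a 45 000-minute unregulated run takes well under a second.
For unregulated interval statistics the simulator is run with r_p = 0:
without feedback the promoter dynamics are independent of M and P, and
dropping protein bookkeeping makes long runs cheap.

MS2 measurement model: each initiation contributes fluorescence ramping
linearly over the polymerase dwell time on the cassette (normalized
kernel length w = dwell/frame = (1.4 kb / 4.8 kb/min)/1 min = 0.29) and
plateauing until termination at one full frame — the minimal
ramp-then-plateau kernel; its exact shape in the cited loading model is
not fully specified, so the kernel is overridable. The loading rate
(promoter × transcription rate, time-dependent under amplitude
regulation) is convolved with this kernel on a fine grid, multiplied by
(1 + N(0, σ_MS2)) noise (σ_MS2 = 0.2), then thresholded to zero below
0.2·w·max r_m — noise first, threshold second.

Intervals: runs of ON/OFF after binarization (direct threshold for
binary/promoter traces; 3-point moving-average threshold 1 a.u. for
noisy measured traces, matching burst calling); boundary runs are
censored and excluded. Exponentiality is tested by KS against a fitted
shifted exponential; frame-discretized durations are dithered by ±½
frame first, since ties otherwise inflate the KS statistic. Period
regularity is the CV of inter-peak intervals (≥ 3 peaks required, NaN
otherwise); for molecular-noise trajectories a short moving average
(5 min) before peak finding suppresses spurious single-sample peaks,
and under that smoothing every regulated preset yields a lower protein
period CV than the unregulated model.

## Synthetic movies

Nuclei are bright ellipsoids (default radii 3×5×5 px) on straight-line
tracks at a fixed speed, placed with enough border margin that the
analysis window around their spot always fits, with per-nucleus MCP
background levels drawn lognormally (spread 0.2 around 100) and Poisson
noise in both channels; a Gaussian spot of the promoter trace's
integrated intensity is rendered at a fixed sub-nuclear offset whenever
the trace is nonzero, and the label movie is exact. What the fixture
does not emulate: optical stripe artifacts, scattering, depth-dependent
attenuation, nuclear divisions, and tracking errors — so end-to-end
tests demonstrate correctness of the measurement chain, not robustness
to tracker failures or optical systematics. Pipeline recovery on this
fixture reaches per-trace R² ≈ 0.99 against the ground-truth promoter
traces.

## Problem sizes

Desk-scale defaults keep every analysis seeded and fast: regime library
5×6 conditions × 50 spots, 227/1023 classifier voxels with the full
100-epoch 5-fold protocol, 40-frame 5-nucleus movies, simulations of
4 000–45 000 min per preset. These sizes are the package's validation
conditions; all scale up linearly.

## Known limitations

- Local background estimation on steeply curved backgrounds carries a
  few-percent bias (see Quantification); reporting both background
  methods makes this visible per spot.
- The CNN is trained on synthetic voxels; applying it to real data will
  require retraining on hand-labeled voxels from that data.
- Nuclear segmentation/tracking is consumed, not performed; tracking
  errors (merges/splits/swaps) pass through uncorrected.
- The burst model ignores other clock genes and cell–cell coupling; it
  is a single-cell, single-gene model.
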