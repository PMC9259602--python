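# Methods

This note documents the models, estimators, and design choices behind
socialscope, in the order data flows through the pipeline. Problem sizes
quoted for tests are the package's own desk-scale choices.

## Behavior model and metrics

The arena is a 45 × 10 cm central chamber with two 10 × 10 cm end
compartments behind wire barriers (geometry configurable; one published
description of the same apparatus quotes a 40 cm chamber — we follow the
more detailed 45 cm specification). Along the chamber axis (origin at the
side-A barrier) five zones partition each frame: 3 cm sniffing strips at
the barriers, 10 cm end zones, and the transition zone. Intervals are
half-open; the nose position decides the sniffing strips, the body
centroid decides the other zones, and the sniff label wins where both
apply, since the strip lies inside the end zone. The tracking software
that produced real coordinates does not state which body point defines the
non-sniff zones; the centroid is the natural choice and is isolated in one
function.

An interaction bout is a maximal run of frames with the nose inside a
strip and the heading within ±45° of the barrier direction (the
orientation criterion is qualitative in the assay description; the
half-angle is configurable), lasting at least `min_duration_s` (default
0.2 s, one frame at 5 Hz). Adjacent runs separated by even one
disqualified frame are distinct bouts; no merge gap is applied.

The discrimination index is DI = (t_pref − t_other)/(t_pref + t_other)
with the session's preferred-class stimulus first (M1 in S1/S2, the novel
M2 in S3). An alternative normalization by whole-session time is sometimes
implied by figure legends; the pairwise form above is standard and is the
one implemented (the denominator choice only rescales, it does not reorder
subjects). Occupancy rasters report the percentage of each 20 s bin spent
interacting, computed from exact bout–bin overlap in seconds, so summed
raster mass conserves total interaction time.

## Synthetic sessions

The generator plants the structure the analyses assume and returns it as
ground truth.

*Behavior*: interaction time per stimulus is split into 3–15 s episodes
placed between smooth random-walk segments; during an episode the nose
sits inside the queried strip with heading toward the barrier, and during
walks the nose is kept out of both strips, so the bout detector recovers
the planted episodes exactly and realized preference matches the target to
one frame. Default preferences: 20% with the conspecific and 10% with the
object for the socially-preferring ("WT-like") regime; 13% with each for
the no-preference ("Rett-like") regime, matching the reported ~20/~10% and
12–15% interaction budgets.

*Traces*: each neuron draws private events from an inhomogeneous Poisson
process at `baseline_rate` (default 2 events/min) times a zone gain
(defaults 1.5 in sniffing strips, 1.2 in end zones — interaction raises
rates). Co-activation uses per-stimulus shared event trains (default 3
trains at 30 events/min each, active only during that stimulus's bouts):
each neuron is randomly assigned to one train and copies its events with
probability w (`loading_w`). Same-train pairs then correlate (≈ w² of
shared variance) while cross-train pairs stay near zero, so the pooled
pairwise-correlation distribution remains centered near zero and its width
grows with w. An earlier design in which every neuron copied from all
trains was rejected: it shifted every pair's correlation upward by the
same amount, moving the distribution's mean rather than its width.
Defaults: w_social = 0.1, w_object = 0.4 (WT-like); equal w = 0.25
(Rett-like, stimulus-independent width). Events are convolved with a
peak-normalized double-exponential kernel (rise 0.2 s, decay 0.75 s,
GCaMP6m-like — chosen so transients are resolvable at the 5 Hz analysis
clock; the indicator kinetics of the original optics are not published) and
Gaussian noise is added (default SD 0.05 ΔF/F, a clean miniscope regime;
peak SNR 20 at unit event amplitude).

*Movies*: footprints are Gaussian-profile disks on a jittered grid
(disjoint by construction; an error is raised if the field of view cannot
hold them), scaled at 50 counts per unit ΔF/F over a 100-count background.
Every soma carries resting fluorescence (0.3 ΔF/F-equivalent) and the
background has smooth static texture, mimicking out-of-focus neuropil and
vasculature — without static landmarks, rigid registration of a
sparse-activity movie is ill-posed. Rigid jitter is planted as intermittent
twitches (a random ~25% of frames shifted by up to ±`jitter_px`), which
keeps the mean projection a usable reference; defective pixels are stuck
at zero. All randomness derives from one master seed through named
`SeedSequence` children, so identical configurations reproduce bytewise.

What the generator does not emulate: biophysical spike-to-fluorescence
coupling, bleaching, non-rigid deformation, overlapping somata, neuropil
contamination, and behavioral idiosyncrasies (grooming, rearing). Passing
tests therefore certify the statistical machinery, not performance on
real optics.

## Movie preprocessing and source extraction

The chain runs in a fixed order: 3×3 median filter (defective-pixel
repair; scipy's reflect edge policy, which repeats the edge sample),
temporal downsampling to 5 Hz by non-overlapping block means, spatial
bandpass as a difference of Gaussians (defaults σ_high = 2 px,
σ_low = 20 px at the reduced field of view; no cutoffs are published),
rigid motion correction, and per-pixel ΔF/F with the temporal minimum as
baseline — F′ = (F − F_min)/F_min, pixels with non-positive baseline
masked and counted.

Motion correction estimates per-frame subpixel translations by FFT
cross-correlation against the mean projection and applies them by Fourier
shift. Because the first mean projection is blurred by the motion itself,
the estimate is refined for a second pass against the corrected mean, with
total shifts re-applied to the original frames so interpolation error does
not accumulate. Shifts are defined up to the common offset of the
reference; the planted-jitter test therefore compares mean-centered
shifts (recovered to <0.5 px; measured ≈0.1 px).

Source extraction requests ceil(1.15 × estimated cell count) components
(the "15% over" rule, rounded up): PCA by SVD of the
(frames × pixels) ΔF/F matrix, then FastICA on the concatenation of
spatial and temporal principal loadings weighted by the spatio-temporal
parameter μ (default 0.2). Each component's spatial map is oriented
positive and thresholded at max(3 robust SDs, 10% of the peak) — the
relative floor suppresses low-weight crosstalk from other cells that would
otherwise fragment the mask. The trace is the weighted mean of the ΔF/F
movie over the mask; SNR is its maximum over the robust noise SD.

ROI quality control applies three rules: (1) area < 4 px or not
soma-shaped (area > 400 px or eccentricity > 0.95 — the published
criterion is visual; this proxy is configurable); (2) SNR < 3 or a spatial
map splitting into more than 2 disconnected blobs (we read "traces that
contained >2 components" as spatial fragmentation; a switch is available
since mixed temporal sources are an alternative reading); (3) of two
centroids closer than 5 px, the higher-SNR member is kept. Every rejection
is logged with its rule. On the planted-movie regime (30 disjoint cells,
peak SNR ≥ 5) the pipeline recovers ≥ 27 footprints with ≤ 2 px centroid
error; on pure noise, QC rejects everything.

## Transients and activity statistics

The robust noise SD of a trace is 1.4826 × the median absolute deviation
of its first differences divided by √2 (differencing removes slow
transients but doubles noise variance). Detection smooths the trace with a
3-sample boxcar (a crude matched filter for the indicator kernel), scales
the noise estimate by 1/√3 accordingly, and takes peaks above
k_sigma × noise (default 3) with ≥ 1 s separation and ≥ 2 × noise
prominence. The amplitude is the raw ΔF/F at the smoothed peak frame — an
unbiased single-event estimate; a max over neighboring samples would bias
it upward by a fraction of the noise SD. At 5 Hz the kernel peaks ~2
frames after the event, so ground-truth matching allows for that lag. On
the independent-event regime at default noise, recall and precision are
≥ 0.9 within a ±2-frame window; when co-activation bursts push inter-event
spacing under the 1 s separation window, merged events lower recall by
design, not by defect.

Zone-conditioned rates divide event counts (attributed to the zone at the
peak frame) by zone occupancy; never-visited zones are flagged undefined,
not zero. The five-zone response field normalizes group-mean rates by the
reference group's maximum and interpolates a cubic B-spline through the
five zone centers. AUC per second integrates the trace over a bout by the
trapezoid rule and divides by the integrated span, so a constant trace
returns the constant. The rate–speed relation bins population rate and
mean speed in 10 s bins and reports the Pearson correlation, flagged
undefined on zero variance.

## The shuffle test and its null

Sa = 2(b·c)/(|b|² + |c|²) is computed exactly; since any reordering of b
preserves |b|², the test over all neurons of a session is a single
(shuffles × frames) by (frames × neurons) matrix product with one shared
set of shuffles — this sharing is what makes 5,000 shuffles × 10⁴ neurons
a seconds-scale computation, and each neuron still has its own Ss
distribution. Classification is strict: responsive iff Sa exceeds at least
99.95% of Ss; the percentile is 100 × #{Ss < Sa}/n, so exact ties (e.g. a
constant trace) never pass.

Two shuffle modes exist. The default, following the literal description
of the procedure, permutes b uniformly. For temporally autocorrelated
traces — and calcium traces are autocorrelated over the indicator decay —
full permutation is anticonservative: Sa retains the correlation between
the trace's slow structure and the bout blocks, while permuted b loses it,
so Ss understates the null spread (measured per-neuron false-positive rate
~13% instead of 0.05% on kernel-convolved null traces). The circular mode
draws random cyclic rotations of b (a subgroup of the permutations) which
preserve relative autocorrelation and recover the nominal rate
(100 × (1 − FPR) ≈ 99.9 vs the 99.95 cutoff, within three binomial
standard errors at 10⁴ neurons); on exchangeable white-noise traces the
unrestricted permutation is itself exactly calibrated (99.95 measured).
The acceptance script uses the circular mode for its calibration
experiment; analyses of real epochs should too.

## Pattern decorrelation

Pairwise Pearson correlations are computed over the concatenated bout
frames of one stimulus, with zero-variance neurons dropped (logged) and a
50-frame minimum guard against unstable coefficients (no guard is
published; results under ~10 s of epoch data are flagged rather than
reported). The FWHM of the pooled coefficients uses a Gaussian KDE with
Silverman bandwidth on a 512-point grid covering at least [−1, 1]; the
width is the distance between the outermost half-maximum crossings around
the global mode, located by linear interpolation. A histogram-binned mode
(0.02 bins) exists for sensitivity checks. The estimator carries a
deterministic +~1.4% Silverman widening and ~3% sampling SD at 5,000
draws; the Gaussian-closed-form test (2√(2 ln 2)σ) therefore averages a
few replicate draws at the stated 5% tolerance. Strong-pair (|r| ≥ 0.2)
and top-5% filters are exact definitions with a stable-sort tie rule.

ΔFWHM = FWHM(non-preferred) − FWHM(preferred) (O − M1 in S1/S2, M1 − M2 in
S3); the sign convention is configurable since the source defines ΔFWHM
only through a figure. Per-subject ΔFWHM is regressed on DI by OLS with
Pearson r and two-sided p. FWHM is computed per subject (per-mouse
averaging), with pooled mode optional.

## VAE latent features

The network follows the standard small convolutional VAE: encoder
conv(32, 3×3, stride 2) → conv(64, 3×3, stride 2) → dense(16) → two means
and two log-variances; the decoder mirrors it with transposed
convolutions ("same" padding, sigmoid output). The per-sample loss is the
reconstruction sum of squared pixel errors plus the KL divergence of the
latent posterior from a standard normal (KL weight 1); the optimizer is
RMSProp (lr 10⁻³, ρ 0.9), batch 128, default 200 epochs ("repeated the
training 200 times" is read as epochs, sufficient for convergence).
Embeddings use posterior means, not samples, for reproducibility.

The layers are implemented directly in NumPy (im2col + GEMM convolutions;
the transposed convolution is the exact adjoint of the forward
convolution, and both gradient paths are verified against numerical
differentiation to ~10⁻⁹). Training is deterministic given the seed.
Inputs are 64×64 (divisible by 4 for the two stride-2 layers); frames are
ROI-masked, block-mean downscaled, and min-max scaled to [0, 1]. The
first-150-frames-per-episode selector implements the familiarity control
that equalizes exposure across episodes.

The radius of a condition is the mean Euclidean distance of its embedded
frames to their centroid — translation-invariant, linear under scaling,
zero for identical frames — and the relative radius divides by session
S1. One VAE is trained per subject across sessions, so sessions share a
latent space. Tests run at reduced scale (≈200 frames, 8–30 epochs):
synthetic frame ensembles whose generating dispersion differs 3:1 keep
their radius ordering after embedding in ≥ 19/20 seeded runs.

## Orchestration

Frames are 0-based, time in seconds, bout intervals half-open. Imaging and
behavior streams share a start trigger; alignment maps imaging frame k to
behavior sample round(k × rate_ratio), clipped and monotone. `run_pipeline`
executes simulate → behavior → events → responsiveness → decorrelation
(→ VAE) per session, writes every intermediate as CSV/JSON under one run
directory, and the markdown report renders flagged statistics as
"undefined", never as 0. Reports regenerate bytewise from the saved
summary.

## Known limitations

- The permutation-mode miscalibration on autocorrelated traces is a
  property of the literal procedure, not of this implementation; the
  circular mode is the corrective.
- PCA/ICA assumes spatially compact, mostly non-overlapping sources;
  heavily overlapping somata need ring-background or CNMF-style models,
  which are out of scope.
- The soma-shape QC proxy (area and eccentricity bounds) approximates a
  visual judgement and will differ from manual curation near the bounds.
- Single-event amplitude estimates at peak SNR 5 carry ~20% noise; only
  averages are tightly calibrated.
- The synthetic co-activation model produces block-structured correlations
  (one train per neuron); real ensembles overlap more smoothly.
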