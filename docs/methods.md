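# Methods

`roaflow` detects and quantifies spontaneous Ca²⁺ events in two-photon
fluorescence time-lapse recordings of glial cells (astrocytes, microglia)
expressing a genetically encoded indicator such as GCaMP3.  The unit of
analysis is the **region of activity (ROA)**: a stationary, connected set
of pixels whose temporal fluorescence profiles are mutually correlated.
This differs from morphological ROIs (ROAs are defined by activity, not
anatomy) and from dynamic-event segmentations (an ROA's footprint does not
move between events).

## Processing model

Let F(t, y, x) be the recorded intensity, with pixel size p (μm) and frame
interval Δt (s); the time of frame i is i·Δt.

### 1. Denoising

Photon-limited recordings carry Poisson shot noise.  The denoiser
(`anscombe-haar-sure-garrote`, named in the provenance of every output)
stabilises the variance with the Anscombe transform z = 2√(F + 3/8),
decomposes each frame with a 2-D Haar wavelet (4 levels where the frame
allows), shrinks every detail subband with the **nonnegative garrote**
g(d) = d − t²/d for |d| > t (0 otherwise), and inverts the transform with
a closed-form unbiased inverse.  The threshold t of each subband minimises
Stein's unbiased risk estimate; estimates from four diagonal spatial shifts
are averaged (cycle spinning) to suppress block artifacts.  The garrote was
chosen over soft thresholding because soft thresholding subtracts t from
every surviving coefficient and we measured 20–90% attenuation of small
transient amplitudes with it; the garrote leaves large signal coefficients
essentially unshrunk while still annihilating pure-noise subbands.  When
the estimated noise scale is exactly zero the data are returned unchanged.

The denoiser is held to a behavioural contract rather than to one specific
published transform: (a) it strictly reduces the mean squared error to the
known clean signal on shot-noise-corrupted synthetic movies, (b) it moves
transient peak times by at most one frame (trivially true here — filtering
is purely spatial), (c) it reproduces noise-free input within 1%.

A **temporal median filter** (default window 3 frames, the smallest that
removes single-frame motion impulses while preserving multi-second
transients) runs after the transform-domain denoiser.  At the recording
edges the window shrinks symmetrically.

### 2. Baseline (F₀) and ΔF/F₀

The basal fluorescence of every pixel is a polynomial in time of
user-chosen degree d (default 3 — enough for slow bleaching and focus
drift over recordings of ≤ 5 min without absorbing 5–10 s transients),
fitted by least squares on a time axis rescaled to [−1, 1] for
conditioning.  Ca²⁺ transients are positive-going, so the fit iterates
**one-sided sigma clipping**: frames whose residual exceeds
median(r) + clip_k · 1.4826 · MAD(r) of the retained residuals (clip_k
default 2) are excluded and the fit repeated until stable (at most 5
rounds).  Anchoring the clip level at the residual median prevents the
one-sided truncation from dragging the fit downward over iterations.  A
pixel whose exclusions leave fewer than d + 2 frames falls back to the
plain fit and is flagged.  ΔF/F₀ = (F − F₀)/F₀; pixels with non-positive
F₀ anywhere are masked out of all downstream analysis.

### 3. ROA detection

* **Range projection**: per pixel, max − min of ΔF/F₀ over time.
* **Seeds**: local maxima of the range projection within a square
  neighbourhood (radius 3 px) that exceed median + 3·MAD of the map.  A
  plateau of exactly tied maxima (a block-transform artifact) yields one
  seed at its row-major-first pixel.
* **Simultaneous region growing**: all seeds grow at once from one global
  best-first frontier ordered by the Pearson correlation r between a
  candidate pixel's full-length temporal profile and its claiming seed's
  profile (ties: lower seed id, then row-major pixel).  A candidate joins
  iff r ≥ 0.2 (configurable).  A pixel reached above threshold by a second
  region keeps its first assignment and is marked as a **boundary pixel**.
  Constant and invalid pixels are never admitted.  Global best-first
  growth — rather than sequential per-seed growth — prevents the first
  seed from conquering territory that correlates better with a later seed
  and makes the partition independent of seed discovery order whenever the
  pairwise correlations are distinct.
* **Fragment merging**: one contiguous active area usually holds several
  range-projection maxima, so simultaneous growth partitions it into
  fragments that follow the same temporal signal.  Adjacent regions whose
  *mean* traces correlate with r ≥ 0.5 are merged.  Mean traces are used
  because single-pixel seed traces are too noisy to separate fragments
  (shared-variance r → 1 as pixel noise averages out) from distinct
  regions that merely co-activate during occasional concerted waves
  (r bounded by the shared-event variance fraction, well below 0.5).
* **Minimum area**: ROAs smaller than 5 μm² (area = pixel count · p²) are
  discarded; labels are renumbered densely.

Growth correlations are evaluated on the median-filtered-only ΔF/F₀,
additionally smoothed along time with a Gaussian of σ = 1.5 frames — not
on the wavelet-denoised data.  Spatial denoising necessarily correlates
neighbouring background pixels far above the 0.2 threshold, which makes
growth leak into quiet background; temporal smoothing leaves distinct
pixels independent while sharpening genuine within-region correlations.
The denoised data still provide the baseline fit, the range projection and
the seeds.  Both choices are configurable (`grow_on_denoised`,
`grow_temporal_sigma`).

### 4. Events and kinetics

Each ROA's trace is the unweighted mean ΔF/F₀ of its pixels per frame,
taken from the **unsmoothed** normalised data: averaging tens to hundreds
of pixels is the variance reducer, and temporal smoothing would clip the
sampled peak of a 5–10 s transient by 10–20% at 1 s frame intervals.

With μ, σ the mean and SD pooled over every sample of every ROA trace in
the field of view, event detection finds local maxima with value
≥ μ + σ (detect_k = 1; the lowest classification band edge doubles as the
detection floor) and prominence ≥ σ; maxima closer than 2 frames merge
into the higher.  Amplitude and peak time are refined by the parabola
through the peak sample and its two neighbours (sub-frame sampling
correction).  Strength classes follow the band edges
μ+σ ≤ a ≤ μ+2σ (low), μ+2σ < a ≤ μ+3σ (mid), a > μ+3σ (high), below μ+σ
(sub).

Kinetics use the FWHM convention with linear interpolation between frames:
start/end are the half-amplitude crossings nearest the peak, duration =
t_end − t_start, rise time = first 90%-of-peak crossing − t_start, decay
time = t_end − last 90% crossing, and integrated fluorescence is the
trapezoidal integral of the trace over [t_start, t_end] (ΔF/F₀·s — the
time-integrated reading of "area under the signal curve").  A crossing
that runs into the recording edge, or into the valley shared with a
neighbouring event, is clamped there and the event flagged `censored`.
Per-ROA frequency is reported only for ROAs with ≥ 2 events, as
60 / mean inter-peak interval (min⁻¹).

### 5. Field-of-view statistics

FOV area = H·W·p².  ROA density and signal density are counts divided by
FOV area, reported per 10⁻³ μm⁻².  The single/multi split is the fraction
of *active* ROAs with exactly one versus more than one event (they sum to
1).  The **coincidence index** is the mean over frames of the fraction of
ROAs active at that frame; a ROA is active when the frame time lies inside
the FWHM window of one of its events (alternative: within one frame of a
peak, via `active_window="peak"`).  Per-metric FOV medians cover
amplitude, duration, rise, decay, integrated fluorescence, ROA area and
frequency.

### 6. Distribution comparison

Signal metrics are compared between groups via relative-frequency
histograms (default 30 equal-width bins over the pooled range) fitted by
*unweighted* least squares with a scaled lognormal
A·LN(x; μ*, σ*), and the **extra-sum-of-squares F test**: the null model
fits one shared curve to both histograms, the alternative fits each
separately; F = [(SSE₀ − SSE₁)/3] / [SSE₁/(2m − 6)] with m kept bins, and
p comes from F(3, 2m−6).  Separate fits are additionally started from the
shared fit's optimum, which guarantees nesting (SSE₁ ≤ SSE₀, F ≥ 0).

Bins with fewer than 8 pooled observations are excluded before fitting.
Near-empty bins have sampling variance up to two orders of magnitude below
populated bins; with unweighted residuals they deflate the denominator
variance estimate and inflate the test's size (we measured a null
rejection rate of ~0.25 at α = 0.05 without the rule, versus ~0.05 with
it, across 1000 simulated null comparisons; the machinery is exact under
iid Gaussian residuals).  The cutoff sits between the textbook
minimum-occupancy recommendations of 5 and 10.  Fit initialisation is
multistart from method-of-moments on the bin-centre expectations; a fit
that cannot converge returns a failure result rather than raising.

## Synthetic movies

The generator renders the study conditions end to end: 300 frames of
256 × 256 px at 0.5 μm/px and 1 s frame interval (a 5 min recording),
basal level 100 counts with −10% linear photobleaching, Poisson shot noise
plus Gaussian read noise (sd 1.5 counts).  Stationary regions are compact
random blobs grown pixel-by-pixel to an exact sampled area (astro profile:
10–180 μm², 20 regions; micro: 5–60 μm²), placed disjointly with 2 px
clearance.  Events arrive per region as a Poisson process at 1 min⁻¹;
amplitudes are uniform in 0.10–0.30 ΔF/F₀ and FWHM durations in 5–10 s —
all inside the ranges reported for spontaneous glial activity.  The
temporal kernel rises linearly over 0.4 × duration and decays
exponentially with τ = (FWHM − rise/2)/ln 2, so its rendered FWHM equals
the sampled duration by construction.  The astro profile adds occasional
concerted waves (rate 0.2 min⁻¹, recruiting ~30% of regions
simultaneously) to exercise the coincidence index; the micro profile is
sparser and uncoordinated.  Drift multiplies baseline and transients
alike, so the true ΔF/F₀ amplitude of an event equals its sampled
amplitude exactly.

Structure (footprints, event times) and noise derive from independent
child streams of one seed, so `clean_twin` renders the identical
transients without noise (and optionally without events) for oracle
comparisons.  What the generator does **not** emulate: optics (PSF,
scattering, depth attenuation), within-region amplitude gradients,
sub-region event localisation, motion beyond single-frame impulses, and
negative-going signals.  Passing tests therefore demonstrate correctness
of the algorithmic chain under idealised imaging physics, not performance
on real tissue.

### Evaluation protocol

Ground-truth matching is greedy one-to-one by peak-time distance (≤ 3 s)
within the ROA mapped to each true region.  Truth events whose peak lies
beyond the last recorded frame are excluded from the recall denominator
(no peak exists in the data).  A truth transient overlapping a neighbour
so closely that the rendered trace has a single maximum cannot be a
separate detection; an unmatched truth peak inside an already-matched
detection's FWHM window therefore counts as covered by that compound
event.  Precision counts strict one-to-one matches only, and
amplitude/duration errors come from the one-to-one pairs.

## Numerical choices and degenerate inputs

* Time axis rescaled to [−1, 1] for polynomial fitting (conditioning).
* All tie-breaks in seed ordering and region growing are lexicographic
  (row-major), making every stage a pure function of its inputs; repeated
  runs are bit-identical.
* Zero-variance traces are never admitted to regions; empty seed sets
  yield an empty ROA map, not an error; empty event sets yield zero
  densities and an undefined (absent) coincidence index when there are no
  ROAs.
* An all-excluded pixel in the baseline fit falls back to the plain fit
  and is flagged rather than failing the run.
* Events truncated by the recording or by a neighbouring event are
  reported with clamped crossings and `censored = True` rather than being
  dropped.

## Problem sizes used in the checks

The bundled property checks run on synthetic movies between 64 × 64 × 300
and the full default 256 × 256 × 300 field of view, 50 random 16 × 16 × 100
stacks for the region-growing oracle, 500 null replicates (n = 500 per
group) for the F-test size, and n = 10⁴ draws for lognormal parameter
recovery.

## Known limitations

* The correlation threshold (0.2) refers to profiles whose noise level
  depends on the preprocessing; the growth-data choices above are part of
  the method's operating point.
* Regions whose entire activity is a single weak transient (amplitude near
  0.1 ΔF/F₀ in a 5 min recording) may grow only partially or fall below
  the area floor.
* Strongly overlapping transients within one ROA are reported as censored
  compound events; no deconvolution is attempted.
* The lognormal comparison tests curve inequality, not any specific
  physiological contrast; its power depends on the binning protocol.
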