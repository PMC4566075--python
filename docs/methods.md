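# Methods

## Scientific setting

During the second postnatal week the mouse retina generates spontaneous
propagating waves of activity.  Müller glial cells — the radial glia of the
retina — respond to the neurotransmitter released during each wave with
calcium transients in their stalks and lateral processes within the inner
plexiform layer.  The standard measurement is simultaneous two-photon
imaging of a genetically encoded sensor in the glia (a slow calcium
indicator, or a faster membrane-bound glutamate sensor) and whole-cell
voltage clamp of a retinal ganglion cell, in which each wave appears as a
prolonged compound inward EPSC.  The analysis question is: *what fraction
of glial compartments is recruited by each wave*, and how does that
fraction change with age and pharmacology (e.g. blocking glutamate uptake
with DL-TBOA).

This package implements that analysis as a reusable pipeline and pairs it
with a generative model of the experiment, so every stage can be validated
against ground truth.

## Synthetic experiment model

The generator (`gliawave.simulate`) draws, per seed:

1. **Layout.**  `n_stalks` disks (radius 3–5 px) and `n_lateral` rotated
   bars (14–22 × 3–4 px, aspect ≥ 3.5) placed uniformly at random in a
   256 × 256 field with a 6 px exclusion gap and a 14 px border margin.
   Disks model the round cross-sections of glial stalks, bars the
   elongated lateral processes.  Placement failure after 2000 retries per
   ROI raises an overcrowded-field error.
2. **Waves.**  Inter-wave intervals are truncated normal (default mean
   40 s, SD 15 s, floor 15 s — wave frequency at these ages is not well
   constrained; these values give well-separated epochs, about five per
   standard 150-frame movie at 0.74 Hz).  Waves are only placed where the
   ensuing glial transient peak (onset + lag + rise) still fits inside the
   recording; a transient truncated by the end of the record would be
   unobservable by construction, a boundary artifact rather than a feature
   of the conditions being emulated.
3. **Recruitment.**  Each wave recruits each ROI independently with
   probability `participation_p`; each recruited ROI fires one transient
   with onset lagged Uniform(0, 3 s) after the wave onset (glial responses
   follow the start of the neuronal wave).
4. **Fluorescence.**  A transient multiplies the ROI's baseline by
   `1 + kernel(t)`: linear rise to `peak_dff` (default 0.5) over `rise_s`,
   then exponential decay with time constant `decay_s`.  Defaults:
   calcium (3.6 s, 0.6 s), giving a full width at 10% of peak of ≈ 4.6 s —
   inside the 3–5 s range characteristic of slow-indicator glial
   transients; glutamate sensor (0.5 s, 0.6 s), ≈ 1.8 s full width.
   ROIs sit at `baseline_f0 = 100` on a `background_f0 = 20` neuropil:
   labelled cells are brighter than their surround, which is what makes
   silent ROIs visible to morphological segmentation.  Additive Gaussian
   pixel noise (default SD 8, i.e. single-pixel transient SNR ≈ 6;
   ROI-mean SNR is far higher), optional integer drift along the row axis,
   and uint16 quantisation complete the movie.
5. **Current trace.**  1 kHz Gaussian baseline noise (SD 5 pA) plus one
   compound-EPSC envelope per wave: the same rise/decay shape with peak
   −100 pA, rise 0.3 s, decay 1.5 s, i.e. a few seconds below baseline per
   wave.  1 kHz comfortably oversamples every feature used downstream;
   the rate is configurable.

All randomness derives from one master seed through spawned generator
streams, so identical configurations reproduce bit-identical outputs.

The packaged condition table maps condition labels to recruitment
probabilities: P7 control 0.42, P9 control 0.48, P11 control 0.13,
P9 + DL-TBOA 0.58, P11 + DL-TBOA 0.61, and for the glutamate sensor
P9 0.38, P11 0.06, P11 + DL-TBOA 0.31.  Pharmacology enters *only* through
this probability (and, for the fast sensor, through kinetics and the
1.7 Hz scan rate); no receptor or transporter kinetics are modelled.

### What the generator does not emulate

Real recordings have structured noise (photon shot noise scaling with
intensity, scan artifacts), partially overlapping and out-of-focus
structures, amplitude heterogeneity across cells and events, slow
bleaching, z-drift, and waves that traverse the field with a visible
propagation delay rather than recruiting all ROIs simultaneously.  Passing
the recovery tests therefore shows the pipeline is *self-consistent* under
the stated statistical model at realistic SNR — not that it is robust to
every failure mode of real data.

## Analysis pipeline

**Registration.**  Integer-pixel (dy, dx) translation per frame by phase
cross-correlation, two passes: first against the initial frame, then
against the mean of the first 10 registered frames.  The two-pass scheme
gives a low-noise reference without the smearing a naive multi-frame mean
suffers on a drifting movie, and recovers injected integer drift exactly
on noiseless input.  Frames are corrected by circular shift; a
configurable bound on |shift| (default 20 px) raises a rejection flag
mirroring the practice of discarding recordings whose focus or position
changed too much.

**Segmentation.**  A negated Laplacian-of-Gaussian (σ = 2.5 px, matched to
the half-width of the simulated structures) is applied to the temporal
mean image (temporal SD available for sparse sensors) and thresholded at
mean + 2·SD of the filtered image.  The resulting seed blobs are grown to
the connected component of the Otsu foreground of the summary image that
contains them, so reported pixel sets follow full cell outlines rather
than the band-pass response; components under 6 px are dropped.  ROIs are
classified as **stalk** when circularity 4πA/P² ≥ 0.7 *and* best-fit
ellipse aspect ≤ 2, else **lateral process**; the cutoffs separate the
generator's disks from its bars with a wide margin (observed stalk
circularity ≈ 1.0 vs ≤ 0.67 for bars).  Circularity is clipped at 1
because the rasterised perimeter estimate underestimates true perimeters
for small shapes.  For neuronal-sensor movies the field is instead
partitioned into 16 identical squares (`grid_roi_masks`).

**ΔF/F and detection.**  F₀ defaults to the 10th percentile of each ROI's
raw trace (robust when transients are sparse; mean-of-first-N and external
F₀ are available).  Detection operates on the binomially smoothed trace
(width 3, kernel ¼–½–¼): onsets where the first difference divided by the
frame interval exceeds *k*·SD of the whole derivative trace, with *k* = 2
at rates ≤ 1 Hz, 4 above, 2.5 in focal mode, and strictly-greater
comparison at ties.  A candidate must additionally reach a peak at least
5 robust (MAD-based) SDs of the trace above its local pre-onset baseline;
without an amplitude criterion a 2·SD derivative threshold alone fires on
noise at a rate that would contaminate low-participation conditions.
Event boundaries are then refined on the *unsmoothed* trace by linear
interpolation: onset at the 10%-of-amplitude crossing, offset at the
return below 50%.  Using the raw trace here avoids the systematic ~1-frame
early shift a symmetric smoothing kernel imposes on rising edges — which
matters because the coincidence window opens exactly at the wave onset.
Onsets closer than 3 s within a ROI are merged.  The offset definition
(half-amplitude return) exists to report durations; with the default
calcium kernel, detected durations fall in the 3–5 s band.

**Wave epochs.**  The current trace is smoothed with a 0.2 s moving
average; baseline = median, noise scale = 1.4826·MAD, and epochs are
maximal runs below baseline − 4·robust SD lasting ≥ 1 s, with runs closer
than 2 s merged.  Because the threshold crossing necessarily lags the
physiological onset, the epoch onset is backtracked to where the smoothed
current last sat within half a robust SD of baseline (stopping short of
baseline itself avoids chasing correlated noise wander).  Charge is the
trapezoidal integral of (baseline − current) over the epoch, reported
positive in pC.  Median/MAD make the detection invariant under positive
rescaling of the trace.

**Coincidence and statistics.**  A ROI is responsive for a wave when one
of its event onsets falls in [wave onset − `pre_s`, wave offset +
`post_s`], defaults 0 and 5 s; the 5 s tail matches the simulated glial
onset lag, and each event is assigned to at most one wave (nearest onset).
Stalks and lateral processes are pooled by default (their responses are
statistically alike); stratification by shape class is available.
Group comparisons delegate to standard routines: Welch/Student t-test for
two groups, one-way ANOVA with Tukey's post-hoc or Kruskal–Wallis with
Dunn's post-hoc for more, α = 0.05, percentages reported to one decimal
as mean ± SD.  Dunn's z-statistics (pooled mean ranks with tie correction,
Bonferroni adjustment) are implemented in-package since no installed
library provides them.

## Problem sizes and numerical choices

Recovery runs use 5–6 retinas per condition, each 150 frames at 0.74 Hz
(calcium) or 300 frames at 1.7 Hz (glutamate sensor), 256 × 256 px with
about 40 ROIs and 3–5 waves — enough pooled waves (~20–25 per condition)
to estimate a binomial mean within ~1–2 percentage points while a full
six-condition sweep completes in about a minute on one CPU.  Known
residual biases of the pipeline, measured against ground truth: events
with true lag near zero occasionally receive an onset estimate a fraction
of a frame before the wave onset and fall outside the default coincidence
window (≈1–2% of events for calcium, up to ~5% for the fast sensor at
1.7 Hz, where the 0.5 s rise is sub-frame); both deflate recovered
participation slightly but well within each condition's reported spread.

Degenerate inputs are handled explicitly: constant summary images yield
zero ROIs; a flat trace yields zero events; all-NaN traces, non-positive
F₀ (named per ROI), non-uniform ephys sampling, ROIs outside the field,
and indivisible grid geometries raise errors.  Single-frame movies
register as identity.

## Known limitations

- Segmentation assumes non-overlapping, contrast-separated structures; it
  does not demix overlapping cells (no matrix-factorisation stage).
- The detector assumes transients are sparse enough that the derivative SD
  is noise-dominated; at very high event rates the threshold inflates and
  recall drops.  An optional quiet-window SD estimator would mitigate
  this; the default follows the whole-trace convention.
- Wave epochs are detected from a single cell's current trace, so the
  wave/no-wave decision inherits that cell's recruitment reliability; the
  simulator assumes the recorded cell sees every wave.
- Exact drift recovery holds for global integer-pixel translation;
  sub-pixel or non-rigid motion is out of scope.
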