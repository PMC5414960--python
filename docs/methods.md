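# Methods

This package measures vocal register transitions ("passaggio events") in
pitch glides from two synchronised data streams: the electroglottographic
(EGG) signal, and the outputs of glottal segmentation of high-speed
laryngeal video — the glottal area waveform (GAW) and the medio-lateral
glottal width per anterior–posterior (A-P) position. This note documents the
models, the numerical choices, and what the synthetic data generator does
and does not emulate.

## Cycle detection (egg_cycles)

The EGG is proportional to relative vocal-fold contact area; its first
derivative (dEGG) has one sharp positive peak per glottal cycle at the
contacting event, the standard landmark for cycle separation. Processing:

1. **Drift removal.** 4th-order zero-phase Butterworth high-pass at 20 Hz
   (electrode drift is unavoidable; the glottal fundamental is ≥ 150 Hz
   here). `sosfiltfilt` is padded with *even* reflection over ~3 filter time
   constants: the default odd reflection inverts the contact pulses in the
   padding and the resulting low-frequency transient measurably distorts the
   first/last cycles' shapes.
2. **Peak detection.** On a ~0.5 ms moving-average-smoothed dEGG
   (differentiation amplifies measurement noise by `fs`), candidate peaks
   must exceed 20% of the 95th-percentile dEGG amplitude in a 50 ms
   neighbourhood — an adaptive rule that survives the 4× fo sweep and the
   amplitude changes of a one-second glide. Peaks closer than one period at
   `fo_max` are resolved in favour of the larger one.
3. **Voicing gate.** Frame-wise normalized autocorrelation (50 ms frames,
   12.5 ms hop): a frame is voiced when the autocorrelation maximum over
   lags `fs/fo_max … fs/fo_min` exceeds 0.5 and the frame holds ≥ 5% of the
   global RMS. Aperiodic input (white noise, silence) is rejected; peaks in
   unvoiced regions are discarded, which also makes boundary positions
   invariant to leading/trailing silence.
4. **Sub-sample refinement.** Parabolic interpolation of the dEGG peak plus
   the half-sample offset of the forward difference, then — when the EGG is
   available — the upward crossing of the local amplitude midline on the
   contacting flank. The crossing sits where the slope is steepest, so its
   position is insensitive to sampling phase and noise; boundary jitter
   after refinement is on the order of 10⁻² samples. Events whose
   refinement window would be truncated by the signal edge are dropped
   (costing at most one cycle per end).

Cycles whose implied fo falls outside `[fo_min, fo_max]` (default
[150, 1200] Hz, A3–A5 with margin) are kept in the boundary array but
flagged invalid; all downstream measures use valid cycles only. This
preserves gaps (e.g. contact-loss episodes) in the time base instead of
silently merging across them.

## Fourier-descriptor sample entropy (fdse)

Each valid cycle is resampled to 64 points with a cubic spline (linear
interpolation leaves an fo-dependent shape bias that masquerades as shape
change) and normalised to zero mean, unit peak-to-peak — descriptors are
shape-only by construction, so the measure is invariant to amplitude.

The **Fourier descriptor** of a cycle is the pair of its first two DFT
components (scaled 1/n), stored as a 4-vector (re₁, im₁, re₂, im₂). The
descriptors are *phase-normalised*: component k is rotated by k·arg(X₁),
the standard rotation-invariant Fourier-descriptor form. This makes the
descriptor exactly independent of where within the cycle the boundary
landmark sits — residual landmark jitter cannot masquerade as shape change —
while the shape-relevant relative phase of the second harmonic is retained
(im₁ becomes identically zero). A non-normalised variant is available
(`phase_normalize=False`).

**Sample entropy** of the descriptor sequence is −ln(A/B), where B counts
template pairs (i < j) whose m consecutive vectors are similar and A those
still similar at point m+1; self-matches are excluded; similarity is the
max-norm over components and offsets. Defaults m = 2, r = 0.2 of the
per-component SD — the conventional settings for short physiological
series. Two numerical choices matter:

* **Tolerance floor.** The per-component tolerance is
  max(r·SD, r_floor·RMS) with r_floor = 0.05 of the RMS descriptor
  magnitude. Without the floor, a noise-free shape-stable glide has
  descriptor variance dominated by numerical jitter (resampling,
  sub-sample boundary error, ~10⁻³ of the descriptor magnitude), and an
  SD-relative tolerance turns that jitter into large spurious entropy. With
  the floor, shape changes below 5% of the descriptor magnitude count as
  "similar", so a fixed-shape pitch glide scores exactly zero — the
  defining control property of the measure — while genuine register events
  (descriptor excursions of 10–100% of the magnitude) are unaffected.
* **Undefined values.** B = 0 (no template matches) or A = 0 (no match
  survives extension) yields NaN, which is flagged and excluded from window
  means, never zeroed.

FDSE_c is the sample entropy over a sliding block of 40 consecutive
descriptors (hop 1), assigned to the block-centre cycle: 40 cycles resolve a
25 ms window at fo ≥ 220 Hz while retaining enough template pairs. FDSE_w
divides the phonation into consecutive 25 ms segments anchored at the signal
start (a partial trailing segment counts) and averages the defined FDSE_c
values of cycles whose midpoints fall in each segment. The segment with the
global maximum (earliest on ties, for determinism) becomes **window 0** of
the 11-window −5…+5 alignment; windows clamped off an edge, or without
defined values, are flagged missing. All per-window measures in the package
(OQ statistics, contours) share this alignment.

## Open-quotient statistics (gaw_metrics)

GAW-native cycle detection places boundaries at the area minimum preceding
each opening: the last frame of the closed plateau (area within 2% of the
inter-peak minimum) before the next area peak. Placing the boundary at the
plateau *end* rather than its first frame keeps every closure strictly
inside its cycle.

Per cycle, OQ = fraction of samples with area > baseline + 0.02 × cycle
peak-to-peak, baseline = cycle minimum. The 2% threshold reflects
segmentation noise (exact zero area is unreliable); the baseline is
per-cycle because endoscope drift moves the apparent closed-glottis area.
Degenerate (flat) cycles yield NaN. Window means, the ten between-window
differences ΔOQ, and their sample SD (ddof = 1, missing deltas excluded
pairwise) quantify how unevenly the glottal configuration moves through the
passaggio.

## Opening/closing contours (glottal_dynamics)

For every A-P position and cycle, the opening instant is the first frame
with local width above 0.5 px (segmentation quantisation makes exact zero
meaningless) and the closing instant the first subsequent frame at or below
it. Positions that never open give missing pairs; positions open through the
cycle end give (0, 1) with a never-closed flag. Instants are divided by the
cycle duration and averaged per analysis window, skipping missing pairs and
publishing per-position coverage. Summary metrics per window: mean open
duration, the least-squares slope of the opening contour versus position
(the A-P opening delay of a "zipper" opening), and the mean never-closed
rate.

Because frame quantisation bounds the precision, contours are reproducible
across frame rates only to one frame period — the frame-rate invariance
test asserts exactly that.

## Synthetic data (synthetic)

The generator emulates the study conditions the pipeline was built for:
one-second pitch glides at 20 kHz (EGG and video clock), 220→440 Hz and
440→880 Hz, with the fo change inside a 50 ms interval centred at 0.5 s.

* **Kinematics.** fo is piecewise-constant per cycle: the sigmoid glide
  (logistic, scale = width/12, so ~99.8% of the change falls inside the
  stated interval) is sampled at cycle starts and each cycle keeps one
  period. This is the operational meaning of "fixed cycle shape": a
  continuous intra-cycle chirp would itself warp the cycle shape by ~2% at
  these glide rates, which a cycle-separable voice source does not do.
* **EGG pulse.** Asymmetric raised-cosine contact pulse (rise over 30% of
  the contact phase), contact quotient = 1 − OQ. Any shape-stable pulse
  family would serve; this one also gives the dEGG a single sharp
  contacting peak.
* **Strategies.** `stereotypical` (fixed shape; the control),
  `smooth_oq_up`/`smooth_oq_down` (linear OQ ramp across the task),
  `abrupt` (fo and OQ step at the transition, plus random cycle-to-cycle OQ
  jitter, SD 0.08, within ±50 ms of the break — the transient vibratory
  irregularity that makes real register breaks audible; a clean
  instantaneous switch between two stationary shapes is not what a break
  looks like and would barely raise sample entropy), and `contact_loss`
  (the task's OQ ramp plus three episodes around the transition in which
  amplitude and contact quotient taper to zero over 6 ms edges around a
  2 ms core with no contact at all).
* **Displacement field.** Per cycle and position, a half-sine width pulse
  open for OQ − slope·(n_positions−1) of the cycle, onset delayed by
  slope·position (zipper), closing 5% of the cycle before the cycle end so
  closure falls strictly inside the cycle; amplitude widest mid-glottis.
  GAW = row sum. Episode cores and optional posterior-gap positions never
  close.
* **Ratings.** score = clip(round(true + rater bias + noise), 1, 5), with
  one duplicated stimulus as in a reliability design; 12 raters and
  20 + 1 stimuli by default. Bias SD 0.3 and noise SD 0.5 are plausible for
  trained expert raters and give average-measure ICCs in the mid-0.9s.
* **Cohort.** 10 subjects × 2 tasks. A planted severity in [0, 1] drives
  both the strategy (smooth < 0.4 ≤ contact loss < 0.7 ≤ abrupt) and the
  true rating 1 + 4·severity. Task OQ endpoints are set so the mean OQ
  rises ~10% (lower glide) and ~18% (upper glide) across the task — the
  average behaviour of trained sopranos; per-phonation OQ dynamics around
  that mean differ by strategy.

What the generator does **not** emulate: vocal-fold biomechanics (no
mass-spring or finite-element model), acoustic vocal-tract filtering or
source–filter interaction, left/right fold asymmetry, endoscope motion, or
segmentation artefacts beyond additive Gaussian noise. Passing recovery
tests therefore shows that the pipeline measures what the generator planted
under realistic sampling, noise and quantisation — not that it is robust to
every artefact of real laryngeal video.

## Statistics (stats)

First-order polynomial regressions are ordinary least squares
(`scipy.stats.linregress`); r² is the squared Pearson correlation. Rater
agreement is the intraclass correlation, by default ICC(A,k) in
McGraw–Wong terms — two-way random effects, absolute agreement, average of
k raters — computed by `pingouin.intraclass_corr`; other forms are
selectable and the form label is always reported alongside the value. The
per-stimulus rating entering regressions is the across-rater mean (median
selectable).

The strategy-separability contract is read as: the median maximum FDSE_w
ranks abrupt > contact loss > smooth, and both non-smooth strategies exceed
smooth on SD(ΔOQ). Between abrupt and contact loss the OQ-variability
ordering is alignment-dependent (episodes interact with the 25 ms window
grid) and is not asserted.

## Problem sizes and determinism

Tests and the acceptance script run on 1 s phonations at the full 20 kHz
study rate; fields use 16–64 A-P positions; cohort statistics use
10 subjects × 2 tasks, and the severity sign test uses ten 6-subject
cohorts. Every stochastic step takes an explicit seed
(`numpy.random.default_rng`); identical inputs, configuration and seeds
reproduce outputs bit-for-bit (rendered wavegram PNGs included).

## Known limitations

* The entropy tolerance floor makes shape changes below ~5% of the
  descriptor magnitude invisible by design; pathologically subtle register
  events would be missed.
* Window alignment assumes one dominant register event per phonation; two
  equally strong events keep only the earlier one at window 0.
* OQ precision is bounded by frame quantisation (~1 frame per cycle edge);
  at 880 Hz and 20 kfps that is ~4% of a cycle.
* The GAW-native and EGG-native cycle segmentations use different landmarks
  (plateau end vs contacting event); per-cycle quantities agree, but
  intra-cycle phases from the two clocks are offset by a constant fraction
  of the cycle.
* Real raters drift and interact; the rating model is exchangeable-noise
  only.
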