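# Methods

## The measurement

High-speed video microscopy of ciliated epithelium records periodic
intensity modulation wherever cilia beat: a pixel over a beating cilium
oscillates at the ciliary beat frequency (CBF), while pixels over bare
epithelium carry only camera noise and slow drift. `ciliaquant` turns
this into two numeric endpoints:

1. **Cilia coverage** — the percent of the analysed area whose temporal
   spectrum shows significant power in the ciliary band, averaged over
   the fields of view sampled across a culture insert. Coverage is a
   surrogate for how widely an ALI culture has ciliated; in vivo
   respiratory epithelium is reported in the 15–50% range.
2. **Mean CBF** — the mean dominant frequency over regions of interest
   drawn on strips of ciliated epithelium, reported against the normal
   ex vivo range of 11–20 Hz at 37 °C.

## Block spectra

Each field of view is tiled into non-overlapping square blocks
(`block_size` ≥ 4 px, default 4 — small enough to resolve single
ciliated cell patches at ×20, large enough to average pixel noise).
Edge residuals that do not fill a block are excluded from both numerator
and denominator of the coverage fraction and their pixel count is
reported on the grid object.

Per block, every pixel's series is mean-detrended, multiplied by a Hann
taper, and Fourier transformed; one-sided power spectra are averaged
across the block's pixels. Two deliberate choices:

* **Power averaging, not amplitude averaging.** Neighbouring cilia beat
  with a spatial phase lag (metachronal wave). Averaging the complex
  spectra — equivalently, transforming the block-mean signal — cancels
  antiphase pixels exactly; averaging power is phase-blind and preserves
  the beat peak. The test suite demonstrates the cancellation
  explicitly.
* **Hann taper by default.** Real beat frequencies are not bin-aligned;
  the taper suppresses spectral leakage that would otherwise smear
  off-grid beats and inflate the in-band noise floor. The rectangular
  window (`window="none"`) is kept for exact-recovery validation, where
  the Parseval identity Σ power = mean per-pixel Σ(x − x̄)² holds to
  1e-9 relative.

Spectra are normalised so that, unwindowed, each series' power sums to
its variance-energy. The grid resolution is `fps / n_frames`
(2 Hz for a 0.5 s clip at 500 fps); reported frequencies are bin
centres, and no sub-bin interpolation is attempted — interpolated peaks
would suggest precision the data do not carry.

## Movement classification

A block is *moving* when

* the in-band (2–50 Hz, inclusive) power peak exists, is non-negligible
  (above 1e-12 of total non-DC power — a machine-precision guard, since
  an out-of-band oscillation leaves O(eps²) rounding dust in the band),
  and
* the peak exceeds `power_ratio_k` × the in-band median power.

The band excludes sub-2 Hz content (slow drift, debris advection,
focus wander) and supra-50 Hz content (not physiological for cilia).
Band edges are inclusive: a 2 Hz or 50 Hz beat counts. The median is a
robust noise-floor estimate: for white noise the in-band bins are
i.i.d., pixel-averaging across a 16-pixel block concentrates their
distribution, and the max/median ratio stays far below the default
`k = 8`. Empirically (1024-block pure-noise fields, seeded), the
false-positive rate at `k = 8` is ≪ 1%, and the pipeline's apparent
coverage on pure noise is 0%. Raising noise variance can only lower the
number of detections for a fixed signal (verified in expectation over
seeds).

Dominant-frequency ties break toward the lower bin for determinism.

## Coverage aggregation

Per field of view, coverage = 100 × moving blocks / total blocks. The
insert-level figure is the **unweighted arithmetic mean of the per-field
percentages** (±sample SD, absent at n = 1), matching the protocol of
averaging the percentage within each of up to 16 fields imaged every 3rd
position along the insert midline (`make_sampling_plan`). Fields spoiled
by moving particulates or mucus debris are excluded by an explicit
operator flag — there is deliberately no automatic debris detector,
because no objective criterion exists for one; excluded fields remain
listed in the output.

## CBF summaries

ROI traces are analysed as one-pixel blocks with the same band and
significance rule. Sample summary conventions:

* fewer than 6 ROIs → status `insufficient` (the mean is still reported
  when computable);
* all ROIs static → mean CBF 0 Hz, status `static`;
* otherwise the mean over *moving* ROIs only, flagged against the
  inclusive 11–20 Hz normal range. Mixed static/moving samples keep
  their mean but carry a `mixed_motility` flag, since such samples
  typically reflect a variable beat pattern and a pooled mean is
  ambiguous.

Inclusive bounds are the conservative reading of an "11–20 Hz" range
stated without open/closed qualification.

## TEER

TEER = (mean test Ω − mean blank Ω) × membrane area (cm²). Three
readings per insert is the convention; other counts warn but compute.
Membrane area is a required input rather than a built-in constant —
insert formats differ and manufacturers publish the growth area.
A negative corrected resistance (blank exceeding test) is returned and
flagged rather than clipped: it usually indicates a failed blank and
should be visible.

## The simulator

`SimScene` emulates the acquisition regime the analysis targets:
500 fps, 250-frame (0.5 s) clips of 128×128 px, sinusoidal intensity at
14 Hz with amplitude 30 on baseline 120 over a 16-bit range, Gaussian
noise SD 10 (amplitude/3, a mid-grade acquisition), coverage target
38.9%. Patches are elliptical "strips" (~3:1 aspect, random position
and orientation) placed until realised coverage is within ±0.01 of the
target; each patch carries a phase gradient along its axis (0.1 rad/px
default) as a metachronal-wave surrogate. An optional 2f harmonic
emulates non-sinusoidal ciliary waveforms; the fundamental must still
dominate the argmax. Optional drifting Gaussian blobs emulate floating
particulates; at their default speed (5 px/s) their temporal energy sits
below the 2 Hz band floor and they are rejected outright, while fast,
high-contrast debris *does* leak detectable power into the band — which
is precisely why real protocols have the operator avoid or exclude such
fields.

**Block-aligned scenes for quantitative recovery.** Coverage is
measured in block units, but ground truth is a pixel mask. A partially
covered boundary block classifies as moving (correctly — it moves), so
elliptical patches make the block-level estimate exceed the pixel-level
truth by roughly the patch perimeter area, ~5–15 percentage points at
these patch sizes. That is a granularity mismatch between the truth and
the measurement unit, not an estimator defect. Recovery benchmarks
therefore use rectangular strips snapped to the 4-px block grid
(`patch_shape="rect"`, `align=4`), where pixel truth and block truth
coincide: noiseless scenes then recover realised coverage *exactly*,
and at noise SD = amplitude/3 the 16-field insert mean lands within
3 percentage points of the target (20 seeded replicates per level at
15%, 38.9% and 50%). Elliptical scenes are retained for robustness and
monotonicity checks.

What the simulator does **not** model: resolved individual cilia,
hydrodynamics, beat waveform shape (only its period), illumination
drift, focus changes, and spatially correlated camera noise. Passing
recovery tests therefore validates the spectral detection and
accounting machinery, not performance on degraded optics or atypical
beat patterns.

## Numerical and interface choices

* Frame rate is never defaulted: a stack without fps metadata is an
  error. Supported interchange is multi-page TIFF or raw binary plus a
  flat key-value sidecar; proprietary camera containers are out of
  scope.
* Rendered maps use the conventional monochrome ramp (0 Hz black →
  25 Hz white). Beats in (25, 50] Hz clip to white in the *display*
  only; the data tables keep the true frequency.
* Pixel coordinates are 0-based (row, column), origin top-left; the
  spectral analysis always runs at the acquisition rate.
* All randomness flows through `numpy.random.default_rng(seed)`; a
  16-field series uses seeds seed, seed+1, … so fields are independent
  but reproducible. CLI runs echo their configuration and are
  byte-for-byte repeatable.
* Problem sizes in the validation suite: spectra are oracle-checked on
  T ≤ 64 blocks against an O(T²) DFT; coverage recovery runs 20
  replicates × 16 fields of 128×128×250 per level; the false-positive
  bound uses a 1024-block field.

## Known limitations

* Frequency resolution is fps/T; half-second clips resolve 2 Hz steps.
  Longer recordings sharpen the grid but assume stationary beating.
* A block containing any sufficiently strong moving pixels counts fully
  toward coverage; sub-block partial motion is not fractionally
  weighted.
* The significance rule assumes a roughly flat in-band noise floor;
  strongly coloured noise would bias the median.
* `power_ratio_k` trades false positives against sensitivity to
  low-amplitude beating; the default 8 favours specificity, consistent
  with coverage being reported only where motion is unambiguous.
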