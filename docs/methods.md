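# Methods

This note documents the models, numerical choices and limitations behind
`nirsnet`. Everything stated here is computed by the test suite or the
examples; nothing is quoted from elsewhere.

## Signal model and conditioning

A recording is a `(channels × time)` matrix of ΔHbO at sampling rate `fs`
(default 13.33 Hz, 600 s segments, 22 channels `CH01`–`CH22`). Two
conditioning steps are provided, composable in either order (default:
low-pass then detrend), both preserving channel count, labels and `fs`:

* **HRF low-pass.** Convolution with a canonical double-gamma hemodynamic
  response function (response gamma peaking at 6 s, undershoot gamma at
  16 s scaled by 1/6, 32 s support, unit dispersion), sampled at `fs` and
  normalized to unit sum so the DC level is preserved exactly. The
  convolution is a single one-sided pass — output at `t` mixes samples at
  and before `t`, like the hemodynamic system itself — with one kernel
  length of reflection padding at the left edge to avoid a startup
  transient. A forward–backward (squared-response) pass was deliberately
  not used: the filter is meant to *be* the HRF, not its autocorrelation.
  Whether to apply this smoothing to resting segments at all is
  switchable (`PreprocessConfig.apply_hrf`).
* **DCT detrend.** A linear idempotent projection removing every DCT-II
  basis function whose period exceeds the cutoff (default 128 s, the
  conventional high-pass default for hemodynamic drift), including the
  constant term; outputs are zero-mean per channel. If the cutoff exceeds
  the recording length only the mean is removed, with a warning.

## Wavelet decomposition

The mother wavelet is the complex Morlet
`ψ(t) = (πB)^(−1/2) exp(2πi f_c t) exp(−t²/B)` with dimensionless
bandwidth `B = 2` and center frequency `f_c = 0.5`. An analysis frequency
`f` maps to scale `s = f_c · fs / f` samples (the standard
center-frequency relation). The default grid is log-spaced, 12 voices per
octave, 0.005–2 Hz, covering all six physiological intervals with uniform
relative resolution; for connectivity it is restricted to frequencies
strictly inside the 0.01–0.1 Hz analysis band.

Numerical choices:

* **L1 normalization.** The kernel's frequency response peaks at exactly 1,
  so a unit complex exponential yields unit-modulus coefficients at its
  own frequency (a real sinusoid of amplitude A yields A/2) and
  time-averaged amplitudes are comparable across scales.
* **Boundary handling.** The transform is evaluated as a circular FFT
  convolution on the series' own grid (`boundary="periodic"`). Zero
  padding was measured to leak spectral energy across frequency zero,
  perturbing low-frequency phases by ~1e−3 rad and degrading the
  complete-coherence identity from 1 − 3e−7 to ≈0.9994; circular
  evaluation preserves a constant cross-channel phase relation to
  numerical precision. Its cost is that coefficients near the edges mix
  the two ends of the (detrended, hence approximately matched) series.
  `boundary="zero"` is available where compact support is preferred.
  Surrogates pass through the same operator, so the validity comparison
  is unaffected by this choice.
* **Cone of influence.** Edge samples are retained: amplitude and WPCO
  average over the whole series. (Time averages, not energy averages:
  the amplitude is the mean instantaneous modulus.)
* **Phase.** Four-quadrant `atan2(b, a)` in (−π, π]; zero-modulus cells
  have undefined phase and are flagged NaN (they map to a zero phasor in
  coherence sums, contributing nothing).

## Coherence and surrogate validity

`WPCO(ω_k) = √(⟨cos Δφ⟩² + ⟨sin Δφ⟩²)` per grid frequency, then averaged
over the analysis band (arithmetic mean over grid frequencies strictly
inside the band). Channel pairs are canonicalized lower-index first; WPCO
is even in Δφ so the orientation is immaterial.

Significance uses classic AAFT surrogates: rank-remap onto a sorted
Gaussian draw, Fourier phase randomization preserving the modulus spectrum
(DC and Nyquist bins fixed), rank-remap back onto the original values. The
surrogate's sorted values equal the original's exactly; the spectrum is
approximate. The ensemble default is m = 100. A pair is valid when
`band WPCO > mean + 2·SD` of the m surrogate band values (sample SD,
strict inequality). Design points:

* **Both channels are surrogated** per realization (default): the phase
  relation is destroyed symmetrically. `surrogate_mode="one"` keeps the
  first channel original.
* **Validity is assessed on the band average** — one test per pair, the
  granularity at which results are reported — while per-frequency
  surrogate means/SDs and masks are stored for finer inspection.
* Each surrogate realization resamples every channel once and scores all
  C(22,2) = 231 pairs against it, so the ensemble costs m CWTs per channel
  rather than m per pair.
* All draws come from named counter-based substreams of one root seed,
  so pair matrices are bit-reproducible.

Under the null (independent channels) the band-level 2·SD rule empirically
passes ≈4% of pairs (the acceptance suite bounds the mean rate below 10%
over 50 cohorts with m = 100) — the surrogate test controls the
low-frequency inflation that makes raw WPCO ≈0.1–0.3 for finite
uncoupled series.

## ROI aggregation

The shipped channel→ROI table maps the 22 channels onto 10 prefrontal
ROIs; CH04 (frontopolar) and CH19 (orbitofrontal) sit on the midline and
belong to both hemispheric instances of their region. The edge between two
ROIs is the mean over their cross-ROI channel pairs (each unordered pair
counted once, same-channel pairs excluded) of the band WPCO with invalid
pairs entering as **zero** — the strict reading of the zeroing rule. The
alternative reading, averaging only the valid pairs, is implemented as
`mode="valid-only"`; the aggregation mode is recorded in every manifest.
Within-ROI coherence is exported separately (`RoiNetwork.intra`), never on
the diagonal, which is zero by convention.

## Group statistics

Features are per-(subject, condition): 10 ROI band amplitudes and 45
ROI-pair band WPCO values.

* **Transfer distance** — paired t per feature, near vs far, matched by
  subject (df = n − 1).
* **Prior level** — subjects are ranked by prior score and split into top
  and bottom `ceil(0.27·n)` groups (the classical item-analysis fraction;
  9 per group at n = 31, ties broken deterministically by subject id, the
  groups always disjoint). The groups contain different people, so the
  paired comparison matches them by within-group rank (k-th highest vs
  k-th lowest-group counterpart), giving df = group size − 1 = 8 at
  n = 31. This is the package's explicit construction of a matching that
  a paired test over such groups implies.
* **Performance** — Pearson r of each feature with the condition's
  performance score, p from the t transform on n − 2 df.

P-values are reported uncorrected — one test per feature, as is common in
exploratory connectivity reports — with Benjamini–Hochberg q-values
alongside, so both conventions are visible. Degenerate cases
(zero-variance differences) are flagged rather than silently dropped.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* **Oscillators** are white noise spectrally masked to
  `center ± fractional_bandwidth·center` and scaled to a target RMS —
  realistic non-sinusoidal rhythms whose spectral mass lies inside the
  declared interval by construction. The default set places one rhythm in
  each physiological interval with the low-frequency (myogenic–endothelial)
  components dominating cardiac/respiratory pulsation, the usual ΔHbO
  profile.
* **Coupling** mixes a shared in-band source (the second channel's copy
  phase-shifted by a fixed lag applied uniformly to its spectrum) with
  weight κ against an independent source with weight 1 − κ, renormalized
  to the oscillator RMS. κ = 1 with zero noise gives an exactly constant
  in-band phase difference; expected WPCO grows monotonically in κ.
* **Drift** is a half-cosine with period twice the recording (exercising
  the DCT detrend); **noise** is i.i.d. Gaussian.
* **Behavior**: per-(subject, condition) coupling modulation
  κ ~ Uniform(kappa_range), performance
  `= intercept + slope·κ + N(0, residual_sd)`, so the planted population
  correlation is `slope·sd(κ) / √(slope²·var(κ) + residual_sd²)`; the
  prior score is an independent standard normal (the concept-sorting
  composite is not modeled further).
* All randomness flows from one root seed through substreams keyed by
  (stream, subject, condition, channel, oscillator/coupling index), so
  any recording can be regenerated bit-identically in isolation.

What the generator does **not** emulate: optode/scalp physics, motion
artifacts, heteroscedastic or non-Gaussian measurement noise, spatially
correlated background networks, or the stimulus protocol. Passing tests
therefore demonstrate that the pipeline recovers the structure it is
pointed at under a faithful signal model — not that real recordings meet
that model.

## Problem sizes in the verification suites

Sampling rate and duration of synthetic inputs are free parameters chosen
per check: the coherence identity and preprocessing checks run at the
reference acquisition scale (13.33 Hz, 600 s); the null calibration uses
50 cohorts of 22 white-noise channels at 0.5 Hz × 1200 s with m = 100
surrogates; κ-recovery uses 2 Hz × 1600 s pairs (long enough that the
finite-sample coherence floor, ≈0.11 there, does not mask the smallest
planted effect); the statistics calibrations draw feature tables directly
(n = 31 subjects, 100 seeds for power at Cohen's d = 1.2, 500 for the
type-I rate). The end-to-end pipeline tests run a 4-subject, 180 s,
8-surrogate configuration plus the shipped 8-subject, 120 s, 30-surrogate
demo configuration.

## Known limitations

* Periodic boundary handling assumes roughly matched series ends; apply
  the DCT detrend first (the default chain does) or use
  `boundary="zero"` for strongly non-stationary inputs.
* AAFT preserves the spectrum only approximately for strongly non-Gaussian
  marginals; iterated refinement (IAAFT) is out of scope.
* The validity rule tests one band per pair; no correction is applied
  across the 231 pairs at the validity stage (the group layer reports
  q-values for its own multiplicity).
* ΔHbR is not modeled; the pipeline operates on ΔHbO only.
* SNIRF ingestion, motion-artifact correction, short-separation
  regression and graph-theoretic network metrics are out of scope.
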