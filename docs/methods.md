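# Methods

## Problem and signal model

Cerebral autoregulation (CA) keeps cerebral blood flow roughly constant as
systemic arterial pressure fluctuates. In the Mayer-wave band (~0.1 Hz,
nominally 0.08–0.12 Hz), intact CA acts like a high-pass element: slow
pressure oscillations reach the middle-cerebral-artery flow velocity damped
and phase-advanced. The phase shift (PS) between the Mayer-band components
of blood-flow velocity (BFV) and blood pressure (BP) is therefore a bedside
index of CA: values around 0.8–1.4 rad are typical of intact regulation;
values near zero indicate impairment. The package estimates this PS, per
hemisphere, from paired uniformly sampled BP/BFV recordings (default
δt = 0.01 s), restricted to times and scales where the two signals are
actually coherent.

Two estimators are implemented on sliding frames of N = 2^14 samples
(163.84 s ≈ 2.7 min at δt = 0.01 s):

* **Wavelet coherence (primary).** Each centered frame is transformed with
  the analytic Morlet wavelet (ω0 = 6) by FFT circular convolution on a
  geometric scale ladder s_j = 2δt·2^(j/12) (12 voices per octave). Scales
  map to pseudo-frequencies via the Fourier factor ω0/(2π) = 0.9549:
  f_j = 0.9549/s_j. On this ladder the Mayer band contains nine
  pseudo-frequencies (0.124 … 0.078 Hz), spaced 0.007 Hz at the top and
  0.005 Hz at the bottom of the band. Cross- and auto-wavelet spectra are
  smoothed (below); squared coherence is

      H²(n,s) = |S(c_x* c_y)|² / ( S(|c_x|²) · S(|c_y|²) ),

  and phase θ(n,s) = atan2(Im, Re) of the smoothed cross-spectrum is
  interpreted only where H² ≥ 0.6 (the Morlet scale-decorrelation
  coefficient). Ungated phase is missing (NaN), never zero, and every
  downstream average skips missing values.
* **Welch/STFT comparator.** The same frame is split into L = N_frame/N_shift
  Hann windows (default 1024 samples, hop 512, L = 32), each window is
  mean-centered and tapered, and auto/cross spectral densities are averaged
  over the frame; magnitude-squared coherence and phase follow from the
  averaged densities. The frequency axis is fixed at k/(N_win·δt) — a
  0.0977 Hz bin width that cannot resolve structure inside the Mayer band,
  which is the comparator's inherent limitation.

Phase sign convention, shared by both methods: **positive phase = BFV leads
BP** (atan2 of conj(BP-side)·(BFV-side)). This makes healthy CA a positive
PS in both estimators, so their outputs are directly comparable.

## Smoothing (wavelet path)

An unsmoothed normalized coefficient product is identically one, so
smoothing is what gives wavelet coherence its meaning; a configuration with
smoothing disabled is refused as an error rather than computed.

* **Time smoothing** multiplies each scale-row's DFT by the Gaussian
  exp(−c·s²·ω²) (unit DC gain). The default coefficient is c = 1/4;
  c = 1/2 — the choice equivalent to convolving with the Morlet's own
  envelope, common in the wavelet-coherence literature — is available as
  `coh.time_kernel_coeff`.
* **Scale smoothing** is a forward boxcar over Ls voices (row j averages
  rows j … j+Ls−1), Ls = round(0.6/δj) = 7 at 12 voices. Rows near the
  deep-scale end average only the available rows (renormalized), so no
  scale is dropped.

Two consequences of these defaults are worth knowing:

* With c = 1/4 the time smoother is narrower than the coefficient
  correlation length, so the estimator has few effective degrees of
  freedom: for *independent* noise pairs the Mayer-band fraction of cells
  passing the 0.6 gate is ≈ 0.27 (the test suite measures this). With
  c = 1/2 the same measurement drops to ≈ 0.17. Interpreting gated
  fractions as evidence of physiological coupling therefore requires the
  stronger smoothing or a null calibration; the default keeps the weaker
  kernel for continuity and exposes the alternative.
* The forward (one-sided) scale window folds a tone's coherence into the
  voices *above* it, biasing the coherence maximum upward in frequency by
  roughly Ls/2 voices (~3 voices ≈ 19%). The subrange-scan recommendation
  inherits this bias; it still separates coupled from uncoupled subranges,
  but its argmax should not be read as the physical oscillation frequency.

## Band metrics

* **Band extraction** reports, per frame, the gated phase at either the
  in-band pseudo-frequency with maximal mean coherence ("maxcoh", default)
  or a fixed configured frequency. In sliding-frame use each frame
  contributes the mean gated phase over its central segment (width = frame
  shift by default), preserving the wavelet transform's time localization;
  the whole frame is used when frames do not overlap.
* **Subrange scan**: per in-band pseudo-frequency, the fraction of time
  samples passing the gate, pooled over frames; the frequency with the
  largest fraction is flagged as the recommended subrange.
* **Sensitivity** of a CO2 challenge: η = |θ_ext − θ̄| / θ̄, where θ̄ is the
  mean gated phase over a pre-episode baseline window and θ_ext the extreme
  gated phase during the episode (minimum for hypercapnia, which depresses
  PS; maximum for hypocapnia, which raises it; the direction is always
  supplied, never guessed). The formula presumes a positive baseline; θ̄ ≤ 0
  raises an undefined-sensitivity error. Both windows must contain at least
  five gated samples.
* **Subject summary**: per-side mean and SD of gated phases with limits
  mean ± 3·SD (multiplier configurable), and a classical pooled two-sample
  t-test between sides as the interhemispheric asymmetry p-value.
  Zero-variance degeneracies are resolved explicitly (identical sides
  → p = 1, distinct constant sides → p = 0). Phase averaging is plain, not
  circular: gated CA phases live well inside (−π, π) in the intended
  regimes, and a warning is emitted if any gated phase comes within 0.2 rad
  of the branch cut.

## Synthetic data: what it emulates, and what it does not

No clinical recordings ship with the package; the generator produces the
surrogates every test runs on. BP is a sum of cardiac (1 Hz), respiratory
(0.25 Hz) and Mayer (0.1 Hz) sinusoids plus AR(1)-and-white noise
(AR coefficient 0.9, so the null-coherence calibration is not trivially
white); BFV channels carry the same components with the Mayer component
phase-advanced by the configured lead — the ground truth the pipeline must
recover — and independent noise realizations. CO2 challenges are emulated
purely as episodes overriding the lead, blended with a 5 s raised-cosine
ramp (an instantaneous phase jump would inject broadband artifacts that no
physiology produces). Cohorts draw healthy leads uniformly from 0.8–1.4 rad,
identical on both sides; unilateral impairment halves one randomly chosen
side. All randomness flows from a single explicit seed.

Defaults represent a clean recording: Mayer amplitude 1.0 against a white
noise SD of 0.1 ("SNR 10"); at these conditions the pipeline recovers a
constructed lead to within 0.05 rad (the test suite sweeps 0.3–1.4 rad).

The generator is deliberately phenomenological. It does not model the
hemodynamic transfer function (no Windkessel or autoregulation ODE), beat
morphology, measurement artifacts, gaps, or non-stationary drift beyond an
optional slow amplitude modulation. Passing tests therefore demonstrate
estimator correctness on signals with known coupling — not robustness to
the full pathology of clinical recordings.

## Numerical choices

* Frames: requested lengths are rounded **down** to a power of two
  (16384 stays 16384; 1000 becomes 512), matching the reference
  parameterization; zero-padding **up** is a config option. Frames are
  mean-centered only; linear detrending is opt-in.
* The CWT is plain circular convolution (no padding) by default; a
  pad-to-2N option suppresses wraparound. The cone of influence
  (√2·s e-folding from each edge) is attached as metadata; masking by it is
  opt-in and off by default.
* Mayer-band membership on the grid compares pseudo-frequencies rounded to
  3 decimals against the band edges, which is what makes the nine-frequency
  band span 0.078–0.124 Hz reproducible (the top grid value is 0.12448 Hz).
* Welch frames use exactly L = N_frame/N_shift windows; the last window
  overruns the frame by N_shift samples and is zero-padded after centering
  and tapering, so the printed L = 32 holds. Coherence bins with vanishing
  auto-power are missing, never zero. The L = 1 configuration (coherence
  identically 1) is refused.
* The sliding STFT path caches per-window spectra and re-sums them in
  window order, making the incremental result bit-identical to per-frame
  recomputation. Streaming replay of a file reproduces batch tables
  bit-for-bit.
* Restricting the scale ladder (`cwt.fmin`/`cwt.fmax`) with at least Ls−1
  voices of margin below the band leaves band rows bit-identical to the
  full 157-scale ladder (forward boxcar ⇒ only deeper rows contribute);
  the test suite exploits this as a pure speedup. Statistical tests run at
  the reference frame size (16384 samples) with seeds fixed in the tests;
  Monte-Carlo repetition counts are kept at 10–50 runs per check.
* Result tables are written with shortest-round-trip float formatting, so
  write→read is the identity; a fixed-precision option exists for export.

## Known limitations

* The 0.6 coherence gate is a fixed convention, not a significance level;
  no AR(1)-surrogate significance testing is provided.
* Recordings with gaps, NaNs or non-uniform sampling are rejected, not
  repaired.
* Left and right hemispheres are analyzed as two independent BP-paired
  channels; no joint bilateral model.
* Phase statistics are non-circular by design (see above) and would be
  biased for phases near ±π.
* The t-test treats gated per-frame phases as independent samples;
  overlapping frames violate this, so asymmetry p-values from heavily
  overlapped sliding analyses are optimistic.
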