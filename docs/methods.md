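# Methods

This note documents the models implemented in `ecgwell`, the choices made
where the procedure was genuinely open, and what the synthetic data can and
cannot demonstrate.

## Pipeline overview

1. **Segmentation.** Each subject-day record (default 500 Hz, 20–25 s) is
   cut into 5 s windows sliding by 1 s: `floor((T − 5)/1) + 1` windows, so a
   20 s record yields 16 and a 25 s record 21. Windows start at integer
   multiples of the step from t = 0; a trailing partial window is dropped.
2. **Resampling.** Each 2500-sample window is reduced to a fixed model
   input length of 500 points by polyphase resampling (`scipy`
   `resample_poly`, linear-edge padding). An anti-aliased reduction was
   chosen because naive decimation would fold energy above 50 Hz into the
   band the frequency-domain features measure. The identity case
   (`target_len == len`) bypasses the filter.
3. **Features.** 184 per segment, in four families (below).
4. **Normalization and labels.** Min–max scaling per feature, fitted on the
   training split only; constant features map to 0 (they carry no
   information and the alternative divides by zero). Test values may leave
   [0, 1]. Labels: per-subject Fisher–Yates (normal-scores) transform of
   the HI series with mid-ranks for ties and the boundary-safe plug-in
   `φ⁻¹(G/(I+1))` — the literal `G/I` sends the top rank to +∞. Scores
   > 0 are *Better* (label 0); a score of exactly 0 (e.g. an all-tied
   series) falls to *Worse* (label 1), since only strictly positive scores
   denote better-than-typical days. Day-*t* features pair with the day
   *t + lag* label, lag 1 by default.
5. **Models.** Random forest and PSO-tuned RBF-SVM (parameters below),
   evaluated by stratified 70/30 holdout or three stratified 67/33
   resampling rounds with arithmetically averaged metrics. The
   "three-fold cross-validation" of the protocol is deliberately
   implemented as repeated resampling, which is how the procedure is
   described (67% train / 33% test in each of three rounds); classical
   disjoint stratified folds are available via `method="kfold"`.

## Feature families

**Time/frequency statistics (F1–F26).** Thirteen shape statistics on the
raw segment and the same thirteen on its one-sided FFT amplitude spectrum.
Two of the thirteen are deliberately non-standard and kept for fidelity to
the feature set being reproduced: `D_x` is the mean squared deviation about
the *absolute* mean, and `K_x = D_x / x_av`. Skewness and kurtosis use the
conventional moment ratios m₃/σ³ and m₄/σ⁴, and the root amplitude is
`(mean √|x|)²` — the only readings under which the dimensionless factors
(crest, shape, clearance, impulse, skewness, kurtosis) are invariant under
amplitude scaling, a property the test suite checks. The frequency-domain
copy applies the same formulas to the amplitude spectrum (scaled so a pure
sinusoid's bin equals its amplitude); whether the original indicators used
amplitude, power or normalized spectra is not specified anywhere, so
amplitude was fixed as the default, DC bin included (configurable).
Zero denominators (all-zero inputs) yield 0 with a logged warning, keeping
feature matrices rectangular.

**Wavelet-packet energies (F27–F34).** Full packet tree to depth 3 (the
8 same-depth bands), terminal-node energies in natural frequency order.
The wavelet family is unspecified in the source protocol; db4 is the
default as a common ECG choice. Boundary handling is periodization: for
orthogonal wavelets and lengths divisible by 2³ the transform is then
orthonormal and band energies sum *exactly* to the signal energy, which
makes energy conservation a sharp test invariant; symmetric extension
(the usual toolbox default) inflates total energy by boundary
coefficients and was rejected for that reason. For 500-point segments
(not divisible by 8) periodization introduces a sub-percent boundary
effect with no consequence for classification.

**EEMD per-IMF statistics (F35–F164).** EMD sifting uses cubic-spline
envelopes through local extrema with mirror extension of two extrema past
each end, Huang's SD stopping criterion at 0.2 with at most 10 sifts per
IMF, and terminates on a monotone residue. These sifting constants are the
classical defaults; the source protocol does not state them. EEMD defaults:
M = 100 trials, white-noise std 0.2 × signal std, per-trial noise from
independent substreams of one master seed (reproducible, parallel-safe).
The feature stage fixes 10 IMF slots because the feature vector is
rectangular by construction: surplus low-frequency modes are folded into
the residue, missing slots zero-padded (their 13 statistics are then 0).
A 500-point segment typically yields 4–7 modes, so trailing slots are
commonly zero — this is expected, not an error. Ordering is IMF-major
(all 13 statistics of IMF1 first); the intra-block order is this
package's canonical choice.

**RCMSE (F165–F184).** Sample entropy with m = 2, r = 0.15 × std (the
canonical multiscale-entropy settings; unspecified in the source
protocol), Chebyshev distance, both template counts over the first N − m
templates, self-matches excluded. The tolerance is anchored once to the
original series' std, not per scale. At scale τ the match counts are
summed over all τ coarse-graining offsets before the logarithm; at τ = 1
this reduces exactly to sample entropy. Undefined values (zero counts)
are imputed as 0, flagged and logged; the composite aggregation makes
them rare even on 500-point segments at τ = 20 — a property verified by
simulation against single-offset multiscale entropy.

## Models

- **Random forest**: 500 trees (unspecified upstream; a conventional
  size), `mtry` = 12 candidate features per split for the 184-feature
  input and 20 for 500-dimensional raw input, per the stated protocol.
- **PSO-SVM**: canonical global-best PSO, 20 particles, ≤ 200 iterations,
  termination when the global best improves by < 10⁻³ over a 20-iteration
  patience window, c₁ = 1.5, c₂ = 1.7, positions clipped to
  [0.1, 100]² and velocities to |v| ≤ 100 (a signed quantity cannot have
  the range "[0.1, 100]", so the upper magnitude is used), inertia
  decreasing linearly 0.9 → 0.4 (a canonical schedule; unstated
  upstream). The objective is 1 − mean stratified k-fold CV accuracy on
  the training split; the final SVM is refit on the full training data.
- **Metrics**: REC, PRE, F-score, ACC from exact integer confusion
  counts. The positive class for REC/PRE/F is label 1 (*Worse*) by
  default — detecting deterioration is the clinical aim and the upstream
  protocol leaves the choice unstated; it is configurable and does not
  affect ACC.

## Synthetic cohort

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T stand-ins) placed
at jittered inter-beat intervals (base heart rate 72 bpm, interval SD
15 ms in the "better" regime), with additive measurement noise at 20 dB
SNR. The "worse" regime inflates interval jitter by (1 + 2·class_effect)
and per-beat morphology jitter by (1 + class_effect); amplitude ranges of
the two regimes overlap by construction, so the class signal lives in
regularity, not scale. HI series are persistent ordinal chains (keep
yesterday's value w.p. 0.6, else redraw from a fixed distribution
(0.05, 0.20, 0.35, 0.25, 0.15) over 1..5); the day's waveform regime is
"better" iff HI ≥ the subject's median, mirroring the downstream
binarization. The HI distribution of the motivating cohort is not
characterized anywhere, so this distribution is a modelling choice, not
an estimate of it.

What passing tests show: the extractors measure what they claim (entropy
rises with beat irregularity; band energies, IMF counts and statistics
behave as the identities require) and the full pipeline separates
regularity regimes far better from constructed features than from raw
waveforms. What they do not show: performance on real elderly ECG, where
morphology variation, artifacts, device noise and the HI's subjective
drift are all richer than this generator emulates. Published metric
values from the motivating private cohort are therefore not targets here;
only the directional conclusion (features ≫ raw) is reproduced.

## Problem sizes and numerical choices

- The feature-vs-raw experiment (`ecgwell.experiments`) uses 6 subjects ×
  11 days (~1200 segments), class_effect 1.0 (the generator default),
  EEMD with M = 10 trials for the bulk extraction, and 10 train/test
  seeds over a single extraction. M = 10 keeps the experiment at minutes
  of CPU; the ensemble size affects IMF smoothness, not the presence of
  the class contrast, and the package default remains M = 100.
- Segments shorter than the window yield an empty segmentation with a
  warning, not an error; monotone inputs yield zero IMFs with the input
  as residue.
- EMD reconstruction (Σ IMFs + residue = input) holds to machine
  precision because sifting is purely subtractive; EEMD reconstruction
  deviates by the non-cancelled ensemble noise, shrinking as 1/√M.
- Seeds everywhere are `numpy` `SeedSequence` substreams of one master
  seed; identical configurations reproduce byte-identical features.

## Known limitations

- The generator has no arrhythmias, baseline wander or electrode
  artifacts; conclusions about real-device data require real data.
- QRS detection and beat annotation are deliberately out of scope — no
  stage uses clinical beat semantics.
- Feature selection/penalization is not implemented (left open upstream
  as future work); deep baselines are excluded behind the pluggable
  classifier contract.
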