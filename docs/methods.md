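# Methods

This note documents the models, conventions and design choices behind
`ssvepnav`, in the order the data flows: simulator → preprocessing →
decoder → game → metrics.

## Synthetic gaze-dependent SSVEP EEG

### What is modelled

The simulator reproduces the *statistical* structure a spatial-topography
decoder exploits, not cortical biophysics. A simulated subject is defined by
`SimConfig.seed`; all subject-level quantities (harmonic phases, drifted
online topographies, SNR calibration) derive from it, while trial noise is
driven by a separate per-session stream, so one subject can be "recorded"
in independent sessions.

**Spatial gain maps.** Each gaze target c has a nonnegative per-channel gain
vector built as a 2-D Gaussian bump on a schematic unit-radius scalp
(azimuthal projection of the 10–20 layout, 32 BioSemi-style channels):

* E — centred on O2 (right-occipital: the flicker falls in the left
  hemifield, the response is contralateral),
* W — centred on O1 (mirror image),
* S — centred on Oz (occipital midline),
* N — centred midway between Oz and Cz (centro-occipital; Pz is the nearest
  channel).

The bump width is `0.45 / topography_sharpness` scalp radii; gains are
normalised to unit maximum. The human literature describes these topography
shifts qualitatively only, so the peak anchors and width are package
choices; sharpness → ∞ degenerates each map to its single peak channel,
which is convenient for testing.

**Signal.** Class c's trial carries
`scale_c · gains_c ⊗ Σ_h a_h sin(2π h f_stim t + φ_{c,h})` with
`f_stim = 15 Hz`, three harmonics, relative amplitudes `(1, 0.5, 0.25)`
(matching the three harmonic pairs the decoder's reference uses). The phases
φ are drawn once per subject per (class, harmonic) and held fixed across
trials: the SSVEP is stimulus-locked, so single-trial phases cluster by
class. Epoch time starts at stimulation onset (t = 0).

**Noise.** Two additive processes per channel, both constructed in the
frequency domain (deterministic spectral shaping × complex Gaussian draws),
which makes their band powers analytic:

* pink noise, amplitude ∝ f^(−1/2) (power ∝ 1/f) flattened below 1 Hz,
  scaled to `noise_rms` (default 10 µV RMS broadband — a typical awake-EEG
  background that keeps clean trials far below the ±100 µV artifact rule);
* alpha, a narrowband Gaussian bump at 10 ± ~1 Hz, scaled to
  `alpha_power · noise_rms` and weighted toward occipital channels
  (0.25 + 0.75 · Gaussian around Oz).

**SNR definition and calibration.** `snr_db` is the ratio of 15 Hz signal
power to noise power in a 1 Hz band around 15 Hz, at the class's peak
channel. Because the noise is spectrally constructed, its expected band
power is computed in closed form and the fundamental's amplitude is solved
for exactly; the realised per-epoch SNR then scatters around the target
(verified to ±1 dB over 100 epochs in the tests). The default `snr_db = 10`
puts the full pipeline in the regime of the human study's high-performing
subjects (cross-validated accuracy ≥ 0.95 on 200 trials); no per-class
amplitudes or SNRs were published, so the default cannot be calibrated to
recorded data.

**Session drift.** `drift ∈ [0, 1]` perturbs the gain maps used for the
"online" session: centres shift by `drift · (0.2–0.4)` scalp radii in a
random direction and gains are roughened by `exp(drift · N(0, 0.5))`, then
renormalised. `drift = 0` makes both sessions identical; `drift = 1`
emulates the low offline/online topography similarity observed in subjects
who lost closed-loop control. The perturbation draws are consumed even at
drift 0 so changing `drift` never reshuffles other subject-level randomness.

### What is *not* modelled

No volume conduction or source geometry, no eye movements / EOG, no
movement or muscle artifacts (the artifact screen is exercised with
constructed spikes), no inter-channel noise correlation beyond the shared
alpha weighting, no non-stationarity within a session, no latency jitter of
the SSVEP relative to the trigger. Passing tests therefore show the pipeline
is correct and behaves sensibly across SNR/drift regimes — not that it would
attain any particular accuracy on recorded EEG.

## Preprocessing

Offline path: 1–80 Hz zero-phase Butterworth bandpass (4th order, applied
forward–backward with `sosfiltfilt`; only the band itself is prescribed by
the protocol, the filter family is a package choice), discard of the first
500 ms after onset (`t0` records the offset so references stay
stimulus-locked), decimation by an integer factor (1024 → 512 Hz; the 80 Hz
band edge is far below the new Nyquist, so plain sample picking is
alias-free), then a fixed ±100 µV peak-amplitude artifact rule — an
automated, reproducible surrogate for the original semi-automatic visual
screening. The online path applies bandpass + crop only, with downsampling
and screening opt-in; the shipped default config enables online downsampling
so closed-loop trials match the geometry the filter bank was trained on.

## Decoder

* `fit_cca` solves CCA via Cholesky whitening of the covariance blocks and
  an SVD of the whitened cross-covariance; covariances use unbiased (T−1)
  normalisation, means are removed per concatenated segment. Rank-deficient
  covariances fall back to an escalating ridge on the diagonal with a
  warning. Sign convention: the largest-magnitude element of each EEG-side
  weight vector is positive (reference-side vector flipped along with it).
  The test suite cross-checks against an independently coded generalized
  eigenproblem and against scikit-learn's iterative CCA.
* Per-class filters are fit on the concatenation of that class's trials,
  each paired with its own onset-locked reference copy; covariances are
  sums over trials, so trial order is irrelevant.
* Features: for each class and component, the Pearson correlation between
  the filtered trial and the filtered reference. The published feature
  vector `[r_1 r_2 r_3 r_4]` leaves the per-class dimensionality ambiguous;
  the default keeps all 6 components per class (24 features), with
  `feature_mode="first"` for the 4-feature variant. Correlations are
  rectified to absolute value (CCA sign ambiguity) and clipped to [0, 1];
  zero-variance projections map to 0.
* LDA: class means + pooled unbiased within-class covariance shrunk as
  `(1−γ)S + γ(tr S/d)I`, default `γ = 1e−6` (numerical stability only);
  γ = 1 reduces prediction to nearest class mean under equal priors.
  Prediction ties break to the lowest class index in the canonical order
  (N, E, W, S); a fully degenerate covariance falls back to an identity
  metric, so identical features yield the prior argmax.
* Cross-validation is stratified k-fold with the filter bank *and* the
  classifier re-fit inside every training fold.
* Models serialise to a single versioned `.npz` (JSON metadata + float64
  arrays); loading reproduces predictions bit-exactly.

## Game and closed loop

Coordinates: `goal_offset = goal − screen centre` in screen coordinates
(x positive toward E, y positive toward S). The command named after a
direction moves the landscape that way: N decrements dy, S increments dy,
E decrements dx, W increments dx. The protocol never defines signs, only
"moved one step in the respective direction"; this convention is fixed here
once. Overshooting past the centre is allowed (symmetric grid). Rounds start
at a uniformly random (±6, ±6) corner, `step_limit = 25`.

The greedy policy reduces the larger |coordinate| first and breaks the
|dx| = |dy| tie toward x — deterministic for testability; it always strictly
reduces the Euclidean distance. `run_closed_loop` spawns one seed per round,
so extending a session never perturbs earlier rounds. Stimulation/animation
(2 s)/blank (1.5 s) durations are accounting metadata for session-time
estimates, not real-time waits. A symmetric-confusion agent (correct with
probability p, else uniform among the other three directions) bypasses EEG
simulation for fast Monte Carlo.

## Metrics

* ITR uses Wolpaw's formula with the 0·log 0 = 0 limits; it is zero at
  chance (P = 1/C) and strictly increasing above it. Note the formula is
  positive at P = 0 (a known property, not a bug). Applied to the published
  offline accuracy column at C = 4, T = 3.5 s it reproduces the published
  offline ITRs for the rows where the printed accuracy rounding is exact;
  the published *online* ITRs are not consistent with T = 3.5 s applied to
  the printed online accuracies, so they are not asserted anywhere.
* The online accuracy estimator is the per-round fraction of steps that
  reduced the Euclidean distance to the goal, averaged unweighted over
  rounds (the per-round normalisation is prescribed; cross-round
  aggregation is not — a step-weighted pooled variant sits behind
  `weighted=True`). Won and lost rounds count identically. **Bias caveat:**
  this estimator lower-bounds the true accuracy only when the user's intent
  may deviate from the optimal strategy. For a simulated agent whose intent
  is *exactly* greedy-optimal it is upward-biased: off-axis, one of the
  three wrong commands also reduces distance, so its expectation is
  p + (1−p)/3 · Pr(off-axis) ≥ p. The tests assert both directions (above
  p for optimal intent, below p for random intent).
* Spectral topographies: squared DFT amplitude at the bin nearest f,
  normalised by the raw sample count (a unit sinusoid at an exact bin gives
  0.25), averaged over trials, zero-padded to the next power of two by
  default — 15 Hz is *not* an exact bin for 3.5 s epochs at 512 Hz
  (bin 52.5), and padding reduces the scalloping loss. Phase uses the
  cosine-reference convention (cos → 0, sin → −π/2), range (−π, π].
  Offline/online similarity is the channel-wise Pearson correlation of
  grand-average maps.

## Problem sizes

The default experiment follows the human protocol: 32 channels at 1024 Hz,
4 s cues, 2 blocks × 50 sequences (400 trials), 16 rounds with a 25-step
limit. The test suite exercises the same code paths at reduced geometry
(mostly 256–512 Hz, 2 s epochs, 40–200 trials) chosen so every statistical
assertion retains comfortable margins; the full-size +10 dB pipeline
(200 trials, 16 closed-loop rounds) runs once in the end-to-end checks.

## I/O formats

Sessions round-trip through MNE's FIF epochs container plus a plain-text
labels CSV (`trial_index, class, onset_sample`); continuous EDF/BDF/FIF
recordings with an events CSV can be epoched on read. FIF was chosen for
writing because it is the native format of the installed MNE stack; EDF
export would require an additional dependency, and hand-writing EDF was
deliberately avoided.

## Known limitations

* The simulator's Gaussian-bump forward model makes class topographies more
  regular than real SSVEP topographies; absolute accuracies at a given
  `snr_db` are not transferable to recorded EEG.
* The artifact rule is amplitude-only; it cannot reproduce judgement calls
  of visual inspection.
* `new_round` randomises only the corner; obstacle layouts and the visual
  environment are out of scope, as is any real-time rendering.
* Alpha is generated independently per channel (spatially weighted but not
  coherent across channels), which slightly understates the spatial
  structure of real occipital alpha.
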