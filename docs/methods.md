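# Methods

## The problem and the model

Infant EEG recorded during naturalistic interaction mixes neural activity
with ocular, muscular and electrode artifacts whose timing covaries with the
behaviour of interest, so segment deletion is not an option. `icareject`
treats the recording as a linear mixture `X = A S` of statistically
independent sources and removes artifacts *losslessly*: ICA estimates the
mixing matrix `A` (scalp pattern per column) and source time courses `S`;
each component is labelled neural (−1) or artifact (+1); artifact columns
are zeroed and the data re-projected, preserving every sample.

The label comes from a binary linear rule

    H = sign(w · z(x) + b),   z(x) = (x − μ) / σ,

where `x` is a six-dimensional feature vector per component and `(μ, σ)`
are the training-set standardisation statistics. An exact zero maps to
neural: when in doubt, a component is retained, which mirrors how careful
human raters work and biases the tool against discarding signal.

## Preprocessing pipeline

Stage order is fixed; all filters are zero-phase (forward–backward) FIR with
Hamming windows, tap count `round-up-to-even(3.3 / (tbw / srate)) + 1` for
transition bandwidth `tbw = 2 |passband − cutoff₋₆dB|`:

1. **High-pass** — passband edge 1 Hz, −6 dB at 0.75 Hz (3381 taps at
   512 Hz). Aggressive for ERP work but chosen to stabilise the ICA.
2. **Line noise** — zero-phase IIR notch at the mains frequency (default
   50 Hz, ~1 Hz wide). ≥ 20 dB suppression of a test tone, near-identity
   elsewhere.
3. **Robust average reference** — the channel mean is computed after
   excluding detected bad channels, then subtracted from every channel.
4. **Bad-channel detection** — a channel is flagged when (a) its absolute
   correlation with a spherical-spline prediction from all other channels
   falls below 0.7 in more than half of the 1-s windows, or (b) the robust
   z-score (median/MAD across channels) of its high-frequency noise ratio
   exceeds 3 *and* the ratio itself exceeds 0.1. The absolute floor stops
   the z-score from manufacturing outliers when every channel is clean
   (e.g. already low-passed data, where all ratios are tiny and tightly
   clustered).
5. **Interpolation** — spherical splines (order m = 4, Legendre series to
   degree 7, regularisation 1e−5, standard literature constants) rebuild the
   flagged channels; afterwards the full reconstructed set is re-referenced
   to its exact zero mean, so a second pipeline pass leaves the reference
   untouched.
6. **Low-pass** — passband edge 20 Hz with a 25% transition (−6 dB at
   22.5 Hz); 40 Hz available through `PreprocessConfig.lp_passband_hz`.
7. **Gross-epoch rejection** — per non-overlapping 1-s epoch, each channel's
   power (mean squared amplitude) is compared against the grand mean plus
   5 SD of all epoch × channel powers (pooled by default; per-channel SDs
   via `pooled_sd=False`). An epoch is removed whole when more than 70% of
   channels exceed the threshold. Non-overlapping windows make the rule
   deterministic and make retained-duration accounting exact.

ICA runs on the retained samples only: the data are projected onto their
numerical rank (interpolation reduces rank, giving fewer components than
channels), decomposed with extended infomax (mne's implementation; any
algorithm meeting the reconstruction and decorrelation contract would do),
and the unmixing is applied to the full recording so cleaning stays
lossless. Mixing columns are normalised to unit Euclidean norm with the
largest-magnitude entry positive; sources absorb scale and sign, so `A S`
is invariant and every feature below is well defined.

**Idempotence caveat.** Re-running the pipeline re-attenuates whatever
energy sits in the filter transition bands (0.5–1 Hz and 20–25 Hz). For
1/f-shaped signals the high-pass band holds substantial power, so exact
idempotence holds only for content strictly inside both passbands; the test
suite probes it with a 3–15 Hz band-limited dipolar field (< 1% RMS change
on a second pass).

## The six features

Topographic features use the normalised pattern; temporal and spectral
features standardise the source to unit variance first, so the whole vector
is invariant to component rescaling and sign flips.

* **Current density norm** — log ‖ŝ‖ of the depth-weighted minimum-norm
  current estimate of the pattern. Forward model: three concentric spherical
  shells (radii 0.87 / 0.92 / 1.0, conductivities 0.33 / 0.0042 / 0.33 S/m)
  solved per Legendre degree from the boundary conditions (the equal-
  conductivity limit reproduces the homogeneous closed form (2n+1)/n, which
  is unit-tested); 642 free-orientation dipoles on an icosphere at 70% of
  the brain radius. Depth weighting divides each column by its norm; the
  Tikhonov parameter is chosen once per montage by generalised
  cross-validation over unit-norm grid-generated patterns with a 10% white
  sensor-noise floor entering through its closed-form expectation — fully
  deterministic and equivariant under electrode reordering — then frozen.
  Focal, physiologically implausible maps (electrode pops) need far more
  current than smooth dipolar maps; at 32 channels the feature is noisier
  than at high density, which is a known limitation of low-density setups.
* **Range within pattern** — log(max − min) of the normalised map; large
  when one electrode dominates.
* **Mean local skewness** — mean over consecutive 15-s windows of the
  absolute sample skewness of the source. Blink-like sparse positive pulses
  score ≫ 1; stationary noise scores ≈ 0.03. The window is configurable
  (`FeatureConfig.skew_window_s`) because infant recordings are short.
* **λ and fit error** — least-squares fit of log P(f) ≈ a − λ log f over
  2–20 Hz (inside the 20 Hz low-pass; nothing above the passband is read),
  on a Welch estimate with 1-s Hamming windows, 50% overlap and a ≤ 0.5 Hz
  grid (FFT zero-padding). Muscle pushes λ toward 0 or below; ocular drift
  pushes it high; rhythmic peaks inflate the residual.
* **Alpha-band power** — mean natural-log power over 6–9 Hz in infant mode
  (the one-year-old alpha peak sits well below the adult 8–13 Hz band;
  adult mode uses 8–13 Hz). The classifier records its training band and
  refuses to score tables extracted in the other mode.

## Classifier

Regularised linear discriminant analysis on z-scored features: shared
within-class covariance shrunk toward a scaled identity, `Σγ = (1−γ)S +
γ (tr S / p) I`, with `γ` either fixed or chosen analytically
(Ledoit–Wolf, the "auto" default); `w = Σγ⁻¹(μ₊ − μ₋)` and
`b = −w·(μ₊+μ₋)/2`, placing the boundary at equal Mahalanobis distance
from the class means. Training requires ≥ 10 examples per class (relaxed to
2 inside cross-validation folds, where leave-one-out would otherwise be
impossible) and refuses constant features by name. Agreement between two
labelings is the disagreement fraction (MSE); stratified k-fold
cross-validation is seeded and deterministic, with k = n handled as
leave-one-out.

## ERP validation

Epochs of −1.0…+0.8 s around fixation onset (saccade onset ≈ −100 ms);
events touching rejected samples are dropped and reported. Baseline is the
−1000…−700 ms mean per epoch and channel. ROI clusters default to
Fp1/Fp2/AF3/AF4 (frontal pole), C3/Cz/C4 (central) and O1/Oz/O2
(occipital) and are fully configurable — the defaults are this package's
choice of plausible 10–20 clusters. The adaptive mean finds the
largest-|amplitude| sample within ±50 ms of the window centre (earliest
sample on ties; absolute amplitude so negative-going infant components are
measured correctly) and averages ±10 ms around it. Ocular transients are
read at the frontal pole in −100…100 ms, the visual response over occipital
electrodes in 200–300 ms.

## Synthetic data

The generator provides labelled components with the statistical structure
the classifier exploits; separation lives in feature space, not in injected
labels, which is what makes held-out classification a meaningful test.
Defaults: 512 Hz, 120 s, 32-channel 10–20 montage on the unit sphere, class
mix 30% alpha-neural / 20% broadband-neural / 15% blink / 10% lateral eye
movement / 15% muscle / 10% electrode pop. Everything is bit-reproducible
from (spec, seed).

* *neural_alpha* — 1/f^λ noise (λ ~ U(0.8, 1.6)) plus an
  amplitude-modulated oscillation at U(6, 9) Hz (infant) or U(9, 13) Hz
  (adult), dipolar map with a posterior bias.
* *neural_broadband* — pure 1/f^λ source; dipolar map with a mild superior
  bias so background activity also reaches central electrodes.
* *blink* — positive 200–400 ms pulses at ~6/min (infants blink far less
  than adults) over a weak pink floor; frontal-pole Gaussian cap map.
* *lateral_eye* — step-like gaze traces (~30 ms sigmoidal transitions);
  left–right antisymmetric frontal map.
* *muscle* — noise whose power rises above ~15 Hz; focal cap on an edge
  electrode.
* *channel_pop* — heavy-tailed (Student-t, ν = 3) electrode noise with
  brief high-amplitude spikes — abrupt impedance transients, not slow
  drifts — on a single-electrode map.

Recordings project the components through per-class gains (neural 20 µV,
blink 60 µV, lateral 30 µV, muscle 15 µV, pop 40 µV at the dominant
electrode) and add pink sensor noise (2 µV independent per channel plus a
spatially smooth shared term). The ERP scene inserts a saccade-locked
frontal transient (σ = 60 ms, peaking 50 ms after saccade onset = −50 ms
relative to fixation, matching the ~200 ms ocular transients seen in
co-registered gaze/EEG work) and a fixation-locked occipital response
(σ = 45 ms, peak +250 ms, ~20 µV — a typical infant visual evoked
amplitude) at 40 events ≥ 2.2 s apart. ERP scenes omit the channel_pop
class: a popping electrode is caught by bad-channel detection and
interpolated before ICA in the real workflow, so leaving one untreated
would misrepresent the data an ERP analysis ever sees.

What the generator does **not** emulate: realistic head geometry (maps come
from dipoles in an idealised spherical conductor, not a BEM model), heart
artifact, cap-pull fussing episodes beyond gross bursts, non-stationary
source coupling, and the 20+ Hz artifact spectrum excluded by the 20 Hz
low-pass. Passing tests therefore demonstrate that the pipeline recovers
the structure it assumes, not field performance on recorded infant EEG —
whose component mixtures are genuinely more ambiguous (human raters
themselves disagree on roughly one component in five).

## Numerical choices and degenerate inputs

* EDF I/O: reading via mne; writing through a minimal 16-bit EDF writer
  (1-s records, µV units, per-channel symmetric physical range) whose
  round trip through the mne reader is exact to within half a quantisation
  step. Non-integer sampling rates are refused; trailing partial seconds
  are zero-padded.
* Classifier JSON stores plain floats (shortest round-trip representation),
  so save/load is bit-exact; a missing field raises a schema error naming
  the field.
* Constant patterns, constant sources, zero mixing columns, single-class
  label sets and NaN features raise typed errors; a component whose
  features cannot be computed yields a flagged all-NaN row rather than
  aborting the whole table.
* Problem sizes in the test-suite and acceptance script — 600-component
  train/test corpora, 120-s recordings, 40-event scenes — were chosen to
  match the defaults above while keeping a full run in the low minutes on
  one CPU.

## Known limitations

* The current density norm degrades at 32 channels; it is retained because
  it still separates focal electrode artifacts clearly.
* The trainer is this package's design choice (regularised LDA): any
  deterministic binary linear trainer satisfying the decision rule would
  fit the same interface.
* No pretrained weights ship with the package: a classifier is only as good
  as the labelled corpus behind it, and users with manually labelled infant
  components should train on those.
* Classification is binary and hard; components mixing neural and artifact
  signal get whichever label the features favour, with ties going to
  retain.
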