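# Methods

This note documents the models, conventions and numerical choices
behind each pipeline stage, what the synthetic generator does and does
not emulate, and the known limitations.

## Signal model and preprocessing

A PPG recording is a uniformly sampled amplitude series. Laboratory
recordings of this kind are contaminated by three noise classes: mains
(powerline) interference, broadband muscle-artifact-like noise, and slow
baseline wander from respiration and sensor drift. The cleanup runs on
the whole recording before segmentation:

* **Downsampling** to `target_fs` (default 200 Hz, from a nominal
  1000 Hz acquisition rate). Integer ratios use an 8th-order
  Butterworth low-pass at 0.8× the target Nyquist, applied forward and
  backward (zero phase), followed by decimation; non-integer ratios use
  polyphase resampling.
* **Denoising**: a 4-level DWT with the `bior3.5` wavelet; every detail
  band is soft-thresholded at the universal threshold
  `σ·sqrt(2 ln N)`, with the noise scale σ estimated per band as
  `median(|d|)/0.6745`. Soft thresholding shrinks coefficients toward
  zero, so detail-band energy never increases. A zero threshold
  (all-zero band) is a no-op.
* **Baseline removal**: an 8-level DWT whose level-8 approximation is
  zeroed before reconstruction. At 200 Hz the discarded band is
  ≈0–0.39 Hz, which contains DC and drift but lies well below the pulse
  fundamental (≈1–2 Hz).

Boundary handling uses symmetric extension, which minimises edge
ringing on oscillatory signals. The cost is that the transform is
slightly redundant, so zero-then-reconstruct is not an exact
projection: a second baseline-removal pass changes a pulse train by
well under 1% relative RMS rather than by machine epsilon. The tests
assert the sub-1% figure.

The decomposition depth, wavelet, threshold rule and target rate are
all configurable (`DenoiseConfig`); the defaults above are the
conditions under which the pipeline is validated.

## Beats and intervals

Systolic peaks are local maxima above an adaptive threshold — the
segment median plus half the 75th percentile of positive excursions —
separated by at least one refractory period (60/max_rate seconds;
rate limits default to 40–180 bpm). The refractory spacing is what
rejects dicrotic bumps. Valleys are the global minima strictly between
consecutive peaks (plus a leading valley when the half-median-NN window
before the first peak contains samples). Segments yielding fewer than
three peaks are dropped with a logged reason.

Peak times are at sample resolution: at 200 Hz the 5 ms quantisation is
accepted rather than interpolated away, and the parameter-recovery
tests budget for it.

NN intervals are peak-to-peak times in ms; VV, VP and PV series are
defined analogously from valleys. The detector sits behind a single
function and can be swapped.

## Feature conventions

The 26 features follow a fixed 1-based ID order (exported by
`feature_registry()`). Where the standard HRV literature admits more
than one convention, the following choices are fixed and unit-tested:

* `Mean_HR` is the mean of instantaneous rates `60000/NNᵢ`, not the
  rate of the mean interval.
* `SDNN`/`SDSD` use sample (n−1) normalisation; `RMSSD` is the plain
  root mean square of successive differences.
* `NN50`/`NN20` count differences *strictly greater than* 50/20 ms.
* Spectral powers come from a Lomb–Scargle periodogram of the
  mean-subtracted NN tachogram (each NN value at its terminal peak
  time), integrated over LF 0.04–0.15 Hz and HF 0.15–0.4 Hz;
  `Total_Power` integrates the full 0–0.4 Hz band. The irregular-grid
  periodogram is used because a 10-s window holds only ~10–15 beats —
  far too few for stable resampling and Welch estimation. A 10-s window
  also cannot physically resolve the 0.04 Hz LF edge; the values are
  computed as defined and a QC message is logged. `nLFP`/`nHFP` are
  fractions of LF+HF.
* Poincaré axes use the algebraic ellipse convention
  `SD1 = RMSSD/√2`, `SD2 = sqrt(2·var_pop(NN) − SD1²)`, under which the
  textbook identities `SD1² + SD2² = 2·var_pop(NN)` and
  `SD1 = RMSSD/√2` hold exactly (the tests check them at 1e-9
  relative). On very short or strictly alternating series the
  longitudinal variance can fall below the transverse one; SD2 then
  clamps to exactly zero and the dependent ratios become sentinels.
  `CSI = SD2/SD1` (the 4·SD2/4·SD1 axis ratio) and `SD12` are
  numerically identical under this convention; both are emitted because
  the registry lists them as separate features. `CVI = log10(16·SD1·SD2)`.

Undefined ratios (zero denominators) are emitted as NaN sentinels; rows
containing any sentinel are dropped before classification, with a
logged count, so the row ledger stays conserved.

## Outlier filtering

Per feature column over the full matrix: `MAD = 1.4826·median|xᵢ − M|`
with `M` the column median; the acceptance band is `M ± 3·MAD`,
inclusive. A row is removed when *any* of its features falls outside
its column's band — per-row removal keeps the matrix rectangular
without imputation. The filter is a single pass (bounds are not
recomputed after removal) and runs before the train/test split, which
is the conventional order for this pipeline but technically lets test
rows influence the bounds; the leakage is confined to the filtering
step. When MAD is zero the band collapses to the median, so only values
strictly different from the median are flagged. Bounds are pooled
across classes. Note that on a strongly bimodal (well-separated
two-class) matrix the pooled band is wide yet still trims both class
tails; the synthetic separable study loses roughly a third of its rows
this way without affecting discrimination.

## Feature selection

SBFS starts from all n features and repeatedly removes the feature
whose removal minimises the 10-fold cross-validated error rate
`e = Nₑ/Nₐ` (misclassified over all test samples, pooled across folds).
After each removal, previously removed features are conditionally
re-added while re-adding *strictly* improves the best error recorded at
the larger size; strictness guarantees termination. The best subset per
size k is recorded; the global optimum is the minimum-error subset,
ties broken toward smaller k and then the lexicographically smaller ID
set. All ties between candidate subsets break toward the
lexicographically smallest ID set, which makes trajectories fully
deterministic. One stratified fold split per run is shared by every
subset evaluation, so comparisons between subsets are paired.

## Classification and metrics

Four classifiers with fixed, widely used defaults (none are prescribed
by the method itself): LDA (default solver), SVM (RBF, C=1,
gamma="scale"), XGBoost (100 rounds, depth 3, learning rate 0.1) and
random forest (100 trees). Evaluation is stratified 10-fold CV; the
[−1, 1] min-max scaling is fitted inside each training fold to avoid
leakage (`paper_faithful=True` restores a single global scaling fit
before CV). Confusion counts pool over folds (micro), class 1 is
positive, and zero-denominator metrics return NaN with a warning. The
metric formulas are F1 = 2TP/(2TP+FP+FN)·100,
Acc = (TP+TN)/total·100, Se = TP/(TP+FN)·100, Sp = TN/(TN+FP)·100.

## Synthetic data

The generator emulates the structure of stimulus-locked laboratory
recordings:

* RR model: `RR(t) = mean + A_LF·sin(2π·0.1·t) + A_HF·sin(2π·0.25·t) +
  N(0, σ)`, clipped to 333–1500 ms (40–180 bpm), beats placed
  cumulatively. An additive sinusoid-plus-noise model was chosen over
  integral pulse frequency modulation because the LF/HF band placement
  is directly controllable for spectral tests.
* Pulse template: two Gaussians — systolic peak at the beat time
  (width 0.08·RR) and a dicrotic bump at +0.35·RR (width 0.12·RR,
  amplitude 0.2) — giving the fast-rise/slow-decay asymmetry that makes
  valley→peak and peak→valley times genuinely different.
* Contaminants: a mains sinusoid (default 50 Hz), a slow drift sinusoid
  (default 0.1 Hz) and white Gaussian noise, all with configurable
  amplitudes.
* Dataset mode: one 14-s block per stimulus (10-s analysis window at
  +2 s, then a gap), blocks shuffled into one long session recording,
  ratings 0/3 encoding the two classes and optional rating-1 blocks
  exercising the drop rule. Default class parameters give class 1 a
  faster, steadier rate with less HF modulation
  (900→650 ms mean RR, 50→15 ms jitter, 40→10 ms HF amplitude); class
  structure is fully parameterised so null experiments pass identical
  configs.

What the generator does **not** emulate: hemodynamically realistic
pulse morphology, motion artifacts, respiration–cardiac coupling,
nonstationary autonomic state, or between-subject variability. Passing
tests therefore demonstrate that the pipeline machinery is correct and
recovers known structure under the stated noise model — not that the
classifier accuracies transfer to human data, where class differences
are far subtler.

Per-block seeds derive from the dataset seed, and waveform noise uses a
stream separate from the RR jitter, so every artifact is reproducible
bit for bit.

## Problem sizes

The bundled studies use 50+50 ten-second segments for the separable
experiment, 100+100 for the null, 30-s recordings for the denoising
experiment and 14-s segments for recovery checks — sizes at which every
stage's behaviour is already asymptotic (the null accuracy band and
recovery tolerances are set accordingly) while the whole suite and the
acceptance script run in minutes on one CPU.

## Known limitations

* Frequency-domain features on 10-s windows are dominated by spectral
  leakage at the LF edge; they are computed as defined, flagged in QC,
  and carry limited physiological meaning at that window length.
* The MAD filter's pooled bounds interact with strong class separation
  (see above) and are computed before the CV split.
* Segment-level cross-validation pools all segments; with multiple
  subjects this admits within-subject correlation between train and
  test folds. Subject-grouped splitting is the appropriate extension
  when subject identifiers are available.
* SD12 and CSI duplicate one another by construction; they are kept as
  two registry entries for schema fidelity, and feature selection may
  exploit the redundancy.
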