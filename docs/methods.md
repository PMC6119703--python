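# Methods

## Problem and pipeline

The package decodes which of three hand gestures (rock / scissors / paper) a
subject performs, from multichannel cortical surface recordings plus a
data-glove trace used only to timestamp movement onset.  The pipeline is:

1. **Onset detection.** Movement onset is the first sample of the earliest run
   of ≥ 5 consecutive first-difference values above a threshold, scanned over
   all glove sensors.  The first difference `x[i+1] − x[i]` is attributed to
   sample `i+1` (the first sample that has already moved); "earliest run
   across sensors, report its first sample" is our convention — the threshold
   and sensor policy are configuration, with no claim of matching any
   particular acquisition setup.
2. **Referencing.** Default is per-channel subtraction of the whole-session
   temporal mean (`session_mean`); instantaneous common-average referencing
   (`car`) is available.  Both are implemented because the two descriptions
   circulate interchangeably in the ECoG literature even though they are
   different operators; the choice is recorded in provenance.
3. **Features.** Each epoch (onset → cue stop) is segmented by a 300 ms
   window, 100 ms stride, 10 segments.  Welch PSD per segment is divided by
   the session's mean relax-stage PSD per channel and frequency bin, then
   averaged within five bands (4–12, 12–40, 40–70, 70–135, 135–200 Hz,
   half-open `[lo, hi)` so edge bins belong to exactly one band).  The result
   is a dimensionless t × n sequence per trial.
4. **Selection.** Greedy forward selection over (channel, band) candidates,
   scored by 3-fold stratified CV accuracy of an RBF SVM on the flattened
   sequence, stopping at the budget (6) or when no candidate strictly
   improves the joint accuracy.
5. **Decoding.** A single-layer LSTM over the 10-step sequence with a softmax
   readout of the final hidden state, against four flattened-vector baselines.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| window / stride | 300 / 100 | ms | preserves within-trial power dynamics at a scale where Welch is still stable |
| segments per trial | 10 | — | fixes the sequence length; the rapid plan rescales stride as (t−300)/9 (t < 300 ms: window t/2, stride w/9) so 10 windows always tile the interval |
| Welch | Hann, 256-sample sub-segments, 50 % overlap, nfft 256, no detrend | — | 7.8 Hz resolution at 2 kHz leaves ≥ 1 bin in the narrow 4–12 Hz band; nfft is held fixed so short rapid windows keep the same frequency grid (sub-segment capped at the window length) |
| SVM grids | C ∈ {0.1, 1, 10, 100, 1000}, γ ∈ {0.01, 0.001, 0.0001} | — | tuned once by inner CV on the full feature set, then frozen for all selection steps — re-tuning per candidate is combinatorially unstable |
| selection budget | 6 | features | later additions buy little and invite overfitting on small sessions |
| hidden units | 32 | — | the sweet spot of the 8–128 sweep exposed by `hidden_unit_sweep` |
| optimizer | Adam, lr 0.001, decay 0.0005/epoch | — | lr decays as lr/(1 + decay·epoch) (inverse-time; exponential is configurable) |
| early stop | best-validation epoch | — | snapshot at the best validation *accuracy* (loss as tie-break), over max 200 epochs, batch 16 |
| onset threshold | 5·10⁻⁴ | flexion/sample | calibrated to the synthetic glove, whose ramp slope is twice the threshold and whose sensor-noise derivative stays below a quarter of it |

The LSTM input is z-scored per feature column (statistics fit on the training
trials).  The baselines scale inputs the same way inside their sklearn
pipelines; giving the recurrent decoder the same conditioning keeps the
comparison about architecture, not normalization.  Weight init is
Glorot-uniform with forget-gate bias +1.  Ties in selection break toward the
lowest (channel, band) index; accuracy comparisons are exact float
comparisons, so the "strictly improving" path is strict up to rounding of
fold means.

## The synthetic sessions

The generator emulates the task protocol: alternating relax (2–2.5 s) and
task (2–3 s) stages, 3 balanced gesture classes, default 32 channels at
2 kHz, motion onset 0.1–0.3 s after the cue, a 14-sensor glove with one
composite sensor carrying a flexion ramp.  Background is Gaussian 1/f^α noise
(α = 1) plus a 50 Hz line component.  Gesture information is planted as
band-limited noise carriers on a small channel subset inside 70–135 and
135–200 Hz; because independent powers add, the carrier variance is set so
the expected task/relax band-power ratio equals the configured gain, and
`effect_size = 1` plants nothing.  Two regimes:

- **decay** (default): gain ramps up within 100 ms of onset and decays to 50 %
  by 1 s.  Feature j orders the classes by the j-th permutation of the level
  triple (1.0, 0.55, 0.25), so each planted feature carries partially
  non-redundant class information — this is what lets greedy selection keep
  improving out to larger budgets.
- **order**: every class reaches the same peak gain, but the bump of feature
  group A sits at a per-trial uniform random position in the analysis window
  and group B's bump is circularly lagged by a class-specific offset
  (+0.3 s / −0.3 s / 0).  Both bump-center marginals are uniform for every
  class, so time-averaged power carries no class information at all; only the
  *relative timing* of the two groups does.  This is the condition used for
  the decoder comparison: a long-window decoder is blind by construction, a
  flattened-vector decoder must learn the pattern at every alignment, and a
  recurrent decoder can exploit shared weights across time.

What the generator does **not** emulate: electrode geometry and volume
conduction, phase-locked evoked components, cross-channel correlation
structure, artifacts, non-stationary baselines, inter-session variability.
Passing tests therefore demonstrate that the pipeline recovers the kinds of
spectral/temporal structure it is designed for — not that it would reach any
particular accuracy on clinical recordings.

## Evaluation protocols

Decoders are compared by repeated random splits: each of the N trials draws a
stratified 10 % test set, every decoder is retrained on the remaining 90 %
(the recurrent decoder carves a further stratified 20 % of its training set
for early stopping), and the splits are shared across decoders so the
accuracy vectors are paired and `scipy.stats.ttest_rel` applies to per-trial
differences.  Raw p-values are reported; no multiple-comparison correction.
Mutual information between a feature (averaged over segments) and the labels
uses 8 quantile bins and the plug-in estimator in bits, with no bias
correction — adequate for the qualitative importance ranking it supports.

Desk-scale problem sizes used by the test battery and acceptance script, all
chosen as the smallest sizes at which the statistical claims are stable:
8–16 channels at 1 kHz, sessions of 30 trials (recovery and rapid-sweep
checks), 150 trials (selection-budget check, one full session's worth), and
240 trials with 50 permutation splits (decoder comparison, matching the
scale of a multi-session dataset).  The comparison scenario fixes the order
regime at effect size 2.0, where no decoder saturates.  For rapid plans the
relax stage is tiled at 50 % window overlap when computing the baseline
rather than with the rapid stride itself, which would generate thousands of
near-duplicate windows for no change in the estimator's expectation.

## Known limitations

- Greedy selection's strict-improvement stop can end below the budget on
  easy data (accuracy saturates); `SelectionResult.stop_reason` says which.
- The plug-in MI estimator is biased upward at small n; fine for ranking,
  not for absolute information estimates.
- The recurrent decoder trains on CPU in NumPy; sessions of a few hundred
  trials train in seconds, but the implementation is not meant for large
  hyperparameter searches.
- `paired_t` refuses zero-variance differences (undefined t); at very small
  permutation counts the CLI reports those pairs as nulls.
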