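# ecogest

Hand-gesture decoding from electrocorticography (ECoG), built around three
ideas: relax-baseline-normalized band-power features on short sliding windows,
greedy forward selection of the informative (channel, frequency-band) pairs,
and a recurrent (LSTM) classifier that reads the per-window feature vectors as
a sequence instead of a flattened blob.  It is aimed at BCI researchers who
want a tested, self-contained reference pipeline for offline gesture decoding
— and, because clinical ECoG is rarely shareable, it ships a synthetic session
generator that plants known spectral and temporal structure so every stage can
be validated against ground truth.

## The method

A trial's decoding epoch runs from the hand-motion onset (first time the
data-glove flexion derivative exceeds a threshold for five consecutive
samples) to the gesture-cue stop.  The epoch is cut into t = 10 windows of
300 ms with a 100 ms stride.  For each window, channel c and frequency f, the
Welch PSD S_{c,f} is divided by the mean relax-stage PSD

    R̄_{c,f} = (1/N_relax) Σ_i R_{c,f}(i),      Ŝ_{c,f}(i) = S_{c,f}(i) / R̄_{c,f},

and averaged within five bands (4–12, 12–40, 40–70, 70–135, 135–200 Hz),
giving a dimensionless t × n feature sequence per trial.

Candidate features are (channel, band) pairs scored by 3-fold CV accuracy of
an RBF-kernel SVM; greedy selection adds, at each step, the candidate that
most improves the joint accuracy and stops at the budget (default 6) or when
nothing improves — redundant duplicates are never picked, unlike independent
top-N ranking.

The decoder is a single-layer LSTM: gates i(t), f(t), o(t) are sigmoids of
affine maps of the input x(t) and previous hidden state h(t−1), the cell is
c(t) = i(t)⊙tanh(W_c x(t) + U_c h(t−1) + b_c) + f(t)⊙c(t−1), and
h(t) = o(t)⊙tanh(c(t)).  Class probabilities come from a softmax readout of
the final hidden state; training is Adam (lr 0.001, decay 0.0005/epoch) with
the parameter snapshot taken at the best-validation epoch.  Comparison
decoders: an RBF SVM on one long window (SVM-Global), and RBF SVM / MLP /
logistic regression on the flattened sequence (·-Segments).  Evaluation uses
repeated random 90/10 splits shared across decoders, paired t-tests, a
hidden-unit sweep, a rapid-recognition sweep over post-onset intervals of
100–1200 ms (window 300 ms, stride (t−300)/9 ms; below 300 ms the window is
t/2 with stride w/9), and quantile-binned mutual information per feature.

## Worked example

```python
import numpy as np
from ecogest import synth, io, preprocess, selection, decoder

cfg = synth.SynthConfig(n_channels=8, fs=1000.0, n_trials=60,
                        informative_channels=(2, 5), effect_size=3.0, seed=0)
rec, glove, truth = synth.generate_session(cfg)
onsets = io.detect_trial_onsets(rec.events, glove, cfg.glove_threshold)
features = preprocess.session_features(rec, onsets)
print(f"features: {features.X.shape}  (trials x segments x channel-band features)")

candidates = selection.candidates_for(cfg.n_channels, features.partition.labels)
result = selection.greedy_select(features.X, features.y, max_k=6, candidates=candidates)
for rank, (f, acc) in enumerate(zip(result.ordered, result.cv_accuracy_path), 1):
    print(f"  {rank}. channel {f.channel}, band {f.band} Hz  ->  CV accuracy {acc:.3f}")
print(f"stop reason: {result.stop_reason}")

X = features.X[:, :, result.indices]
train, test = np.arange(48), np.arange(48, 60)
dec = decoder.train_decoder(X[train], features.y[train],
                            cfg=decoder.DecoderConfig(hidden_size=32, seed=0))
print(f"held-out accuracy: {dec.accuracy(X[test], features.y[test]):.3f}")
```

prints

```
features: (60, 10, 40)  (trials x segments x channel-band features)
  1. channel 2, band 135-200 Hz  ->  CV accuracy 0.850
  2. channel 5, band 135-200 Hz  ->  CV accuracy 0.950
  3. channel 5, band 70-135 Hz  ->  CV accuracy 1.000
stop reason: no_improvement
held-out accuracy: 0.917
```

The session planted gesture-dependent power on channels 2 and 5 in the
70–135 Hz and 135–200 Hz bands; selection recovers exactly those pairs, the
CV accuracy path climbs monotonically until nothing improves, and the LSTM
decodes held-out trials well above the 1/3 chance level.

The same pipeline is scriptable from the shell:

```bash
ecogest simulate --seed 3 --out run/sim
ecogest preprocess --session run/sim/session.h5 --out run/feats
ecogest select --features run/feats/features.h5 --budget 6 --out run/sel
ecogest train --features run/feats/features.h5 --selection run/sel/selection.json --out run/model
ecogest evaluate --features run/feats/features.h5 --selection run/sel/selection.json \
                 --session run/sim/session.h5 --out run/eval
```

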