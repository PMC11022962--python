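# dbgcn

Depression classification from resting-state EEG using differential-entropy
(DE) time-frequency features, a BiLSTM temporal encoder, a
Pearson-correlation brain network, and a graph convolutional classifier
(DBGCN), evaluated with subject-wise cross-validation.

The package is aimed at researchers working on EEG biomarkers of major
depressive disorder who want a tested, reproducible implementation of this
family of correlation-graph classifiers — including a synthetic-EEG
generator so the entire pipeline runs end to end with no data download.

## Method

Each subject's multichannel recording is cleaned (50 Hz notch, 0.3–50 Hz
band-pass, 1–50 Hz order-4 Butterworth, all zero-phase), baseline-corrected
over the first 120 s, and cut into 4 s windows with 2 s stride (50% overlap).
Every window is decomposed into the canonical rhythms — delta (0.5–4 Hz),
theta (4–8 Hz), alpha (8–12 Hz), beta (12–30 Hz) — and the differential
entropy

    DE = ½ ln(2πe σ²)

of each (channel, 1 s sub-window, band) is collected into a tensor
X ∈ R^{n×t×d}. A shared-weight BiLSTM reads each channel's sequence and
emits node features H = BiLSTM(X) ∈ R^{n×d′}. Electrodes form a graph whose
adjacency A is the pairwise Pearson correlation of the (training subjects')
continuous signals; graph convolutions propagate

    H^{l+1} = σ( D̃^{-1/2} Ã D̃^{-1/2} H^l W^l ),   Ã = A′ + I,

with σ a bounded ReLU, each layer followed by 50% pooling (greedy heavy-edge
matching halves the node count), ending in a dense softmax for the binary
control/depressed decision. The loss is cross-entropy with an L2 penalty
λ·Σ(w² + b²). Evaluation uses subject-wise 10-fold cross-validation — all of
a subject's segments stay on one side of each fold, and the correlation
graph and feature normalizer are fitted on training subjects only.

The network and its gradients (backpropagation through time for the LSTM)
are implemented directly in NumPy and validated against finite differences
in the test suite.

## Worked example

```python
from dbgcn.experiments import scaled_cv

result = scaled_cv("easy", seed=1)     # 20 subjects, 16 channels, 30 s each
print(round(result.mean("accuracy"), 4))
for fold in result.fold_metrics[:3]:
    print(fold.as_dict())
```

prints

```
1.0
{'tp': 14, 'fp': 0, 'tn': 14, 'fn': 0, 'accuracy': 1.0, 'precision': 1.0, 'sensitivity': 1.0, 'specificity': 1.0, 'f1': 1.0}
{'tp': 0, 'fp': 0, 'tn': 28, 'fn': 0, 'accuracy': 1.0, 'precision': 0.0, 'sensitivity': 0.0, 'specificity': 1.0, 'f1': 0.0}
{'tp': 14, 'fp': 0, 'tn': 14, 'fn': 0, 'accuracy': 1.0, 'precision': 1.0, 'sensitivity': 1.0, 'specificity': 1.0, 'f1': 1.0}
```

On the `easy` synthetic preset (depressed subjects get triple the low-band
power) every one of the 280 held-out segments across 10 subject-wise folds is
classified correctly. Folds hold out 2 of the 20 subjects, so some folds
contain a single class; rates whose denominator is empty are reported as 0.
The `null` preset (no class effect) stays near chance.

The same pipeline runs from the shell:

```bash
dbgcn simulate --preset easy --seed 1 --out cohort/
dbgcn cv --input cohort/ --class-weights --seed 1 --out metrics.json
```

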