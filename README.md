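# cyspred

Prediction of cysteine S-carboxyethylation sites — and, generically, any
post-translational modification of a residue at the center of a fixed-length
peptide window — from protein sequence alone.

S-carboxyethylation attaches a carboxyethyl group (-CH₂-COOH) to the thiol
of a cysteine and is implicated in autoimmune disease; identifying modified
sites by mass spectrometry is slow and expensive, which motivates sequence-
based prediction. `cyspred` provides the full modelling pipeline for this
problem: window extraction from FASTA, position-weighted sequence encoding,
a CNN–BiLSTM–attention classifier, leakage-free evaluation, and analysis
tools that interrogate *where* in the window the model looks.

## The method

**Binary-weight encoding (BWE).** Each residue of an L-residue window
(default L = 41, cysteine at the center) is one-hot encoded over the 20
amino acids, and row *i* is scaled by a positional weight

&nbsp;&nbsp;&nbsp;&nbsp;W_i = p · e^(−α·d_i),&nbsp;&nbsp; d_i = |i − (L−1)/2|,

so positions near the candidate cysteine count more than distal ones.
α = 0 recovers plain one-hot encoding. Comparison encoders (EAAC, DPC,
TPC, CTD) are included.

**Classifier.** Two 1-D convolutions with max-pooling (local motifs), a
bidirectional LSTM (context in both directions), additive Bahdanau-style
attention over the retained timesteps — score_t = vᵀ tanh(w1·O_t + w2·H),
softmax-normalized — and two fully connected layers with dropout feeding a
softmax. The attention weight vector is exposed per window. The network
runs on a small, fully tested reverse-mode autodiff engine over NumPy; no
GPU or deep-learning framework is required.

**Evaluation.** Grouped k-fold cross-validation (all windows of one parent
protein share a fold), Sn / Sp / ACC / MCC / AUROC / AUPR with mean ± SD
across folds and repeats, Mann-Whitney U comparisons between models, and
classical baselines (SVM / RF / XGBoost) over flattened encodings.

**Attention analysis.** The mean attention profile is stretched to window
length by linear interpolation and compared to the normalized positional
weight curve with dynamic time warping (distance plus optimal path). On
data whose signal concentrates near the center, the learned attention
profile tracks the exponential weight curve closely.

**Synthetic data.** A seeded generator produces labeled windows whose
positives carry a compositional signal (enrichment of a residue set) that
decays exponentially with distance from the center at rate β — the analytic
per-position enrichment is available in closed form, so the generator
itself is testable.

## Worked example

```python
import cyspred as cp

# 300 + 300 synthetic 41-mers: positives enriched in K/R/E near the center
spec = cp.SignalSpec(L=41, signal_strength=0.8, signal_decay=0.05, seed=7)
ds = cp.generate_dataset(spec, n_pos=300, n_neg=300)

enc = cp.EncodingConfig(alpha=0.02, L=41)          # BWE with alpha = 0.02
mcfg = cp.ModelConfig(conv_channels=(16, 32), lstm_hidden=32,
                      attention_dim=32, fc_sizes=(32, 16))
tspec = cp.TrainSpec(epochs=20, batch_size=64, seed=7,
                     early_stopping_patience=4)

summary = cp.cross_validate(ds, mcfg, enc, tspec, k=5, repeats=1)
for m in ("acc", "mcc", "auroc", "aupr"):
    print(f"{m:>6}: {summary.mean[m]:.4f} +/- {summary.sd[m]:.4f}")

model = cp.build_model(mcfg, L=41, feature_dim=20, seed=7)
cp.train(model, ds, enc, tspec)
report = cp.compare_attention_to_position_weights(model, ds, enc)
print(f"DTW distance: {report.distance:.4f} "
      f"(normalized {report.normalized_distance:.6f})")
```

Output:

```
   acc: 0.9917 +/- 0.0105
   mcc: 0.9837 +/- 0.0206
 auroc: 0.9999 +/- 0.0001
  aupr: 0.9999 +/- 0.0001
DTW distance: 0.2154 (normalized 0.003590)
```

Grouped 5-fold CV recovers the planted center signal almost perfectly
(ACC 0.99, AUROC ≈ 1.0), and the trained model's attention profile sits a
normalized DTW distance of 0.0036 from the exponential position-weight
curve — the attention mechanism rediscovers the same center-peaked
weighting that BWE encodes by construction.

The same experiments run from the shell:

```bash
cyspred simulate --out windows.tsv --n-pos 300 --n-neg 300 --seed 7
cyspred cv --input windows.tsv --alpha 0.02 --k 5 --out cv.json
cyspred train --input windows.tsv --model-out model --seed 7
cyspred analyze-attention --input windows.tsv --model model --out attn.json
cyspred sweep --alphas 0,0.01,0.02,0.05 --lengths 21,41 --out grid.csv
cyspred tsne --input windows.tsv --model model --out embedding.tsv
```

Every command writes a `*.manifest.json` (resolved options, seed, versions)
from which its outputs can be regenerated exactly.

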