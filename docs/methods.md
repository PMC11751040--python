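# Methods

## Problem setting

Cysteine S-carboxyethylation is a post-translational modification (PTM) in
which the thiol of a cysteine residue gains a carboxyethyl group. Predicting
whether a given cysteine is modified is framed here, as for most PTM site
predictors, as binary classification of a fixed-length peptide window
centered on the candidate residue. The package is generic over the centered
residue and window length; the defaults (cysteine, 41 residues) match the
common choice for this modification.

## Window extraction and dataset assembly

Windows of odd length L are cut around every occurrence of the center
residue in a protein. Windows overhanging a terminus are padded with `'X'`,
which every encoder maps to an all-zero row: padding therefore contributes
no composition signal and preserves matrix shape. (Excluding terminal
windows would have been the alternative; padding was chosen so that no
candidate site is silently dropped.)

Datasets are assembled at a requested positive:negative ratio (balanced 1:1
for training, imbalanced such as 1:10 for realistic test sets). Exact
duplicate sequences are removed within each class. Negative subsampling is
seeded and stratified round-robin over parent proteins so that no single
protein dominates the negative class. Similarity-based redundancy reduction
(e.g. clustering at 45% identity) is expected to have been performed
upstream with standard tools; the package only removes exact duplicates.

Cross-validation folds are group-aware: all windows from one parent protein
share a fold, preventing homology leakage between training and validation.
Groups are assigned greedily, largest group first into the currently
smallest fold, with a seeded shuffle breaking ties, so fold sizes stay
balanced and the assignment is deterministic.

## Binary-weight encoding

Each residue is one-hot encoded over the alphabet `ACDEFGHIKLMNPQRSTVWY`
(row of length 20). Binary-weight encoding (BWE) scales row i by

    W_i = p · exp(−α · d_i),    d_i = |i − (L−1)/2|,

treating the center as a signal source whose influence decays exponentially
with distance in residues. Parameters:

- **α (decay coefficient)** — per-residue decay rate; default 0.02, the
  value at which downstream accuracy peaks for L = 41 in the sweep
  experiment. α = 0 recovers plain one-hot encoding exactly, so the
  unweighted encoder is a special case of the weighted one.
- **p (source strength)** — default 1. Only the product p·e^(−αd) enters
  the features, so p is a uniform rescaling; it is exposed for completeness.
- **L (window length)** — default 41, odd by construction.

The comparison descriptors (EAAC with sliding window 5, DPC, TPC, CTD over
the standard seven physicochemical attribute groupings) are implemented
from their usual definitions; positions containing `'X'` are excluded from
numerators and denominators. EAAC produces a (L−4)×20 matrix and can feed
the sequence model directly; DPC/TPC/CTD are flat descriptors and are
viewed as single-channel sequences when forced through the deep model
(their natural consumers are the classical baselines).

## Classifier

The model is a stack of: two valid-mode 1-D convolutions (ReLU) and a
non-overlapping max-pool; a bidirectional LSTM whose per-timestep
forward/backward hidden states are concatenated; additive (Bahdanau-style)
attention; and two fully connected ReLU layers with dropout followed by a
linear layer and softmax over two classes.

Attention scores are computed per retained timestep t as

    score_t = vᵀ tanh(w1·O_t + w2·H),

softmax-normalized over timesteps, and used to form the context vector
C = Σ_t a_t O_t. The additive-attention formulation expects a decoder
state H; in a classifier there is no decoder, so H is the concatenated
final forward/backward LSTM hidden state — the only summary-state vector
available. Attention operates on the pooled CNN timesteps (not the raw
positions), which is why the mean attention profile must be stretched back
to window length before comparison with the positional weight curve.

Default sizes (all overridable): conv channels (32, 64), kernels (5, 5),
pool 2, LSTM hidden 64, attention dim 64, FC (64, 32), dropout 0.5. Each
stage can be switched off independently (`use_cnn`, `use_bilstm`,
`use_attention`) so architecture ablations run from configuration alone.
With a stage off: the LSTM consumes the encoded matrix directly (no CNN);
the summary state falls back to the mean over timesteps (no LSTM); the
context falls back to the summary state and attention is reported uniform
(no attention).

The network and its gradients are implemented on a compact reverse-mode
automatic-differentiation engine over NumPy arrays (`cyspred.nn`), in
float64. Every operation's gradient, and the end-to-end model gradient,
are verified against central finite differences in the test suite.

## Training and evaluation

Cross-entropy loss, Adam (lr 1e−3), batch 64, default 100 epochs with
early stopping (patience 10). Early stopping monitors validation loss on a
stratified 10% holdout carved from the *training* split — never on the CV
evaluation fold, so model selection cannot leak into the reported metrics.
The best-validation-loss weights are restored. All randomness (shuffling,
dropout masks, initialization) derives from the run seed; evaluation mode
is deterministic, and duplicate windows receive identical scores.

Metrics: Sn, Sp, ACC and MCC from the confusion matrix at threshold 0.5
(ties at the threshold go to the negative class), plus AUROC (trapezoidal,
rank-averaged ties) and AUPR (step interpolation) computed through
scikit-learn. A metric whose denominator vanishes is reported as 0 and
flagged `degenerate` rather than NaN. Cross-validation reports per-fold
metrics and mean ± SD, where SD is the population standard deviation over
all fold×repeat evaluations. Model comparisons use the two-sided
Mann-Whitney U test (exact null for small tie-free samples, normal
approximation with tie correction otherwise) with significance tiers at
0.05 / 0.01 / 0.001.

Classical baselines (SVM, random forest, XGBoost) are a thin harness over
scikit-learn and xgboost, fed flattened encodings; they exist for
comparison, not as part of the method.

## Attention-weight analysis

For a trained model, per-window attention scores are averaged into a mean
profile over the retained timesteps (positives and negatives pooled by
default; a flag restricts to positives). The profile is stretched to window
length by linear interpolation of the T values placed uniformly on
[0, L−1], then renormalized to sum to 1; compression is refused. Linear
interpolation was chosen over repetition or zero-padding because it is
order-preserving and leaves constant profiles constant.

The stretched profile is compared with the normalized positional-weight
curve by classic dynamic time warping: steps {(1,0),(0,1),(1,1)}, cost
|a_i − b_j|, no window constraint, path recovered by backtrace with a
deterministic tie-break (diagonal preferred, then the step advancing the
first profile, then the second). DTW is not a metric, so no triangle
inequality is asserted anywhere. The control curve for locality claims is
the positional curve *rank-reversed* (largest value moved to the position
of the smallest and so on), i.e. a center-lowest curve with the same value
multiset.

## Synthetic data generator

The generator emulates the assumed structure of a centered-residue PTM
dataset: every window has `'C'` fixed at the center; negatives are drawn
i.i.d. from a background composition (uniform over the 20 residues by
default); positives draw each off-center residue from a small signal set
(default {K, R, E}) with probability s0·e^(−β·d), otherwise from the
background. The analytic per-position signal-residue frequency,
s0·e^(−βd) + (1 − s0·e^(−βd))·(background mass of the signal set), is
exposed for calibration checks, and the empirical enrichment is verified
against it within binomial confidence bounds in the tests.

Defaults: s0 = 0.8, β = 0.05, L = 41, 60 synthetic proteins assigned
round-robin. These give a strongly learnable but not trivial signal spread
across the window — at distance 20 the emission probability is still
0.8·e^(−1) ≈ 0.29 against a background mass of 0.15.

What the generator does *not* emulate: homology structure between proteins
(synthetic protein ids are arbitrary groupings, so grouped CV is exercised
mechanically but there is no real shared-ancestry signal), realistic
proteome composition, motif syntax beyond single-residue enrichment, and
any observation noise from mass-spectrometry site assignment. Passing the
synthetic-recovery tests therefore demonstrates that the pipeline can
learn and localize a center-concentrated compositional signal — not that
it attains any particular accuracy on real S-carboxyethylation data.

β is deliberately independent of the encoder's α so that recovery
experiments can ask whether the best α tracks the data's decay rate.

## Study configuration used by the acceptance runs

The bundled studies (`cyspred.experiments`, used by `scripts/acceptance.py`
and the heavier tests) run on 600 positive + 600 negative synthetic windows
(L = 41, s0 = 0.8, β = 0.05) with a half-width variant of the default
architecture — same layer stack, channels (16, 32), LSTM hidden 32,
attention 32, FC (32, 16) — trained for up to 20 epochs with patience-4
early stopping. These sizes keep a full study (five seeds × two encoders ×
five folds, plus three attention trainings) in the ten-minute range on one
CPU while leaving the classifier far above chance; they are the package's
standard desk-scale study conditions, not a statement about the limits of
the method.

## Numerical choices and edge cases

- float64 throughout the network; probabilities and attention weights are
  softmax outputs and sum to 1 within 1e−6 per window.
- Argmax ties at the classification threshold resolve to class 0.
- Non-finite training loss aborts with diagnostics instead of continuing.
- `group_kfold` requires at least k distinct proteins; `build_dataset`
  names the exact negative shortfall when a ratio is unattainable.
- The DTW backtrace tie-break makes paths deterministic; distances are
  symmetric, and paths transpose under argument swap (up to ties).
- Window tables round-trip through TSV (`sequence label protein_id
  center_position`) field-for-field.

## Known limitations

- The NumPy network trains on one CPU; it is sized for desk-scale
  experiments (~10^5 parameters, ~10^3 windows), not proteome-wide scans.
- Real-data claims require real data: the synthetic generator cannot stand
  in for mass-spec-derived sites (see above).
- The AAindex physicochemical encoder and learned embeddings are out of
  scope; only the descriptor encoders listed above are provided.
- t-SNE plots are a delegated visualization (scikit-learn), intended for
  qualitative inspection only.
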