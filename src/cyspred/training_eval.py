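"""Training loop, evaluation metrics, grouped cross-validation, model comparison.

Metrics follow the standard binary-classification definitions: sensitivity
Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy, and the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FN)(TP+FP)(TN+FP)),

plus the threshold-free AUROC and AUPR. Any metric whose denominator
vanishes is reported as 0 with a ``degenerate`` flag rather than NaN.

Cross-validation is group-aware: windows from one parent protein never split
across training and validation. Metric samples from repeated CV runs can be
compared between models with the Mann-Whitney U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .encoding import EncodingConfig, as_sequence_features, encode_dataset
from .io_datasets import LabeledDataset, group_kfold
from .model import ModelConfig, SitePredictor, build_model
from . import nn

METRIC_NAMES = ("sn", "sp", "acc", "mcc", "auroc", "aupr")


@dataclass(frozen=True)
class TrainSpec:
    """Optimization settings for one training run."""

    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    seed: int = 0
    early_stopping_patience: int | None = 10
    validation_fraction: float = 0.1  # carved from training data for early stopping

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.optimizer_name.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer_name!r}")


@dataclass
class EvalReport:
    """Confusion counts and derived metrics for one evaluation."""

    tp: int
    fn: int
    tn: int
    fp: int
    sn: float
    sp: float
    acc: float
    mcc: float
    auroc: float
    aupr: float
    threshold: float = 0.5
    degenerate: tuple = ()

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def to_dict(self) -> dict:
        d = asdict(self)
        d["degenerate"] = list(self.degenerate)
        return d


@dataclass
class CVSummary:
    """Per-fold reports plus mean +/- SD per metric across folds x repeats."""

    reports: list[EvalReport]
    n_folds: int
    n_repeats: int
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.mean:
            for m in METRIC_NAMES:
                vals = np.array([getattr(r, m) for r in self.reports], dtype=float)
                self.mean[m] = float(vals.mean())
                self.sd[m] = float(vals.std())  # population SD

    def metric_samples(self, metric: str) -> np.ndarray:
        return np.array([getattr(r, metric) for r in self.reports], dtype=float)

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "mean": self.mean,
            "sd": self.sd,
            "reports": [r.to_dict() for r in self.reports],
        }


def confusion_metrics(tp: int, fn: int, tn: int, fp: int):
    """Sensitivity, specificity, accuracy and MCC from confusion counts.

    Returns ``(sn, sp, acc, mcc, degenerate)`` where ``degenerate`` names
    metrics whose denominator vanished (reported as 0).
    """
    counts = (tp, fn, tn, fp)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative confusion counts {counts}")
    total = sum(counts)
    if total == 0:
        raise ValueError("all confusion counts are zero")
    degenerate = []
    if tp + fn > 0:
        sn = tp / (tp + fn)
    else:
        sn = 0.0
        degenerate.append("sn")
    if tn + fp > 0:
        sp = tn / (tn + fp)
    else:
        sp = 0.0
        degenerate.append("sp")
    acc = (tp + tn) / total
    denom = (tp + fn) * (tn + fn) * (tp + fp) * (tn + fp)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        mcc = 0.0
        degenerate.append("mcc")
    return sn, sp, acc, mcc, tuple(degenerate)


def roc_pr_curves(scores, labels) -> tuple[float, float]:
    """AUROC (rank-averaged ties) and AUPR (step interpolation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to compute AUROC/AUPR")
    return float(roc_auc_score(labels, scores)), float(
        average_precision_score(labels, scores)
    )


def evaluate_scores(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Full evaluation report from class-1 scores and true labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores > threshold).astype(int)  # ties at threshold go to class 0
    tp = int(((pred == 1) & (labels == 1)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    sn, sp, acc, mcc, degenerate = confusion_metrics(tp, fn, tn, fp)
    auroc, aupr = roc_pr_curves(scores, labels)
    return EvalReport(tp=tp, fn=fn, tn=tn, fp=fp, sn=sn, sp=sp, acc=acc,
                      mcc=mcc, auroc=auroc, aupr=aupr, threshold=threshold,
                      degenerate=degenerate)


def _stratified_holdout(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Split indices into (train, holdout) preserving class balance."""
    train_idx, hold_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_hold = max(1, int(round(fraction * len(idx))))
        hold_idx.extend(idx[:n_hold])
        train_idx.extend(idx[n_hold:])
    return np.sort(np.array(train_idx)), np.sort(np.array(hold_idx))


def train(model: SitePredictor, dataset: LabeledDataset,
          encoder_config: EncodingConfig | None = None, spec: TrainSpec | None = None,
          encoder: str = "bwe", X: np.ndarray | None = None,
          verbose: bool = False):
    """Train the predictor with Adam on cross-entropy loss.

    When ``spec.early_stopping_patience`` is set, a stratified
    ``validation_fraction`` of the training windows is held out to monitor
    validation loss; the best-loss weights are restored at the end. All
    randomness (shuffling, dropout) derives from ``spec.seed``.

    Returns ``(model, history)`` where history maps ``train_loss`` (and
    ``val_loss`` when early stopping is active) to per-epoch lists.
    """
    spec = spec or TrainSpec()
    encoder_config = encoder_config or EncodingConfig(L=dataset.L)
    if X is None:
        X = as_sequence_features(encode_dataset(dataset, encoder, encoder_config))
    y = dataset.labels
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(spec.seed)
    use_es = spec.early_stopping_patience is not None
    if use_es:
        tr_idx, va_idx = _stratified_holdout(y, spec.validation_fraction, rng)
        X_tr, y_tr = X[tr_idx], y[tr_idx]
        X_va, y_va = X[va_idx], y[va_idx]
    else:
        X_tr, y_tr = X, y
    opt = nn.Adam(model.params, lr=spec.learning_rate)
    history: dict[str, list[float]] = {"train_loss": []}
    if use_es:
        history["val_loss"] = []
    best_loss, best_weights, patience_left = np.inf, None, spec.early_stopping_patience
    n = len(y_tr)
    for epoch in range(spec.epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, spec.batch_size):
            idx = perm[lo : lo + spec.batch_size]
            opt.zero_grad()
            loss = model.loss(X_tr[idx], y_tr[idx], rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {lo // spec.batch_size}; "
                    f"lr={spec.learning_rate}, batch_size={spec.batch_size}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if use_es:
            logits, _, _ = model._forward(X_va, train=False)
            val_loss = nn.softmax_cross_entropy(logits, y_va).item()
            history["val_loss"].append(val_loss)
            if val_loss < best_loss - 1e-6:
                best_loss, best_weights = val_loss, model.get_weights()
                patience_left = spec.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        if verbose:
            print(f"epoch {epoch + 1}: train_loss={history['train_loss'][-1]:.4f}")
    if use_es and best_weights is not None:
        model.set_weights(best_weights)
    model.trained = True
    return model, history


def evaluate(model: SitePredictor, dataset: LabeledDataset,
             encoder_config: EncodingConfig | None = None, encoder: str = "bwe",
             threshold: float = 0.5, X: np.ndarray | None = None) -> EvalReport:
    """Evaluate a trained model on a labeled dataset."""
    encoder_config = encoder_config or EncodingConfig(L=dataset.L)
    if X is None:
        X = as_sequence_features(encode_dataset(dataset, encoder, encoder_config))
    probs = model.predict_proba(X)[:, 1]
    return evaluate_scores(probs, dataset.labels, threshold=threshold)


def cross_validate(dataset: LabeledDataset, model_config: ModelConfig,
                   encoder_config: EncodingConfig | None = None,
                   spec: TrainSpec | None = None, k: int = 5, repeats: int = 10,
                   encoder: str = "bwe", threshold: float = 0.5,
                   collect_predictions: bool = False):
    """Repeated group-aware k-fold cross-validation.

    For repeat r, folds come from ``group_kfold(seed=spec.seed + r)``; a
    fresh model is trained per fold and evaluated on the held-out fold.
    Returns a :class:`CVSummary`, plus per-window prediction rows
    ``(window_index, repeat, fold, score, label)`` when requested.
    """
    spec = spec or TrainSpec()
    encoder_config = encoder_config or EncodingConfig(L=dataset.L)
    X_all = as_sequence_features(encode_dataset(dataset, encoder, encoder_config))
    y_all = dataset.labels
    reports: list[EvalReport] = []
    prediction_rows = []
    for r in range(repeats):
        folds = group_kfold(dataset, k=k, seed=spec.seed + r)
        for fold in range(k):
            va_idx = folds.fold_indices(fold)
            tr_idx = np.setdiff1d(np.arange(len(dataset)), va_idx)
            model = build_model(model_config, L=X_all.shape[1],
                                feature_dim=X_all.shape[2],
                                seed=spec.seed * 1000 + r * k + fold)
            fold_spec = TrainSpec(
                epochs=spec.epochs, batch_size=spec.batch_size,
                learning_rate=spec.learning_rate, seed=spec.seed * 1000 + r * k + fold,
                early_stopping_patience=spec.early_stopping_patience,
                validation_fraction=spec.validation_fraction,
            )
            train(model, dataset[tr_idx], encoder_config, fold_spec,
                  encoder=encoder, X=X_all[tr_idx])
            probs = model.predict_proba(X_all[va_idx])[:, 1]
            reports.append(evaluate_scores(probs, y_all[va_idx], threshold=threshold))
            if collect_predictions:
                for wi, s, lab in zip(va_idx, probs, y_all[va_idx]):
                    prediction_rows.append((int(wi), r, fold, float(s), int(lab)))
    summary = CVSummary(reports=reports, n_folds=k, n_repeats=repeats)
    if collect_predictions:
        return summary, prediction_rows
    return summary


SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def mann_whitney_compare(samples_a, samples_b):
    """Two-sided Mann-Whitney U comparison of two metric samples.

    Returns ``(U, p, tier)`` with tier in {NS, *, **, ***} at thresholds
    0.05 / 0.01 / 0.001. Uses the exact null distribution for small tie-free
    samples, otherwise the normal approximation with tie correction.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per sample")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return float(len(a) * len(b) / 2.0), 1.0, "NS"
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    tier = "NS"
    for threshold, label in SIGNIFICANCE_TIERS:
        if p < threshold:
            tier = label
            break
    return float(res.statistic), p, tier


def fit_baseline(name: str, dataset: LabeledDataset,
                 encoder_config: EncodingConfig | None = None,
                 encoder: str = "bwe", seed: int = 0, **params):
    """Fit a classical baseline (svm / rf / xgboost) on flattened encodings.

    Returns a fitted object with ``predict_proba`` over flattened features;
    use :func:`baseline_scores` to score a dataset.
    """
    encoder_config = encoder_config or EncodingConfig(L=dataset.L)
    X = encode_dataset(dataset, encoder, encoder_config).reshape(len(dataset), -1)
    y = dataset.labels
    name = name.lower()
    if name == "svm":
        from sklearn.svm import SVC

        clf = SVC(probability=True, random_state=seed, **params)
    elif name == "rf":
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(random_state=seed, **params)
    elif name == "xgboost":
        from xgboost import XGBClassifier

        clf = XGBClassifier(random_state=seed, eval_metric="logloss", **params)
    else:
        raise ValueError(f"unknown baseline {name!r}; choose svm, rf or xgboost")
    clf.fit(X, y)
    return clf


def baseline_scores(clf, dataset: LabeledDataset,
                    encoder_config: EncodingConfig | None = None,
                    encoder: str = "bwe") -> np.ndarray:
    encoder_config = encoder_config or EncodingConfig(L=dataset.L)
    X = encode_dataset(dataset, encoder, encoder_config).reshape(len(dataset), -1)
    return clf.predict_proba(X)[:, 1]
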