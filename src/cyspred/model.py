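"""The CNN–BiLSTM–additive-attention site classifier.

Architecture (all stages optional via config flags, enabling ablations):

1. Two valid-mode 1-D convolutions with ReLU, then non-overlapping max
   pooling — local motif detectors over the encoded window.
2. A bidirectional LSTM over the retained timesteps; the per-timestep
   forward/backward hidden states are concatenated into outputs O, and the
   final hidden states of the two directions are concatenated into a summary
   state H.
3. Additive (Bahdanau-style) attention: per-timestep scores
   score_t = v^T tanh(w1 O_t + w2 H), softmax-normalized over timesteps,
   yield a weighted context vector C = sum_t a_t O_t. The normalized scores
   are exposed for interpretation.
4. Two fully connected ReLU layers with dropout, a linear output layer and a
   softmax over the two classes.

The classifier is binary: class 1 means the centered residue carries the
modification. Everything is seeded and deterministic in evaluation mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The layer types are fixed by the architecture; the sizes below are
    overridable defaults. ``use_cnn`` / ``use_bilstm`` / ``use_attention``
    switch stages off for ablation studies.
    """

    conv_channels: tuple[int, int] = (32, 64)
    kernel_sizes: tuple[int, int] = (5, 5)
    pool_size: int = 2
    lstm_hidden: int = 64
    attention_dim: int = 64
    fc_sizes: tuple[int, int] = (64, 32)
    dropout: float = 0.5
    n_classes: int = 2
    use_cnn: bool = True
    use_bilstm: bool = True
    use_attention: bool = True

    def __post_init__(self):
        sizes = (*self.conv_channels, *self.kernel_sizes, self.pool_size,
                 self.lstm_hidden, self.attention_dim, *self.fc_sizes)
        if any(s <= 0 for s in sizes):
            raise ValueError("all architecture sizes must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")

    def min_input_length(self) -> int:
        """Smallest L for which the conv/pool stack retains >= 1 timestep."""
        if not self.use_cnn:
            return 1
        return self.kernel_sizes[0] + self.kernel_sizes[1] - 2 + self.pool_size

    def retained_timesteps(self, L: int) -> int:
        if not self.use_cnn:
            return L
        t = L - self.kernel_sizes[0] + 1 - self.kernel_sizes[1] + 1
        return t // self.pool_size

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("conv_channels", "kernel_sizes", "fc_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def additive_attention(O, H, w1, w2, v):
    """Additive attention over timesteps.

    Parameters
    ----------
    O : (N, T, D) array — encoder outputs per timestep.
    H : (N, Dh) array — summary state broadcast to every timestep.
    w1 : (D, A); w2 : (Dh, A); v : (A, 1) — trainable projections.

    Returns
    -------
    C : (N, D) context vectors; scores : (N, T) softmax attention weights.
    """
    O_t, H_t = nn._as_tensor(O), nn._as_tensor(H)
    w1_t, w2_t, v_t = nn._as_tensor(w1), nn._as_tensor(w2), nn._as_tensor(v)
    C, scores = _attention_graph(O_t, H_t, w1_t, w2_t, v_t)
    return C.data, scores.data


def _attention_graph(O: Tensor, H: Tensor, w1: Tensor, w2: Tensor,
                     v: Tensor) -> tuple[Tensor, Tensor]:
    n, t, d = O.shape
    proj_o = nn.matmul(O, w1)                      # (N, T, A)
    proj_h = nn.reshape(nn.matmul(H, w2), (n, 1, -1))  # (N, 1, A)
    e = nn.matmul(nn.tanh(nn.add(proj_o, proj_h)), v)  # (N, T, 1)
    scores = nn.softmax(nn.reshape(e, (n, t)), axis=1)  # (N, T)
    weighted = nn.mul(O, nn.reshape(scores, (n, t, 1)))
    context = nn.sum_(weighted, axis=1)            # (N, D)
    return context, scores


class SitePredictor:
    """The classifier with its parameters; build via :func:`build_model`."""

    def __init__(self, config: ModelConfig, L: int, feature_dim: int = 20,
                 seed: int = 0):
        if config.retained_timesteps(L) < 1:
            raise ValueError(
                f"input length {L} too small for the conv/pool stack; "
                f"minimum is {config.min_input_length()}"
            )
        self.config = config
        self.L = L
        self.feature_dim = feature_dim
        self.seed = seed
        self.trained = False
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))

    # -- construction -----------------------------------------------------
    def _add_param(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        in_ch = self.feature_dim
        if cfg.use_cnn:
            (c1, c2), (k1, k2) = cfg.conv_channels, cfg.kernel_sizes
            self._add_param("conv1_w", _glorot(rng, (k1, in_ch, c1)))
            self._add_param("conv1_b", np.zeros(c1))
            self._add_param("conv2_w", _glorot(rng, (k2, c1, c2)))
            self._add_param("conv2_b", np.zeros(c2))
            seq_ch = c2
        else:
            seq_ch = in_ch
        if cfg.use_bilstm:
            h = cfg.lstm_hidden
            for direction in ("fwd", "bwd"):
                self._add_param(f"lstm_{direction}_wx", _glorot(rng, (seq_ch, 4 * h)))
                self._add_param(f"lstm_{direction}_wh", _glorot(rng, (h, 4 * h)))
                b = np.zeros(4 * h)
                b[h : 2 * h] = 1.0  # forget-gate bias starts open
                self._add_param(f"lstm_{direction}_b", b)
            feat_dim = 2 * h
        else:
            feat_dim = seq_ch
        if cfg.use_attention:
            a = cfg.attention_dim
            self._add_param("attn_w1", _glorot(rng, (feat_dim, a)))
            self._add_param("attn_w2", _glorot(rng, (feat_dim, a)))
            self._add_param("attn_v", _glorot(rng, (a, 1)))
        f1, f2 = cfg.fc_sizes
        self._add_param("fc1_w", _glorot(rng, (feat_dim, f1)))
        self._add_param("fc1_b", np.zeros(f1))
        self._add_param("fc2_w", _glorot(rng, (f1, f2)))
        self._add_param("fc2_b", np.zeros(f2))
        self._add_param("out_w", _glorot(rng, (f2, cfg.n_classes)))
        self._add_param("out_b", np.zeros(cfg.n_classes))

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # -- forward ----------------------------------------------------------
    def _lstm_pass(self, O: Tensor, direction: str) -> tuple[list[Tensor], Tensor]:
        """Run one LSTM direction; returns per-step hidden states and the final one."""
        wx = self.params[f"lstm_{direction}_wx"]
        wh = self.params[f"lstm_{direction}_wh"]
        b = self.params[f"lstm_{direction}_b"]
        n, t, _ = O.shape
        hdim = self.config.lstm_hidden
        h = Tensor(np.zeros((n, hdim)))
        c = Tensor(np.zeros((n, hdim)))
        z_input = nn.add(nn.matmul(O, wx), b)  # input projection for all steps at once
        steps = range(t) if direction == "fwd" else range(t - 1, -1, -1)
        outputs: dict[int, Tensor] = {}
        for step in steps:
            z = nn.add(nn.select(z_input, step), nn.matmul(h, wh))

            # gate order: input, forget, candidate, output — candidate uses tanh
            def narrow(t_, lo, hi):
                def bwd(g, lo=lo, hi=hi):
                    gz = np.zeros_like(t_.data)
                    gz[:, lo:hi] = g
                    return (gz,)
                return Tensor(t_.data[:, lo:hi], (t_,), bwd)

            i_t = nn.sigmoid(narrow(z, 0, hdim))
            f_t = nn.sigmoid(narrow(z, hdim, 2 * hdim))
            g_t = nn.tanh(narrow(z, 2 * hdim, 3 * hdim))
            o_t = nn.sigmoid(narrow(z, 3 * hdim, 4 * hdim))
            c = nn.add(nn.mul(f_t, c), nn.mul(i_t, g_t))
            h = nn.mul(o_t, nn.tanh(c))
            outputs[step] = h
        return [outputs[s] for s in range(t)], h

    def _forward(self, X: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None,
                 collect_hidden: bool = False):
        """Forward pass; returns (logits, attention scores, hidden dict)."""
        cfg = self.config
        if X.ndim != 3 or X.shape[1] != self.L or X.shape[2] != self.feature_dim:
            raise ValueError(
                f"expected features of shape (N, {self.L}, {self.feature_dim}), "
                f"got {X.shape}"
            )
        if train and rng is None:
            raise ValueError("training-mode forward needs an RNG for dropout")
        hidden: dict[str, np.ndarray] = {}
        n = X.shape[0]
        out = Tensor(X)
        if collect_hidden:
            hidden["encoded"] = X.reshape(n, -1)
        if cfg.use_cnn:
            out = nn.relu(nn.conv1d(out, self.params["conv1_w"], self.params["conv1_b"]))
            out = nn.relu(nn.conv1d(out, self.params["conv2_w"], self.params["conv2_b"]))
            out = nn.maxpool1d(out, cfg.pool_size)
            if collect_hidden:
                hidden["cnn"] = out.data.reshape(n, -1)
        if cfg.use_bilstm:
            fwd_steps, h_fwd = self._lstm_pass(out, "fwd")
            bwd_steps, h_bwd = self._lstm_pass(out, "bwd")
            per_step = [nn.concat([f, b], axis=1) for f, b in zip(fwd_steps, bwd_steps)]
            out = nn.stack(per_step, axis=1)          # (N, T, 2H)
            summary = nn.concat([h_fwd, h_bwd], axis=1)
            if collect_hidden:
                hidden["bilstm"] = out.data.reshape(n, -1)
        else:
            summary = nn.mean_(out, axis=1)
        if cfg.use_attention:
            context, scores = _attention_graph(
                out, summary,
                self.params["attn_w1"], self.params["attn_w2"], self.params["attn_v"],
            )
        else:
            context = summary
            t = out.shape[1]
            scores = Tensor(np.full((n, t), 1.0 / t))
        if collect_hidden:
            hidden["attention"] = context.data.copy()
        x = nn.relu(nn.add(nn.matmul(context, self.params["fc1_w"]), self.params["fc1_b"]))
        x = nn.dropout(x, cfg.dropout, rng, train)
        x = nn.relu(nn.add(nn.matmul(x, self.params["fc2_w"]), self.params["fc2_b"]))
        x = nn.dropout(x, cfg.dropout, rng, train)
        logits = nn.add(nn.matmul(x, self.params["out_w"]), self.params["out_b"])
        return logits, scores, hidden

    def loss(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> Tensor:
        logits, _, _ = self._forward(X, train=True, rng=rng)
        return nn.softmax_cross_entropy(logits, y)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256,
                      return_attention: bool = False):
        """Class probabilities (N, 2) in eval mode (dropout off, deterministic)."""
        probs, attns = [], []
        for lo in range(0, X.shape[0], batch_size):
            logits, scores, _ = self._forward(X[lo : lo + batch_size], train=False)
            probs.append(nn.softmax(logits, axis=1).data)
            attns.append(scores.data)
        probs = np.concatenate(probs) if probs else np.empty((0, self.config.n_classes))
        if return_attention:
            return probs, (np.concatenate(attns) if attns else np.empty((0, 0)))
        return probs

    def hidden_features(self, X: np.ndarray, batch_size: int = 256) -> dict[str, np.ndarray]:
        """Per-stage feature maps (flattened per window) for visualization."""
        stages: dict[str, list[np.ndarray]] = {}
        for lo in range(0, X.shape[0], batch_size):
            _, _, hidden = self._forward(X[lo : lo + batch_size], collect_hidden=True)
            for k, v in hidden.items():
                stages.setdefault(k, []).append(v)
        return {k: np.concatenate(v) for k, v in stages.items()}

    # -- persistence ------------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.array(weights[k], dtype=np.float64)

    def save(self, path) -> None:
        """Save weights as .npz with a JSON sidecar of the configuration."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.get_weights())
        sidecar = {
            "config": self.config.to_dict(),
            "L": self.L,
            "feature_dim": self.feature_dim,
            "seed": self.seed,
            "trained": self.trained,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "SitePredictor":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(
            ModelConfig.from_dict(sidecar["config"]),
            L=sidecar["L"],
            feature_dim=sidecar["feature_dim"],
            seed=sidecar["seed"],
        )
        with np.load(path.with_suffix(".npz")) as npz:
            model.set_weights({k: npz[k] for k in npz.files})
        model.trained = sidecar["trained"]
        return model


def build_model(config: ModelConfig, L: int, feature_dim: int = 20,
                seed: int = 0) -> SitePredictor:
    """Construct an untrained predictor with seeded initial parameters."""
    return SitePredictor(config, L=L, feature_dim=feature_dim, seed=seed)


def predict(model: SitePredictor, dataset, encoder_config=None,
            encoder: str = "bwe", allow_untrained: bool = False):
    """Score every window: probability of class 1 plus attention scores.

    Output order equals input order; evaluation mode is deterministic.
    """
    from .encoding import EncodingConfig, as_sequence_features, encode_dataset

    if not model.trained and not allow_untrained:
        raise ValueError("model is untrained; pass allow_untrained=True to override")
    encoder_config = encoder_config or EncodingConfig(L=dataset.L)
    X = as_sequence_features(encode_dataset(dataset, encoder, encoder_config))
    if X.shape[1] != model.L:
        raise ValueError(f"window length {X.shape[1]} != model input length {model.L}")
    probs, attn = model.predict_proba(X, return_attention=True)
    return probs[:, 1], attn
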