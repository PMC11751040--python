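"""Comparing learned attention profiles with the positional weight curve.

A trained model assigns a softmax attention weight to each retained timestep
of every window. Averaging these over a dataset gives a mean attention
profile; because pooling shortens the sequence axis, the profile is
"stretched" back to the original window length by linear interpolation, then
compared against the (normalized) exponential positional-weight curve of the
encoder using Dynamic Time Warping. A small DTW distance — and a near-
diagonal optimal path — indicate that the attention mechanism concentrates
weight around the center the same way the encoder's decay weights do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .encoding import EncodingConfig, position_weights


@dataclass(frozen=True)
class WeightProfile:
    """An ordered nonnegative weight curve (attention or positional)."""

    values: tuple
    label: str = "attention"

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("profile must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("profile values must be finite and nonnegative")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def normalized(self) -> "WeightProfile":
        arr = self.array
        total = arr.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        return WeightProfile(tuple(arr / total), self.label)


@dataclass(frozen=True)
class DTWResult:
    """DTW distance and the optimal monotone warping path."""

    distance: float
    path: tuple

    def __post_init__(self):
        if self.distance < 0:
            raise ValueError("DTW distance cannot be negative")

    @property
    def normalized_distance(self) -> float:
        return self.distance / len(self.path)


def dtw(a, b) -> DTWResult:
    """Dynamic time warping with steps {(1,0),(0,1),(1,1)} and |a_i - b_j| cost.

    The optimal path is recovered by backtrace with a deterministic
    tie-break: diagonal preferred, then vertical (advance in ``a``), then
    horizontal.
    """
    a = a.array if isinstance(a, WeightProfile) else np.asarray(a, dtype=float)
    b = b.array if isinstance(b, WeightProfile) else np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("profiles must be non-empty")
    n, m = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :])
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        D[i, 1:] = cost[i - 1]
        for j in range(1, m + 1):
            D[i, j] += min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    path = [(n - 1, m - 1)]
    i, j = n, m
    while (i, j) != (1, 1):
        candidates = ((D[i - 1, j - 1], (i - 1, j - 1)),
                      (D[i - 1, j], (i - 1, j)),
                      (D[i, j - 1], (i, j - 1)))
        best = min(c[0] for c in candidates)
        for value, (pi, pj) in candidates:  # first match = preferred step
            if value == best and pi >= 1 and pj >= 1:
                i, j = pi, pj
                break
        path.append((i - 1, j - 1))
    path.reverse()
    return DTWResult(distance=float(D[n, m]), path=tuple(path))


def mean_attention_profile(model, dataset, encoder_config=None,
                           encoder: str = "bwe", positives_only: bool = False,
                           allow_untrained: bool = False) -> WeightProfile:
    """Average per-window attention scores over a dataset (sums to 1)."""
    from .model import predict

    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    _, attn = predict(model, dataset, encoder_config, encoder=encoder,
                      allow_untrained=allow_untrained)
    if positives_only:
        mask = dataset.labels == 1
        if not mask.any():
            raise ValueError("positives_only requested but no positive windows")
        attn = attn[mask]
    return WeightProfile(tuple(attn.mean(axis=0)), label="attention")


def stretch_profile(profile: WeightProfile, L: int) -> WeightProfile:
    """Linearly interpolate a T-point profile onto L points, renormalized.

    The T values are placed uniformly on [0, L-1]; compression (L < T) is
    refused.
    """
    t = len(profile)
    if L < t:
        raise ValueError(f"cannot compress profile of length {t} to {L}")
    arr = profile.array
    if t == 1:
        stretched = np.full(L, arr[0])
    else:
        stretched = np.interp(np.linspace(0.0, t - 1.0, L), np.arange(t), arr)
    total = stretched.sum()
    if total > 0:
        stretched = stretched / total
    return WeightProfile(tuple(stretched), label=profile.label)


def rank_reversed(profile: WeightProfile) -> WeightProfile:
    """Reverse a profile about its ranks: the largest value moves to the
    position of the smallest, and so on. For a center-peaked curve this
    produces a center-lowest control with the same multiset of values."""
    arr = profile.array
    order = np.argsort(arr, kind="stable")
    out = np.empty_like(arr)
    out[order] = arr[order[::-1]]
    return WeightProfile(tuple(out), label=profile.label + "_rank_reversed")


@dataclass
class AttentionComparison:
    """Serializable report of the attention-vs-position-weight comparison."""

    attention_curve: list
    position_curve: list
    distance: float
    normalized_distance: float
    path: list
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "attention_curve": list(self.attention_curve),
                "position_curve": list(self.position_curve),
                "distance": self.distance,
                "normalized_distance": self.normalized_distance,
                "path": [list(p) for p in self.path],
                "extras": self.extras,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "AttentionComparison":
        d = json.loads(text)
        return cls(
            attention_curve=d["attention_curve"],
            position_curve=d["position_curve"],
            distance=d["distance"],
            normalized_distance=d["normalized_distance"],
            path=[tuple(p) for p in d["path"]],
            extras=d.get("extras", {}),
        )


def compare_attention_to_position_weights(
    model, dataset, encoder_config: EncodingConfig | None = None,
    encoder: str = "bwe", positives_only: bool = False,
    allow_untrained: bool = False,
) -> AttentionComparison:
    """Stretch the mean attention profile to window length and DTW-compare it
    with the normalized positional-weight curve."""
    encoder_config = encoder_config or EncodingConfig(L=dataset.L)
    profile = mean_attention_profile(
        model, dataset, encoder_config, encoder=encoder,
        positives_only=positives_only, allow_untrained=allow_untrained,
    )
    stretched = stretch_profile(profile, encoder_config.L)
    pos_curve = position_weights(encoder_config)
    pos_profile = WeightProfile(tuple(pos_curve / pos_curve.sum()), label="position")
    result = dtw(stretched, pos_profile)
    return AttentionComparison(
        attention_curve=list(stretched.array),
        position_curve=list(pos_profile.array),
        distance=result.distance,
        normalized_distance=result.normalized_distance,
        path=list(result.path),
        extras={"timesteps": len(profile), "L": encoder_config.L},
    )
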