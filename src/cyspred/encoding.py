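"""Numeric encoders for peptide windows.

The central encoder is *binary-weight encoding* (BWE): standard one-hot
encoding of each residue, with row i scaled by a positional weight

    W_i = p * exp(-alpha * d_i),

where d_i is the distance (in residues) of position i from the window center,
p the source strength and alpha the decay coefficient. The weighting treats
the modified residue at the center as a signal source whose influence decays
exponentially with distance; alpha = 0 recovers plain one-hot encoding.

Also provided are the classical comparison descriptors: enhanced amino-acid
composition (EAAC, sliding-window residue frequencies), dipeptide and
tripeptide composition (DPC/TPC) and the composition/transition/distribution
descriptor (CTD) over seven physicochemical attributes.

Unknown or padding residues 'X' encode as zero rows and are excluded from
composition counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .io_datasets import ALPHABET, EXTENDED_ALPHABET, PeptideWindow

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Encoders that produce a (timesteps x channels) matrix suitable for the
#: sequence model directly; the remaining encoders produce flat vectors.
MATRIX_ENCODERS = ("binary", "bwe", "eaac")
ALL_ENCODERS = ("binary", "bwe", "eaac", "dpc", "tpc", "ctd")


@dataclass(frozen=True)
class EncodingConfig:
    """Parameters of binary-weight encoding.

    alpha : exponential decay coefficient per residue of distance (>= 0).
    p : signal-source strength; scales the whole feature matrix (> 0).
    L : window length (odd).
    """

    alpha: float = 0.02
    p: float = 1.0
    L: int = 41
    alphabet: str = ALPHABET

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.p <= 0:
            raise ValueError(f"p must be > 0, got {self.p}")
        if self.L % 2 == 0 or self.L < 3:
            raise ValueError(f"L must be odd and >= 3, got {self.L}")
        if sorted(set(self.alphabet)) != sorted(self.alphabet) or len(self.alphabet) != 20:
            raise ValueError("alphabet must be 20 distinct letters")


def _window_seq(window) -> str:
    return window.sequence if isinstance(window, PeptideWindow) else str(window)


def binary_encode(window, alphabet: str = ALPHABET) -> np.ndarray:
    """One-hot encode a window into an (L, 20) matrix; 'X' rows are zero."""
    seq = _window_seq(window)
    idx = {aa: i for i, aa in enumerate(alphabet)}
    mat = np.zeros((len(seq), len(alphabet)))
    for i, ch in enumerate(seq):
        if ch == "X":
            continue
        if ch not in idx:
            raise ValueError(f"character {ch!r} at position {i} not in alphabet")
        mat[i, idx[ch]] = 1.0
    return mat


def position_weights(config: EncodingConfig) -> np.ndarray:
    """Positional weight vector W_i = p * exp(-alpha * |i - center|)."""
    center = (config.L - 1) // 2
    d = np.abs(np.arange(config.L) - center)
    return config.p * np.exp(-config.alpha * d)


def bwe_encode(window, config: EncodingConfig) -> np.ndarray:
    """Binary-weight encoding: one-hot rows scaled by positional weights."""
    seq = _window_seq(window)
    if len(seq) != config.L:
        raise ValueError(f"window length {len(seq)} != config L {config.L}")
    return binary_encode(seq, config.alphabet) * position_weights(config)[:, None]


def eaac_encode(window, sliding_window_size: int = 5, alphabet: str = ALPHABET) -> np.ndarray:
    """Enhanced amino-acid composition: per-subwindow residue frequencies.

    Returns an (L - w + 1, 20) matrix; 'X' is excluded from numerator and
    denominator, and an all-'X' subwindow yields a zero row.
    """
    seq = _window_seq(window)
    w = sliding_window_size
    if w > len(seq):
        raise ValueError(f"sliding window {w} exceeds sequence length {len(seq)}")
    idx = {aa: i for i, aa in enumerate(alphabet)}
    n_blocks = len(seq) - w + 1
    out = np.zeros((n_blocks, len(alphabet)))
    for b in range(n_blocks):
        sub = seq[b : b + w]
        valid = [c for c in sub if c != "X"]
        if not valid:
            continue
        for c in valid:
            out[b, idx[c]] += 1.0
        out[b] /= len(valid)
    return out


def dpc_encode(window, alphabet: str = ALPHABET) -> np.ndarray:
    """Dipeptide composition: normalized counts of overlapping residue pairs.

    Pairs containing 'X' are skipped. Returns a 400-vector in alphabet-major
    order (AA, AC, ..., YY); zero vector if no valid pair exists.
    """
    seq = _window_seq(window)
    idx = {aa: i for i, aa in enumerate(alphabet)}
    counts = np.zeros(400)
    total = 0
    for a, b in zip(seq, seq[1:]):
        if a == "X" or b == "X":
            continue
        counts[idx[a] * 20 + idx[b]] += 1.0
        total += 1
    return counts / total if total else counts


def tpc_encode(window, alphabet: str = ALPHABET) -> np.ndarray:
    """Tripeptide composition: normalized counts of overlapping triples (8000-vector)."""
    seq = _window_seq(window)
    idx = {aa: i for i, aa in enumerate(alphabet)}
    counts = np.zeros(8000)
    total = 0
    for a, b, c in zip(seq, seq[1:], seq[2:]):
        if "X" in (a, b, c):
            continue
        counts[(idx[a] * 20 + idx[b]) * 20 + idx[c]] += 1.0
        total += 1
    return counts / total if total else counts


# Standard three-group partitions of the 20 residues under seven
# physicochemical attributes (hydrophobicity, normalized van der Waals
# volume, polarity, polarizability, charge, secondary structure propensity,
# solvent accessibility) used by the CTD descriptor.
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}


def ctd_encode(window) -> np.ndarray:
    """Composition/Transition/Distribution descriptor (147-vector).

    For each of the seven attributes: 3 group composition fractions, 3
    group-pair transition frequencies, and for each group the relative
    positions (percent of sequence length) of its first, 25%, 50%, 75% and
    last occurrence (15 values). 'X' residues are dropped before computing.
    """
    seq = [c for c in _window_seq(window) if c != "X"]
    n = len(seq)
    feats: list[float] = []
    for attr, groups in CTD_GROUPS.items():
        gmap = {}
        for gi, letters in enumerate(groups):
            for ch in letters:
                gmap[ch] = gi
        labels = [gmap[c] for c in seq]
        # composition
        counts = [labels.count(g) for g in range(3)]
        feats.extend([c / n if n else 0.0 for c in counts])
        # transitions between distinct group pairs (unordered)
        trans = [0, 0, 0]  # (0,1), (0,2), (1,2)
        pair_index = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
        for a, b in zip(labels, labels[1:]):
            if a != b:
                trans[pair_index[(min(a, b), max(a, b))]] += 1
        n_pairs = max(n - 1, 1)
        feats.extend([t / n_pairs for t in trans])
        # distribution: position percentiles of each group's occurrences
        for g in range(3):
            positions = [i + 1 for i, lab in enumerate(labels) if lab == g]
            if not positions:
                feats.extend([0.0] * 5)
                continue
            m = len(positions)
            for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                rank = max(int(np.ceil(frac * m)), 1)
                feats.append(positions[rank - 1] / n * 100.0)
    return np.asarray(feats)


def encode_window(window, encoder: str, config: EncodingConfig | None = None,
                  **kwargs) -> np.ndarray:
    """Encode one window with the named encoder."""
    config = config or EncodingConfig(L=len(_window_seq(window)))
    if encoder == "binary":
        return binary_encode(window, config.alphabet)
    if encoder == "bwe":
        return bwe_encode(window, config)
    if encoder == "eaac":
        return eaac_encode(window, alphabet=config.alphabet, **kwargs)
    if encoder == "dpc":
        return dpc_encode(window, alphabet=config.alphabet)
    if encoder == "tpc":
        return tpc_encode(window, alphabet=config.alphabet)
    if encoder == "ctd":
        return ctd_encode(window)
    raise ValueError(f"unknown encoder {encoder!r}; choose from {ALL_ENCODERS}")


def encode_dataset(dataset, encoder: str = "bwe",
                   config: EncodingConfig | None = None, **kwargs) -> np.ndarray:
    """Encode all windows; matrix encoders give (N, T, C), flat give (N, D)."""
    mats = [encode_window(w, encoder, config, **kwargs) for w in dataset]
    return np.stack(mats)


def as_sequence_features(X: np.ndarray) -> np.ndarray:
    """Reshape encoded features for the sequence model.

    Matrix encoders pass through as (N, T, C); flat descriptor vectors are
    viewed as (N, D, 1) single-channel sequences.
    """
    if X.ndim == 3:
        return X
    if X.ndim == 2:
        return X[:, :, None]
    raise ValueError(f"unexpected feature array of ndim {X.ndim}")


def feature_names(encoder: str, L: int, sliding_window_size: int = 5,
                  alphabet: str = ALPHABET) -> list[str]:
    """Stable column names for the flattened feature CSV export."""
    if encoder in ("binary", "bwe"):
        return [f"pos{i}_{aa}" for i in range(L) for aa in alphabet]
    if encoder == "eaac":
        return [
            f"win{b}_{aa}"
            for b in range(L - sliding_window_size + 1)
            for aa in alphabet
        ]
    if encoder == "dpc":
        return [a + b for a, b in product(alphabet, repeat=2)]
    if encoder == "tpc":
        return ["".join(t) for t in product(alphabet, repeat=3)]
    if encoder == "ctd":
        names = []
        for attr in CTD_GROUPS:
            names += [f"{attr}_comp_g{g}" for g in range(1, 4)]
            names += [f"{attr}_trans_{p}" for p in ("g1g2", "g1g3", "g2g3")]
            for g in range(1, 4):
                names += [f"{attr}_dist_g{g}_p{q}" for q in (0, 25, 50, 75, 100)]
        return names
    raise ValueError(f"unknown encoder {encoder!r}")
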