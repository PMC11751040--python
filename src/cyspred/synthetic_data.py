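"""Synthetic peptide-window datasets with a center-concentrated signal.

The generator emulates the assumed structure of a centered-residue PTM
dataset: every window has the candidate residue (cysteine) fixed at the
center, negatives are drawn i.i.d. from a background composition, and
positives carry a compositional signal — at each off-center position,
with probability s0 * exp(-beta * d) (d = distance from the center) the
residue is drawn from a small set of signal residues instead of the
background. The signal is strongest next to the modified cysteine and
decays with distance, which is exactly the premise that motivates both
positional down-weighting in the encoder and center-focused attention.

The decay rate beta of the data is deliberately independent of the
encoder's decay coefficient alpha, so recovery experiments can ask whether
the best alpha tracks beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import ALPHABET
from .io_datasets import LabeledDataset, PeptideWindow


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of the synthetic center-signal generator.

    signal_strength (s0): probability of emitting a signal residue at
    distance 0+ (before decay), in [0, 1].
    signal_decay (beta): exponential decay rate of that probability per
    residue of distance (>= 0).
    background: per-residue composition over the 20-letter alphabet
    (uniform by default).
    """

    L: int = 41
    signal_residues: tuple = ("K", "R", "E")
    signal_strength: float = 0.8
    signal_decay: float = 0.05
    background: tuple = field(default=tuple(1.0 / 20 for _ in range(20)))
    n_proteins: int = 60
    windows_per_protein: int | None = None
    center_residue: str = "C"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError(f"signal_strength must be in [0,1], got {self.signal_strength}")
        if self.signal_decay < 0:
            raise ValueError(f"signal_decay must be >= 0, got {self.signal_decay}")
        if self.L % 2 == 0 or self.L < 3:
            raise ValueError(f"L must be odd and >= 3, got {self.L}")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a valid distribution over 20 residues")
        bad = set(self.signal_residues) - set(ALPHABET)
        if bad:
            raise ValueError(f"signal residues {sorted(bad)} not in alphabet")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")

    @property
    def background_array(self) -> np.ndarray:
        return np.asarray(self.background, dtype=float)

    def background_mass(self) -> float:
        """Background probability mass of the signal-residue set."""
        bg = self.background_array
        return float(sum(bg[ALPHABET.index(r)] for r in self.signal_residues))


def expected_signal_frequency(spec: SignalSpec, d: int) -> float:
    """Analytic probability that a positive-class residue at distance ``d``
    from the center is a signal residue.

    The residue is a signal draw with probability s0*exp(-beta*d); otherwise
    it comes from the background, which itself contains the signal residues
    with mass ``background_mass``.
    """
    half = (spec.L - 1) // 2
    if d == 0:
        raise ValueError("d=0 is the fixed center residue; no signal model there")
    if not (1 <= d <= half):
        raise ValueError(f"d must be in [1, {half}], got {d}")
    p_signal = spec.signal_strength * np.exp(-spec.signal_decay * d)
    return float(p_signal + (1.0 - p_signal) * spec.background_mass())


def _draw_windows(spec: SignalSpec, n: int, positive: bool,
                  rng: np.random.Generator) -> list[str]:
    half = (spec.L - 1) // 2
    letters = np.array(list(ALPHABET))
    bg = spec.background_array
    seqs = []
    d = np.abs(np.arange(spec.L) - half)
    p_sig = spec.signal_strength * np.exp(-spec.signal_decay * d) if positive else np.zeros(spec.L)
    signal_letters = np.array(list(spec.signal_residues))
    for _ in range(n):
        chars = letters[rng.choice(20, size=spec.L, p=bg)]
        if positive:
            use_signal = rng.random(spec.L) < p_sig
            use_signal[half] = False
            n_sig = int(use_signal.sum())
            if n_sig:
                chars[use_signal] = signal_letters[rng.integers(len(signal_letters), size=n_sig)]
        chars[half] = spec.center_residue
        seqs.append("".join(chars))
    return seqs


def generate_dataset(spec: SignalSpec, n_pos: int, n_neg: int) -> LabeledDataset:
    """Generate a labeled dataset of synthetic centered windows.

    Windows are assigned to ``spec.n_proteins`` synthetic protein ids
    round-robin (positives and negatives interleaved across the same id
    space) so that group-aware fold splitting is exercised. Fully
    deterministic given ``spec.seed``.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError(f"n_pos and n_neg must be positive, got {n_pos}, {n_neg}")
    rng = np.random.default_rng(spec.seed)
    pos_seqs = _draw_windows(spec, n_pos, positive=True, rng=rng)
    neg_seqs = _draw_windows(spec, n_neg, positive=False, rng=rng)
    half = (spec.L - 1) // 2
    n_proteins = spec.n_proteins
    if spec.windows_per_protein is not None:
        n_proteins = max(1, -(-(n_pos + n_neg) // spec.windows_per_protein))
    windows = []
    for i, (seq, label) in enumerate(
        [(s, 1) for s in pos_seqs] + [(s, 0) for s in neg_seqs]
    ):
        windows.append(
            PeptideWindow(
                sequence=seq,
                label=label,
                protein_id=f"syn{i % n_proteins:04d}",
                center_position=half + 1,
                center_residue=spec.center_residue,
            )
        )
    return LabeledDataset(windows)
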