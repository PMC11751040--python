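"""Reading proteins, extracting centered peptide windows, assembling datasets.

A *peptide window* is a fixed, odd-length subsequence of a protein centered on
a candidate modified residue (by default a cysteine). Windows that run off a
protein terminus are padded with ``'X'``, which every encoder maps to a zero
vector. Datasets carry parent-protein identifiers so cross-validation folds
can be made group-aware: all windows from one protein share a fold, which
prevents homology leakage between training and validation splits.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 proteinogenic amino acids, in the fixed column order used throughout.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Extended alphabet: the 20 residues plus 'X' for unknown/padding.
EXTENDED_ALPHABET = ALPHABET + "X"

_VALID = set(EXTENDED_ALPHABET)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"protein {self.id!r}: characters {sorted(bad)} outside alphabet"
            )


@dataclass(frozen=True)
class PeptideWindow:
    """Fixed-length window centered on a candidate modified residue.

    ``center_position`` is the 1-based position of the center residue in the
    parent protein; ``label`` is 1 (modified), 0 (unmodified) or None for
    windows not yet labeled.
    """

    sequence: str
    protein_id: str
    center_position: int
    label: int | None = None
    center_residue: str = "C"

    def __post_init__(self):
        L = len(self.sequence)
        if L % 2 == 0 or L < 3:
            raise ValueError(f"window length {L} must be odd and >= 3")
        mid = self.sequence[(L - 1) // 2]
        if mid != self.center_residue:
            raise ValueError(
                f"window center is {mid!r}, expected {self.center_residue!r}"
            )
        if self.label not in (None, 0, 1):
            raise ValueError(f"label must be 0/1/None, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """An ordered collection of labeled windows sharing one length."""

    windows: list[PeptideWindow] = field(default_factory=list)

    def __post_init__(self):
        if self.windows:
            lengths = {len(w) for w in self.windows}
            if len(lengths) > 1:
                raise ValueError(f"mixed window lengths {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i):
        if isinstance(i, (slice, list, np.ndarray)):
            idx = i if isinstance(i, slice) else list(np.asarray(i))
            sel = self.windows[idx] if isinstance(idx, slice) else [self.windows[j] for j in idx]
            return LabeledDataset(sel)
        return self.windows[i]

    @property
    def L(self) -> int:
        if not self.windows:
            raise ValueError("empty dataset has no window length")
        return len(self.windows[0])

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=np.int64)

    @property
    def sequences(self) -> list[str]:
        return [w.sequence for w in self.windows]

    @property
    def protein_ids(self) -> list[str]:
        return [w.protein_id for w in self.windows]

    @property
    def class_ratio(self) -> tuple[int, int]:
        y = self.labels
        return int((y == 1).sum()), int((y == 0).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": self.sequences,
                "label": [w.label for w in self.windows],
                "protein_id": self.protein_ids,
                "center_position": [w.center_position for w in self.windows],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "LabeledDataset":
        df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "protein_id": str})
        required = {"sequence", "label", "protein_id", "center_position"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"window table {path}: missing columns {sorted(missing)}")
        windows = [
            PeptideWindow(
                sequence=row.sequence,
                label=int(row.label),
                protein_id=str(row.protein_id),
                center_position=int(row.center_position),
                center_residue=row.sequence[(len(row.sequence) - 1) // 2],
            )
            for row in df.itertuples()
        ]
        return cls(windows)


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of dataset indices into k folds, grouped by protein."""

    k: int
    assignment: tuple

    def fold_indices(self, fold: int) -> np.ndarray:
        arr = np.asarray(self.assignment)
        return np.flatnonzero(arr == fold)

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"index": np.arange(len(self.assignment)), "fold": list(self.assignment)}
        ).to_csv(path, sep="\t", index=False)


def sanitize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase ``seq`` and replace characters outside the alphabet by 'X'."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    cleaned = re.sub(f"[^{EXTENDED_ALPHABET}]", "X", seq)
    n_bad = sum(a != b for a, b in zip(seq, cleaned))
    logger.warning(
        "record %s: replaced %d non-standard character(s) with 'X'", record_id, n_bad
    )
    return cleaned


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into sanitized :class:`ProteinRecord` objects."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}: malformed FASTA header at line {lineno}")
            break
        else:
            raise ValueError(f"{path}: no records")
    records = [
        ProteinRecord(id=rec.id, sequence=sanitize_sequence(str(rec.seq), rec.id))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def extract_windows(
    protein: ProteinRecord, center_residue: str = "C", L: int = 41
) -> list[PeptideWindow]:
    """Extract one L-length window per occurrence of ``center_residue``.

    Windows overhanging the protein termini are padded with 'X' so that every
    window has exactly length L with the target residue at the center.
    """
    if L % 2 == 0 or L < 3:
        raise ValueError(f"window length must be odd and >= 3, got {L}")
    half = (L - 1) // 2
    seq = protein.sequence
    out = []
    for idx, ch in enumerate(seq):
        if ch != center_residue:
            continue
        left = seq[max(0, idx - half) : idx]
        right = seq[idx + 1 : idx + 1 + half]
        window = "X" * (half - len(left)) + left + ch + right + "X" * (half - len(right))
        out.append(
            PeptideWindow(
                sequence=window,
                protein_id=protein.id,
                center_position=idx + 1,
                center_residue=center_residue,
            )
        )
    return out


def _dedup(windows) -> list[PeptideWindow]:
    seen = set()
    out = []
    for w in windows:
        key = w.sequence
        if key not in seen:
            seen.add(key)
            out.append(w)
    return out


def parse_ratio(ratio) -> tuple[int, int] | None:
    """Parse a pos:neg ratio like ``"1:10"``; ``"all"`` returns None."""
    if ratio in (None, "all"):
        return None
    if isinstance(ratio, str):
        m = re.fullmatch(r"(\d+):(\d+)", ratio.strip())
        if not m:
            raise ValueError(f"cannot parse ratio {ratio!r}; expected 'P:N' or 'all'")
        return int(m.group(1)), int(m.group(2))
    p, n = ratio
    return int(p), int(n)


def build_dataset(positives, negatives, ratio="1:1", seed: int = 0) -> LabeledDataset:
    """Assemble a labeled dataset at the requested positive:negative ratio.

    Exact duplicate sequences are removed within each class. Negatives are
    subsampled with a seeded RNG, stratified over parent proteins so no single
    protein dominates the negative class.
    """
    pos = [replace(w, label=1) for w in _dedup(positives)]
    neg = [replace(w, label=0) for w in _dedup(negatives)]
    parsed = parse_ratio(ratio)
    if parsed is None:
        return LabeledDataset(pos + neg)
    if not pos or not neg:
        raise ValueError("both classes must be non-empty for a fixed ratio")
    rp, rn = parsed
    n_neg_needed = (len(pos) * rn) // rp
    if n_neg_needed > len(neg):
        raise ValueError(
            f"ratio {rp}:{rn} needs {n_neg_needed} negatives but only "
            f"{len(neg)} are available (short by {n_neg_needed - len(neg)})"
        )
    rng = np.random.default_rng(seed)
    # stratified round-robin over proteins: shuffle within each protein, then
    # draw one window per protein in shuffled protein order until filled
    by_protein: dict[str, list[PeptideWindow]] = {}
    for w in neg:
        by_protein.setdefault(w.protein_id, []).append(w)
    prot_ids = sorted(by_protein)
    rng.shuffle(prot_ids)
    for pid in prot_ids:
        rng.shuffle(by_protein[pid])
    chosen: list[PeptideWindow] = []
    depth = 0
    while len(chosen) < n_neg_needed:
        advanced = False
        for pid in prot_ids:
            bucket = by_protein[pid]
            if depth < len(bucket):
                chosen.append(bucket[depth])
                advanced = True
                if len(chosen) == n_neg_needed:
                    break
        if not advanced:
            break
        depth += 1
    return LabeledDataset(pos + chosen)


def group_kfold(dataset: LabeledDataset, k: int, seed: int = 0) -> FoldAssignment:
    """Group-aware k-fold assignment: windows of one protein share a fold.

    Proteins are ordered by descending window count (seeded shuffle breaks
    ties) and assigned greedily to the currently smallest fold, balancing
    fold sizes.
    """
    groups: dict[str, list[int]] = {}
    for i, w in enumerate(dataset):
        groups.setdefault(w.protein_id, []).append(i)
    if len(groups) < k:
        raise ValueError(f"only {len(groups)} protein groups for k={k} folds")
    rng = np.random.default_rng(seed)
    prot_ids = sorted(groups)
    rng.shuffle(prot_ids)
    prot_ids.sort(key=lambda pid: -len(groups[pid]))  # stable: keeps shuffle order on ties
    fold_sizes = np.zeros(k, dtype=np.int64)
    assignment = np.empty(len(dataset), dtype=np.int64)
    for pid in prot_ids:
        fold = int(np.argmin(fold_sizes))  # lowest index wins ties
        assignment[groups[pid]] = fold
        fold_sizes[fold] += len(groups[pid])
    return FoldAssignment(k=k, assignment=tuple(int(f) for f in assignment))
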