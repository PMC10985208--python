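"""Distributed matrix representation of a precursor for the CNN.

Each candidate becomes a 7 x L matrix (L = 200 by default):

* rows 0-3 — one-hot nucleotide identity in the order A, U, C, G;
* rows 4-5 — structure code per column: [1, 0] paired, [0, 1] unpaired,
  [0.5, 0.5] for gap/padding columns beyond the precursor;
* row 6   — read coverage, normalized by the count of the most abundant
  read of the window, overlaps resolved by the per-position maximum.

Shorter precursors are right-padded; the one-hot rows of padding columns
are all zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .precursor_extraction import PrecursorCandidate

MATRIX_HEIGHT = 7
DEFAULT_WIDTH = 200

_ROW_OF_BASE = {"A": 0, "U": 1, "C": 2, "G": 3}
_BASE_OF_ROW = "AUCG"


@dataclass
class EncodedMatrix:
    """7 x L input matrix with optional supervised label (1 miRNA, 0 other)."""

    values: np.ndarray
    label: Optional[int] = None
    candidate_id: str = ""

    @property
    def width(self) -> int:
        return self.values.shape[1]


def normalize_read_track(
    mapped_reads: Sequence[Tuple[int, int, int, str]] | Sequence[Tuple[int, int, int]],
    n: int,
) -> np.ndarray:
    """Per-position coverage normalized by the most abundant read's count.

    Each read paints count/max_count over its span; overlapping reads take
    the per-position maximum.  Uncovered positions are zero.  The result is
    order-invariant and scale-invariant in the raw counts.
    """
    track = np.zeros(n, dtype=np.float32)
    if not mapped_reads:
        return track
    max_count = max(r[2] for r in mapped_reads)
    for r in mapped_reads:
        off, length, count = r[0], r[1], r[2]
        lo, hi = max(0, off), min(n, off + length)
        if lo < hi:
            np.maximum(track[lo:hi], count / max_count, out=track[lo:hi])
    return track


def encode_precursor(
    candidate: PrecursorCandidate, L: int = DEFAULT_WIDTH
) -> EncodedMatrix:
    """Encode one folded candidate as a 7 x L matrix."""
    seq = candidate.sequence
    n = len(seq)
    if n > L:
        raise ValueError(
            f"candidate length {n} exceeds matrix width {L}; "
            "restrict window selection upstream"
        )
    if candidate.fold is None:
        raise ValueError("candidate must be folded before encoding")

    values = np.zeros((MATRIX_HEIGHT, L), dtype=np.float32)
    for i, base in enumerate(seq):
        values[_ROW_OF_BASE[base], i] = 1.0
    paired = candidate.fold.pair_table >= 0
    values[4, :n] = np.where(paired, 1.0, 0.0)
    values[5, :n] = np.where(paired, 0.0, 1.0)
    values[4:6, n:] = 0.5
    values[6, :n] = normalize_read_track(candidate.mapped_reads, n)

    label = {"miRNA": 1, "other": 0}.get(candidate.label)
    cid = f"{candidate.chrom}:{candidate.start}-{candidate.end}({candidate.strand})"
    return EncodedMatrix(values=values, label=label, candidate_id=cid)


def decode_matrix(matrix: EncodedMatrix) -> Tuple[str, np.ndarray]:
    """Recover the precursor sequence and per-base paired flags (round-trip
    companion of encode_precursor, used to validate the encoding)."""
    values = matrix.values
    present = values[:4].sum(axis=0) > 0
    n = int(present.sum())
    seq = "".join(_BASE_OF_ROW[int(values[:4, i].argmax())] for i in range(n))
    paired = values[4, :n] == 1.0
    return seq, paired


def stack_batch(
    matrices: Sequence[EncodedMatrix],
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Stack encodings into an (N, 1, 7, L) array with labels (-1 where
    unlabeled) and candidate ids."""
    X = np.stack([m.values for m in matrices])[:, None, :, :]
    y = np.array([-1 if m.label is None else m.label for m in matrices], dtype=np.int64)
    ids = [m.candidate_id for m in matrices]
    return X, y, ids


def save_batch(path, matrices: Sequence[EncodedMatrix]) -> None:
    X, y, ids = stack_batch(matrices)
    np.savez_compressed(path, X=X, y=y, ids=np.array(ids))


def load_batch(path) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    data = np.load(path, allow_pickle=False)
    return data["X"], data["y"], [str(s) for s in data["ids"]]
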