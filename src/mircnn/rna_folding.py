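"""Secondary structure prediction for precursor windows.

The built-in folder maximizes the number of nested base pairs (Nussinov
dynamic program) over the pair set {AU, UA, GC, CG, GU, UG} with a minimum
hairpin loop of 3 nt.  Base-pair maximization is deliberately simple: it is
dependency-free, admits an exact brute-force enumeration oracle at small n,
and recovers designed stem-loops reliably.  ``fold`` is the extension
point — any callable with the same signature (e.g. wrapping a
thermodynamic folder) can stand in for it throughout the pipeline.

The hairpin decision used for precursor filtering requires (a) a single
terminal loop in the arm system containing the candidate mature span,
(b) at least 60% of mature bases paired, and (c) every mature partner on
one side of the mature span (the opposite arm).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Tuple

import numpy as np
from numba import njit

MIN_LOOP = 3
MIN_MATURE_PAIRED_FRAC = 0.6

# base codes: A=0, C=1, G=2, U=3.  Allowed pairs AU/UA (sum 3), CG/GC (sum 3),
# GU/UG (sum 5); code sums 3 and 5 arise from exactly those combinations.
_CODES = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass
class FoldResult:
    """Sequence, dot-bracket string, pair count, and the pair table
    (pair_table[i] = j if i pairs j, -1 if unpaired)."""

    sequence: str
    dotbracket: str
    pair_count: int
    pair_table: np.ndarray

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HairpinReport:
    """Per-check detail behind the hairpin decision."""

    frac_mature_paired: float
    partners_one_side: bool
    single_terminal_loop: bool
    n_terminal_loops: int
    passes: bool


@njit(cache=True)
def _nussinov_fill(codes, min_loop):  # pragma: no cover - exercised via fold()
    n = codes.shape[0]
    M = np.zeros((n + 1, n + 1), dtype=np.int32)
    for d in range(min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            best = M[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                s = codes[i] + codes[k]
                if s == 3 or s == 5:
                    v = 1 + M[i + 1, k - 1] + M[k + 1, j]
                    if v > best:
                        best = v
            M[i, j] = best
    return M


@njit(cache=True)
def _nussinov_traceback(M, codes, min_loop):  # pragma: no cover
    n = codes.shape[0]
    pair_table = np.full(n, -1, dtype=np.int32)
    stack_i = np.empty(2 * n + 2, dtype=np.int32)
    stack_j = np.empty(2 * n + 2, dtype=np.int32)
    top = 0
    stack_i[0] = 0
    stack_j[0] = n - 1
    while top >= 0:
        i = stack_i[top]
        j = stack_j[top]
        top -= 1
        if i >= j or M[i, j] == 0:
            continue
        if M[i, j] == M[i + 1, j]:
            # tie-break: prefer leaving i unpaired
            top += 1
            stack_i[top] = i + 1
            stack_j[top] = j
            continue
        for k in range(i + min_loop + 1, j + 1):
            s = codes[i] + codes[k]
            if (s == 3 or s == 5) and M[i, j] == 1 + M[i + 1, k - 1] + M[k + 1, j]:
                # tie-break: pair i with the smallest feasible partner
                pair_table[i] = k
                pair_table[k] = i
                top += 1
                stack_i[top] = i + 1
                stack_j[top] = k - 1
                top += 1
                stack_i[top] = k + 1
                stack_j[top] = j
                break
    return pair_table


def fold(sequence: str, min_loop: int = MIN_LOOP) -> FoldResult:
    """Maximum base-pair structure of an RNA sequence.

    DNA input (T) is transparently read as RNA (U).  Tie-breaking in the
    traceback is deterministic: a position is left unpaired whenever an
    optimal structure allows it, otherwise it pairs with its smallest
    feasible partner.
    """
    if not sequence:
        raise ValueError("cannot fold an empty sequence")
    rna = sequence.upper().replace("T", "U")
    try:
        codes = np.array([_CODES[b] for b in rna], dtype=np.int8)
    except KeyError as err:
        raise ValueError(f"invalid character {err} in sequence") from None

    M = _nussinov_fill(codes, min_loop)
    pair_table = _nussinov_traceback(M, codes, min_loop)

    db = np.full(len(rna), ".", dtype="<U1")
    for i, j in enumerate(pair_table):
        if j > i:
            db[i] = "("
            db[j] = ")"
    pair_count = int(M[0, len(rna) - 1]) if len(rna) > 1 else 0
    assert pair_count == int((pair_table >= 0).sum()) // 2
    return FoldResult(rna, "".join(db), pair_count, pair_table)


def _terminal_loops(pair_table: np.ndarray, lo: int, hi: int) -> int:
    """Number of hairpin (terminal) loops closed by pairs within [lo, hi]."""
    n_loops = 0
    for i in range(lo, hi + 1):
        j = pair_table[i]
        if j > i and j <= hi:
            # terminal loop iff no paired base strictly inside (i, j)
            if not any(pair_table[k] >= 0 for k in range(i + 1, j)):
                n_loops += 1
    return n_loops


def is_hairpin(
    fold_result: FoldResult,
    mature_span: Tuple[int, int],
    min_paired_frac: float = MIN_MATURE_PAIRED_FRAC,
) -> Tuple[bool, HairpinReport]:
    """Decide whether the structure is a single stem-loop around the mature span.

    The mature span (0-based half-open) must be mostly paired, all its
    partners must sit on one side of it (a single opposite arm), and the
    region spanning mature and partners must close exactly one terminal
    loop (no multiloop separating mature from its pairing partner region).
    """
    a, b = mature_span
    pt = fold_result.pair_table
    if not (0 <= a < b <= len(pt)):
        raise ValueError(f"mature span {mature_span} outside sequence of length {len(pt)}")

    partners = [int(pt[i]) for i in range(a, b) if pt[i] >= 0]
    frac = len(partners) / (b - a)
    if not partners:
        report = HairpinReport(0.0, False, False, 0, False)
        return False, report

    one_side = min(partners) >= b or max(partners) < a
    lo = min(a, min(partners))
    hi = max(b - 1, max(partners))
    n_loops = _terminal_loops(pt, lo, hi)
    single_loop = n_loops == 1

    passes = frac >= min_paired_frac and one_side and single_loop
    return passes, HairpinReport(frac, one_side, single_loop, n_loops, passes)


def write_vienna(
    records: Iterable[Tuple[str, FoldResult]], path: str | Path
) -> None:
    """Vienna format: one header, sequence line, dot-bracket line per record."""
    with open(path, "w") as fh:
        for name, fr in records:
            fh.write(f">{name}\n{fr.sequence}\n{fr.dotbracket}\n")
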