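"""Small RNA read loading, collapsing and length filtering.

Raw small RNA-seq reads (assumed adapter-trimmed) are collapsed to unique
sequences with counts, normalized to an internal DNA alphabet (U -> T,
upper case), and filtered to the canonical plant miRNA length range of
20-24 nt.  Reads containing N are dropped, since downstream mapping is
exact-match only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Tuple

from Bio import SeqIO

logger = logging.getLogger(__name__)

MIRNA_MIN_LEN = 20
MIRNA_MAX_LEN = 24

_VALID_BASES = frozenset("ACGT")


class MalformedRecordError(ValueError):
    """Raised when an input record cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class SmallRNARead:
    """A collapsed unique read: DNA sequence, total raw count, stable id."""

    sequence: str
    count: int
    read_id: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"read count must be >= 1, got {self.count}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid bases {sorted(bad)} in read {self.read_id}")

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(seq: str) -> str:
    """Upper-fold and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def _parse_collapsed_header(header: str, line_no: int) -> Tuple[str, int]:
    # accepted dialects: ">id_count" and ">id x count"
    if " x " in header:
        name, _, count_s = header.rpartition(" x ")
    elif "_" in header:
        name, _, count_s = header.rpartition("_")
    else:
        raise MalformedRecordError(
            f"line {line_no}: collapsed-fasta header '{header}' carries no count "
            "(expected '>id_count' or '>id x count')"
        )
    try:
        count = int(count_s)
    except ValueError:
        raise MalformedRecordError(
            f"line {line_no}: cannot parse count from header '{header}'"
        ) from None
    if count < 1:
        raise MalformedRecordError(f"line {line_no}: count {count} < 1 in '{header}'")
    return name, count


def load_reads(path: str | Path, format: str = "fasta") -> List[SmallRNARead]:
    """Load reads and collapse them to unique sequences with summed counts.

    ``format`` is one of ``fastq``, ``fasta``, ``collapsed-fasta``.  In the
    collapsed dialect each header carries the raw read count (">id_count" or
    ">id x count").  U is normalized to T and case is upper-folded.  Reads
    containing N are dropped (exact-match mapping cannot place them); the
    number dropped is logged.  An empty file yields an empty list.
    """
    path = Path(path)
    if format not in ("fastq", "fasta", "collapsed-fasta"):
        raise ValueError(f"unknown format {format!r}")
    seqio_fmt = "fastq" if format == "fastq" else "fasta"

    if format == "collapsed-fasta":
        header_lines = _fasta_header_lines(path)

    counts: dict[str, int] = {}
    order: List[str] = []
    n_dropped = 0
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), seqio_fmt)):
            seq = normalize_sequence(str(rec.seq))
            if format == "collapsed-fasta":
                _, count = _parse_collapsed_header(rec.description, header_lines[i])
            else:
                count = 1
            if "N" in seq:
                n_dropped += count
                continue
            bad = set(seq) - _VALID_BASES
            if bad:
                line_no = header_lines[i] if format == "collapsed-fasta" else 4 * i + 1
                raise MalformedRecordError(
                    f"near line {line_no}: invalid characters {sorted(bad)} "
                    f"in record {rec.id!r}"
                )
            if seq not in counts:
                counts[seq] = 0
                order.append(seq)
            counts[seq] += count
    except MalformedRecordError:
        raise
    except ValueError as err:  # Biopython parse failure
        raise MalformedRecordError(f"{path}: malformed {seqio_fmt} record: {err}") from err

    if n_dropped:
        logger.info("dropped %d raw reads containing N from %s", n_dropped, path)
    return [
        SmallRNARead(sequence=seq, count=counts[seq], read_id=f"read{i + 1}")
        for i, seq in enumerate(order)
    ]


def _fasta_header_lines(path: Path) -> List[int]:
    lines = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                lines.append(i)
    return lines


def collapse(reads: Iterable[SmallRNARead]) -> List[SmallRNARead]:
    """Merge reads with identical sequences, summing counts (idempotent)."""
    counts: dict[str, int] = {}
    order: List[str] = []
    for r in reads:
        if r.sequence not in counts:
            counts[r.sequence] = 0
            order.append(r.sequence)
        counts[r.sequence] += r.count
    return [
        SmallRNARead(sequence=s, count=counts[s], read_id=f"read{i + 1}")
        for i, s in enumerate(order)
    ]


def filter_by_length(
    reads: Iterable[SmallRNARead],
    min_len: int = MIRNA_MIN_LEN,
    max_len: int = MIRNA_MAX_LEN,
) -> List[SmallRNARead]:
    """Keep reads within [min_len, max_len] nucleotides, preserving order."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in reads if min_len <= len(r) <= max_len]


def write_collapsed_fasta(reads: Iterable[SmallRNARead], path: str | Path) -> None:
    """Write reads in the ">id_count" collapsed-FASTA dialect."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}_{r.count}\n{r.sequence}\n")
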