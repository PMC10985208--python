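"""Candidate precursor excision around read clusters.

For each read cluster the most abundant read is taken as the putative
mature miRNA.  Windows of 100/150/200 nt are cut around it with three
anchorings — mature near the window 5' end (15-nt flank), centered, and
near the 3' end — because the mature can sit on either precursor arm.
Windows are transcribed (reverse-complemented for minus-strand clusters,
T -> U), folded, and reduced to at most one hairpin-forming candidate per
cluster: the window with the most paired mature bases (ties: shortest,
then leftmost).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .genome_mapping import GenomeIndex, LocusCluster, revcomp
from .rna_folding import FoldResult, fold, is_hairpin

logger = logging.getLogger(__name__)

WINDOW_LENGTHS = (100, 150, 200)
MIN_PRECURSOR_LEN = 100
MAX_PRECURSOR_LEN = 200
MATURE_FLANK = 15


@dataclass
class PrecursorCandidate:
    """A genomic window with transcribed sequence, structure and read stack.

    ``mapped_reads`` holds (offset, length, count, read_id) tuples in
    transcribed-strand coordinates; ``mature_span`` is the half-open span
    of the most abundant member read.
    """

    chrom: str
    strand: str
    start: int
    end: int
    sequence: str  # RNA, transcribed strand
    mapped_reads: List[Tuple[int, int, int, str]]
    mature_span: Tuple[int, int]
    cluster_id: str
    fold: Optional[FoldResult] = None
    label: str = "unlabeled"

    def __len__(self) -> int:
        return self.end - self.start


def _mature_locus(cluster: LocusCluster):
    # maximal count; ties resolved to the transcript-5'-most placement
    # (genomic leftmost on +, rightmost on -), keeping strands symmetric
    if cluster.strand == "+":
        return max(cluster.members, key=lambda l: (l.count, -l.start))
    return max(cluster.members, key=lambda l: (l.count, l.end))


def extract_candidates(
    index: GenomeIndex,
    cluster: LocusCluster,
    window_lengths: Sequence[int] = WINDOW_LENGTHS,
    flank: int = MATURE_FLANK,
) -> List[PrecursorCandidate]:
    """Excise candidate windows around the cluster's most abundant read.

    Windows are clipped to chromosome bounds and kept only if still at
    least 100 nt; an empty list (logged) results when no valid window
    exists near a contig end.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    chrom_seq = index.sequences[cluster.chrom]
    chrom_len = len(chrom_seq)
    mature = _mature_locus(cluster)
    mlen = mature.end - mature.start
    cluster_id = f"{cluster.chrom}:{cluster.start}-{cluster.end}({cluster.strand})"

    seen: set[Tuple[int, int]] = set()
    candidates: List[PrecursorCandidate] = []
    for W in sorted(window_lengths):
        # offsets of the mature read within the window, in transcribed coords
        offsets = (flank, (W - mlen) // 2, W - flank - mlen)
        for o in offsets:
            if cluster.strand == "+":
                w_start = mature.start - o
                w_end = w_start + W
            else:
                w_end = mature.end + o
                w_start = w_end - W
            w_start = max(0, w_start)
            w_end = min(chrom_len, w_end)
            if w_end - w_start < MIN_PRECURSOR_LEN:
                continue
            if not (w_start <= mature.start and mature.end <= w_end):
                continue
            if (w_start, w_end) in seen:
                continue
            seen.add((w_start, w_end))

            genomic = chrom_seq[w_start:w_end]
            if cluster.strand == "+":
                seq = genomic
                to_offset = lambda l: l.start - w_start  # noqa: E731
            else:
                seq = revcomp(genomic)
                to_offset = lambda l: w_end - l.end  # noqa: E731
            reads = [
                (to_offset(l), l.end - l.start, l.count, l.read_id)
                for l in cluster.members
                if w_start <= l.start and l.end <= w_end
            ]
            reads.sort()
            m_off = to_offset(mature)
            candidates.append(
                PrecursorCandidate(
                    chrom=cluster.chrom,
                    strand=cluster.strand,
                    start=w_start,
                    end=w_end,
                    sequence=seq.replace("T", "U"),
                    mapped_reads=reads,
                    mature_span=(m_off, m_off + mlen),
                    cluster_id=cluster_id,
                )
            )
    if not candidates:
        logger.info("cluster %s yielded no valid window", cluster_id)
    return candidates


def _mature_paired_bases(cand: PrecursorCandidate) -> int:
    a, b = cand.mature_span
    return int((cand.fold.pair_table[a:b] >= 0).sum())


def select_hairpin_candidates(
    candidates: Iterable[PrecursorCandidate],
    min_paired_frac: float = 0.6,
) -> List[PrecursorCandidate]:
    """Fold (if needed), keep hairpin-passing windows, and reduce to one
    candidate per cluster: most mature-span paired bases, ties to the
    shortest window, then the window placing the mature closest to the
    transcript 5' end (a strand-symmetric rule, so plus- and minus-strand
    plantings of one locus select the same window)."""
    per_cluster: Dict[str, List[PrecursorCandidate]] = {}
    order: List[str] = []
    for cand in candidates:
        if cand.fold is None:
            cand.fold = fold(cand.sequence)
        ok, _ = is_hairpin(cand.fold, cand.mature_span, min_paired_frac)
        if not ok:
            continue
        if cand.cluster_id not in per_cluster:
            per_cluster[cand.cluster_id] = []
            order.append(cand.cluster_id)
        per_cluster[cand.cluster_id].append(cand)

    survivors: List[PrecursorCandidate] = []
    for cid in order:
        best = max(
            per_cluster[cid],
            key=lambda c: (
                _mature_paired_bases(c),
                -len(c),
                -c.mature_span[0],
                -c.start,
            ),
        )
        survivors.append(best)
    return survivors


def write_candidate_table(
    candidates: Iterable[PrecursorCandidate], path: str | Path
) -> None:
    """TSV of candidate windows with structure, mature span and read stack."""
    cols = (
        "chrom\tstart\tend\tstrand\tlabel\tmature_start\tmature_end"
        "\tsequence\tdotbracket\treads\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for c in candidates:
            reads = ";".join(
                f"{rid}:{off}:{length}:{count}" for off, length, count, rid in c.mapped_reads
            )
            db = c.fold.dotbracket if c.fold is not None else ""
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{c.label}"
                f"\t{c.mature_span[0]}\t{c.mature_span[1]}\t{c.sequence}\t{db}\t{reads}\n"
            )


def write_candidate_fasta(
    candidates: Iterable[PrecursorCandidate], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.chrom}:{c.start}-{c.end}({c.strand})\n{c.sequence}\n")
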