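"""Exact-match read mapping against both genome strands, and locus clustering.

Mature miRNA reads are genome-templated, so exact full-length matching
suffices for precursor discovery and avoids an external aligner.  A simple
k-mer seed index (default k=12) anchors candidate sites; each seed hit is
verified by full-length string comparison.  Mapped loci are then clustered
per chromosome and strand with a gap threshold chosen so that the mature
and star reads of one precursor (at most ~200 nt apart) always co-cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from Bio import SeqIO

from .read_processing import SmallRNARead

logger = logging.getLogger(__name__)

DEFAULT_SEED_K = 12
DEFAULT_MAX_GAP = 100
DEFAULT_MAX_HITS = 20

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeIndex:
    """Chromosome sequences plus a k-mer position index."""

    sequences: Dict[str, str]
    k: int
    kmer_index: Dict[str, List[Tuple[str, int]]] = field(repr=False)

    def lookup(self, kmer: str) -> List[Tuple[str, int]]:
        return self.kmer_index.get(kmer, [])


@dataclass(frozen=True)
class MappedLocus:
    """One exact placement of a read (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    read_id: str
    count: int


@dataclass
class LocusCluster:
    chrom: str
    strand: str
    start: int
    end: int
    members: List[MappedLocus]


def build_index(genome: str | Path | Mapping[str, str], k: int = DEFAULT_SEED_K) -> GenomeIndex:
    """Index every k-mer position of a genome (FASTA path or name->sequence map)."""
    if isinstance(genome, (str, Path)):
        sequences: Dict[str, str] = {}
        for rec in SeqIO.parse(str(genome), "fasta"):
            if rec.id in sequences:
                raise ValueError(f"duplicate chromosome name {rec.id!r}")
            sequences[rec.id] = str(rec.seq).upper()
    else:
        sequences = {name: seq.upper() for name, seq in genome.items()}
    if not sequences:
        raise ValueError("genome contains no sequences")
    shortest = min(len(s) for s in sequences.values())
    if not 1 <= k <= shortest:
        raise ValueError(f"k={k} must be within [1, {shortest}] (shortest chromosome)")

    index: Dict[str, List[Tuple[str, int]]] = {}
    for chrom, seq in sequences.items():
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((chrom, pos))
    return GenomeIndex(sequences=sequences, k=k, kmer_index=index)


def map_read(index: GenomeIndex, read: SmallRNARead) -> List[MappedLocus]:
    """All exact full-length placements of a read on either strand.

    Results are sorted by (chrom, start, strand).  An unmapped read gives
    an empty list.
    """
    seq = read.sequence
    if len(seq) < index.k:
        raise ValueError(f"read {read.read_id} shorter than seed length k={index.k}")
    hits: List[MappedLocus] = []
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        for chrom, pos in index.lookup(query[: index.k]):
            end = pos + len(query)
            if index.sequences[chrom][pos:end] == query:
                hits.append(
                    MappedLocus(chrom, pos, end, strand, read.read_id, read.count)
                )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def map_reads(
    index: GenomeIndex,
    reads: Iterable[SmallRNARead],
    max_hits: int = DEFAULT_MAX_HITS,
) -> List[MappedLocus]:
    """Map a read set; reads with more than max_hits placements are dropped
    as repeat-derived (logged)."""
    loci: List[MappedLocus] = []
    n_repeat = 0
    for read in reads:
        hits = map_read(index, read)
        if len(hits) > max_hits:
            n_repeat += 1
            continue
        loci.extend(hits)
    if n_repeat:
        logger.info("dropped %d reads with > %d genomic placements", n_repeat, max_hits)
    return loci


def cluster_loci(
    loci: Sequence[MappedLocus], max_gap: int = DEFAULT_MAX_GAP
) -> List[LocusCluster]:
    """Transitively merge same-chromosome, same-strand loci whose spans are
    within max_gap nt of each other.  Every locus lands in exactly one cluster."""
    by_group: Dict[Tuple[str, str], List[MappedLocus]] = {}
    for locus in loci:
        by_group.setdefault((locus.chrom, locus.strand), []).append(locus)

    clusters: List[LocusCluster] = []
    for (chrom, strand), group in sorted(by_group.items()):
        group.sort(key=lambda l: (l.start, l.end))
        current: List[MappedLocus] = []
        cur_end = -1
        for locus in group:
            if current and locus.start - cur_end > max_gap:
                clusters.append(
                    LocusCluster(chrom, strand, current[0].start, cur_end, current)
                )
                current = []
            current.append(locus)
            cur_end = max(cur_end, locus.end)
        if current:
            clusters.append(
                LocusCluster(chrom, strand, current[0].start, cur_end, current)
            )
    return clusters


def write_bed(loci: Iterable[MappedLocus | LocusCluster], path: str | Path) -> None:
    """BED6 output for mapped loci or clusters."""
    with open(path, "w") as fh:
        for i, item in enumerate(loci):
            if isinstance(item, LocusCluster):
                name, score = f"cluster{i + 1}", len(item.members)
            else:
                name, score = item.read_id, item.count
            fh.write(
                f"{item.chrom}\t{item.start}\t{item.end}\t{name}\t{score}\t{item.strand}\n"
            )
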