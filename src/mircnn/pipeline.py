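"""End-to-end orchestration: reads + genome -> labeled, encoded candidates.

Chains the stages in pipeline order: length filter, exact mapping, locus
clustering, window extraction, hairpin selection, rule-based duplex
labeling, and matrix encoding.  Helpers at the bottom match candidates
back to a simulator truth set for supervised training and for measuring
per-locus recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import annotation, encoding, genome_mapping, precursor_extraction, read_processing
from .encoding import EncodedMatrix
from .precursor_extraction import PrecursorCandidate
from .read_processing import SmallRNARead
from .synthetic_data import TruthRecord


@dataclass
class PipelineResult:
    candidates: List[PrecursorCandidate]  # one per cluster, hairpin-passing, labeled
    matrices: List[EncodedMatrix]
    n_reads_after_filter: int
    n_clusters: int


def run_pipeline(
    genome: Mapping[str, str] | str,
    reads: Sequence[SmallRNARead],
    k: int = genome_mapping.DEFAULT_SEED_K,
    max_hits: int = genome_mapping.DEFAULT_MAX_HITS,
    max_gap: int = genome_mapping.DEFAULT_MAX_GAP,
    window_lengths: Sequence[int] = precursor_extraction.WINDOW_LENGTHS,
    L: int = encoding.DEFAULT_WIDTH,
) -> PipelineResult:
    """Run the discovery pipeline and return labeled encoded candidates."""
    reads = read_processing.filter_by_length(reads)
    index = genome_mapping.build_index(genome, k=k)
    loci = genome_mapping.map_reads(index, reads, max_hits=max_hits)
    clusters = genome_mapping.cluster_loci(loci, max_gap=max_gap)

    all_candidates: List[PrecursorCandidate] = []
    for cluster in clusters:
        all_candidates.extend(
            precursor_extraction.extract_candidates(index, cluster, window_lengths)
        )
    survivors = precursor_extraction.select_hairpin_candidates(all_candidates)
    for cand in survivors:
        annotation.label_candidate(cand)
    matrices = [encoding.encode_precursor(c, L=L) for c in survivors]
    return PipelineResult(
        candidates=survivors,
        matrices=matrices,
        n_reads_after_filter=len(reads),
        n_clusters=len(clusters),
    )


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def assign_truth_labels(
    candidates: Sequence[PrecursorCandidate],
    truth: Sequence[TruthRecord],
    min_overlap: int = 20,
) -> List[Optional[str]]:
    """Truth kind ("miRNA"/"other") per candidate by maximal genomic overlap
    with a planted locus (strand-agnostic: inverted repeats legitimately
    produce mirror candidates on the opposite strand); None when the
    candidate overlaps no planted locus."""
    by_chrom: Dict[str, List[TruthRecord]] = {}
    for t in truth:
        by_chrom.setdefault(t.chrom, []).append(t)
    labels: List[Optional[str]] = []
    for cand in candidates:
        best, best_ov = None, min_overlap - 1
        for t in by_chrom.get(cand.chrom, []):
            ov = _overlap(cand.start, cand.end, t.start, t.end)
            if ov > best_ov:
                best, best_ov = t, ov
        labels.append(best.kind if best is not None else None)
    return labels


def labeled_matrices(
    result: PipelineResult,
    truth: Sequence[TruthRecord],
) -> List[EncodedMatrix]:
    """Encoded matrices with supervised labels taken from the truth set;
    candidates outside any planted locus are dropped."""
    kinds = assign_truth_labels(result.candidates, truth)
    out: List[EncodedMatrix] = []
    for matrix, kind in zip(result.matrices, kinds):
        if kind is None:
            continue
        matrix.label = 1 if kind == "miRNA" else 0
        out.append(matrix)
    return out


@dataclass
class RecoveryReport:
    n_mirna_loci: int
    n_sirna_loci: int
    n_mirna_recovered: int  # miRNA loci with a surviving candidate
    n_mirna_labeled_mirna: int  # ... additionally rule-labeled miRNA
    n_sirna_labeled_mirna: int  # siRNA loci with any candidate labeled miRNA

    @property
    def recovery_rate(self) -> float:
        return self.n_mirna_recovered / self.n_mirna_loci

    @property
    def mirna_label_rate(self) -> float:
        return self.n_mirna_labeled_mirna / self.n_mirna_loci

    @property
    def sirna_mislabel_rate(self) -> float:
        return self.n_sirna_labeled_mirna / self.n_sirna_loci


def locus_recovery(
    candidates: Sequence[PrecursorCandidate],
    truth: Sequence[TruthRecord],
    min_overlap: int = 20,
) -> RecoveryReport:
    """Per planted locus: was it recovered as a surviving candidate, and did
    the annotation rules call it miRNA."""
    recovered: Dict[str, bool] = {t.locus_id: False for t in truth}
    labeled: Dict[str, bool] = {t.locus_id: False for t in truth}
    for cand in candidates:
        for t in truth:
            if t.chrom != cand.chrom:
                continue
            if _overlap(cand.start, cand.end, t.start, t.end) >= min_overlap:
                recovered[t.locus_id] = True
                if cand.label == "miRNA":
                    labeled[t.locus_id] = True
    mirna = [t for t in truth if t.kind == "miRNA"]
    sirna = [t for t in truth if t.kind != "miRNA"]
    return RecoveryReport(
        n_mirna_loci=len(mirna),
        n_sirna_loci=len(sirna),
        n_mirna_recovered=sum(recovered[t.locus_id] for t in mirna),
        n_mirna_labeled_mirna=sum(labeled[t.locus_id] for t in mirna),
        n_sirna_labeled_mirna=sum(labeled[t.locus_id] for t in sirna),
    )
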