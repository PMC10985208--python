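"""Rule-based miRNA annotation of hairpin candidates.

Implements the community duplex criteria for plant miRNA annotation: the
miRNA/miRNA* duplex may carry at most five mismatched positions, of which
at most three nucleotides sit in asymmetric bulges, and must contain no
secondary stem or large loop.  A read-precision rule (mature + star reads
holding at least 75% of the locus read count) stands in for the precise-
processing requirement.  These labels provide CNN training truth on data
without curated annotation and serve as a network-free baseline.

``match_known`` scores a candidate mature sequence against a reference
set of known mature miRNAs by ungapped identity; more than 18 identical
aligned bases marks the candidate as a known miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .precursor_extraction import PrecursorCandidate
from .rna_folding import FoldResult

MAX_DUPLEX_MISMATCH = 5
MAX_ASYM_BULGE_NT = 3
MAX_INTERNAL_LOOP = 5  # an unpaired stretch longer than this is a "large loop"
STAR_OVERHANG = 2
MIN_DUPLEX_READ_FRACTION = 0.75
READ_SPAN_PAD = 3
KNOWN_MIRNA_MIN_MATCHES = 18  # "known" requires strictly more matches


@dataclass
class DuplexReport:
    """Bookkeeping of the miRNA/miRNA* duplex criteria."""

    star_span: Optional[Tuple[int, int]]
    n_mismatch: int
    n_asym_bulge_nt: int
    has_secondary_stem: bool
    has_large_loop: bool
    passes: bool


def locate_star(
    fold_result: FoldResult, mature_span: Tuple[int, int]
) -> Optional[Tuple[int, int]]:
    """Span of the miRNA* on the opposite arm, with the 2-nt 3' overhang.

    The star span is the mirror of the mature's pairing partners shifted
    by the canonical Dicer 2-nt 3' overhang.  Returns None when fewer than
    half the mature bases have partners.
    """
    a, b = mature_span
    pt = fold_result.pair_table
    partners = [int(pt[i]) for i in range(a, b) if pt[i] >= 0]
    if len(partners) < (b - a) / 2:
        return None
    lo, hi = min(partners), max(partners)
    star = (lo + STAR_OVERHANG, hi + STAR_OVERHANG + 1)
    return (max(0, star[0]), min(len(pt), star[1]))


def evaluate_duplex(
    fold_result: FoldResult,
    mature_span: Tuple[int, int],
    star_span: Tuple[int, int],
    max_mismatch: int = MAX_DUPLEX_MISMATCH,
    max_asym_bulge_nt: int = MAX_ASYM_BULGE_NT,
    max_internal_loop: int = MAX_INTERNAL_LOOP,
) -> DuplexReport:
    """Score the mature/star duplex against the annotation criteria.

    ``star_span`` follows the Dicer-product convention of ``locate_star``
    (shifted by the 2-nt 3' overhang); the pairing bookkeeping undoes the
    shift, so a perfect inverted-repeat duplex scores zero mismatches.
    Mismatches are mature positions that are unpaired or paired outside
    the star's pairing window.  Internal loops are read off consecutive
    paired mature positions: a mature-side stretch longer than its
    opposite stretch is an asymmetric bulge and its nucleotides count
    toward the bulge budget; any stretch longer than
    ``max_internal_loop`` on either side is a large loop.
    """
    a, b = mature_span
    sa, sb = star_span
    pt = fold_result.pair_table
    # pairing window of the star: the mirror of the mature's partners
    pa, pb = sa - STAR_OVERHANG, sb - STAR_OVERHANG

    in_star = [i for i in range(a, b) if pt[i] >= 0 and pa <= pt[i] < pb]
    n_mismatch = (b - a) - len(in_star)

    # secondary stem: a duplex base pairing away from its expected arm
    secondary = any(pt[i] >= 0 and not (pa <= pt[i] < pb) for i in range(a, b))
    pad = STAR_OVERHANG
    secondary = secondary or any(
        pt[j] >= 0 and not (a - pad <= pt[j] < b + pad)
        for j in range(max(0, pa), min(len(pt), pb))
    )

    n_asym = 0
    large_loop = False
    for i1, i2 in zip(in_star, in_star[1:]):
        g_mature = i2 - i1 - 1
        g_star = abs(int(pt[i1]) - int(pt[i2])) - 1
        if g_mature > g_star:
            n_asym += g_mature
        if max(g_mature, g_star) > max_internal_loop:
            large_loop = True

    passes = (
        n_mismatch <= max_mismatch
        and n_asym <= max_asym_bulge_nt
        and not secondary
        and not large_loop
    )
    return DuplexReport(
        star_span=(sa, sb),
        n_mismatch=n_mismatch,
        n_asym_bulge_nt=n_asym,
        has_secondary_stem=secondary,
        has_large_loop=large_loop,
        passes=passes,
    )


def duplex_read_fraction(
    candidate: PrecursorCandidate,
    star_span: Tuple[int, int],
    pad: int = READ_SPAN_PAD,
) -> float:
    """Fraction of the candidate's read count inside the padded mature or
    star spans (a precise-processing signature)."""
    total = sum(count for _, _, count, _ in candidate.mapped_reads)
    if total == 0:
        return 0.0
    spans = [candidate.mature_span, star_span]
    in_duplex = 0
    for off, length, count, _ in candidate.mapped_reads:
        for lo, hi in spans:
            if lo - pad <= off and off + length <= hi + pad:
                in_duplex += count
                break
    return in_duplex / total


def label_candidate(
    candidate: PrecursorCandidate,
    min_read_fraction: float = MIN_DUPLEX_READ_FRACTION,
) -> str:
    """Label a hairpin candidate "miRNA" or "other".

    miRNA requires a passing mature/star duplex and at least
    ``min_read_fraction`` of the locus read count within the padded
    mature/star spans.  The label is stored on the candidate and returned.
    """
    if candidate.fold is None:
        raise ValueError("candidate must be folded before labeling")
    star = locate_star(candidate.fold, candidate.mature_span)
    label = "other"
    if star is not None:
        report = evaluate_duplex(candidate.fold, candidate.mature_span, star)
        if report.passes and duplex_read_fraction(candidate, star) >= min_read_fraction:
            label = "miRNA"
    candidate.label = label
    return label


def _identity_at_offsets(query: str, ref: str) -> int:
    best = 0
    for shift in range(-(len(ref) - 1), len(query)):
        n_id = 0
        for qi in range(max(0, shift), min(len(query), shift + len(ref))):
            if query[qi] == ref[qi - shift]:
                n_id += 1
        if n_id > best:
            best = n_id
    return best


def match_known(
    query: str, reference: Sequence[str] | Iterable[str]
) -> Tuple[int, bool]:
    """Best ungapped identity of a query against known mature miRNAs.

    Returns (best_identity, is_known) where is_known requires strictly
    more than 18 identical aligned bases.  Sequences are compared as
    given (no reverse complement); U/T differences are normalized away.
    """
    refs = [r.upper().replace("U", "T") for r in reference]
    if not refs:
        raise ValueError("reference set is empty")
    q = query.upper().replace("U", "T")
    best = max(_identity_at_offsets(q, r) for r in refs)
    return best, best > KNOWN_MIRNA_MIN_MATCHES


def write_labeled_table(
    candidates: Sequence[PrecursorCandidate], path
) -> None:
    """TSV with label and duplex-report columns appended."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tstrand\tlabel\tstar_start\tstar_end"
            "\tn_mismatch\tn_asym_bulge_nt\tsecondary_stem\tlarge_loop\n"
        )
        for c in candidates:
            star = locate_star(c.fold, c.mature_span) if c.fold is not None else None
            if star is None:
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{c.label}"
                    "\t.\t.\t.\t.\t.\t.\n"
                )
                continue
            r = evaluate_duplex(c.fold, c.mature_span, star)
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{c.label}"
                f"\t{star[0]}\t{star[1]}\t{r.n_mismatch}\t{r.n_asym_bulge_nt}"
                f"\t{int(r.has_secondary_stem)}\t{int(r.has_large_loop)}\n"
            )
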