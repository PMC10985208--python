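"""Seeded simulator of toy genomes with planted miRNA and siRNA-like loci.

miRNA loci are fold-back precursors: a lower stem, the mature/miRNA*
duplex with a controlled number of mismatches and asymmetric bulges, a
short upper stem and a terminal loop.  Their read stacks show precise
processing — two sharp stacks with homogeneous 5' ends at the mature and
star, the mature dominating.  siRNA-like loci are the hard negatives:
near-perfect inverted repeats (they fold into hairpins just as well) but
with reads dispersed across both arms at heterogeneous positions.

All designed-unpaired elements (terminal loop, mismatched positions,
bulged nucleotides, tails) are adenosine runs and the short upper stem
between duplex and loop is G/C-only.  Under the AU/GC/GU pair set an A
can then pair with nothing nearby — not with another designed-unpaired
A, not with the G/C upper stem — so the base-pair-maximizing folder has
no equal-score alternative structure around the terminal loop and
recovers the designed stem-loop; this is what lets the generator promise
that its miRNA loci satisfy the annotation criteria by construction.

Everything derives from one seed; identical specs give byte-identical
FASTA/FASTQ/BED output.  The default class ratio is three negatives per
positive, matching the imbalance typical of hairpin-forming loci in real
small RNA-seq training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .genome_mapping import revcomp
from .read_processing import SmallRNARead

_BASES = "ACGT"
_GC = "GC"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
STAR_OVERHANG = 2


@dataclass
class SimulationSpec:
    """Study conditions for the simulator (ranges are inclusive)."""

    n_mirna_loci: int = 20
    n_sirna_loci: int = 60
    mature_len_range: Tuple[int, int] = (20, 24)
    duplex_mismatches: Tuple[int, int] = (0, 4)
    asym_bulge_nt: Tuple[int, int] = (0, 2)
    loop_len_range: Tuple[int, int] = (4, 15)
    precursor_len_range: Tuple[int, int] = (100, 200)
    mirna_read_precision: float = 0.9
    sirna_phase_jitter: int = 3
    depth_range: Tuple[int, int] = (30, 120)
    spacer_len: int = 150
    sequencing_error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (20 <= self.mature_len_range[0] <= self.mature_len_range[1] <= 24):
            raise ValueError("mature_len_range must lie within [20, 24]")
        if not (0 <= self.duplex_mismatches[0] <= self.duplex_mismatches[1] <= 5):
            raise ValueError("duplex_mismatches must lie within [0, 5]")
        if not (0 <= self.asym_bulge_nt[0] <= self.asym_bulge_nt[1] <= 3):
            raise ValueError("asym_bulge_nt must lie within [0, 3]")
        if not (4 <= self.loop_len_range[0] <= self.loop_len_range[1] <= 15):
            raise ValueError("loop_len_range must lie within [4, 15]")
        lo, hi = self.precursor_len_range
        if not (100 <= lo <= hi <= 200):
            raise ValueError("precursor_len_range must lie within [100, 200]")
        if not 0.0 <= self.mirna_read_precision <= 1.0:
            raise ValueError("mirna_read_precision must be in [0, 1]")
        if self.spacer_len <= 100:
            raise ValueError("spacer_len must exceed the clustering gap (100)")
        if self.sirna_phase_jitter == 0:
            warnings.warn(
                "sirna_phase_jitter=0: degenerate siRNA loci with few reads "
                "drift toward miRNA-like read stacks"
            )


@dataclass
class MirnaLocus:
    sequence: str  # DNA, transcribed orientation
    mature_span: Tuple[int, int]
    star_span: Tuple[int, int]  # Dicer-product convention (2-nt 3' overhang)
    reads: List[Tuple[int, int, int]]  # (offset, length, count)
    n_mismatch: int
    n_asym_bulge_nt: int
    kind: str = "miRNA"


@dataclass
class SirnaLocus:
    sequence: str
    reads: List[Tuple[int, int, int]]
    kind: str = "other"


@dataclass
class TruthRecord:
    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    mature_start: int  # genomic; -1 for siRNA loci
    mature_end: int
    locus_id: str


@dataclass
class SyntheticDataset:
    genome: Dict[str, str]
    reads: List[SmallRNARead]
    truth: List[TruthRecord]
    spec: SimulationSpec
    raw_records: List[Tuple[str, str]] = field(repr=False, default_factory=list)

    def write(self, out_dir: str | Path) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "reads": out / "reads.fq",
            "truth": out / "truth.bed",
        }
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        with open(paths["reads"], "w") as fh:
            for rid, seq in self.raw_records:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        with open(paths["truth"], "w") as fh:
            for t in self.truth:
                thick_s = t.mature_start if t.mature_start >= 0 else t.start
                thick_e = t.mature_end if t.mature_end >= 0 else t.start
                fh.write(
                    f"{t.chrom}\t{t.start}\t{t.end}\t{t.locus_id}|{t.kind}\t0"
                    f"\t{t.strand}\t{thick_s}\t{thick_e}\n"
                )
        return paths


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = _BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _nonpairing(rng: np.random.Generator, n: int = 1) -> str:
    # adenosine runs: inert under AU/GC/GU pairing next to a G/C upper stem
    return "A" * n


def generate_mirna_locus(rng: np.random.Generator, spec: SimulationSpec) -> MirnaLocus:
    """One fold-back miRNA locus with its truth spans and read stack.

    The mature sits on the 5' or 3' arm at random.  Mismatched duplex
    positions become symmetric 1-nt internal loops; bulged nucleotides
    form one mature-side asymmetric bulge.  The most abundant read is the
    mature; the star stack is lower; a spec-controlled fraction of reads
    have jittered 5' ends.
    """
    spec.validate()
    M = int(rng.integers(spec.mature_len_range[0], spec.mature_len_range[1] + 1))
    n_mm = int(rng.integers(spec.duplex_mismatches[0], spec.duplex_mismatches[1] + 1))
    n_asym = int(rng.integers(spec.asym_bulge_nt[0], spec.asym_bulge_nt[1] + 1))
    n_asym = min(n_asym, n_mm, 3)
    n_sym = n_mm - n_asym
    if n_mm > M - 10:
        raise ValueError(f"{n_mm} mismatches infeasible for a {M}-nt mature")

    mature = list(_rand_seq(rng, M))

    # place the asymmetric bulge run and the symmetric mismatch positions
    # in the mature interior, pairwise non-adjacent
    interior = list(range(3, M - 4))
    asym_run: List[int] = []
    if n_asym:
        start = int(rng.integers(3, M - 4 - n_asym))
        asym_run = list(range(start, start + n_asym))
    blocked = set(asym_run) | {asym_run[0] - 1 if asym_run else -9} | {
        asym_run[-1] + 1 if asym_run else -9
    }
    free = [i for i in interior if i not in blocked]
    rng.shuffle(free)
    sym_pos: List[int] = []
    for i in free:
        if len(sym_pos) == n_sym:
            break
        if all(abs(i - j) >= 2 for j in sym_pos):
            sym_pos.append(i)
    n_sym = len(sym_pos)

    # build the arm opposite the mature (antiparallel): for mature position
    # i the partner base is appended in reverse order; bulged positions get
    # no partner, mismatched positions get a non-pairing base on both sides.
    # Neighbors of designed-unpaired positions are forced to G/C so the
    # folder cannot shift the pairing register into the mismatch column
    # (an A/U neighbor would offer an equal-score alternative pairing).
    unpaired = set(sym_pos) | set(asym_run)
    for i in sym_pos + asym_run:
        mature[i] = _nonpairing(rng)
        for q in (i - 1, i + 1):
            if 0 <= q < M and q not in unpaired and mature[q] in "AT":
                mature[q] = _GC[int(rng.integers(0, 2))]
    opp: List[str] = []
    for i in range(M - 1, -1, -1):
        if i in asym_run:
            continue
        if i in sym_pos:
            opp.append(_nonpairing(rng))
        else:
            opp.append(_COMP[mature[i]])
    mature_s = "".join(mature)
    opp_s = "".join(opp)

    u = int(rng.integers(3, 9))
    upper5 = _rand_seq(rng, u, _GC)
    upper3 = revcomp(upper5)
    loop = _nonpairing(rng, int(rng.integers(spec.loop_len_range[0], spec.loop_len_range[1] + 1)))

    P = int(rng.integers(spec.precursor_len_range[0], spec.precursor_len_range[1] + 1))
    core = len(mature_s) + len(opp_s) + 2 * u + len(loop)
    low_total = max(4, P - core)
    low5_len = low_total // 2
    low5 = _rand_seq(rng, low5_len)
    tail = _nonpairing(rng, low_total - 2 * low5_len)

    on_5p_arm = bool(rng.integers(0, 2))
    if on_5p_arm:
        seq = low5 + mature_s + upper5 + loop + upper3 + opp_s + revcomp(low5) + tail
        m0 = low5_len
        opp0 = low5_len + M + u + len(loop) + u
    else:
        seq = low5 + opp_s + upper5 + loop + upper3 + mature_s + revcomp(low5) + tail
        opp0 = low5_len
        m0 = low5_len + len(opp_s) + u + len(loop) + u
    mature_span = (m0, m0 + M)
    lo, hi = opp0, opp0 + len(opp_s) - 1
    star_span = (lo + STAR_OVERHANG, hi + STAR_OVERHANG + 1)

    reads = _mirna_reads(rng, spec, seq, mature_span, star_span)
    return MirnaLocus(seq, mature_span, star_span, reads, n_mm, n_asym)


def _mirna_reads(rng, spec, seq, mature_span, star_span):
    D = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
    prec = spec.mirna_read_precision
    c_mature = max(2, round(0.8 * prec * D))
    c_star = max(1, round(0.2 * prec * D))
    m0, m1 = mature_span
    s0 = star_span[0]
    s_len = int(np.clip(star_span[1] - star_span[0], 20, 24))
    s_len = min(s_len, len(seq) - s0)
    reads: Dict[Tuple[int, int], int] = {}
    reads[(m0, m1 - m0)] = c_mature
    reads[(s0, s_len)] = reads.get((s0, s_len), 0) + c_star

    n_jitter = round((1 - prec) * D)
    while n_jitter > 0:
        base = m0 if rng.random() < 0.7 else s0
        length = m1 - m0 if base == m0 else s_len
        shift = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
        off = int(np.clip(base + shift, 0, len(seq) - length))
        if off == base:
            off = base + 1
        c = min(n_jitter, int(rng.integers(1, 4)))
        key = (off, length)
        reads[key] = reads.get(key, 0) + c
        n_jitter -= c
    return [(off, length, count) for (off, length), count in sorted(reads.items())]


def generate_sirna_locus(rng: np.random.Generator, spec: SimulationSpec) -> SirnaLocus:
    """One siRNA-like hard negative: a hairpin-forming inverted repeat with
    dispersed, 5'-heterogeneous reads on both arms."""
    spec.validate()
    P = int(rng.integers(spec.precursor_len_range[0], spec.precursor_len_range[1] + 1))
    loop = _nonpairing(rng, int(rng.integers(spec.loop_len_range[0], spec.loop_len_range[1] + 1)))
    arm_len = (P - len(loop)) // 2
    arm = list(_rand_seq(rng, arm_len))
    right = list(revcomp("".join(arm)))
    # symmetric imperfection columns spaced so that every >= 20-nt read
    # crosses at least one: real siRNA fold-backs are imperfect, and the
    # imperfections keep arm reads from exact-mapping back onto the
    # opposite strand as spurious miRNA-like single-read loci
    n_imp = max(2, -(-arm_len // 12))
    for t in range(n_imp):
        i = round((t + 0.5) * arm_len / n_imp) + int(rng.integers(-3, 4))
        i = int(np.clip(i, 2, arm_len - 3))
        arm[i] = _nonpairing(rng)
        right[arm_len - 1 - i] = _nonpairing(rng)
        for q in (i - 1, i + 1):
            if arm[q] in "AT":
                arm[q] = _GC[int(rng.integers(0, 2))]
                right[arm_len - 1 - q] = _COMP[arm[q]]
    seq = "".join(arm) + loop + "".join(right)
    seq += _nonpairing(rng, P - len(seq))

    D = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
    k = int(rng.integers(8, 17))
    w = rng.gamma(2.0, size=k)
    w = w / w.sum()
    reads: Dict[Tuple[int, int], int] = {}
    for t in range(k):
        length = int(rng.integers(20, 25))
        off = int(rng.integers(0, len(seq) - length + 1))
        if spec.sirna_phase_jitter:
            off += int(rng.integers(-spec.sirna_phase_jitter, spec.sirna_phase_jitter + 1))
            off = int(np.clip(off, 0, len(seq) - length))
        count = max(1, round(w[t] * D))
        key = (off, length)
        reads[key] = reads.get(key, 0) + count
    return SirnaLocus(seq, [(o, l, c) for (o, l), c in sorted(reads.items())])


def generate_dataset(
    spec: SimulationSpec, out_dir: Optional[str | Path] = None
) -> SyntheticDataset:
    """Assemble loci into chromosomes with spacers, realize reads, and
    (optionally) write genome FASTA, reads FASTQ and truth BED."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    loci: List[MirnaLocus | SirnaLocus] = [
        generate_mirna_locus(rng, spec) for _ in range(spec.n_mirna_loci)
    ] + [generate_sirna_locus(rng, spec) for _ in range(spec.n_sirna_loci)]
    order = rng.permutation(len(loci))

    per_chrom = 200  # keep chromosomes (and the k-mer index) modest
    chrom_parts: List[str] = []
    chroms: Dict[str, str] = {}
    truth: List[TruthRecord] = []
    raw_records: List[Tuple[str, str]] = []
    counts: Dict[str, int] = {}
    chrom_i = 1
    pos = 0

    def flush_chrom():
        nonlocal chrom_parts, chrom_i, pos
        if chrom_parts:
            chroms[f"chr{chrom_i}"] = "".join(chrom_parts)
            chrom_parts = []
            chrom_i += 1
            pos = 0

    for n_done, li in enumerate(order):
        locus = loci[li]
        chrom = f"chr{chrom_i}"
        spacer = _rand_seq(rng, spec.spacer_len + int(rng.integers(0, 51)))
        chrom_parts.append(spacer)
        pos += len(spacer)

        strand = "+" if rng.random() < 0.5 else "-"
        segment = locus.sequence if strand == "+" else revcomp(locus.sequence)
        start = pos
        end = pos + len(segment)
        chrom_parts.append(segment)
        pos = end

        if isinstance(locus, MirnaLocus):
            if strand == "+":
                ms, me = start + locus.mature_span[0], start + locus.mature_span[1]
            else:
                ms = end - locus.mature_span[1]
                me = end - locus.mature_span[0]
        else:
            ms = me = -1
        locus_id = f"{locus.kind.lower()}_{n_done + 1}"
        truth.append(TruthRecord(chrom, start, end, strand, locus.kind, ms, me, locus_id))

        for r_i, (off, length, count) in enumerate(locus.reads):
            rseq = locus.sequence[off : off + length]
            if spec.sequencing_error_rate > 0.0:
                rseq = _with_errors(rng, rseq, spec.sequencing_error_rate)
            counts[rseq] = counts.get(rseq, 0) + count
            for dup in range(count):
                raw_records.append((f"{locus_id}_r{r_i + 1}_d{dup + 1}", rseq))

        if (n_done + 1) % per_chrom == 0:
            flush_chrom()
    chrom_parts.append(_rand_seq(rng, spec.spacer_len))
    flush_chrom()

    reads = [
        SmallRNARead(sequence=s, count=c, read_id=f"read{i + 1}")
        for i, (s, c) in enumerate(sorted(counts.items()))
    ]
    dataset = SyntheticDataset(chroms, reads, truth, spec, raw_records)
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset


def _with_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _BASES[int(rng.integers(0, 4))]
    return "".join(out)
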