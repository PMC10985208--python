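import numpy as np
import pytest

import mircnn as m
from mircnn.annotation import (
    duplex_read_fraction,
    evaluate_duplex,
    label_candidate,
    locate_star,
    match_known,
)
from mircnn.genome_mapping import revcomp
from mircnn.rna_folding import fold

from conftest import candidate_from_locus

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def build_hairpin(mature, sym_pos=(), asym_run=(), low=12, upper="GCGCG", loop="AAAAA"):
    """Deterministic duplex construction: mature on the 5' arm, designed
    mismatches as 'A' columns (callers place them between G/C neighbors).
    Returns (sequence, mature_span, designed_star_span)."""
    mature = list(mature)
    unpaired = set(sym_pos) | set(asym_run)
    for i in unpaired:
        mature[i] = "A"
    opp = []
    for i in range(len(mature) - 1, -1, -1):
        if i in asym_run:
            continue
        opp.append("A" if i in sym_pos else _COMP[mature[i]])
    low5 = ("GACT" * 10)[:low]
    seq = (
        low5 + "".join(mature) + upper + loop + revcomp(upper)
        + "".join(opp) + revcomp(low5)
    )
    m0 = low
    opp0 = low + len(mature) + 2 * len(upper) + len(loop)
    star = (opp0 + 2, opp0 + len(opp) + 2)
    return seq, (m0, m0 + len(mature)), star


class TestLocateStar:
    def test_perfect_duplex_star_offset_by_overhang(self):
        mature = "GC" * 11  # 22 nt, fully pairable
        seq, mspan, designed_star = build_hairpin(mature)
        star = locate_star(fold(seq), mspan)
        assert star == designed_star
        assert star[1] - star[0] == len(mature)

    def test_unpaired_mature_gives_sentinel(self):
        assert locate_star(fold("A" * 80), (30, 51)) is None

    def test_bulged_mature_shortens_star(self):
        mature = "GC" * 12
        seq, mspan, _ = build_hairpin(mature, asym_run=(10, 11))
        star = locate_star(fold(seq), mspan)
        assert star[1] - star[0] == len(mature) - 2


class TestEvaluateDuplex:
    @pytest.mark.parametrize("M", range(19, 25))
    def test_perfect_stem_scores_all_zero(self, M):
        mature = ("GC" * 13)[:M]
        seq, mspan, _ = build_hairpin(mature)
        fr = fold(seq)
        report = evaluate_duplex(fr, mspan, locate_star(fr, mspan))
        assert (report.n_mismatch, report.n_asym_bulge_nt) == (0, 0)
        assert not report.has_secondary_stem and not report.has_large_loop
        assert report.passes

    def test_six_scattered_mismatches_fail(self):
        mature = "GC" * 12
        seq, mspan, _ = build_hairpin(mature, sym_pos=(3, 6, 9, 12, 15, 18))
        fr = fold(seq)
        report = evaluate_duplex(fr, mspan, locate_star(fr, mspan))
        assert report.n_mismatch == 6
        assert not report.passes

    def test_four_nt_asymmetric_bulge_fails(self):
        mature = "GC" * 12
        seq, mspan, _ = build_hairpin(mature, asym_run=(9, 10, 11, 12))
        fr = fold(seq)
        report = evaluate_duplex(fr, mspan, locate_star(fr, mspan))
        assert report.n_asym_bulge_nt == 4
        assert not report.passes

    def test_large_internal_loop_detected(self):
        mature = "GC" * 12
        seq, mspan, _ = build_hairpin(mature, sym_pos=(8, 9, 10, 11, 12, 13))
        fr = fold(seq)
        report = evaluate_duplex(fr, mspan, locate_star(fr, mspan))
        assert report.has_large_loop
        assert not report.passes

    def test_mismatch_count_monotone(self):
        counts = []
        for k in range(5):
            mature = "GC" * 12
            seq, mspan, _ = build_hairpin(mature, sym_pos=tuple(range(3, 3 + 2 * k, 2)))
            fr = fold(seq)
            counts.append(evaluate_duplex(fr, mspan, locate_star(fr, mspan)).n_mismatch)
        assert counts == sorted(counts)
        assert counts == [0, 1, 2, 3, 4]

    def test_bulge_budget_within_mismatch_budget(self, rng):
        spec = m.SimulationSpec(seed=0)
        for _ in range(25):
            locus = m.generate_mirna_locus(rng, spec)
            fr = fold(locus.sequence)
            star = locate_star(fr, locus.mature_span)
            report = evaluate_duplex(fr, locus.mature_span, star)
            assert report.n_asym_bulge_nt <= report.n_mismatch


class TestLabelCandidate:
    def test_simulated_mirna_locus_labeled_mirna(self, rng):
        spec = m.SimulationSpec(seed=0)
        for _ in range(10):
            cand = candidate_from_locus(m.generate_mirna_locus(rng, spec))
            assert label_candidate(cand) == "miRNA"

    def test_simulated_sirna_locus_labeled_other(self, rng):
        spec = m.SimulationSpec(seed=0)
        labels = [
            label_candidate(candidate_from_locus(m.generate_sirna_locus(rng, spec)))
            for _ in range(20)
        ]
        assert labels.count("miRNA") <= 1

    def test_read_smear_alone_blocks_mirna_label(self, rng):
        spec = m.SimulationSpec(seed=1)
        locus = m.generate_mirna_locus(rng, spec)
        cand = candidate_from_locus(locus)
        assert label_candidate(cand) == "miRNA"
        # same structure, but reads uniformly smeared across the precursor
        n = len(locus.sequence)
        cand.mapped_reads = [
            (off, 21, 5, f"s{off}") for off in range(0, n - 21, 10)
        ]
        star = locate_star(cand.fold, cand.mature_span)
        assert duplex_read_fraction(cand, star) < 0.75
        assert label_candidate(cand) == "other"

    def test_unfolded_candidate_raises(self, rng):
        spec = m.SimulationSpec(seed=0)
        cand = candidate_from_locus(m.generate_mirna_locus(rng, spec))
        cand.fold = None
        with pytest.raises(ValueError):
            label_candidate(cand)


def brute_identity(query: str, ref: str) -> int:
    """All-offsets scan counting identical aligned bases (oracle)."""
    best = 0
    for shift in range(-len(ref) + 1, len(query)):
        n = sum(
            1
            for qi in range(len(query))
            if 0 <= qi - shift < len(ref) and query[qi] == ref[qi - shift]
        )
        best = max(best, n)
    return best


class TestMatchKnown:
    def test_identical_reference_is_known(self):
        q = "UGGAAGCUAGCUAGCUAGGUA"
        best, known = match_known(q, [q])
        assert (best, known) == (21, True)

    def test_exactly_18_matches_is_not_known(self):
        q = "G" * 21
        ref = "G" * 18 + "AAA"  # best overlap: 18 identities at offset 0
        best, known = match_known(q, [ref])
        assert best == 18
        assert not known

    def test_agrees_with_brute_force_scan(self, rng):
        refs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 21)) for _ in range(8)]
        for _ in range(20):
            q = "".join("ACGT"[i] for i in rng.integers(0, 4, 22))
            best, known = match_known(q, refs)
            oracle = max(brute_identity(q, r) for r in refs)
            assert best == oracle
            assert known == (oracle > 18)

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            match_known("ACGU", [])
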