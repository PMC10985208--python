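"""Shared fixtures: simulated datasets and the cross-validation experiment.

The heavy experiment (1,600 simulated loci through the full pipeline plus
five-fold CV) is session-scoped so the classification and training-
hygiene checks share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

import mircnn as m
from mircnn.precursor_extraction import PrecursorCandidate
from mircnn.rna_folding import fold


def candidate_from_locus(locus) -> PrecursorCandidate:
    """Build a folded candidate directly from a simulated locus (bypassing
    mapping/extraction) for stage-level tests."""
    reads = [
        (off, length, count, f"r{i}")
        for i, (off, length, count) in enumerate(locus.reads)
    ]
    mature = max(reads, key=lambda r: (r[2], -r[0]))
    return PrecursorCandidate(
        chrom="chrT",
        strand="+",
        start=0,
        end=len(locus.sequence),
        sequence=locus.sequence.replace("T", "U"),
        mapped_reads=reads,
        mature_span=(mature[0], mature[0] + mature[1]),
        cluster_id="chrT:0",
        fold=fold(locus.sequence),
    )


@pytest.fixture(scope="session")
def toy_dataset():
    """20 miRNA + 60 siRNA loci, pipeline output and per-locus recovery."""
    ds = m.generate_dataset(m.SimulationSpec(n_mirna_loci=20, n_sirna_loci=60, seed=11))
    result = m.run_pipeline(ds.genome, ds.reads)
    recovery = m.locus_recovery(result.candidates, ds.truth)
    return ds, result, recovery


@pytest.fixture(scope="session")
def cv_experiment():
    """400 miRNA + 1,200 siRNA loci through the full pipeline, truth-labeled,
    trained with five-fold cross-validation."""
    ds = m.generate_dataset(
        m.SimulationSpec(n_mirna_loci=400, n_sirna_loci=1200, seed=7)
    )
    result = m.run_pipeline(ds.genome, ds.reads)
    matrices = m.labeled_matrices(result, ds.truth)
    cv = m.train(matrices, config=m.CNNConfig(epochs=15), folds=5, seed=7)
    return {"dataset": ds, "result": result, "matrices": matrices, "cv": cv}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
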