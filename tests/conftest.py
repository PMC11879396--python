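import pandas as pd
import pytest

import mtasepref as mp
from mtasepref.preference import OEProfile


def profile_from_rows(rows, motif="CG", target_index=1):
    """Build an OEProfile directly from {position: (A, C, G, T) o/e values}."""
    idx = list(rows)
    oe = pd.DataFrame(
        [rows[p] for p in idx], index=idx, columns=list("ACGT"), dtype=float
    )
    return OEProfile(
        motif=motif, target_index=target_index, oe=oe,
        pool_freq=oe * 0 + 0.25, methylated_counts=oe * 0, total_counts=oe * 0,
        n_methylated=10, n_total=20,
    )


def raw_from_records(records):
    """SeqRecord FASTQ records -> RawRead objects (skips disk round-trip)."""
    return [
        mp.RawRead(r.id, str(r.seq), list(r.letter_annotations["phred_quality"]))
        for r in records
    ]


@pytest.fixture(scope="session")
def gcgc_design():
    return mp.motif_design("GCGC", 2)


@pytest.fixture(scope="session")
def cn_library_design():
    return mp.cn_design()


@pytest.fixture(scope="session")
def gcgc_model():
    """Known multiplicative model over +/-2 flanks of GCGC."""
    return mp.PreferenceModel(
        motif="GCGC",
        target_index=2,
        flank_factors={
            -2: {"A": 0.6, "C": 2.0, "G": 0.8, "T": 1.0},
            -1: {"A": 1.0, "C": 1.5, "G": 0.5, "T": 1.1},
            1: {"A": 1.4, "C": 0.7, "G": 1.3, "T": 1.0},
            2: {"A": 1.0, "C": 1.0, "G": 1.6, "T": 0.9},
        },
    )


@pytest.fixture(scope="session")
def clean_dataset(gcgc_design, gcgc_model):
    """Noise-free simulated experiment: conversion 1, no errors/duplicates."""
    t = mp.time_for_target_methylation(gcgc_model, gcgc_design, 0.3)
    reads, manifest = mp.simulate_experiment(
        gcgc_design, gcgc_model, 5000, t, seed=42, conv_rate=1.0
    )
    processed, stats = mp.process_reads(raw_from_records(reads), gcgc_design)
    return {
        "design": gcgc_design,
        "model": gcgc_model,
        "t": t,
        "reads": reads,
        "manifest": manifest,
        "processed": processed,
        "stats": stats,
    }
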