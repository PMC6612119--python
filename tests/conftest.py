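"""Shared fixtures and the independent brute-force mapping oracle."""

from __future__ import annotations

import numpy as np
import pytest

import clonetrace as ct


def brute_force_map(sequence: str, genome: ct.Genome, max_mismatch: int = 1):
    """Independent oracle: score every offset of every chromosome on both
    strands with a numpy sliding-window mismatch count, then apply the same
    unique/ambiguous/unmapped decision rule as the mapper.

    Returns (status, hits) where hits is the set of best placements
    (chrom, 1-based start, strand, mismatches).
    """
    n = len(sequence)
    hits = []
    for chrom, chrom_seq in genome.sequences.items():
        if n > len(chrom_seq):
            continue
        text = np.frombuffer(chrom_seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(text, n)
        for strand, query in (("+", sequence), ("-", ct.revcomp(sequence))):
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            mismatches = (windows != q).sum(axis=1)
            for start0 in np.flatnonzero(mismatches <= max_mismatch):
                hits.append((chrom, int(start0) + 1, strand, int(mismatches[start0])))
    if not hits:
        return "unmapped", set()
    best = min(h[3] for h in hits)
    winners = {h for h in hits if h[3] == best}
    return ("unique" if len(winners) == 1 else "ambiguous"), winners


@pytest.fixture(scope="session")
def oracle():
    return brute_force_map


@pytest.fixture(scope="session")
def small_genome():
    """Two 40-kb chromosomes with three planted IR decoys."""
    genome, decoys = ct.generate_genome(
        n_chrom=2, chrom_length=40_000, n_decoys=3, seed=11
    )
    return genome, decoys


@pytest.fixture(scope="session")
def truth_and_reads(small_genome):
    """Six insertions, error-free reads at depth 10 with duplicates and
    background, plus the per-read truth table."""
    genome, decoys = small_genome
    truth = ct.plant_insertions(genome, k=6, seed=5, decoys=decoys)
    pairs, read_truth = ct.simulate_reads(
        genome, truth, depth=10, dup_rate=0.3, error_rate=0.0,
        n_background=60, seed=2,
    )
    return truth, pairs, read_truth


@pytest.fixture(scope="session")
def annotation_features(small_genome):
    genome, _ = small_genome
    return ct.generate_annotation(genome, seed=4)
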