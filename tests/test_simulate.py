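"""Generator behaviour: seeded determinism, planted truth, growth arithmetic,
fixture round-trips."""

import numpy as np
import pandas as pd
import pytest

import clonetrace as ct


class TestGenerateGenome:
    def test_no_decoys_requested(self):
        genome, decoys = ct.generate_genome(1, 50_000, 0, seed=1)
        assert list(genome.lengths.values()) == [50_000]
        assert decoys == []

    def test_planted_decoys_are_verbatim_motif_copies(self):
        genome, decoys = ct.generate_genome(2, 100_000, 3, seed=7)
        assert len(decoys) == 3
        for chrom, pos in decoys:
            assert genome.fetch(chrom, pos, pos + 19) == ct.IR_SEQUENCE
        # decoy list is a full scan of the emitted sequence
        found = [
            (chrom, i + 1)
            for chrom, seq in genome.sequences.items()
            for i in _find_all(seq, ct.IR_SEQUENCE)
        ]
        assert sorted(found) == sorted(decoys)

    def test_seeded_determinism(self):
        a, da = ct.generate_genome(2, 60_000, 3, seed=42)
        b, db = ct.generate_genome(2, 60_000, 3, seed=42)
        assert a.sequences == b.sequences
        assert da == db

    def test_ttaa_guaranteed(self):
        genome, _ = ct.generate_genome(1, 50_000, 0, seed=3)
        assert "TTAA" in genome.sequences["chr1"]

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError):
            ct.generate_genome(1, 100, 0, seed=0)


def _find_all(text, pattern):
    out, i = [], text.find(pattern)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


class TestPlantInsertions:
    def test_zero_events(self, small_genome):
        genome, decoys = small_genome
        truth = ct.plant_insertions(genome, 0, seed=1, decoys=decoys)
        assert truth.events == []
        assert truth.offset == 5

    def test_events_sit_on_ttaa_and_are_separated(self, small_genome):
        genome, decoys = small_genome
        truth = ct.plant_insertions(genome, 5, seed=3, decoys=decoys)
        assert len(truth.events) == 5
        for e in truth.events:
            assert genome.fetch(e.chrom, e.position, e.position + 3) == "TTAA"
        for i, a in enumerate(truth.events):
            for b in truth.events[i + 1 :]:
                assert a.chrom != b.chrom or abs(a.position - b.position) > truth.offset

    def test_capacity_error(self, small_genome):
        genome, decoys = small_genome
        with pytest.raises(ValueError, match="eligible TTAA"):
            ct.plant_insertions(genome, 10_000, seed=1, decoys=decoys)


class TestSimulateReads:
    def test_read_lengths_and_mate_counts(self, truth_and_reads):
        _, pairs, _ = truth_and_reads
        for p in pairs:
            assert len(p.seq1) == len(p.seq2) == ct.READ_LENGTH

    def test_junction_reads_end_at_recorded_positions(self, small_genome):
        """Trimming each junction mate must leave genome sequence whose
        IR-adjacent base is n (left flank) or n+d (right flank)."""
        genome, decoys = small_genome
        truth = ct.plant_insertions(genome, 3, seed=9, decoys=[])
        pairs, read_truth = ct.simulate_reads(
            genome, truth, depth=4, dup_rate=0.0, error_rate=0.0, seed=3
        )
        by_id = {p.pair_id: p for p in pairs}
        for row in read_truth.itertuples():
            if row.origin != "event" or row.status != "emitted":
                continue
            pair = by_id[row.pair_id]
            jseq = pair.seq1 if row.junction_mate == 1 else pair.seq2
            trimmed = ct.trim_ir(jseq)
            assert trimmed.ir_found
            g = trimmed.trimmed_length
            n = int(row.expected_position)
            if row.flank == "L":
                assert trimmed.sequence == genome.fetch(row.chrom, n - g + 1, n)
            else:
                assert trimmed.sequence == ct.revcomp(
                    genome.fetch(row.chrom, n, n + g - 1)
                )

    def test_duplicates_double_depth4(self, small_genome):
        genome, _ = small_genome
        truth = ct.plant_insertions(genome, 1, seed=9, decoys=[])
        pairs, _ = ct.simulate_reads(
            genome, truth, depth=4, dup_rate=0.5, error_rate=0.0, seed=4
        )
        distinct = {(p.seq1, p.seq2) for p in pairs}
        assert len(distinct) == 8  # 2 flanks x 4, duplicates collapse

    def test_background_only_has_no_ir(self):
        genome, _ = ct.generate_genome(1, 40_000, 0, seed=19)
        truth = ct.InsertionTruth(events=[], decoys=[], offset=5)
        pairs, _ = ct.simulate_reads(
            genome, truth, depth=1, error_rate=0.0, n_background=100, seed=5
        )
        assert len(pairs) == 100
        for p in pairs:
            assert ct.IR_SEQUENCE not in p.seq1
            assert ct.IR_SEQUENCE not in p.seq2

    def test_seeded_determinism(self, small_genome):
        genome, decoys = small_genome
        truth = ct.plant_insertions(genome, 2, seed=1, decoys=decoys)
        a, ta = ct.simulate_reads(genome, truth, depth=3, seed=8, n_background=10)
        b, tb = ct.simulate_reads(genome, truth, depth=3, seed=8, n_background=10)
        assert a == b
        pd.testing.assert_frame_equal(ta, tb)


class TestSimulateGrowth:
    def test_single_clone_doubles(self):
        growth = ct.simulate_growth({"a": 1.0}, {"a": 500_000}, days=7)
        final = growth.loc[growth.day == 7, "cells_counted"].item()
        assert final == pytest.approx(64_000_000)

    def test_equal_rates_stay_balanced(self):
        growth = ct.simulate_growth(
            {"a": 0.8, "b": 0.8}, {"a": 1000.0, "b": 1000.0},
            days=14, passage_every=7, total_reseed=2000,
        )
        assert np.allclose(growth["fraction"], 0.5)

    def test_closed_form_fractions(self):
        growth = ct.simulate_growth(
            {"fast": 1.0, "slow": 0.5}, {"fast": 500.0, "slow": 500.0}, days=7
        )
        day7 = growth[growth.day == 7].set_index("clone")["fraction"]
        expect_fast = 2**7 / (2**7 + 2**3.5)
        assert day7["fast"] == pytest.approx(expect_fast, abs=1e-12)

    def test_fractions_sum_to_one_and_passaging_preserves_them(self):
        growth = ct.simulate_growth(
            {"a": 1.1, "b": 0.4, "c": 0.7},
            {"a": 100.0, "b": 300.0, "c": 600.0},
            days=28, passage_every=7, total_reseed=500_000,
        )
        sums = growth.groupby("day")["fraction"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
        for day in (7, 14, 21, 28):
            sub = growth[growth.day == day].set_index("clone")
            np.testing.assert_allclose(
                sub["cells_seeded"] / sub["cells_seeded"].sum(), sub["fraction"]
            )

    def test_bad_passaging_rejected(self):
        with pytest.raises(ValueError):
            ct.simulate_growth({"a": 1.0}, {"a": 10.0}, days=10,
                               passage_every=7, total_reseed=10)


class TestStrFixture:
    def test_reference_and_clone_cells(self):
        table = ct.make_str_fixture()
        assert table.loc["D7S820", "ATCC HTB-26"] == "8,9"
        assert table.loc["TH01", "MDA-MB-231"] == "7,9.3"
        assert table.loc["vWA", "mKO E10"] == "15,16"

    def test_ten_loci_five_profiles(self):
        table = ct.make_str_fixture()
        assert table.shape == (10, 5)
        assert list(table.index) == [
            "D5S818", "D13S317", "D7S820", "D16S539", "vWA",
            "TH01", "TPOX", "CSF1PO", "D21S11", "Amelogenin",
        ]


class TestWriteFixtures:
    def test_round_trip(self, tmp_path, small_genome, truth_and_reads, annotation_features):
        genome, decoys = small_genome
        truth, pairs, read_truth = truth_and_reads
        growth = ct.simulate_growth({"a": 1.0}, {"a": 10.0}, days=2)
        paths = ct.write_fixtures(
            tmp_path, genome, truth, pairs, read_truth,
            annotation_features, growth, ct.make_str_fixture(),
        )
        assert ct.Genome.from_fasta(paths["genome"]).sequences == genome.sequences
        back = ct.read_fastq_pairs(paths["reads_1"], paths["reads_2"])
        assert back == pairs
        events = pd.read_csv(paths["truth_events"], sep="\t")
        assert len(events) == len(truth.events)
        feats, chroms = ct.read_gff3(paths["annotation"])
        assert set(feats) == set(annotation_features)
        assert chroms == set(genome.sequences)
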