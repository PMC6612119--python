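"""Synthetic inputs for the insertion-calling and clonal-dynamics pipeline.

This module generates every input the pipeline consumes, with recorded
ground truth: a desk-scale random genome carrying TTAA integration sites and
endogenous inverted-repeat (IR) decoys, paired-end junction reads around
planted insertions, a gene annotation, deterministic multi-clone growth
trajectories with passaging, and the STR authentication profiles of the
MDA-MB-231-derived clonal cell lines.

The transposon model follows the PiggyBac system: the transposase inserts
its cargo at TTAA host sites with a staggered cut that duplicates a short
host tract, so a single genuine insertion produces junction evidence at two
genome positions, ``n`` and ``n + d`` (``d`` = 5 by default). Endogenous
occurrences of the 20-nt IR motif ("decoys") produce junction-like reads at
a single position only, which is what lets the caller reject them.

Read geometry: the junction mate carries genome sequence 5' of a 3'-terminal
IR copy (adapter-read-through geometry), so removing the IR shortens the
read below the raw read length and leaves the genome base contiguous to the
IR at the read's 3' end. Left-flank reads are forward-strand and end at
``n``; right-flank reads are reverse-strand and start at ``n + d``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AnnotationFeature, write_gff3
from .genome import Genome, revcomp

#: Terminal inverted repeat of the transposon, as sequenced at junctions.
IR_SEQUENCE = "GATTATCTTTCTAGGGTTAA"

#: Raw read length of the paired-end run emulated here.
READ_LENGTH = 151

#: Size of the target-site duplication left by the staggered cut.
TSD_OFFSET = 5

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class IRMotif:
    """The transposon inverted-repeat motif searched for in reads."""

    sequence: str = IR_SEQUENCE

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class InsertionSite:
    """One planted insertion: ``position`` is n, the 1-based first base of the
    duplicated tract; the event is reportable at n and n + d."""

    chrom: str
    position: int
    strand: str


@dataclass
class InsertionTruth:
    """Ground truth for a simulated run: planted events, endogenous IR decoys
    and the duplication offset d."""

    events: list[InsertionSite] = field(default_factory=list)
    decoys: list[tuple[str, int]] = field(default_factory=list)
    offset: int = TSD_OFFSET


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())


def generate_genome(
    n_chrom: int = 1,
    chrom_length: int = 50_000,
    n_decoys: int = 0,
    seed: int = 0,
    motif: IRMotif = IRMotif(),
    decoy_margin: int = 600,
) -> tuple[Genome, list[tuple[str, int]]]:
    """Random ACGT genome with planted IR decoys and guaranteed TTAA sites.

    Exactly ``n_decoys`` verbatim copies of the IR motif are planted at
    non-overlapping positions, kept ``decoy_margin`` bp away from chromosome
    ends so that reads can be drawn around them. The returned decoy list is
    a scan of the final sequence for the motif, so it also records chance
    occurrences (vanishingly rare at these sizes). TTAA tetramers are
    guaranteed by planting one per 5 kb window where none arose by chance.

    Returns the genome and the decoy list as (chrom, 1-based position).
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    min_len = 10 * (READ_LENGTH + motif.length)
    if chrom_length < min_len:
        raise ValueError(f"chrom_length must be >= {min_len}")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = {name: _random_sequence(rng, chrom_length) for name in names}

    # distribute decoys over chromosomes, non-overlapping, away from ends
    usable = chrom_length - 2 * decoy_margin - motif.length
    if n_decoys and usable < n_decoys * (2 * motif.length):
        raise ValueError(
            f"chromosomes of {chrom_length} bp are too short to host {n_decoys} decoys"
        )
    motif_bytes = motif.sequence.encode()
    placed: dict[str, list[int]] = {name: [] for name in names}
    for _ in range(n_decoys):
        chrom = names[rng.integers(0, n_chrom)]
        for _attempt in range(1000):
            pos = int(rng.integers(decoy_margin + 1, chrom_length - decoy_margin - motif.length))
            if all(abs(pos - p) >= motif.length for p in placed[chrom]):
                placed[chrom].append(pos)
                seqs[chrom][pos - 1 : pos - 1 + motif.length] = motif_bytes
                break
        else:  # pragma: no cover - would need a pathologically crowded genome
            raise ValueError("could not place all requested decoys without overlap")

    # guarantee TTAA occurrences: one per 5 kb window if absent by chance
    decoy_spans = {
        name: [(p, p + motif.length - 1) for p in placed[name]] for name in names
    }
    for name in names:
        seq = seqs[name]
        for w0 in range(0, chrom_length, 5000):
            window = bytes(seq[w0 : w0 + 5000])
            if b"TTAA" not in window:
                pos0 = int(rng.integers(w0, min(w0 + 5000, chrom_length - 4)))
                if any(s - 4 <= pos0 + 1 <= e for s, e in decoy_spans[name]):
                    pos0 = max(0, w0)
                seq[pos0 : pos0 + 4] = b"TTAA"

    genome = Genome({name: bytes(seq).decode() for name, seq in seqs.items()})
    decoys = [
        (name, i + 1)
        for name, seq in genome.sequences.items()
        for i in _find_all(seq, motif.sequence)
    ]
    return genome, decoys


def _find_all(text: str, pattern: str) -> list[int]:
    """All 0-based occurrence indices of ``pattern`` in ``text``."""
    out, i = [], text.find(pattern)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


# ---------------------------------------------------------------------------
# insertions
# ---------------------------------------------------------------------------


def plant_insertions(
    genome: Genome,
    k: int,
    offset: int = TSD_OFFSET,
    seed: int = 0,
    decoys: list[tuple[str, int]] | None = None,
    margin: int = 600,
    min_separation: int = 1000,
    motif: IRMotif = IRMotif(),
) -> InsertionTruth:
    """Select ``k`` TTAA sites as insertion events.

    Each event records n, the 1-based position of the first base of the
    duplicated tract (the first T of the chosen TTAA), and a strand. Events
    are kept ``margin`` bp from chromosome ends (so full read pairs can be
    drawn), at least ``min_separation`` bp apart, and clear of decoy motif
    footprints. Raises if the genome cannot host ``k`` such sites.
    """
    if min_separation <= offset:
        raise ValueError("min_separation must exceed offset")
    decoys = decoys or []
    rng = np.random.default_rng(seed)
    candidates: list[tuple[str, int]] = []
    for chrom, seq in genome.sequences.items():
        spans = [(p, p + motif.length - 1) for c, p in decoys if c == chrom]
        for i in _find_all(seq, "TTAA"):
            pos = i + 1
            if pos <= margin or pos + offset + margin > len(seq):
                continue
            if any(s - 4 < pos <= e for s, e in spans):
                continue
            candidates.append((chrom, pos))
    order = rng.permutation(len(candidates))
    chosen: list[tuple[str, int]] = []
    for idx in order:
        chrom, pos = candidates[idx]
        if all(c != chrom or abs(pos - p) > min_separation for c, p in chosen):
            chosen.append((chrom, pos))
            if len(chosen) == k:
                break
    if len(chosen) < k:
        raise ValueError(
            f"genome hosts only {len(chosen)} eligible TTAA sites, {k} requested"
        )
    chosen.sort()
    strands = rng.choice(list("+-"), size=k)
    events = [
        InsertionSite(chrom, pos, str(strand))
        for (chrom, pos), strand in zip(chosen, strands)
    ]
    return InsertionTruth(events=events, decoys=list(decoys), offset=offset)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

_ANCHOR_GAP = 300  # bp between junction and anchor mate windows


def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float, protect: tuple[int, int]
) -> str:
    """Substitute bases at ``error_rate`` outside the half-open 0-based
    ``protect`` span (the IR copy, whose detection must stay exact)."""
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < error_rate)
    hits = hits[(hits < protect[0]) | (hits >= protect[1])]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_reads(
    genome: Genome,
    truth: InsertionTruth,
    depth: int = 10,
    dup_rate: float = 0.0,
    error_rate: float = 0.001,
    n_background: int = 0,
    seed: int = 0,
    motif: IRMotif = IRMotif(),
    read_length: int = READ_LENGTH,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Emit paired-end reads for every event flank, decoy and background locus.

    For each event, ``depth`` junction pairs are drawn per flank: the
    junction mate is genome sequence ending at the IR-adjacent base (n on
    the left flank as + strand, n + d on the right flank as - strand)
    followed by a 3'-terminal IR copy and random transposon cargo; its mate
    is pure genome within 500 bp. Decoys emit IR-containing reads supported
    at a single position (d upstream partner never arises). Background pairs
    are pure genome. Duplicates are exact copies added with probability
    ``dup_rate`` per pair; substitution errors are applied at ``error_rate``
    per base outside the IR copy.

    Returns the read pairs and a per-read truth table mapping every pair id
    to its origin and, for junction reads, the candidate position the
    pipeline should recover.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0 <= dup_rate < 1 and 0 <= error_rate < 1):
        raise ValueError("dup_rate and error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    d = truth.offset
    L, L_IR = read_length, motif.length
    max_genome = L - L_IR  # junction mate genome part after trimming (<= 131)
    pairs: list[ReadPair] = []
    rows: list[dict] = []

    def emit(pair_id, jseq, jqual, aseq, aqual, origin, src, chrom, flank, expect):
        junction_first = bool(rng.integers(0, 2))
        if junction_first:
            pair = ReadPair(pair_id, jseq, jqual, aseq, aqual)
            jmate = 1
        else:
            pair = ReadPair(pair_id, aseq, aqual, jseq, jqual)
            jmate = 2
        pairs.append(pair)
        rows.append(
            dict(
                pair_id=pair_id,
                origin=origin,
                source=src,
                chrom=chrom,
                flank=flank,
                expected_position=expect,
                junction_mate=jmate,
                duplicate_of="",
                status="emitted",
            )
        )

    qual = "I" * L

    for e_idx, event in enumerate(truth.events):
        seq = genome.sequences[event.chrom]
        n = event.position
        for flank in "LR":
            for i in range(depth):
                g = max_genome - (i % 52)  # distinct lengths -> distinct pairs
                pair_id = f"ev{e_idx}_{flank}{i}"
                shift = i % 100
                if flank == "L":
                    gstart, gend = n - g + 1, n
                    a_lo = n - 450 + shift
                    a_hi = a_lo + L - 1
                    expect = n
                else:
                    gstart, gend = n + d, n + d + g - 1
                    a_lo = n + d + _ANCHOR_GAP + shift
                    a_hi = a_lo + L - 1
                    expect = n + d
                if gstart < 1 or gend > len(seq) or a_lo < 1 or a_hi > len(seq):
                    warnings.warn(
                        f"event {e_idx} flank {flank}: too close to a chromosome "
                        "end to draw a full pair; skipped"
                    )
                    rows.append(
                        dict(
                            pair_id=pair_id,
                            origin="event",
                            source=e_idx,
                            chrom=event.chrom,
                            flank=flank,
                            expected_position=expect,
                            junction_mate=0,
                            duplicate_of="",
                            status="skipped",
                        )
                    )
                    continue
                gpart = genome.fetch(event.chrom, gstart, gend)
                if flank == "R":
                    gpart = revcomp(gpart)
                cargo = _random_sequence(rng, L - g - L_IR).decode()
                jseq = _apply_errors(
                    rng, gpart + motif.sequence + cargo, error_rate, (g, g + L_IR)
                )
                anchor = genome.fetch(event.chrom, a_lo, a_hi)
                anchor = revcomp(anchor) if flank == "L" else anchor
                aseq = _apply_errors(rng, anchor, error_rate, (L, L))
                emit(pair_id, jseq, qual, aseq, qual, "event", e_idx, event.chrom, flank, expect)

    for d_idx, (chrom, dpos) in enumerate(truth.decoys):
        seq = genome.sequences[chrom]
        for i in range(depth):
            left = 111 - (i % 40)  # genome bases retained after trimming
            pair_id = f"dc{d_idx}_{i}"
            r_lo = dpos - left
            r_hi = r_lo + L - 1
            a_lo = r_lo - 350 + (i % 50)
            a_hi = a_lo + L - 1
            expect = dpos - 1
            if r_lo < 1 or r_hi > len(seq) or a_lo < 1 or a_hi > len(seq):
                rows.append(
                    dict(
                        pair_id=pair_id,
                        origin="decoy",
                        source=d_idx,
                        chrom=chrom,
                        flank="",
                        expected_position=expect,
                        junction_mate=0,
                        duplicate_of="",
                        status="skipped",
                    )
                )
                continue
            jseq = _apply_errors(
                rng, genome.fetch(chrom, r_lo, r_hi), error_rate, (left, left + L_IR)
            )
            aseq = _apply_errors(
                rng, revcomp(genome.fetch(chrom, a_lo, a_hi)), error_rate, (L, L)
            )
            emit(pair_id, jseq, qual, aseq, qual, "decoy", d_idx, chrom, "", expect)

    chrom_names = list(genome.sequences)
    for b_idx in range(n_background):
        chrom = chrom_names[rng.integers(0, len(chrom_names))]
        seq = genome.sequences[chrom]
        s = int(rng.integers(1, len(seq) - (2 * L + _ANCHOR_GAP)))
        m1 = _apply_errors(rng, genome.fetch(chrom, s, s + L - 1), error_rate, (L, L))
        m2_lo = s + L + _ANCHOR_GAP
        m2 = _apply_errors(
            rng, revcomp(genome.fetch(chrom, m2_lo, m2_lo + L - 1)), error_rate, (L, L)
        )
        pair_id = f"bg{b_idx}"
        pairs.append(ReadPair(pair_id, m1, qual, m2, qual))
        rows.append(
            dict(
                pair_id=pair_id,
                origin="background",
                source=b_idx,
                chrom=chrom,
                flank="",
                expected_position=-1,
                junction_mate=0,
                duplicate_of="",
                status="emitted",
            )
        )

    if dup_rate > 0:
        originals = list(pairs)
        for pair in originals:
            if rng.random() < dup_rate:
                dup_id = f"{pair.pair_id}_dup"
                pairs.append(
                    ReadPair(dup_id, pair.seq1, pair.qual1, pair.seq2, pair.qual2)
                )
                src_row = next(r for r in rows if r["pair_id"] == pair.pair_id)
                dup_row = dict(src_row)
                dup_row.update(pair_id=dup_id, duplicate_of=pair.pair_id)
                rows.append(dup_row)

    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def generate_annotation(
    genome: Genome,
    seed: int = 0,
    genes_per_chrom: int = 4,
    add_lncrna: bool = True,
) -> list[AnnotationFeature]:
    """Non-overlapping genes with 2-4 exons each, tiled across every chromosome.

    When ``add_lncrna`` is set, one lncRNA overlapping the first gene of each
    chromosome is added, emulating stacked annotations at a single locus.
    """
    rng = np.random.default_rng(seed)
    features: list[AnnotationFeature] = []
    for chrom, seq in genome.sequences.items():
        length = len(seq)
        cursor = 200
        for i in range(genes_per_chrom):
            span = int(rng.integers(3000, 8000))
            start = cursor + int(rng.integers(200, 1500))
            end = min(start + span, length - 200)
            if end - start < 1500:
                break
            strand = "+" if rng.integers(0, 2) else "-"
            name = f"{chrom.upper()}G{i + 1}"
            features.append(AnnotationFeature(chrom, start, end, strand, name, "gene"))
            n_exons = int(rng.integers(2, 5))
            bounds = sorted(
                int(x) for x in rng.choice(
                    np.arange(start + 100, end - 100), size=2 * n_exons, replace=False
                )
            )
            for j in range(n_exons):
                features.append(
                    AnnotationFeature(
                        chrom, bounds[2 * j], bounds[2 * j + 1], strand,
                        f"{name}.e{j + 1}", "exon", parent=name,
                    )
                )
            if i == 0 and add_lncrna:
                lnc_start = max(1, start - 500)
                lnc_end = min(length, start + 2000)
                features.append(
                    AnnotationFeature(
                        chrom, lnc_start, lnc_end,
                        "-" if strand == "+" else "+",
                        f"{chrom.upper()}LNC1", "lncRNA",
                    )
                )
            cursor = end
    return features


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------


def simulate_growth(
    clone_rates: dict[str, float],
    seed_counts: dict[str, float],
    days: int,
    passage_every: int = 0,
    total_reseed: float | None = None,
) -> pd.DataFrame:
    """Deterministic exponential co-culture growth with periodic passaging.

    Each clone grows as N_i(t+1) = N_i(t) * 2**rate_i (rates in population
    doublings per day). Every ``passage_every`` days (0 disables passaging)
    the whole dish is reseeded at ``total_reseed`` cells, preserving clone
    fractions exactly — the paper's weekly trypsinize-count-reseed protocol.

    Returns a long table with columns ``day, clone, cells_counted,
    cells_seeded, fraction``: ``cells_counted`` is the population at that day
    before reseeding, ``cells_seeded`` what is carried into the next day.
    """
    if set(clone_rates) != set(seed_counts):
        raise ValueError("clone_rates and seed_counts must name the same clones")
    if any(not np.isfinite(r) for r in clone_rates.values()):
        raise ValueError("rates must be finite")
    if any(c <= 0 for c in seed_counts.values()):
        raise ValueError("seed counts must be positive")
    if passage_every:
        if days % passage_every:
            raise ValueError("passage_every must divide days")
        if total_reseed is None:
            raise ValueError("total_reseed required when passaging")
    clones = list(clone_rates)
    counts = np.array([float(seed_counts[c]) for c in clones])
    rates = np.array([clone_rates[c] for c in clones])
    rows = []

    def record(day, counted, seeded):
        total = counted.sum()
        for c, n_count, n_seed in zip(clones, counted, seeded):
            rows.append(
                dict(day=day, clone=c, cells_counted=n_count, cells_seeded=n_seed,
                     fraction=n_count / total)
            )

    record(0, counts.copy(), counts.copy())
    for day in range(1, days + 1):
        counts = counts * 2.0 ** rates
        counted = counts.copy()
        if passage_every and day % passage_every == 0:
            counts = counts / counts.sum() * total_reseed
        record(day, counted, counts.copy())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# STR fixture
# ---------------------------------------------------------------------------

#: GenePrint-10 authentication profiles of the parental MDA-MB-231 line
#: (ATCC HTB-26 database entry) and the three color-coded clonal lines.
STR_TABLE: dict[str, dict[str, str]] = {
    "D5S818": dict.fromkeys(
        ["ATCC HTB-26", "MDA-MB-231", "GFP C3", "mKO E10", "Sapphire D7"], "12"
    ),
    "D13S317": dict.fromkeys(
        ["ATCC HTB-26", "MDA-MB-231", "GFP C3", "mKO E10", "Sapphire D7"], "13"
    ),
    "D7S820": {
        "ATCC HTB-26": "8,9", "MDA-MB-231": "8", "GFP C3": "8",
        "mKO E10": "8", "Sapphire D7": "8",
    },
    "D16S539": dict.fromkeys(
        ["ATCC HTB-26", "MDA-MB-231", "GFP C3", "mKO E10", "Sapphire D7"], "12"
    ),
    "vWA": {
        "ATCC HTB-26": "15,18", "MDA-MB-231": "15", "GFP C3": "15",
        "mKO E10": "15,16", "Sapphire D7": "15",
    },
    "TH01": dict.fromkeys(
        ["ATCC HTB-26", "MDA-MB-231", "GFP C3", "mKO E10", "Sapphire D7"], "7,9.3"
    ),
    "TPOX": dict.fromkeys(
        ["ATCC HTB-26", "MDA-MB-231", "GFP C3", "mKO E10", "Sapphire D7"], "8,9"
    ),
    "CSF1PO": dict.fromkeys(
        ["ATCC HTB-26", "MDA-MB-231", "GFP C3", "mKO E10", "Sapphire D7"], "12,13"
    ),
    "D21S11": dict.fromkeys(
        ["ATCC HTB-26", "MDA-MB-231", "GFP C3", "mKO E10", "Sapphire D7"], "30,33.2"
    ),
    "Amelogenin": dict.fromkeys(
        ["ATCC HTB-26", "MDA-MB-231", "GFP C3", "mKO E10", "Sapphire D7"], "x"
    ),
}


def make_str_fixture() -> pd.DataFrame:
    """STR profile table: rows are loci, columns are profiles, cells are
    comma-separated allele labels (kept as strings, e.g. "9.3", "x")."""
    df = pd.DataFrame(STR_TABLE).T
    df.index.name = "locus"
    return df


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------


def write_fastq(pairs: list[ReadPair], path1, path2) -> None:
    def records(mate):
        for p in pairs:
            seq = p.seq1 if mate == 1 else p.seq2
            q = p.qual1 if mate == 1 else p.qual2
            rec = SeqRecord(Seq(seq), id=f"{p.pair_id}/{mate}", description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in q]
            yield rec

    SeqIO.write(records(1), str(path1), "fastq")
    SeqIO.write(records(2), str(path2), "fastq")


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Load two mate FASTQ files back into pairs, matched by record order."""
    recs1 = list(SeqIO.parse(str(path1), "fastq"))
    recs2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError(
            f"mate files differ in record count: {len(recs1)} vs {len(recs2)}"
        )

    def qual(rec):
        return "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])

    return [
        ReadPair(r1.id.rsplit("/", 1)[0], str(r1.seq), qual(r1), str(r2.seq), qual(r2))
        for r1, r2 in zip(recs1, recs2)
    ]


def write_fixtures(
    outdir,
    genome: Genome,
    truth: InsertionTruth,
    pairs: list[ReadPair],
    read_truth: pd.DataFrame,
    features: list[AnnotationFeature],
    growth: pd.DataFrame,
    profiles: pd.DataFrame,
) -> dict[str, Path]:
    """Write every fixture to ``outdir``; re-reading reproduces the objects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "reads_1": outdir / "reads_1.fastq",
        "reads_2": outdir / "reads_2.fastq",
        "annotation": outdir / "annotation.gff3",
        "truth_events": outdir / "truth_events.tsv",
        "truth_reads": outdir / "truth_reads.tsv",
        "growth": outdir / "growth.tsv",
        "str_profiles": outdir / "str_profiles.tsv",
    }
    try:
        genome.to_fasta(paths["genome"])
        write_fastq(pairs, paths["reads_1"], paths["reads_2"])
        write_gff3(paths["annotation"], genome.lengths, features)
        pd.DataFrame(
            [
                dict(chrom=e.chrom, position=e.position, strand=e.strand,
                     offset=truth.offset)
                for e in truth.events
            ],
            columns=["chrom", "position", "strand", "offset"],
        ).to_csv(paths["truth_events"], sep="\t", index=False)
        read_truth.to_csv(paths["truth_reads"], sep="\t", index=False)
        growth.to_csv(paths["growth"], sep="\t", index=False)
        profiles.to_csv(paths["str_profiles"], sep="\t")
    except OSError as exc:  # pragma: no cover
        raise OSError(f"failed writing fixtures under {outdir}: {exc}") from exc
    return paths
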