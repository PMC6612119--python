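"""Exhaustive-uniqueness read mapping and junction-position extraction.

The mapper finds every placement of a read on either strand within a small
mismatch budget and classifies the read as ``unique`` (exactly one placement
attains the minimum mismatch count), ``ambiguous`` (tied best placements) or
``unmapped``. Uniqueness here is exact, playing the role a mapping-quality
threshold plays for heuristic aligners. Candidate placements are generated
by pigeonhole seeding — a read with at most k mismatches must contain one of
k+1 exact segments — and then verified, which is equivalent to scanning
every offset but far faster.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import Genome, revcomp


@dataclass(frozen=True)
class Alignment:
    """Placement of one mate. ``start`` is the 1-based leftmost mapped base
    on the forward genome; minus-strand reads are placed via their reverse
    complement."""

    pair_id: str
    mate: int
    chrom: str | None
    start: int
    strand: str
    mismatches: int
    mapped_length: int
    status: str  # unique | ambiguous | unmapped

    @property
    def end(self) -> int:
        return self.start + self.mapped_length - 1


@dataclass(frozen=True)
class JunctionCandidate:
    """One read's vote: the genome base contiguous to the trimmed IR."""

    chrom: str
    position: int
    strand: str
    pair_id: str


def _occurrences(text: str, pattern: str) -> list[int]:
    out, i = [], text.find(pattern)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def _candidate_starts(chrom_seq: str, read: str, max_mismatch: int) -> set[int]:
    """0-based candidate offsets via pigeonhole seeding: split the read into
    ``max_mismatch + 1`` segments; any placement within budget matches at
    least one segment exactly."""
    n, k = len(read), max_mismatch
    seg = n // (k + 1)
    starts: set[int] = set()
    for i in range(k + 1):
        lo = i * seg
        hi = n if i == k else (i + 1) * seg
        for occ in _occurrences(chrom_seq, read[lo:hi]):
            cand = occ - lo
            if 0 <= cand <= len(chrom_seq) - n:
                starts.add(cand)
    return starts


def _count_mismatches(a: str, b: str, budget: int) -> int | None:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return None
    return mm


def map_read(
    sequence: str,
    genome: Genome,
    max_mismatch: int = 1,
    pair_id: str = "",
    mate: int = 0,
) -> Alignment:
    """Place a read on the genome, requiring a single best placement.

    Evaluates both strands of every chromosome. Status is ``unique`` iff
    exactly one location attains the minimum mismatch count within
    ``max_mismatch``; tied minima give ``ambiguous``; no location within
    budget gives ``unmapped``.
    """
    if not sequence:
        raise ValueError("cannot map an empty read")
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    n = len(sequence)
    hits: list[tuple[str, int, str, int]] = []
    for chrom, chrom_seq in genome.sequences.items():
        if n > len(chrom_seq):
            continue
        for strand, query in (("+", sequence), ("-", revcomp(sequence))):
            for start0 in _candidate_starts(chrom_seq, query, max_mismatch):
                mm = _count_mismatches(
                    chrom_seq[start0 : start0 + n], query, max_mismatch
                )
                if mm is not None:
                    hits.append((chrom, start0 + 1, strand, mm))
    if not hits:
        return Alignment(pair_id, mate, None, 0, ".", -1, n, "unmapped")
    best = min(h[3] for h in hits)
    winners = [h for h in hits if h[3] == best]
    chrom, start, strand, mm = winners[0]
    status = "unique" if len(winners) == 1 else "ambiguous"
    return Alignment(pair_id, mate, chrom, start, strand, mm, n, status)


def filter_aligned_pairs(
    aligned: list[tuple[Alignment, Alignment]],
    max_span: int = 1000,
) -> list[tuple[Alignment, Alignment]]:
    """Keep pairs whose mates both map uniquely, to the same chromosome,
    within ``max_span`` bp end to end — the unambiguous-paired-mapping
    filter of the pipeline."""
    out = []
    for a1, a2 in aligned:
        if a1.status != "unique" or a2.status != "unique":
            continue
        if a1.chrom != a2.chrom:
            continue
        span = max(a1.end, a2.end) - min(a1.start, a2.start) + 1
        if span <= max_span:
            out.append((a1, a2))
    return out


def extract_junction_position(alignment: Alignment, trim_side: str = "3'") -> JunctionCandidate:
    """Genome base contiguous to the removed IR.

    With the IR trimmed from the 3' end, a forward-strand placement abuts
    the IR at its rightmost mapped base (start + length - 1); a
    reverse-strand placement abuts it at its leftmost base (start).
    """
    if alignment.status != "unique":
        raise ValueError("junction extraction requires a uniquely mapped read")
    if trim_side != "3'":
        raise ValueError("only 3'-trimmed junction mates are supported")
    if alignment.strand == "+":
        position = alignment.end
    else:
        position = alignment.start
    return JunctionCandidate(
        chrom=alignment.chrom,
        position=position,
        strand=alignment.strand,
        pair_id=alignment.pair_id,
    )
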