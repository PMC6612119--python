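"""PCR-duplicate removal, inverted-repeat trimming, and junction-pair selection.

A junction read carries the transposon's terminal inverted repeat (IR) at
its 3' end; removing the IR and everything downstream of it shortens the
read, and a trimmed length of at most L - L_IR (131 nt for a 151-nt read and
the 20-nt IR) flags the pair as covering a transposition event.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import IRMotif, ReadPair, READ_LENGTH


@dataclass(frozen=True)
class TrimmedRead:
    """One mate after IR trimming. ``trim_side`` is "3'" when a cut was made
    (the IR is only ever searched as a 3'-anchored adapter) and None
    otherwise; ``ir_found`` False implies the sequence is unchanged."""

    pair_id: str
    mate: int
    sequence: str
    quality: str
    original_length: int
    ir_found: bool
    trim_side: str | None

    @property
    def trimmed_length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class JunctionPair:
    """A selected pair with the indices of its junction mate(s)."""

    mate1: TrimmedRead
    mate2: TrimmedRead
    junction_mates: tuple[int, ...]


def remove_duplicate_pairs(pairs: list[ReadPair]) -> list[ReadPair]:
    """Keep one representative per distinct ordered (mate1, mate2) sequence
    tuple, preserving first-occurrence order (FastUniq-style; mate-swapped
    pairs count as distinct)."""
    seen: set[tuple[str, str]] = set()
    out = []
    for pair in pairs:
        key = (pair.seq1, pair.seq2)
        if key not in seen:
            seen.add(key)
            out.append(pair)
    return out


def _mismatches_at(seq: str, pattern: str, start: int, budget: int) -> int | None:
    """Mismatch count of ``pattern`` aligned at ``start``, or None if > budget."""
    mm = 0
    for a, b in zip(seq[start : start + len(pattern)], pattern):
        if a != b:
            mm += 1
            if mm > budget:
                return None
    return mm


def _find_cut(seq: str, motif: str, max_mismatch: int, min_prefix: int) -> int | None:
    """Leftmost cut point: a full-motif occurrence anywhere, else a
    3'-terminal occurrence of a motif prefix of length >= ``min_prefix``."""
    m = len(motif)
    if max_mismatch == 0:
        i = seq.find(motif)
        if i != -1:
            return i
    else:
        for i in range(len(seq) - m + 1):
            if _mismatches_at(seq, motif, i, max_mismatch) is not None:
                return i
    for plen in range(min(m - 1, len(seq)), min_prefix - 1, -1):
        start = len(seq) - plen
        if _mismatches_at(seq, motif[:plen], start, max_mismatch) is not None:
            return start
    return None


def trim_ir(
    sequence: str,
    motif: IRMotif = IRMotif(),
    max_mismatch: int = 0,
    pair_id: str = "",
    mate: int = 0,
    quality: str | None = None,
    min_prefix: int = 10,
) -> TrimmedRead:
    """Remove the IR motif and everything 3' of it from a read.

    The motif is located allowing up to ``max_mismatch`` substitutions,
    either in full anywhere in the read or as a 3'-terminal prefix of at
    least ``min_prefix`` nt (a read ending inside the IR). Cutting repeats
    until no match remains, which makes the operation idempotent. A read
    without any match is returned unchanged with ``ir_found=False``.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    quality = quality if quality is not None else "I" * len(sequence)
    seq, qual = sequence, quality
    found = False
    while True:
        cut = _find_cut(seq, motif.sequence, max_mismatch, min_prefix)
        if cut is None:
            break
        found = True
        seq, qual = seq[:cut], qual[:cut]
    return TrimmedRead(
        pair_id=pair_id,
        mate=mate,
        sequence=seq,
        quality=qual,
        original_length=len(sequence),
        ir_found=found,
        trim_side="3'" if found else None,
    )


def trim_pairs(
    pairs: list[ReadPair],
    motif: IRMotif = IRMotif(),
    max_mismatch: int = 0,
) -> list[tuple[TrimmedRead, TrimmedRead]]:
    """IR-trim both mates of every pair."""
    return [
        (
            trim_ir(p.seq1, motif, max_mismatch, p.pair_id, 1, p.qual1),
            trim_ir(p.seq2, motif, max_mismatch, p.pair_id, 2, p.qual2),
        )
        for p in pairs
    ]


def select_junction_pairs(
    trimmed: list[tuple[TrimmedRead, TrimmedRead]],
    read_length: int = READ_LENGTH,
    ir_length: int = IRMotif().length,
) -> list[JunctionPair]:
    """Keep pairs where at least one mate was IR-trimmed to at most
    ``read_length - ir_length`` nt — the signature of a read covering a
    transposition junction. Shorter partial-IR trims (length above the
    threshold) do not qualify."""
    if read_length <= ir_length:
        raise ValueError("read_length must exceed ir_length")
    threshold = read_length - ir_length
    out = []
    for t1, t2 in trimmed:
        junction = tuple(
            t.mate for t in (t1, t2) if t.ir_found and t.trimmed_length <= threshold
        )
        if junction:
            out.append(JunctionPair(t1, t2, junction))
    return out
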