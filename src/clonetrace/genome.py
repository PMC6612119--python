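"""Small in-memory genome container with FASTA round-trip.

Coordinates are 1-based inclusive everywhere in this package, matching the
convention of the insertion tables the pipeline produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A set of named chromosome sequences restricted to the ACGT alphabet.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to nucleotide string. Names are unique by
        construction (dict keys); sequences must be non-empty and contain
        only A/C/G/T.
    """

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            if not _ALPHABET.issuperset(seq):
                bad = sorted(set(seq) - _ALPHABET)
                raise ValueError(f"chromosome {name!r} contains non-ACGT symbols: {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of ``chrom`` from ``start`` to ``end``, 1-based inclusive."""
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start - 1 : end]

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(sequences)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")
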