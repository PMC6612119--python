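"""STR cell-line authentication by reference-anchored allele matching.

A profile maps each short-tandem-repeat locus to its set of allele labels
(kept verbatim as strings: "9.3", "x", ...). A sample is authenticated
against a reference database entry by counting, locus by locus, the
reference alleles the sample shares, over the total number of reference
alleles; the percent match is that fraction as a truncated whole-number
percentage (14/16 prints as 87%, not 88%).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class STRProfile:
    name: str
    loci: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for locus, alleles in self.loci.items():
            if not alleles:
                raise ValueError(f"profile {self.name!r}: empty allele set at {locus}")


@dataclass(frozen=True)
class MatchReport:
    """Shared-allele summary of a sample against a reference database entry."""

    sample: str
    reference: str
    shared: int
    db_total: int

    @property
    def percent(self) -> int:
        return (100 * self.shared) // self.db_total


def parse_profiles(source) -> list[STRProfile]:
    """Read a locus-by-profile TSV (first column: locus names; one column
    per profile; cells: comma-separated allele labels) into profiles.

    Allele strings are preserved verbatim. Duplicate locus rows and empty
    cells are rejected, naming the offending locus.
    """
    df = pd.read_csv(source, sep="\t", index_col=0, dtype=str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate locus rows: {sorted(set(dup))}")
    profiles = []
    for column in df.columns:
        loci: dict[str, frozenset[str]] = {}
        for locus, cell in df[column].items():
            if pd.isna(cell) or not str(cell).strip():
                raise ValueError(f"profile {column!r}: empty cell at locus {locus}")
            loci[locus] = frozenset(a.strip() for a in str(cell).split(","))
        profiles.append(STRProfile(name=column, loci=loci))
    return profiles


def match_profiles(sample: STRProfile, reference: STRProfile) -> MatchReport:
    """Count reference alleles shared with the sample.

    shared = sum over reference loci of |reference ∩ sample| at that locus;
    db_total = total reference alleles. Loci present only in the sample are
    ignored (the reference database defines the denominator).
    """
    common = set(sample.loci) & set(reference.loci)
    if not common:
        raise ValueError(
            f"profiles {sample.name!r} and {reference.name!r} share no loci"
        )
    shared = 0
    db_total = 0
    for locus, ref_alleles in reference.loci.items():
        db_total += len(ref_alleles)
        if locus in sample.loci:
            shared += len(ref_alleles & sample.loci[locus])
    return MatchReport(
        sample=sample.name, reference=reference.name, shared=shared, db_total=db_total
    )
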