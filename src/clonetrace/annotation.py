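"""Genomic feature model and GFF3 input/output.

Features are kept as a flat list: top-level features (``gene``, ``lncRNA``)
plus their ``exon`` children linked through ``parent``. Intron calls are
derived at annotation time as gene territory not covered by an exon.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils


@dataclass(frozen=True)
class AnnotationFeature:
    """One annotated interval, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    feature_type: str  # gene | lncRNA | exon
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.name!r}: start {self.start} > end {self.end}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


def write_gff3(path, chrom_lengths: dict[str, int], features: list[AnnotationFeature]) -> None:
    """Write features as GFF3, declaring every chromosome as a sequence-region."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for feat in features:
            attrs = [f"ID={feat.name}", f"Name={feat.name}"]
            if feat.parent:
                attrs.append(f"Parent={feat.parent}")
            fh.write(
                "\t".join(
                    [
                        feat.chrom,
                        "clonetrace",
                        feat.feature_type,
                        str(feat.start),
                        str(feat.end),
                        ".",
                        feat.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> tuple[list[AnnotationFeature], set[str]]:
    """Parse a GFF3 file into features plus the set of declared chromosomes.

    Chromosomes come from ``##sequence-region`` pragmas when present, and
    always include every chromosome that carries a feature.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[AnnotationFeature] = []
    chroms: set[str] = set()
    for f in db.all_features():
        chroms.add(f.seqid)
        parents = f.attributes.get("Parent", [])
        name = f.attributes.get("Name", f.attributes.get("ID", [f.id]))[0]
        features.append(
            AnnotationFeature(
                chrom=f.seqid,
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                name=name,
                feature_type=f.featuretype,
                parent=parents[0] if parents else None,
            )
        )
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                chroms.add(line.split()[1])
            elif not line.startswith("#"):
                break
    return features, chroms
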