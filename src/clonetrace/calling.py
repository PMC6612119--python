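"""Staggered-cut insertion calling and genomic-context annotation.

The PiggyBac transposase makes a staggered cut that duplicates d host bases
(d = 5), so a genuine insertion leaves junction evidence at two genome
positions, n and n + d. Positions supported by reads but lacking a partner
at distance d are endogenous-IR artefacts and are reported separately.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .annotation import AnnotationFeature
from .mapping import JunctionCandidate


@dataclass(frozen=True)
class AnnotationRow:
    """One genomic-context label for an event (an event overlapping stacked
    features carries several rows)."""

    name: str
    feature_type: str  # gene | lncRNA | Intergenic
    region: str  # Exon | Intron | Intergenic
    strand: str


@dataclass
class InsertionEvent:
    """A called integration site reported at posL = n and posR = n + d."""

    chrom: str
    posL: int
    posR: int
    strand: str
    support_L: int
    support_R: int
    annotations: list[AnnotationRow] = field(default_factory=list)


@dataclass(frozen=True)
class ArtefactSite:
    """A supported position with no partner at distance d (endogenous IR)."""

    chrom: str
    position: int
    support: int


def call_events(
    candidates: list[JunctionCandidate],
    d: int = 5,
    min_support: int = 1,
) -> tuple[list[InsertionEvent], list[ArtefactSite]]:
    """Aggregate junction candidates and call (n, n+d) position pairs.

    Candidates are pooled per (chromosome, position) across strands — the
    criterion is purely positional. Each pair of positions at distance d,
    both with at least ``min_support`` reads, becomes one event (greedy,
    left to right). Supported positions without a partner are returned as
    artefacts. The event strand is the majority strand of its supporting
    reads, ties resolved to "+".
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    support: Counter = Counter()
    strand_votes: defaultdict = defaultdict(Counter)
    for c in candidates:
        key = (c.chrom, c.position)
        support[key] += 1
        strand_votes[key][c.strand] += 1
    supported = sorted(k for k, v in support.items() if v >= min_support)
    supported_set = set(supported)
    events: list[InsertionEvent] = []
    used: set = set()
    for chrom, pos in supported:
        if (chrom, pos) in used:
            continue
        partner = (chrom, pos + d)
        if partner in supported_set and partner not in used:
            votes = strand_votes[(chrom, pos)] + strand_votes[partner]
            plus, minus = votes.get("+", 0), votes.get("-", 0)
            events.append(
                InsertionEvent(
                    chrom=chrom,
                    posL=pos,
                    posR=pos + d,
                    strand="-" if minus > plus else "+",
                    support_L=support[(chrom, pos)],
                    support_R=support[partner],
                )
            )
            used.update(((chrom, pos), partner))
    artefacts = [
        ArtefactSite(chrom, pos, support[(chrom, pos)])
        for chrom, pos in supported
        if (chrom, pos) not in used
    ]
    return events, artefacts


def annotate_events(
    events: list[InsertionEvent],
    features: list[AnnotationFeature],
    known_chroms: set[str] | None = None,
) -> list[InsertionEvent]:
    """Label each event with every overlapping top-level feature.

    An event inside a gene is "Exon" if it touches one of the gene's exons
    and "Intron" otherwise; an event overlapping no feature is "Intergenic".
    Stacked features (e.g. a gene and an lncRNA at the same locus) each
    produce one annotation row. Events on chromosomes unknown to the
    annotation raise, listing the unmatched names.
    """
    chroms = set(known_chroms or ()) | {f.chrom for f in features}
    unmatched = sorted({e.chrom for e in events} - chroms)
    if unmatched:
        raise ValueError(
            f"events on chromosomes absent from the annotation: {unmatched}"
        )
    top = [f for f in features if f.feature_type != "exon"]
    exons_by_parent: defaultdict = defaultdict(list)
    for f in features:
        if f.feature_type == "exon" and f.parent:
            exons_by_parent[f.parent].append(f)
    for event in events:
        rows: list[AnnotationRow] = []
        for feat in top:
            if feat.chrom == event.chrom and feat.overlaps(event.posL, event.posR):
                in_exon = any(
                    x.overlaps(event.posL, event.posR)
                    for x in exons_by_parent.get(feat.name, ())
                )
                rows.append(
                    AnnotationRow(
                        name=feat.name,
                        feature_type=feat.feature_type,
                        region="Exon" if in_exon else "Intron",
                        strand=feat.strand,
                    )
                )
        if not rows:
            rows.append(AnnotationRow("-", "Intergenic", "Intergenic", "."))
        event.annotations = rows
    return events


def events_to_frame(events: list[InsertionEvent], cell_line: str = "") -> pd.DataFrame:
    """Flatten events into the insertion-table layout (one row per
    annotation): cell line, chromosome, posL, posR, type, strand, name,
    relative location, support at each position."""
    rows = []
    for e in events:
        for a in e.annotations or [AnnotationRow("-", "Intergenic", "Intergenic", ".")]:
            rows.append(
                dict(
                    cell_line=cell_line,
                    chrom=e.chrom,
                    posL=e.posL,
                    posR=e.posR,
                    type=a.feature_type,
                    strand=a.strand,
                    name=a.name,
                    relative_location=a.region,
                    support_L=e.support_L,
                    support_R=e.support_R,
                )
            )
    columns = [
        "cell_line", "chrom", "posL", "posR", "type", "strand",
        "name", "relative_location", "support_L", "support_R",
    ]
    return pd.DataFrame(rows, columns=columns)


def artefacts_to_frame(artefacts: list[ArtefactSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(chrom=a.chrom, position=a.position, support=a.support) for a in artefacts],
        columns=["chrom", "position", "support"],
    )
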