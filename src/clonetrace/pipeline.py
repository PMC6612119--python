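"""End-to-end insertion calling: dedup -> trim -> select -> map -> filter ->
extract -> call -> annotate."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import AnnotationFeature, read_gff3
from .calling import (
    ArtefactSite,
    InsertionEvent,
    annotate_events,
    artefacts_to_frame,
    call_events,
    events_to_frame,
)
from .genome import Genome
from .mapping import extract_junction_position, filter_aligned_pairs, map_read
from .preprocess import remove_duplicate_pairs, select_junction_pairs, trim_pairs
from .simulate import IRMotif, ReadPair, READ_LENGTH, read_fastq_pairs


@dataclass
class PipelineResult:
    events: list[InsertionEvent]
    artefacts: list[ArtefactSite]
    log: dict = field(default_factory=dict)

    def events_frame(self, cell_line: str = "") -> pd.DataFrame:
        return events_to_frame(self.events, cell_line)

    def artefacts_frame(self) -> pd.DataFrame:
        return artefacts_to_frame(self.artefacts)


def call_insertions(
    pairs: list[ReadPair],
    genome: Genome,
    features: list[AnnotationFeature] | None = None,
    known_chroms: set[str] | None = None,
    offset: int = 5,
    min_support: int = 1,
    max_mismatch: int = 1,
    max_span: int = 1000,
    motif: IRMotif = IRMotif(),
    read_length: int = READ_LENGTH,
    trim_max_mismatch: int = 0,
) -> PipelineResult:
    """Run the full calling pipeline on in-memory read pairs.

    Stages: remove PCR duplicates; trim the IR from both mates; select pairs
    with a junction mate (trimmed length <= read_length - IR length); map
    both mates, keeping unambiguous same-chromosome pairs within
    ``max_span``; extract the IR-adjacent genome position of each junction
    mate; call (n, n+offset) events with at least ``min_support`` reads per
    position; annotate against ``features`` when provided.
    """
    log: dict = {"input_pairs": len(pairs)}
    stage = "dedup"
    try:
        deduped = remove_duplicate_pairs(pairs)
        log["after_dedup"] = len(deduped)

        stage = "trim"
        trimmed = trim_pairs(deduped, motif, trim_max_mismatch)

        stage = "select"
        selected = select_junction_pairs(trimmed, read_length, motif.length)
        log["junction_pairs"] = len(selected)

        stage = "map"
        candidates = []
        kept_pairs = 0
        for jp in selected:
            alignments = tuple(
                map_read(t.sequence, genome, max_mismatch, t.pair_id, t.mate)
                for t in (jp.mate1, jp.mate2)
                if t.sequence
            )
            if len(alignments) != 2:
                continue
            stage = "filter"
            kept = filter_aligned_pairs([alignments], max_span)
            if not kept:
                continue
            kept_pairs += 1
            stage = "extract"
            for a in kept[0]:
                if a.mate in jp.junction_mates:
                    candidates.append(extract_junction_position(a))
            stage = "map"
        log["mapped_pairs"] = kept_pairs
        log["junction_candidates"] = len(candidates)

        stage = "call"
        events, artefacts = call_events(candidates, offset, min_support)
        log["events"] = len(events)
        log["artefacts"] = len(artefacts)

        if features is not None:
            stage = "annotate"
            annotate_events(events, features, known_chroms)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {log}") from exc
    return PipelineResult(events=events, artefacts=artefacts, log=log)


def run_pipeline(
    fastq1,
    fastq2,
    genome_fasta,
    annotation_gff3=None,
    outdir=None,
    cell_line: str = "",
    **kwargs,
) -> PipelineResult:
    """File-level wrapper: FASTQ pair + FASTA genome (+ optional GFF3) in,
    insertion/artefact tables (optionally written as TSV) out."""
    pairs = read_fastq_pairs(fastq1, fastq2)
    genome = Genome.from_fasta(genome_fasta)
    features = known = None
    if annotation_gff3 is not None:
        features, known = read_gff3(annotation_gff3)
    result = call_insertions(pairs, genome, features, known, **kwargs)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.events_frame(cell_line).to_csv(
            outdir / "events.tsv", sep="\t", index=False
        )
        result.artefacts_frame().to_csv(
            outdir / "artefacts.tsv", sep="\t", index=False
        )
        pd.Series(result.log).to_csv(outdir / "pipeline_log.tsv", sep="\t", header=False)
    return result
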