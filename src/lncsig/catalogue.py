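"""Classify candidate transcripts against a reference annotation.

A candidate reconstructed transcript of spliced length >= ``min_length``
is called intergenic (MLINC) when it overlaps no annotated transcript by
``min_overlap`` bp or more on either strand, antisense-overlapping
(MLOANC) when every overlap is on the opposite strand, and an annotated
sense overlap otherwise. Shorter reconstructions are set aside as
TOO_SHORT and unstranded overlapping candidates get a dedicated class,
because an antisense call requires a strand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

from .refmodel import (
    STRAND_MINUS,
    STRAND_PLUS,
    STRAND_UNKNOWN,
    AnnotationSet,
    GenomeSequence,
    TranscriptModel,
    spliced_sequence,
)

logger = logging.getLogger(__name__)


class CandidateClass(Enum):
    MLINC = "MLINC"
    MLOANC = "MLOANC"
    ANNOTATED_SENSE_OVERLAP = "ANNOTATED_SENSE_OVERLAP"
    TOO_SHORT = "TOO_SHORT"
    UNSTRANDED_OVERLAP = "UNSTRANDED_OVERLAP"


@dataclass
class ClassifyParams:
    """Thresholds of the classification rules.

    min_length: minimum spliced length in nt to be considered (default 200).
    overlap_level: compare candidate/reference at "transcript-span" level
        (introns included) or exon level.
    min_overlap: minimum shared bp for two intervals to count as
        overlapping (default 1).
    """

    min_length: int = 200
    overlap_level: str = "transcript-span"
    min_overlap: int = 1

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.overlap_level not in ("transcript-span", "exon"):
            raise ValueError(f"bad overlap_level {self.overlap_level!r}")


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0])


def _overlap_bp(
    candidate: TranscriptModel, reference: TranscriptModel, level: str
) -> int:
    """Maximum pairwise interval overlap at the chosen feature level."""
    if level == "transcript-span":
        return _interval_overlap(candidate.span, reference.span)
    best = 0
    for ce in candidate.exons:
        for re_ in reference.exons:
            best = max(best, _interval_overlap(ce, re_))
    return best


def classify_transcripts(
    candidates: AnnotationSet,
    reference: AnnotationSet,
    params: ClassifyParams | None = None,
) -> dict[str, CandidateClass]:
    """Assign exactly one :class:`CandidateClass` per candidate.

    Candidates on contigs absent from the reference namespace are
    classified with an empty overlap set (logged as a warning).
    Unknown-strand reference transcripts are treated as same-strand,
    so overlapping candidates are conservatively excluded from the
    antisense class.
    """
    params = params or ClassifyParams()
    ref_contigs = reference.contigs()
    result: dict[str, CandidateClass] = {}
    for cand in candidates:
        if cand.spliced_length < params.min_length:
            result[cand.transcript_id] = CandidateClass.TOO_SHORT
            continue
        if cand.contig not in ref_contigs:
            logger.warning(
                "candidate %s on contig %s absent from reference; "
                "classified with empty overlap set",
                cand.transcript_id,
                cand.contig,
            )
        start, end = cand.span
        overlapping = [
            ref
            for ref in reference.overlapping(cand.contig, start, end)
            if _overlap_bp(cand, ref, params.overlap_level) >= params.min_overlap
        ]
        if not overlapping:
            result[cand.transcript_id] = CandidateClass.MLINC
        elif cand.strand == STRAND_UNKNOWN:
            result[cand.transcript_id] = CandidateClass.UNSTRANDED_OVERLAP
        elif any(
            ref.strand == cand.strand or ref.strand == STRAND_UNKNOWN
            for ref in overlapping
        ):
            result[cand.transcript_id] = CandidateClass.ANNOTATED_SENSE_OVERLAP
        else:
            result[cand.transcript_id] = CandidateClass.MLOANC
    return result


def gc_fraction(seq: str) -> float:
    """(G+C) / (A+C+G+T); Ns excluded from the denominator.

    An all-N sequence returns NaN; an empty string is a domain error.
    """
    if not seq:
        raise ValueError("gc_fraction of empty sequence")
    gc = sum(seq.count(b) for b in "GC")
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return math.nan
    return gc / acgt


@dataclass
class CatalogueSummary:
    """Per-class distributional summaries of a candidate catalogue."""

    class_counts: dict[str, int]
    spliced_lengths: dict[str, list[int]]
    exon_lengths: dict[str, list[int]]
    gc_fractions: dict[str, list[float]]
    mono_exonic_fraction: dict[str, float]
    multi_isoform_fraction: float


def summarize_catalogue(
    candidates: AnnotationSet,
    classes: dict[str, CandidateClass],
    genome: GenomeSequence,
) -> CatalogueSummary:
    """Length / exon-length / GC / mono-exonic / isoform summaries."""
    missing = set(t.transcript_id for t in candidates) - set(classes)
    if missing:
        raise ValueError(f"classes missing for {len(missing)} candidates")
    counts: dict[str, int] = {}
    lengths: dict[str, list[int]] = {}
    exon_lengths: dict[str, list[int]] = {}
    gcs: dict[str, list[float]] = {}
    mono: dict[str, list[bool]] = {}
    for cand in candidates:
        cls = classes[cand.transcript_id].value
        counts[cls] = counts.get(cls, 0) + 1
        lengths.setdefault(cls, []).append(cand.spliced_length)
        exon_lengths.setdefault(cls, []).extend(e - s for s, e in cand.exons)
        gcs.setdefault(cls, []).append(gc_fraction(spliced_sequence(cand, genome)))
        mono.setdefault(cls, []).append(cand.n_exons == 1)
    mono_frac = {cls: sum(v) / len(v) for cls, v in mono.items()}
    n_genes = len(candidates.genes)
    n_multi = sum(1 for tids in candidates.genes.values() if len(tids) > 1)
    return CatalogueSummary(
        class_counts=counts,
        spliced_lengths=lengths,
        exon_lengths=exon_lengths,
        gc_fractions=gcs,
        mono_exonic_fraction=mono_frac,
        multi_isoform_fraction=n_multi / n_genes if n_genes else 0.0,
    )


def catalogue_table(
    candidates: AnnotationSet,
    classes: dict[str, CandidateClass],
    genome: GenomeSequence,
) -> list[dict[str, object]]:
    """Per-candidate rows for the classification TSV output."""
    rows = []
    for cand in sorted(
        candidates, key=lambda t: (t.contig, t.span[0], t.transcript_id)
    ):
        gc = gc_fraction(spliced_sequence(cand, genome))
        rows.append(
            {
                "transcript_id": cand.transcript_id,
                "gene_id": cand.gene_id,
                "class": classes[cand.transcript_id].value,
                "spliced_length": cand.spliced_length,
                "n_exons": cand.n_exons,
                "gc": f"{gc:.4f}" if not math.isnan(gc) else "NA",
            }
        )
    return rows
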