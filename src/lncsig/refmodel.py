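"""Coordinate and sequence model shared by every pipeline stage.

Internal convention: 0-based, half-open intervals on uppercase sequences.
GTF input/output converts at the boundary (GTF is 1-based, inclusive).
Strand ``.`` is carried through as :data:`STRAND_UNKNOWN`, never coerced.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from intervaltree import IntervalTree

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_UNKNOWN = "unknown"

_VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Named nucleotide sequences, uppercase, alphabet A/C/G/T/N."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise FormatError("empty contig name")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript on one contig.

    Exons are 0-based half-open intervals, sorted by start and
    pairwise non-overlapping.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    source_class: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in (STRAND_PLUS, STRAND_MINUS, STRAND_UNKNOWN):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        self.exons = sorted(self.exons)
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon ({start},{end}) empty"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


class AnnotationSet:
    """A collection of transcripts with per-contig interval indices.

    Overlap queries return exactly the transcripts whose *span*
    intersects the query interval (equivalent to a linear scan).
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, list[str]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
            self.transcripts[t.transcript_id] = t
            self.genes.setdefault(t.gene_id, []).append(t.transcript_id)
            start, end = t.span
            self._trees.setdefault(t.contig, IntervalTree()).addi(
                start, end, t.transcript_id
            )

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def overlapping(self, contig: str, start: int, end: int) -> list[TranscriptModel]:
        """Transcripts whose span intersects [start, end) on ``contig``."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = tree.overlap(start, end)
        return [self.transcripts[iv.data] for iv in hits]

    def contigs(self) -> set[str]:
        return set(self._trees)


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a multi-record FASTA into memory, uppercased.

    The contig name is the header token before the first whitespace.
    Duplicate names and empty records raise :class:`FormatError`.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    with open(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if not name:
                raise FormatError(f"{path}: record with empty header")
            if name in contigs:
                raise FormatError(f"{path}: duplicate contig name {name!r}")
            seq = str(record.seq).upper()
            if not seq:
                raise FormatError(f"{path}: contig {name!r} has an empty sequence")
            contigs[name] = seq
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSequence(contigs)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(
    path: str | Path, feature_filter: set[str] = frozenset({"exon"})
) -> AnnotationSet:
    """Read an Ensembl-dialect GTF, grouping exon rows into transcripts.

    Coordinates are converted from 1-based inclusive to 0-based
    half-open at this boundary; strand ``.`` becomes unknown.
    """
    path = Path(path)
    exons: dict[str, dict] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            contig, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in feature_filter:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            attributes = _parse_attributes(attrs)
            tid = attributes.get("transcript_id")
            if not tid:
                raise FormatError(f"{path}:{lineno}: exon missing transcript_id")
            gid = attributes.get("gene_id")
            if not gid:
                raise FormatError(f"{path}:{lineno}: exon missing gene_id")
            st = strand if strand in (STRAND_PLUS, STRAND_MINUS) else STRAND_UNKNOWN
            rec = exons.setdefault(
                tid, {"gene_id": gid, "contig": contig, "strand": st, "exons": []}
            )
            if rec["contig"] != contig:
                raise FormatError(f"{path}:{lineno}: transcript {tid} spans contigs")
            rec["exons"].append((start1 - 1, end1))
    models = [
        TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            contig=rec["contig"],
            strand=rec["strand"],
            exons=rec["exons"],
        )
        for tid, rec in exons.items()
    ]
    return AnnotationSet(models)


def write_gtf(annotation: AnnotationSet, path: str | Path, source: str = "lncsig") -> None:
    """Write exon rows in GTF (1-based inclusive), deterministic order."""
    order = sorted(
        annotation, key=lambda t: (t.contig, t.span[0], t.transcript_id)
    )
    with open(path, "w") as out:
        for t in order:
            strand = t.strand if t.strand != STRAND_UNKNOWN else "."
            for start, end in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                out.write(
                    f"{t.contig}\t{source}\texon\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
                )


def spliced_sequence(t: TranscriptModel, genome: GenomeSequence) -> str:
    """Concatenated exon sequence, reverse-complemented on the minus strand.

    Unknown strand yields the forward orientation (caller may warn).
    """
    contig_seq = genome[t.contig]
    for start, end in t.exons:
        if end > len(contig_seq) or start < 0:
            raise ValueError(
                f"transcript {t.transcript_id}: exon ({start},{end}) exceeds "
                f"contig {t.contig} length {len(contig_seq)}"
            )
    seq = "".join(contig_seq[s:e] for s, e in t.exons)
    if t.strand == STRAND_MINUS:
        seq = reverse_complement(seq)
    return seq


def write_tsv(
    records: Sequence[Mapping[str, object]], path: str | Path, columns: Sequence[str]
) -> None:
    """Header + rows, tab-separated. Empty record list writes header only."""
    with open(path, "w") as out:
        out.write("\t".join(columns) + "\n")
        for rec in records:
            out.write("\t".join(str(rec[c]) for c in columns) + "\n")


def write_bed(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """BED6 of transcript spans; rows ordered by (contig, start, id)."""
    rows = sorted(transcripts, key=lambda t: (t.contig, t.span[0], t.transcript_id))
    with open(path, "w") as out:
        for t in rows:
            start, end = t.span
            strand = t.strand if t.strand != STRAND_UNKNOWN else "."
            out.write(f"{t.contig}\t{start}\t{end}\t{t.transcript_id}\t0\t{strand}\n")
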