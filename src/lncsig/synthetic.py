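"""Deterministic synthetic fixtures with recorded ground truth.

Every generator is a pure function of (seed, parameters) and emits its
planted truth alongside the fixture, so the whole pipeline — transcript
classification, signature extraction, FASTQ quantification, feature
selection and single-cell marker calling — is testable without any
external download. Background sequence is i.i.d. uniform A/C/G/T: at
k = 31 and fixture sizes well below a megabase, accidental k-mer
collisions are vanishingly improbable, so planted-uniqueness oracles
are stable. Read errors are substitutions only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .refmodel import (
    STRAND_MINUS,
    STRAND_PLUS,
    AnnotationSet,
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
    spliced_sequence,
)
from .select import ExpressionMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a fixture."""

    seed: int
    classes: dict[str, str] = field(default_factory=dict)
    gene_spans: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    abundances: dict[str, float] = field(default_factory=dict)
    marker_features: list[str] = field(default_factory=list)
    cell_labels: pd.Series | None = None


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_reference(
    seed: int = 0,
    n_contigs: int = 1,
    contig_length: int = 50_000,
    n_genes: int = 10,
    exons_per_gene: tuple[int, int] = (1, 3),
    exon_length: tuple[int, int] = (150, 400),
    intron_length: tuple[int, int] = (60, 200),
    minus_strand_fraction: float = 0.5,
    min_gap: int = 600,
) -> tuple[GenomeSequence, AnnotationSet, SyntheticTruth]:
    """Uniform-background genome with non-overlapping genes on both strands.

    Genes are laid out left to right with at least ``min_gap`` bp
    between genomic spans, leaving room to plant intergenic candidates
    later. Raises when the requested genes cannot be packed.
    """
    rng = np.random.default_rng(seed)
    contigs = {
        f"chr{i + 1}": _random_sequence(rng, contig_length) for i in range(n_contigs)
    }
    truth = SyntheticTruth(seed=seed)
    transcripts = []
    per_contig = [n_genes // n_contigs] * n_contigs
    for i in range(n_genes % n_contigs):
        per_contig[i] += 1
    gene_no = 0
    for ci, (contig, n_here) in enumerate(zip(contigs, per_contig)):
        cursor = min_gap
        for _ in range(n_here):
            gene_no += 1
            n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
            exons = []
            pos = cursor
            for e in range(n_exons):
                elen = int(rng.integers(exon_length[0], exon_length[1] + 1))
                exons.append((pos, pos + elen))
                pos += elen
                if e < n_exons - 1:
                    pos += int(rng.integers(intron_length[0], intron_length[1] + 1))
            if pos + min_gap > contig_length:
                raise ValueError(
                    f"cannot pack {n_genes} genes into {n_contigs} x "
                    f"{contig_length} bp contigs"
                )
            strand = STRAND_MINUS if rng.random() < minus_strand_fraction else STRAND_PLUS
            gid = f"GENE{gene_no:04d}"
            tid = f"{gid}.1"
            transcripts.append(
                TranscriptModel(tid, gid, contig, strand, exons)
            )
            truth.gene_spans[gid] = (contig, exons[0][0], exons[-1][1], strand)
            cursor = pos + min_gap
    genome = GenomeSequence(contigs)
    return genome, AnnotationSet(transcripts), truth


def _free_intervals(
    contig_length: int, occupied: Sequence[tuple[int, int]], margin: int = 2
) -> list[tuple[int, int]]:
    """Complement of occupied spans, shrunk by ``margin`` on each side."""
    free = []
    pos = 0
    for start, end in sorted(occupied):
        if start - pos > 2 * margin:
            free.append((pos + margin, start - margin))
        pos = max(pos, end)
    if contig_length - pos > 2 * margin:
        free.append((pos + margin, contig_length - margin))
    return free


def plant_candidates(
    genome: GenomeSequence,
    reference: AnnotationSet,
    truth: SyntheticTruth,
    n_mlinc: int = 4,
    n_mloanc: int = 2,
    n_sense_overlap: int = 2,
    n_short: int = 2,
    mlinc_length: tuple[int, int] = (250, 600),
    short_length: tuple[int, int] = (80, 150),
    seed: int | None = None,
) -> tuple[AnnotationSet, SyntheticTruth]:
    """Plant candidate transcripts of each class and record true labels.

    Intergenic candidates sit at least 1 bp clear of every annotated
    span; antisense candidates sit inside a gene span on the opposite
    strand; sense overlaps share the host gene's strand; short
    candidates have spliced length under 200 nt.
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    spans_by_contig: dict[str, list[tuple[int, int]]] = {}
    for t in reference:
        spans_by_contig.setdefault(t.contig, []).append(t.span)

    free_by_contig = {
        contig: _free_intervals(len(genome[contig]), spans)
        for contig, spans in spans_by_contig.items()
    }

    candidates: list[TranscriptModel] = []
    counter = 0

    def take_free_slot(length: int) -> tuple[str, int]:
        for contig, free in free_by_contig.items():
            for i, (start, end) in enumerate(free):
                if end - start >= length:
                    pos = start
                    free[i] = (start + length + 2, end)
                    return contig, pos
        raise ValueError("no free interval large enough to plant candidate")

    def new_id(prefix: str) -> tuple[str, str]:
        nonlocal counter
        counter += 1
        return f"CAND.{counter}.1", f"CAND.{counter}"

    for _ in range(n_mlinc):
        length = int(rng.integers(*mlinc_length))
        contig, pos = take_free_slot(length)
        tid, gid = new_id("mlinc")
        strand = STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
        candidates.append(TranscriptModel(tid, gid, contig, strand, [(pos, pos + length)]))
        truth.classes[tid] = "MLINC"

    for _ in range(n_short):
        length = int(rng.integers(*short_length))
        contig, pos = take_free_slot(length)
        tid, gid = new_id("short")
        candidates.append(TranscriptModel(tid, gid, contig, STRAND_PLUS, [(pos, pos + length)]))
        truth.classes[tid] = "TOO_SHORT"

    host_genes = sorted(
        (t for t in reference if t.span[1] - t.span[0] >= 260),
        key=lambda t: t.transcript_id,
    )
    if len(host_genes) < n_mloanc + n_sense_overlap:
        raise ValueError("not enough wide reference genes to host overlap candidates")
    hosts = list(rng.permutation(len(host_genes)))

    for j in range(n_mloanc):
        host = host_genes[hosts[j]]
        start, end = host.span
        length = min(int(rng.integers(*mlinc_length)), end - start - 20)
        pos = start + 10
        tid, gid = new_id("mloanc")
        strand = STRAND_MINUS if host.strand == STRAND_PLUS else STRAND_PLUS
        candidates.append(TranscriptModel(tid, gid, host.contig, strand, [(pos, pos + length)]))
        truth.classes[tid] = "MLOANC"

    for j in range(n_mloanc, n_mloanc + n_sense_overlap):
        host = host_genes[hosts[j]]
        start, end = host.span
        length = min(int(rng.integers(*mlinc_length)), end - start - 20)
        pos = start + 10
        tid, gid = new_id("sense")
        candidates.append(
            TranscriptModel(tid, gid, host.contig, host.strand, [(pos, pos + length)])
        )
        truth.classes[tid] = "ANNOTATED_SENSE_OVERLAP"

    return AnnotationSet(candidates), truth


def simulate_reads(
    genome: GenomeSequence,
    transcripts: AnnotationSet,
    abundance: Mapping[str, float],
    n_reads: int = 10_000,
    read_length: int = 80,
    error_rate: float = 0.0,
    orientation: str = "unstranded",
    seed: int = 0,
    paired: bool = False,
) -> list[str] | tuple[list[str], list[str]]:
    """Draw error-free or substitution-noised reads from transcripts.

    A read's source transcript is chosen proportionally to
    abundance x (spliced_length - read_length + 1); its start is
    uniform over valid windows. Orientation "stranded" emits the
    transcript's sense sequence; "unstranded" flips a fair coin per
    read. Transcripts shorter than the read length are excluded with a
    warning. Paired mode returns (R1, R2) with R2 the reverse
    complement of R1 (fully-overlapping mates).
    """
    if orientation not in ("stranded", "unstranded"):
        raise ValueError(f"bad orientation {orientation!r}")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    weights: list[float] = []
    for tid, ab in sorted(abundance.items()):
        if ab < 0:
            raise ValueError("negative abundance")
        if ab == 0:
            continue
        seq = spliced_sequence(transcripts[tid], genome)
        if len(seq) < read_length:
            import logging

            logging.getLogger(__name__).warning(
                "transcript %s shorter than read length; excluded", tid
            )
            continue
        seqs.append(seq)
        weights.append(ab * (len(seq) - read_length + 1))
    if not seqs:
        raise ValueError("no transcript is long enough / abundant enough to sample")
    w = np.array(weights) / sum(weights)
    reads: list[str] = []
    choices = rng.choice(len(seqs), size=n_reads, p=w)
    for c in choices:
        seq = seqs[c]
        start = int(rng.integers(0, len(seq) - read_length + 1))
        read = seq[start : start + read_length]
        if orientation == "unstranded" and rng.random() < 0.5:
            read = reverse_complement(read)
        if error_rate > 0:
            arr = list(read)
            for i in range(len(arr)):
                if rng.random() < error_rate:
                    arr[i] = str(rng.choice([b for b in "ACGT" if b != arr[i]]))
            read = "".join(arr)
        reads.append(read)
    if paired:
        return reads, [reverse_complement(r) for r in reads]
    return reads


def write_fastq(reads: Sequence[str], path: str | Path, sample_id: str = "read") -> None:
    """Write 4-line FASTQ records; .gz paths are gzipped with mtime 0
    so reruns are byte-identical."""
    path = Path(path)
    if path.suffix == ".gz":
        raw = open(path, "wb")
        handle = gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0)
        out = handle
        try:
            for i, read in enumerate(reads, 1):
                out.write(f"@{sample_id}.{i}\n{read}\n+\n{'I' * len(read)}\n".encode())
        finally:
            handle.close()
            raw.close()
    else:
        with open(path, "w") as out:
            for i, read in enumerate(reads, 1):
                out.write(f"@{sample_id}.{i}\n{read}\n+\n{'I' * len(read)}\n")


def simulate_feature_matrix(
    n_per_group: int = 100,
    n_informative: int = 20,
    n_noise: int = 180,
    effect_sd: float = 2.0,
    seed: int = 0,
    base_log2: float = 5.0,
    noise_sd: float = 1.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Group-structured abundance matrix with planted informative features.

    Values are 2**N(base_log2, noise_sd); informative features are
    shifted by effect_sd x noise_sd on the log2 scale in the target
    group. effect_sd = 0 yields a global-null matrix.
    """
    if n_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)
    n_features = n_informative + n_noise
    n_samples = 2 * n_per_group
    log2x = rng.normal(base_log2, noise_sd, size=(n_features, n_samples))
    log2x[:n_informative, :n_per_group] += effect_sd * noise_sd
    values = 2.0 ** log2x
    features = [f"INFO{i + 1:03d}" for i in range(n_informative)] + [
        f"NOISE{i + 1:03d}" for i in range(n_noise)
    ]
    samples = [f"T{i + 1:03d}" for i in range(n_per_group)] + [
        f"R{i + 1:03d}" for i in range(n_per_group)
    ]
    groups = {s: ("target" if s.startswith("T") else "rest") for s in samples}
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), groups, "target"
    )
    truth = SyntheticTruth(seed=seed, marker_features=features[:n_informative])
    return matrix, truth


def simulate_cells(
    n_cells: int = 500,
    n_genes: int = 50,
    marker_gene: str = "MARKER",
    positive_fraction: float = 0.4,
    n_de_genes: int = 5,
    effect_fold: float = 4.0,
    seed: int = 0,
    base_mean: float = 5.0,
    dispersion: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Cell x gene negative-binomial counts with a marker-positive subpopulation.

    The marker gene is expressed mainly in the positive subpopulation;
    ``n_de_genes`` further genes are shifted ``effect_fold``-fold there.
    Returns (raw counts, scaled matrix, truth). The scaled matrix is the
    per-gene z-score of ln(1 + count), the usual input of
    positive-cell thresholding.
    """
    if not 0 < positive_fraction < 1:
        raise ValueError("positive_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    genes = [marker_gene] + [f"DE{i + 1:02d}" for i in range(n_de_genes)] + [
        f"BG{i + 1:03d}" for i in range(n_genes - 1 - n_de_genes)
    ]
    n_pos = int(round(positive_fraction * n_cells))
    positive = np.zeros(n_cells, dtype=bool)
    positive[:n_pos] = True
    positive = positive[rng.permutation(n_cells)]

    mean = np.full((n_cells, len(genes)), base_mean)
    mean[positive, 0] *= effect_fold * 2  # marker gene: strongly on in positives
    mean[~positive, 0] *= 0.05
    for j in range(1, 1 + n_de_genes):
        mean[positive, j] *= effect_fold
    # NB parametrisation: variance = mu + mu^2 / dispersion
    r = dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)
    raw = pd.DataFrame(
        counts, index=[f"cell{i + 1:04d}" for i in range(n_cells)], columns=genes
    )
    log = np.log1p(raw.values.astype(float))
    mu = log.mean(axis=0)
    sd = log.std(axis=0)
    sd[sd == 0] = 1.0
    scaled = pd.DataFrame((log - mu) / sd, index=raw.index, columns=raw.columns)
    truth = SyntheticTruth(
        seed=seed,
        marker_features=genes[1 : 1 + n_de_genes],
        cell_labels=pd.Series(positive, index=raw.index),
    )
    return raw, scaled, truth
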