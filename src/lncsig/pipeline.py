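"""End-to-end orchestration: classify -> signatures -> quantify -> select.

Glue used by both the command-line interface and the reproduction
script. Each stage is the corresponding module's public API; this file
only wires them together on in-memory objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import catalogue, quant, select, signature, synthetic
from .refmodel import AnnotationSet, GenomeSequence, spliced_sequence


@dataclass
class PipelineFixture:
    """The default synthetic study: genome, annotation, planted candidates
    and group-structured per-sample reads."""

    genome: GenomeSequence
    reference: AnnotationSet
    candidates: AnnotationSet
    truth: synthetic.SyntheticTruth
    sample_reads: dict[str, list[str]]
    groups: dict[str, str]
    abundances: dict[str, dict[str, float]]  # group -> transcript -> molar abundance


def default_fixture(
    seed: int = 0,
    n_target: int = 8,
    n_rest: int = 8,
    reads_per_sample: int = 2000,
    read_length: int = 80,
    mlinc_target_abundance: float = 8.0,
    sample_jitter_sd: float = 0.2,
) -> PipelineFixture:
    """Build the default synthetic marker-discovery study.

    Planted intergenic candidates are expressed only in the target
    group; antisense candidates and annotated genes are expressed
    equally in both groups, so selection should confirm exactly the
    intergenic set. Per-sample molar abundances get multiplicative
    log-normal jitter to emulate biological replicates.
    """
    genome, reference, truth = synthetic.simulate_reference(
        seed=seed, n_contigs=1, contig_length=60_000, n_genes=8
    )
    candidates, truth = synthetic.plant_candidates(
        genome, reference, truth, n_mlinc=4, n_mloanc=2, n_sense_overlap=2, n_short=2
    )
    mlincs = sorted(t for t, c in truth.classes.items() if c == "MLINC")
    mloancs = sorted(t for t, c in truth.classes.items() if c == "MLOANC")

    merged = AnnotationSet(list(reference) + list(candidates))
    base: dict[str, float] = {t.transcript_id: 1.0 for t in reference}
    for tid in mloancs:
        base[tid] = 1.0
    abundances = {
        "target": {**base, **{tid: mlinc_target_abundance for tid in mlincs}},
        "rest": {**base, **{tid: 0.0 for tid in mlincs}},
    }

    rng = np.random.default_rng(seed + 17)
    sample_reads: dict[str, list[str]] = {}
    groups: dict[str, str] = {}
    for group, n in (("target", n_target), ("rest", n_rest)):
        for i in range(n):
            sample = f"{group}{i + 1:02d}"
            groups[sample] = group
            jitter = {
                tid: ab * float(np.exp(rng.normal(0.0, sample_jitter_sd)))
                for tid, ab in abundances[group].items()
            }
            reads = synthetic.simulate_reads(
                genome,
                merged,
                jitter,
                n_reads=reads_per_sample,
                read_length=read_length,
                orientation="unstranded",
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sample_reads[sample] = reads
    return PipelineFixture(
        genome=genome,
        reference=reference,
        candidates=candidates,
        truth=truth,
        sample_reads=sample_reads,
        groups=groups,
        abundances=abundances,
    )


def candidate_signatures(
    genome: GenomeSequence,
    reference: AnnotationSet,
    candidates: AnnotationSet,
    classes: Mapping[str, catalogue.CandidateClass],
    params: signature.SignatureParams | None = None,
    novel_classes: Sequence[str] = ("MLINC", "MLOANC"),
) -> list[signature.KmerSignature]:
    """Extract unannotated-mode signatures for every novel candidate.

    The genome index covers the genome contigs; the transcriptome index
    covers the spliced reference transcripts.
    """
    params = params or signature.SignatureParams()
    genome_idx = signature.build_kmer_index(genome.contigs, params, "genome")
    tx_seqs = {t.transcript_id: spliced_sequence(t, genome) for t in reference}
    gene_of = {t.transcript_id: t.gene_id for t in reference}
    tx_idx = signature.build_kmer_index(tx_seqs, params, "transcriptome", gene_of=gene_of)
    sigs = []
    for cand in sorted(candidates, key=lambda t: t.transcript_id):
        cls = classes[cand.transcript_id]
        name = cls.value if hasattr(cls, "value") else str(cls)
        if name not in novel_classes:
            continue
        seq = spliced_sequence(cand, genome)
        sigs.append(
            signature.extract_specific_kmers(
                seq,
                cand.transcript_id,
                cand.gene_id,
                genome_idx,
                tx_idx,
                mode="unannotated",
                params=params,
            )
        )
    return sigs


def quantify_samples(
    signatures: Sequence[signature.KmerSignature],
    sample_reads: Mapping[str, Sequence[str]],
    k: int,
    orientation: str = "canonical",
    scheme: str = "kpm",
    tmpdir=None,
) -> pd.DataFrame:
    """kpm matrix (candidates x samples) from in-memory reads.

    Reads are round-tripped through on-disk FASTQ when ``tmpdir`` is
    given (exercising the streaming path); otherwise counted via a
    temporary in-memory FASTQ-formatted buffer on disk-free path.
    """
    import logging
    import tempfile
    from pathlib import Path

    empty = [s.candidate_id for s in signatures if s.size == 0]
    if empty:
        logging.getLogger(__name__).warning(
            "candidates with empty signatures cannot be quantified: %s", empty
        )
        signatures = [s for s in signatures if s.size > 0]
    if not signatures:
        raise ValueError("no candidate has a non-empty signature")
    results = []
    with tempfile.TemporaryDirectory() as td:
        base = Path(tmpdir) if tmpdir is not None else Path(td)
        for sample, reads in sorted(sample_reads.items()):
            fq = base / f"{sample}.fastq"
            synthetic.write_fastq(reads, fq, sample_id=sample)
            counts, stats = quant.count_signatures_in_fastq(
                list(signatures), fq, orientation=orientation, sample_id=sample
            )
            for sig in signatures:
                results.append(
                    quant.normalize(
                        counts[sig.candidate_id],
                        stats,
                        scheme=scheme,
                        candidate_id=sig.candidate_id,
                    )
                )
    return quant.quant_matrix(results)


@dataclass
class MarkerDiscoveryResult:
    classes: dict[str, catalogue.CandidateClass]
    signatures: list[signature.KmerSignature]
    kpm: pd.DataFrame
    diff: select.DiffResult
    overexpressed: list[str]
    selection: select.SelectionResult
    top: list[str]


def run_marker_discovery(
    fixture: PipelineFixture,
    seed: int = 0,
    classify_params: catalogue.ClassifyParams | None = None,
    signature_params: signature.SignatureParams | None = None,
    selection_params: select.SelectionParams | None = None,
) -> MarkerDiscoveryResult:
    """Full chain on a fixture: classify, extract signatures, quantify
    every sample, filter over-expressed candidates and select markers."""
    classes = catalogue.classify_transcripts(
        fixture.candidates, fixture.reference, classify_params
    )
    sig_params = signature_params or signature.SignatureParams()
    sigs = candidate_signatures(
        fixture.genome, fixture.reference, fixture.candidates, classes, sig_params
    )
    kpm = quantify_samples(sigs, fixture.sample_reads, sig_params.k)
    matrix = select.ExpressionMatrix(kpm, fixture.groups, "target")
    diff = select.two_group_test(matrix)
    sel_params = selection_params or select.SelectionParams(rng_seed=seed)
    overexpressed = select.filter_overexpressed(diff, sel_params)
    # selection runs on the candidates passing the enrichment filter,
    # provided enough features remain to shadow-test
    if len(overexpressed) >= 2:
        matrix = select.ExpressionMatrix(
            kpm.loc[overexpressed], fixture.groups, "target"
        )
    selection = select.shadow_feature_select(matrix, sel_params)
    top = select.top_n(selection, sel_params.n_top)
    return MarkerDiscoveryResult(
        classes=classes,
        signatures=sigs,
        kpm=kpm,
        diff=diff,
        overexpressed=overexpressed,
        selection=selection,
        top=top,
    )
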