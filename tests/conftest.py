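"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's index structures: overlap
is checked pairwise, and k-mer occurrence is counted by scanning every
position of every sequence with str.find.
"""

from __future__ import annotations

import numpy as np
import pytest

from lncsig.refmodel import (
    STRAND_UNKNOWN,
    AnnotationSet,
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
)


def count_overlapping(haystack: str, needle: str) -> int:
    """Occurrences of needle in haystack, overlaps included."""
    count = 0
    pos = haystack.find(needle)
    while pos != -1:
        count += 1
        pos = haystack.find(needle, pos + 1)
    return count


def naive_kmer_occurrences(sequences: dict[str, str], kmer: str, orientation: str) -> int:
    """Positional scan over every sequence; canonical adds the reverse
    complement unless the k-mer is its own reverse complement."""
    total = sum(count_overlapping(seq, kmer) for seq in sequences.values())
    if orientation == "canonical":
        rc = reverse_complement(kmer)
        if rc != kmer:
            total += sum(count_overlapping(seq, rc) for seq in sequences.values())
    return total


def brute_force_specific_kmers(
    candidate_seq: str,
    gene_id: str,
    candidate_id: str,
    genome_seqs: dict[str, str],
    tx_seqs: dict[str, str],
    gene_of: dict[str, str],
    mode: str,
    k: int,
    orientation: str,
    scope: str = "gene",
) -> list[str]:
    """Window-by-window specificity check against raw sequence scans."""
    kept, seen = [], set()
    for i in range(len(candidate_seq) - k + 1):
        w = candidate_seq[i : i + k]
        if "N" in w or w in seen:
            continue
        if naive_kmer_occurrences(genome_seqs, w, orientation) != 1:
            continue
        occ_tx = {
            tid
            for tid, seq in tx_seqs.items()
            if naive_kmer_occurrences({tid: seq}, w, orientation) > 0
        }
        if mode == "unannotated":
            if occ_tx:
                continue
        elif scope == "gene":
            if {gene_of[tid] for tid in occ_tx} - {gene_id}:
                continue
        else:
            if occ_tx - {candidate_id}:
                continue
        seen.add(w)
        kept.append(w)
    return kept


def brute_force_classify(
    candidates: AnnotationSet,
    reference: AnnotationSet,
    min_length: int = 200,
    min_overlap: int = 1,
    level: str = "transcript-span",
) -> dict[str, str]:
    """O(n*m) pairwise re-derivation of the classification rules."""

    def overlap_bp(c: TranscriptModel, r: TranscriptModel) -> int:
        if c.contig != r.contig:
            return 0
        if level == "transcript-span":
            pairs = [(c.span, r.span)]
        else:
            pairs = [(ce, re_) for ce in c.exons for re_ in r.exons]
        return max(min(a[1], b[1]) - max(a[0], b[0]) for a, b in pairs)

    out = {}
    for cand in candidates:
        if cand.spliced_length < min_length:
            out[cand.transcript_id] = "TOO_SHORT"
            continue
        hits = [r for r in reference if overlap_bp(cand, r) >= min_overlap]
        if not hits:
            out[cand.transcript_id] = "MLINC"
        elif cand.strand == STRAND_UNKNOWN:
            out[cand.transcript_id] = "UNSTRANDED_OVERLAP"
        elif any(r.strand in (cand.strand, STRAND_UNKNOWN) for r in hits):
            out[cand.transcript_id] = "ANNOTATED_SENSE_OVERLAP"
        else:
            out[cand.transcript_id] = "MLOANC"
    return out


def naive_fastq_counts(reads: list[str], kmers: list[str], orientation: str) -> list[int]:
    """Per-k-mer counts by scanning every read window directly."""
    counts = []
    for kmer in kmers:
        targets = {kmer}
        if orientation == "canonical":
            targets.add(reverse_complement(kmer))
        k = len(kmer)
        c = 0
        for read in reads:
            for i in range(len(read) - k + 1):
                w = read[i : i + k]
                if "N" not in w and w in targets:
                    c += 1
        counts.append(c)
    return counts


@pytest.fixture
def toy_genome() -> GenomeSequence:
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return GenomeSequence(
        {"chr1": "".join(bases[rng.integers(0, 4, 5000)]),
         "chr2": "".join(bases[rng.integers(0, 4, 3000)])}
    )
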