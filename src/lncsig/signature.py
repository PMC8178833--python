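"""Specific k-mer signature extraction.

A specific k-mer of an unannotated candidate (novel lncRNA) is a k-nt
window that occurs exactly once in the genome and nowhere in the
reference transcriptome. For an annotated candidate the transcriptome
occurrences must instead be confined to the candidate's own gene
(isoforms of one gene share sequence, so strict transcriptome
uniqueness would void most gene-level markers). Default k is 31.

Orientation "canonical" merges each k-mer with its reverse complement
(strand-agnostic matching, as read mapping is); "stranded" keeps them
distinct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .refmodel import reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class SignatureParams:
    k: int = 31
    orientation: str = "canonical"
    annotated_mode_scope: str = "gene"

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 64:
            raise ValueError("k must be in [1, 64]")
        if self.orientation not in ("canonical", "stranded"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.annotated_mode_scope not in ("gene", "transcript"):
            raise ValueError(f"bad scope {self.annotated_mode_scope!r}")


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def iter_kmers(seq: str, k: int):
    """Yield (position, k-mer) for every N-free window of length k."""
    n = len(seq)
    for i in range(n - k + 1):
        window = seq[i : i + k]
        if "N" in window:
            continue
        yield i, window


class KmerIndex:
    """Occurrence counts of every N-free k-length window of a sequence set.

    In canonical orientation the key is min(kmer, revcomp(kmer)).
    For transcriptome indices, per-key gene and transcript membership is
    recorded so that annotated-mode specificity can be scoped.
    """

    def __init__(self, k: int, orientation: str, provenance: str):
        self.k = k
        self.orientation = orientation
        self.provenance = provenance
        self.counts: dict[str, int] = {}
        self.gene_members: dict[str, set[str]] = {}
        self.transcript_members: dict[str, set[str]] = {}

    def _key(self, kmer: str) -> str:
        return canonical(kmer) if self.orientation == "canonical" else kmer

    def add_sequence(
        self,
        seq: str,
        gene_id: str | None = None,
        transcript_id: str | None = None,
    ) -> None:
        for _, kmer in iter_kmers(seq, self.k):
            key = self._key(kmer)
            self.counts[key] = self.counts.get(key, 0) + 1
            if gene_id is not None:
                self.gene_members.setdefault(key, set()).add(gene_id)
            if transcript_id is not None:
                self.transcript_members.setdefault(key, set()).add(transcript_id)

    def count(self, kmer: str) -> int:
        return self.counts.get(self._key(kmer), 0)

    def total_occurrences(self) -> int:
        return sum(self.counts.values())


def build_kmer_index(
    sequences: Mapping[str, str],
    params: SignatureParams,
    provenance: str,
    gene_of: Mapping[str, str] | None = None,
) -> KmerIndex:
    """Index every sequence; for transcriptomes pass ``gene_of`` mapping
    sequence name (transcript_id) to gene_id so membership is recorded."""
    idx = KmerIndex(params.k, params.orientation, provenance)
    any_window = False
    for name, seq in sequences.items():
        if len(seq) >= params.k:
            any_window = True
        gid = gene_of.get(name) if gene_of is not None else None
        tid = name if gene_of is not None else None
        idx.add_sequence(seq, gene_id=gid, transcript_id=tid)
    if sequences and not any_window:
        logger.warning("k=%d larger than every sequence; index is empty", params.k)
    return idx


@dataclass
class KmerSignature:
    """The candidate-specific k-mers of one candidate, in its orientation."""

    candidate_id: str
    k: int
    kmers: list[str]
    mode: str
    n_windows: int = 0

    @property
    def size(self) -> int:
        return len(self.kmers)

    @property
    def retained_fraction(self) -> float:
        return self.size / self.n_windows if self.n_windows else 0.0


def extract_specific_kmers(
    candidate_seq: str,
    candidate_id: str,
    gene_id: str,
    genome_idx: KmerIndex,
    tx_idx: KmerIndex,
    mode: str,
    params: SignatureParams | None = None,
) -> KmerSignature:
    """Keep each N-free window that is unique in the genome and passes
    the transcriptome rule for ``mode``.

    unannotated: absent from the reference transcriptome.
    annotated: every transcriptome occurrence lies within the
        candidate's own gene (scope "gene") or the candidate transcript
        itself (scope "transcript").
    """
    params = params or SignatureParams()
    if mode not in ("annotated", "unannotated"):
        raise ValueError(f"bad mode {mode!r}")
    if genome_idx.k != tx_idx.k or genome_idx.orientation != tx_idx.orientation:
        raise ValueError("genome and transcriptome indices disagree on k/orientation")
    if params.k != genome_idx.k:
        raise ValueError("params.k does not match index k")
    k = params.k
    if len(candidate_seq) < k:
        logger.warning(
            "candidate %s shorter than k=%d; empty signature", candidate_id, k
        )
        return KmerSignature(candidate_id, k, [], mode, n_windows=0)

    kept: list[str] = []
    seen: set[str] = set()
    n_windows = 0
    for _, w in iter_kmers(candidate_seq, k):
        n_windows += 1
        if genome_idx.count(w) != 1:
            continue
        key = tx_idx._key(w)
        if mode == "unannotated":
            if tx_idx.counts.get(key, 0) != 0:
                continue
        else:
            if params.annotated_mode_scope == "gene":
                members = tx_idx.gene_members.get(key, set())
                if members - {gene_id}:
                    continue
            else:
                members = tx_idx.transcript_members.get(key, set())
                if members - {candidate_id}:
                    continue
        if w not in seen:  # a repeated window within the candidate counts once
            seen.add(w)
            kept.append(w)
    return KmerSignature(candidate_id, k, kept, mode, n_windows=n_windows)


def signature_report(signatures: Iterable[KmerSignature]) -> list[dict[str, object]]:
    """One row per candidate: id, mode, signature size, retained fraction."""
    rows = []
    for sig in signatures:
        rows.append(
            {
                "candidate_id": sig.candidate_id,
                "mode": sig.mode,
                "n_kmers": sig.size,
                "retained_fraction": f"{sig.retained_fraction:.4f}",
            }
        )
    return rows


def write_signature_fasta(signatures: Iterable[KmerSignature], path) -> None:
    """Signature FASTA with headers ``candidate_id.kmer_index``."""
    with open(path, "w") as out:
        for sig in signatures:
            for i, kmer in enumerate(sig.kmers, 1):
                out.write(f">{sig.candidate_id}.{i}\n{kmer}\n")
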