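"""Alignment-free quantification of signature k-mers in raw FASTQ.

Each sample's FASTQ file(s) are streamed once; every k-length read
window is looked up against the union of all candidate signatures
(which must be mutually disjoint, or a window would be double-counted).
The sampling depth T is the total number of k-length windows in the
file, Sigma over reads of max(0, len - k + 1), counting windows that
contain N: T is a file-size normaliser, matchability is a separate
concern (a flag restores the N-free convention).

Normalisations:
  kpm       = mean per-k-mer count x 1e6 / T   (k-mers per million)
  rpm_reads = mean per-k-mer count x 1e6 / n_reads
The mean may optionally drop zero-count k-mers ("zero values deleted").
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .refmodel import FormatError, reverse_complement
from .signature import KmerSignature, canonical


@dataclass
class SampleStats:
    sample_id: str
    n_reads: int
    total_kmers: int  # T


@dataclass
class QuantResult:
    candidate_id: str
    sample_id: str
    counts: list[int]
    mean_count: float
    normalized: float
    scheme: str
    all_zero: bool = False
    drop_zeros: bool = False


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq_reads(path: str | Path):
    """Yield read sequences from a 4-line-record FASTQ(.gz)."""
    with _open_maybe_gz(path) as handle:
        record_idx = 0
        while True:
            header = handle.readline()
            if not header:
                return
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            record_idx += 1
            if not (seq and plus and qual):
                raise FormatError(f"{path}: truncated FASTQ record {record_idx}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise FormatError(f"{path}: malformed FASTQ record {record_idx}")
            yield seq.strip().upper()


def count_signatures_in_fastq(
    signatures: Sequence[KmerSignature],
    fastq_paths: Sequence[str | Path] | str | Path,
    orientation: str = "canonical",
    sample_id: str = "sample",
    count_n_windows_in_total: bool = True,
) -> tuple[dict[str, list[int]], SampleStats]:
    """Stream one sample's FASTQ file(s) and count signature k-mer hits.

    Paired files of one sample are pooled into a single SampleStats.
    Returns ({candidate_id: per-k-mer raw counts}, stats).
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    if not signatures:
        raise ValueError("no signatures given")
    ks = {sig.k for sig in signatures}
    if len(ks) != 1:
        raise ValueError("signatures disagree on k")
    k = ks.pop()

    def key_of(kmer: str) -> str:
        return canonical(kmer) if orientation == "canonical" else kmer

    # global lookup k-mer key -> (candidate, slot); signature sets must be disjoint
    lookup: dict[str, tuple[str, int]] = {}
    for sig in signatures:
        for i, kmer in enumerate(sig.kmers):
            key = key_of(kmer)
            if key in lookup and lookup[key][0] != sig.candidate_id:
                raise ValueError(
                    f"k-mer {kmer} claimed by both {lookup[key][0]} "
                    f"and {sig.candidate_id}; signature sets must be disjoint"
                )
            lookup[key] = (sig.candidate_id, i)

    counts = {sig.candidate_id: [0] * sig.size for sig in signatures}
    n_reads = 0
    total_kmers = 0
    for path in fastq_paths:
        for seq in _iter_fastq_reads(path):
            n_reads += 1
            n_windows = max(0, len(seq) - k + 1)
            if count_n_windows_in_total:
                total_kmers += n_windows
            for i in range(n_windows):
                w = seq[i : i + k]
                if "N" in w:
                    continue
                if not count_n_windows_in_total:
                    total_kmers += 1
                hit = lookup.get(key_of(w))
                if hit is not None:
                    cid, slot = hit
                    counts[cid][slot] += 1
    return counts, SampleStats(sample_id, n_reads, total_kmers)


def normalize(
    raw_counts: Sequence[int],
    stats: SampleStats,
    scheme: str = "kpm",
    drop_zeros: bool = False,
    candidate_id: str = "",
) -> QuantResult:
    """Apply one of the two normalisation schemes to a candidate's counts."""
    if scheme not in ("kpm", "rpm_reads"):
        raise ValueError(f"bad scheme {scheme!r}")
    m = len(raw_counts)
    if m < 1:
        raise ValueError("empty signature: no counts to normalise")
    if any(c < 0 for c in raw_counts):
        raise ValueError("negative raw count")
    all_zero = all(c == 0 for c in raw_counts)
    if drop_zeros:
        nonzero = [c for c in raw_counts if c > 0]
        mean_count = sum(nonzero) / len(nonzero) if nonzero else 0.0
    else:
        mean_count = sum(raw_counts) / m
    if scheme == "kpm":
        if stats.total_kmers == 0:
            raise ValueError("total k-mers T = 0; kpm undefined")
        value = mean_count * 1e6 / stats.total_kmers
    else:
        if stats.n_reads == 0:
            raise ValueError("n_reads = 0; rpm_reads undefined")
        value = mean_count * 1e6 / stats.n_reads
    return QuantResult(
        candidate_id=candidate_id,
        sample_id=stats.sample_id,
        counts=list(raw_counts),
        mean_count=mean_count,
        normalized=value,
        scheme=scheme,
        all_zero=all_zero,
        drop_zeros=drop_zeros,
    )


def quant_matrix(results: Iterable[QuantResult]) -> pd.DataFrame:
    """Candidates x samples matrix of normalised abundances.

    Missing (candidate, sample) cells are filled with 0. Mixed
    normalisation schemes are an error; ordering is deterministic.
    """
    results = list(results)
    schemes = {r.scheme for r in results}
    if len(schemes) > 1:
        raise ValueError(f"mixed normalisation schemes: {sorted(schemes)}")
    cells: dict[tuple[str, str], float] = {}
    for r in results:
        cells[(r.candidate_id, r.sample_id)] = r.normalized
    candidates = sorted({r.candidate_id for r in results})
    samples = sorted({r.sample_id for r in results})
    data = [
        [cells.get((c, s), 0.0) for s in samples]
        for c in candidates
    ]
    return pd.DataFrame(data, index=candidates, columns=samples)
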