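"""FASTQ k-mer counting exactness and normalisation closed forms."""

import numpy as np
import pytest

from conftest import naive_fastq_counts
from lncsig.quant import (
    SampleStats,
    count_signatures_in_fastq,
    normalize,
    quant_matrix,
)
from lncsig.refmodel import FormatError, reverse_complement
from lncsig.signature import KmerSignature
from lncsig.synthetic import simulate_reads, write_fastq

K = 31


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _sig(cid, kmers):
    return KmerSignature(cid, K, list(kmers), "unannotated", n_windows=len(kmers))


def _write(tmp_path, reads, name="s.fastq"):
    p = tmp_path / name
    write_fastq(reads, p)
    return p


class TestCounting:
    def test_single_exact_read_gives_kpm_1e6(self, tmp_path):
        rng = np.random.default_rng(0)
        kmer = _rand_seq(rng, K)
        fq = _write(tmp_path, [kmer])
        counts, stats = count_signatures_in_fastq([_sig("c", [kmer])], fq)
        assert counts["c"] == [1]
        assert stats.n_reads == 1 and stats.total_kmers == 1
        assert normalize(counts["c"], stats, "kpm").normalized == pytest.approx(1e6)

    def test_reverse_complemented_read_matches_in_canonical_mode(self, tmp_path):
        rng = np.random.default_rng(1)
        kmer = _rand_seq(rng, K)
        fq = _write(tmp_path, [reverse_complement(kmer)])
        counts, _ = count_signatures_in_fastq([_sig("c", [kmer])], fq)
        assert counts["c"] == [1]
        counts2, _ = count_signatures_in_fastq(
            [_sig("c", [kmer])], fq, orientation="stranded"
        )
        assert counts2["c"] == [0]

    def test_counts_equal_naive_per_read_scan(self, tmp_path):
        rng = np.random.default_rng(2)
        transcript = _rand_seq(rng, 300)
        reads = [
            transcript[i : i + 80]
            for i in rng.integers(0, 300 - 80, size=500)
        ]
        kmers = [transcript[i : i + K] for i in range(0, 260, 13)]
        fq = _write(tmp_path, reads)
        counts, stats = count_signatures_in_fastq([_sig("c", kmers)], fq)
        assert counts["c"] == naive_fastq_counts(reads, kmers, "canonical")
        assert stats.total_kmers == 500 * (80 - K + 1)

    def test_read_duplication_doubles_counts_keeps_kpm(self, tmp_path):
        rng = np.random.default_rng(3)
        transcript = _rand_seq(rng, 200)
        reads = [transcript[i : i + 60] for i in range(0, 140, 7)]
        kmers = [transcript[i : i + K] for i in range(0, 100, 10)]
        fq1 = _write(tmp_path, reads, "a.fastq")
        fq2 = _write(tmp_path, reads + reads, "b.fastq")
        c1, s1 = count_signatures_in_fastq([_sig("c", kmers)], fq1)
        c2, s2 = count_signatures_in_fastq([_sig("c", kmers)], fq2)
        assert c2["c"] == [2 * c for c in c1["c"]]
        assert s2.total_kmers == 2 * s1.total_kmers
        assert normalize(c1["c"], s1, "kpm").normalized == pytest.approx(
            normalize(c2["c"], s2, "kpm").normalized
        )

    def test_read_order_permutation_invariance(self, tmp_path):
        rng = np.random.default_rng(4)
        reads = [_rand_seq(rng, 60) for _ in range(100)]
        kmers = [reads[0][:K], reads[5][10 : 10 + K]]
        fq1 = _write(tmp_path, reads, "f.fastq")
        fq2 = _write(tmp_path, reads[::-1], "r.fastq")
        c1, s1 = count_signatures_in_fastq([_sig("c", kmers)], fq1)
        c2, s2 = count_signatures_in_fastq([_sig("c", kmers)], fq2)
        assert c1 == c2 and s1.total_kmers == s2.total_kmers

    def test_paired_files_pool_in_either_order(self, tmp_path):
        rng = np.random.default_rng(5)
        r1 = [_rand_seq(rng, 60) for _ in range(50)]
        r2 = [reverse_complement(r) for r in r1]
        kmers = [r1[3][:K]]
        f1 = _write(tmp_path, r1, "R1.fastq")
        f2 = _write(tmp_path, r2, "R2.fastq")
        a = count_signatures_in_fastq([_sig("c", kmers)], [f1, f2])
        b = count_signatures_in_fastq([_sig("c", kmers)], [f2, f1])
        assert a[0] == b[0]
        assert a[1].n_reads == b[1].n_reads == 100

    def test_gzip_input_equivalent(self, tmp_path):
        rng = np.random.default_rng(6)
        reads = [_rand_seq(rng, 60) for _ in range(20)]
        kmers = [reads[0][:K]]
        plain = _write(tmp_path, reads, "x.fastq")
        gz = tmp_path / "x.fastq.gz"
        write_fastq(reads, gz)
        a = count_signatures_in_fastq([_sig("c", kmers)], plain)
        b = count_signatures_in_fastq([_sig("c", kmers)], gz)
        assert a[0] == b[0] and a[1].total_kmers == b[1].total_kmers

    def test_n_windows_never_match(self, tmp_path):
        kmer = "A" * K
        read = "A" * 15 + "N" + "A" * 15  # every window crosses the N
        fq = _write(tmp_path, [read])
        counts, stats = count_signatures_in_fastq([_sig("c", [kmer])], fq)
        assert counts["c"] == [0]
        assert stats.total_kmers == 1  # window existence still counted in T

    def test_overlapping_signatures_rejected(self, tmp_path):
        kmer = "ACGT" * 7 + "ACG"
        fq = _write(tmp_path, [kmer])
        with pytest.raises(ValueError, match="disjoint"):
            count_signatures_in_fastq([_sig("a", [kmer]), _sig("b", [kmer])], fq)

    def test_truncated_fastq_is_format_error(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\n")
        with pytest.raises(FormatError, match="record 1"):
            count_signatures_in_fastq([_sig("c", ["A" * K])], p)

    def test_planted_3_to_1_ratio_recovered(self, tmp_path):
        from lncsig.refmodel import AnnotationSet, GenomeSequence, TranscriptModel

        rng = np.random.default_rng(7)
        t1, t2 = _rand_seq(rng, 500), _rand_seq(rng, 500)
        genome = GenomeSequence({"c1": t1, "c2": t2})
        ann = AnnotationSet([
            TranscriptModel("hi", "g1", "c1", "+", [(0, 500)]),
            TranscriptModel("lo", "g2", "c2", "+", [(0, 500)]),
        ])
        reads = simulate_reads(genome, ann, {"hi": 3.0, "lo": 1.0},
                               n_reads=10_000, read_length=80, seed=7)
        fq = _write(tmp_path, reads)
        sig_hi = _sig("hi", [t1[i : i + K] for i in range(0, 470, 10)])
        sig_lo = _sig("lo", [t2[i : i + K] for i in range(0, 470, 10)])
        counts, stats = count_signatures_in_fastq([sig_hi, sig_lo], fq)
        kpm_hi = normalize(counts["hi"], stats, "kpm").normalized
        kpm_lo = normalize(counts["lo"], stats, "kpm").normalized
        # binomial 99% CI on the read split at p = 0.75, n = 1e4
        from scipy import stats as st

        lo_n, hi_n = st.binom.ppf([0.005, 0.995], 10_000, 0.75)
        assert lo_n / (10_000 - lo_n) <= kpm_hi / kpm_lo <= hi_n / (10_000 - hi_n)


class TestNormalize:
    def test_mean_and_kpm(self):
        stats = SampleStats("s", n_reads=10, total_kmers=10**6)
        r = normalize([2, 0, 4], stats, "kpm")
        assert r.mean_count == 2.0 and r.normalized == pytest.approx(2.0)

    def test_drop_zeros_mean(self):
        stats = SampleStats("s", n_reads=10, total_kmers=10**6)
        r = normalize([2, 0, 4], stats, "kpm", drop_zeros=True)
        assert r.mean_count == 3.0 and r.normalized == pytest.approx(3.0)

    def test_rpm_reads(self):
        stats = SampleStats("s", n_reads=2 * 10**6, total_kmers=1)
        r = normalize([4, 4, 4], stats, "rpm_reads")
        assert r.normalized == pytest.approx(2.0)

    def test_all_zero_drop_zeros_flagged_zero(self):
        stats = SampleStats("s", n_reads=10, total_kmers=100)
        r = normalize([0, 0], stats, "kpm", drop_zeros=True)
        assert r.normalized == 0.0 and r.all_zero

    def test_zero_total_kmers_is_domain_error(self):
        with pytest.raises(ValueError, match="T = 0"):
            normalize([1], SampleStats("s", 1, 0), "kpm")


class TestQuantMatrix:
    def _res(self, cid, sid, value, scheme="kpm"):
        from lncsig.quant import QuantResult

        return QuantResult(cid, sid, [1], 1.0, value, scheme)

    def test_rectangular_with_zero_fill(self):
        m = quant_matrix([
            self._res("c1", "s1", 1.0), self._res("c1", "s2", 2.0),
            self._res("c2", "s1", 3.0),
        ])
        assert m.shape == (2, 2)
        assert m.loc["c2", "s2"] == 0.0

    def test_mixed_schemes_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            quant_matrix([
                self._res("c1", "s1", 1.0, "kpm"),
                self._res("c2", "s1", 1.0, "rpm_reads"),
            ])
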