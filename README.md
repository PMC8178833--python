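# lncsig

Marker discovery for novel long non-coding RNAs (lncRNAs) from
RNA-seq, for researchers who need cell-specific transcriptional
markers when no annotated gene is specific enough: classification of
ab initio-reconstructed transcripts against a reference annotation,
candidate-specific k-mer signature extraction, alignment-free
quantification directly in raw FASTQ, and machine-learning marker
selection with downstream screening statistics.

## What it computes

1. **Catalogue classification.** Each candidate transcript (e.g. a
   StringTie reconstruction) with spliced length ≥ 200 nt is classed
   against the reference annotation by genomic overlap (≥ 1 bp):
   no overlap on either strand → intergenic lncRNA (*Mlinc*);
   overlap only on the opposite strand → antisense-overlapping
   lncRNA (*Mloanc*); any same-strand overlap → annotated sense
   overlap (flagged, kept).
2. **Specific k-mers.** A candidate's signature is the set of 31-nt
   windows occurring exactly once in the genome and (for novel
   candidates) absent from the reference transcriptome — effectively
   in-silico probes: for candidate sequence *s*,
   {w ∈ windows₃₁(s) : occ_genome(w) = 1 ∧ occ_tx(w) = 0}.
3. **Quantification.** Signature k-mers are counted by streaming raw
   FASTQ; a candidate's abundance in a sample is
   kpm = mean(cᵢ) × 10⁶ / T, the mean per-k-mer count per million
   k-length read windows T in the file (an `rpm_reads` per-read
   scheme and a drop-zero mean are also provided).
4. **Selection.** Features over-expressed in the target cell type
   (log₂FC > 0.5, p ≤ 0.05, up only) go through iterative
   shadow-feature selection (Boruta family: importance vs shuffled
   shadow copies, binomial hit test at α = 0.01 with Bonferroni,
   ≤ 10 000 runs), and the top 35 Confirmed features by importance
   form the marker working set.
5. **Screening.** Welch t tests with significance stars, knock-down
   screen calls on drop-zero means, subcellular compartment profiles,
   single-cell positive-cell marker calling (scaled expression ≥ 0.1,
   |log FC| ≥ 0.15, rank-sum test) and ddCt relative quantification
   (RQ = 2^−ΔΔCt) for qPCR validation.

A deterministic synthetic-fixture module generates toy genomes,
planted candidates of every class, stranded/unstranded reads from
group-structured expression profiles, feature matrices and single-cell
counts — with ground truth — so the entire pipeline is testable
without downloading any data. See `docs/methods.md` for the models
and design decisions.

## Worked example

```sh
# generate the default synthetic study (genome, GTFs, FASTQs, truth)
lncsig simulate --seed 11 --out study/

# classify candidates against the reference annotation
lncsig classify --candidates study/candidates.gtf \
    --reference study/reference.gtf --genome study/genome.fa --out cls/

# extract specific 31-mers for the novel classes
lncsig kmers --candidates study/candidates.gtf \
    --reference study/reference.gtf --genome study/genome.fa \
    --classes cls/classes.tsv --out sig/

# quantify one sample's raw FASTQ
lncsig quant --signatures sig/signatures.fa \
    --fastq study/target01.fastq.gz --sample-id target01 --out q/
```

`cls/classes.tsv` then contains one row per candidate:

```
transcript_id  gene_id  class       spliced_length  n_exons  gc
CAND.1.1       CAND.1   MLINC       464             1        0.4784
CAND.6.1       CAND.6   TOO_SHORT   126             1        0.4762
CAND.2.1       CAND.2   MLINC       337             1        0.5341
...
```

and `q/target01.quant.tsv` reports, per candidate, the signature size,
raw counts and kpm in that sample:

```
candidate_id  sample_id  n_kmers  sum_count  mean_count  kpm
CAND.1.1      target01   434      27150      62.5576     625.576
CAND.2.1      target01   307      13400      43.6482     436.482
...
```

A planted intergenic candidate such as `CAND.1.1` retains all 434 of
its 31-nt windows as specific k-mers (retained fraction 1.0) and shows
kpm ≈ 626 in a target-group sample versus 0 in controls, while the
antisense candidates overlapping exonic sequence retain only ~40% of
their windows. Feeding the per-sample kpm matrix to `lncsig select`
confirms exactly the planted target-specific candidates and ranks
them by importance.

The same steps are available as a library
(`lncsig.pipeline.run_marker_discovery` runs the whole chain on an
in-memory fixture).

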