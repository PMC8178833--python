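# Methods

`lncsig` implements a marker-discovery workflow for novel long
non-coding RNAs (lncRNAs): candidate transcripts reconstructed ab
initio from RNA-seq are classified against a reference annotation,
each retained candidate receives a set of specific 31-mers usable as
in-silico probes, those probes are counted directly in raw FASTQ files
across many samples, and cell-specific markers are selected by an
enrichment filter followed by shadow-feature selection. Downstream
screening utilities (group tests, knock-down screen calls, subcellular
compartment profiles, single-cell positive-cell marker calling, ddCt)
complete the chain. This note records the models, the defaults and the
design choices that were genuinely open.

## Coordinate and sequence model

All coordinates are 0-based, half-open internally. GTF input/output
(1-based, inclusive) converts at the boundary; BED output is 0-based,
half-open. Sequences are uppercased at read time; `N` is preserved
because the k-mer stages must see it (a window containing `N` is never
indexed or matched). Strand `"."` is carried as *unknown* and never
silently coerced: an antisense call requires a strand, so unknown-strand
candidates that overlap annotation receive a dedicated class instead of
being forced into the antisense bin.

## Transcript classification

A candidate with spliced length (sum of exon lengths) below
`min_length` (default 200 nt, the conventional lncRNA size floor) is
set aside as `TOO_SHORT`. Otherwise its overlap with every reference
transcript is evaluated; an overlap counts from `min_overlap` bp
(default 1). A candidate with no overlap on either strand is an
intergenic lncRNA (`MLINC`); a candidate whose overlaps are all on the
opposite strand is an antisense-overlapping lncRNA (`MLOANC`); any
same-strand overlap makes it an annotated sense overlap, which is
retained and flagged rather than dropped so the filtering can be
audited.

Open choices and how they were resolved:

- *Feature level.* "Annotated coordinates" is read as the reference
  transcript span, introns included — the default of span-level
  interval operations on transcript features. An exon-level mode is
  available (`overlap_level="exon"`); with it, a candidate inside an
  intron on the opposite strand is intergenic rather than antisense.
- *Spliced vs genomic length.* The 200-nt floor applies to spliced
  length, the conservative reading for multi-exon reconstructions.
- *Unknown-strand reference transcripts.* When a stranded candidate
  overlaps a reference transcript of unknown strand, the overlap is
  treated as same-strand. This deliberately errs toward excluding the
  candidate from the antisense class, which is the safe direction for
  marker discovery.

The classifier is backed by per-contig interval trees; its contract is
exact equality with a pairwise overlap scan, which the test suite
enforces on randomized fixtures.

## Specific k-mer signatures

A *specific k-mer* of a candidate is a k-nt window (k = 31 by default)
that occurs exactly once in the genome and — for unannotated
candidates (novel lncRNAs) — nowhere in the reference transcriptome.
For annotated candidates the transcriptome rule is relaxed to: every
transcriptome occurrence lies within the candidate's own gene
(`annotated_mode_scope="gene"`), because isoforms of one gene share
sequence and strict transcriptome uniqueness would void most
gene-level markers; a stricter transcript scope is available.

Matching is *canonical* by default: a k-mer and its reverse complement
are one key, as in strand-agnostic read matching. A stranded mode is
provided for stranded library chemistries. Odd k avoids self-reverse-
complement palindromes. Windows containing `N` are excluded from both
indices and signatures. Occurrence indices are plain key→count maps;
the contract (enforced by tests) is value-equality with a brute-force
positional scan.

## FASTQ quantification and normalisation

Signature k-mers are counted by streaming each sample's FASTQ(.gz)
once and looking up every k-length read window. Signature sets of
different candidates must be disjoint (enforced at load) or a window
would be double-counted. Paired files of one sample are pooled.

The sampling depth `T` is the total number of k-length windows in the
file, `Σ_reads max(0, len − k + 1)`, *including* windows that contain
`N`: `T` is a file-size normaliser and matchability is a separate
concern. A flag (`count_n_windows_in_total=False`) restores the
N-free convention; at typical N rates the difference is negligible.

Two normalisations are provided for a candidate with m signature
k-mers and raw counts c₁…c_m:

- `kpm` (k-mers per million): `mean(c) × 10⁶ / T` — the primary scheme;
- `rpm_reads`: `mean(c) × 10⁶ / n_reads` — a TPM-like per-read scheme
  for protocols (e.g. CAGE) where read count is the natural depth.

The mean may drop zero-count k-mers ("zero values deleted"), which is
robust to signature k-mers that are unmatchable in a given sample; an
all-zero candidate is reported as 0 with a flag. `kpm` is invariant to
read duplication and read order, which the tests verify exactly.

## Enrichment filter and shadow-feature selection

The two-group enrichment stage keeps features with log2 fold-change
β > 0.5 (strict), p ≤ 0.05 (inclusive), up-regulated in the target
group only. The default (β, p) provider is a Welch t test on
log2(x + 1); it is a documented stand-in satisfying a pluggable
contract, so any external differential-expression engine can be
substituted.

Marker selection is an iterative shadow-feature algorithm in the
Boruta family with defaults: at most 10 000 runs, α = 0.01,
Bonferroni adjustment on, final cut at the top 35 Confirmed features
by mean importance (the 35 is an arbitrary, overridable working-set
size). Each run appends a within-sample shuffled (shadow) copy of
every original feature, computes ensemble importances, and a live
feature scores a hit when its importance exceeds the best shadow.
Hits are tested two-sided against Binomial(runs, ½); a feature is
Confirmed (hits high) or Rejected (hits low) when its Bonferroni-
adjusted p falls to α, and Rejected features leave the live set.

Two design points matter for calibration, and both were settled by
null simulations (30 datasets of 20 pure-noise features, n = 100,
run cap 200):

- *Shadows always mirror the full original feature set.* If shadows
  are drawn only from the shrinking live set, the last surviving
  features face an ever-weaker max-shadow bar and pure noise ends up
  Confirmed far above α. Keeping the bar at the permutation null of
  the whole feature family removes this failure mode. The Bonferroni
  adjustment likewise spans all original features.
- *The importance provider is a heavily randomized ensemble* —
  extra-trees with one candidate feature per split — rather than a
  classic random forest. On a fixed finite sample, the best of m
  noise features has a genuine chance correlation with the labels; a
  forest that reproduces the same importance ranking every run lets
  that feature beat the best shadow at a rate well above ½, and the
  sequential binomial test then "confirms" noise. Randomized splits
  inject enough per-run importance noise to keep null hit rates below
  ½ while leaving real effects (≥ 2 SD) at hit rates near 1. A
  classic random-forest provider remains available
  (`select.rf_importance_provider`), and any callable
  `(X, y, rng) → importances` can be plugged in.

With the final design the measured null Confirmed rate is 0.5%
(3/600 features at α = 1%) and a planted study with 20 informative
features shifted 2 SD among 80 noise features at n = 200 yields 20/20
informative Confirmed and 80/80 noise Rejected.

## Screening statistics

- Significance stars follow the conventional thresholds: ns p > 0.05,
  `*` ≤ 0.05, `**` ≤ 0.01, `***` ≤ 0.001, `****` ≤ 0.0001, as a
  total, monotone function of p.
- Group comparisons default to Welch (unequal-variance) t tests; an
  equal-variance flag exists because the original figure legends do
  not state the variant.
- The knock-down screen compares control vs each KD group on per-
  sample drop-zero mean k-mer abundances; singleton KD groups are
  flagged and excluded.
- Compartment profiles report each fraction's share of the total
  signal and the argmax compartment.
- Single-cell marker calling: droplets with a total count below
  10 000 are removed; cells with scaled expression ≥ 0.1 for the
  query marker are labelled positive; per-gene log fold-change is the
  difference of mean ln(x + 1) between positive and negative cells,
  genes with |lfc| < 0.15 are excluded before testing (the threshold
  is on the log scale — a raw fold-change of 0.15 would be a
  down-regulation filter, inconsistent with marker calling), and the
  test is a Mann–Whitney rank-sum with Bonferroni adjustment. The
  upstream single-cell preprocessing chain (empty-droplet knee
  detection, batch correction, cell-cycle regression, embeddings) is
  out of scope; inputs are an already-scaled matrix plus raw counts.
- ddCt: per sample, dCt = mean Ct_target − mean Ct_reference; ddCt
  subtracts the calibrator group's mean dCt; RQ = 2^−ddCt. The
  computation is shift-invariant in Ct, which the tests check.

## Synthetic fixtures

The generator module emulates the study conditions end to end with
recorded ground truth; every generator is a pure function of
(seed, parameters):

- *Reference*: i.i.d. uniform A/C/G/T contigs with non-overlapping
  genes on both strands (1–3 exons of 150–400 nt, introns 60–200 nt,
  ≥ 600 bp intergenic gaps). At k = 31 and sub-megabase sizes,
  accidental k-mer collisions in uniform background are vanishingly
  improbable, so planted-uniqueness oracles are stable.
- *Candidates*: intergenic candidates planted ≥ 1 bp clear of every
  annotated span, antisense candidates inside a gene span on the
  opposite strand, sense overlaps on the host strand, and short
  candidates under 200 nt.
- *Reads*: drawn per transcript proportional to molar abundance ×
  number of read-length windows, uniform start, substitution errors
  only (no indels — exact-match counting is the unit under test),
  optional pairing with fully-overlapping mates. FASTQ.gz output
  fixes the gzip mtime and omits the filename so reruns are
  byte-identical.
- *Feature matrices*: 2^N(5, 1) abundances; informative features are
  shifted by `effect_sd` × SD on the log2 scale in the target group.
- *Cells*: negative-binomial counts (variance = μ + μ²/2) with a
  marker-positive subpopulation; the scaled matrix is the per-gene
  z-score of ln(1 + count).

The default end-to-end study uses one 60 kb contig, 8 genes, 4
intergenic + 2 antisense + 2 sense + 2 short planted candidates, and
8 + 8 samples of 2 000 × 80 nt unstranded reads, with intergenic
candidates expressed (molar abundance 8) only in the target group and
log-normal per-sample jitter (σ = 0.2). These sizes keep every stage
exactly checkable against brute-force oracles while exercising the
full chain; what passing them shows is correctness of the
computations, not robustness to real-data artefacts (sequencing
error profiles, repeats, GC bias, ambient RNA), which the generators
deliberately do not model.

## Numerical conventions

- GC fraction excludes `N` from the denominator; an all-N sequence is
  NaN, an empty sequence an error.
- Degenerate two-group tests (zero variance in both groups, identical
  means) report p = 1.
- Ties in importance or coordinates are broken lexicographically by
  feature/transcript id; all outputs are deterministically ordered.
- Seeds: every stochastic routine takes an explicit seed; derived
  seeds stay below 2³¹.

## Known limitations

- K-mer indices are in-memory hash maps; the package targets
  fixture-to-gene-panel scales, not whole-genome human indices.
- The default (β, p) provider is a t test on log-transformed
  abundances, not a count-model Wald test; for real studies plug in a
  dedicated differential-expression engine.
- Selection calibration was validated on the synthetic study family
  described above; heavy-tailed or strongly correlated feature sets
  may need the run cap and α revisited.
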