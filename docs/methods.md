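# Methods

This package re-implements, as a tested pipeline over synthetic data,
the small RNA population analysis used to characterize normal human
testis against testicular germ cell tumors (TGCT): read signature
profiling, strand-specific contig construction, annotation-based
classification, negative-binomial (NB) differential expression in the
style of the classic exact-test workflow, clustering/volcano reporting,
tRNA-fragment typing and delta-delta-CT qPCR quantification.  The real
study's raw sequencing data is not publicly deposited, so all
statistical claims made by the test suite are claims about *parameter
recovery on simulated data*, not about the biological dataset.

## The synthetic cohort

`simdata` generates a toy genome (default 3 chromosomes of 2 Mb) with
six mutually non-overlapping feature tracks: 60 miRNA loci (22 bp), 114
piRNA clusters (1–5 kb), 500 tRNA genes (72 bp), 60 repeat elements,
200 exons and 80 unannotated background loci.  Features are placed with
a 150 bp spacer — larger than the contig gap tolerance plus the maximum
read length — so reads from adjacent features can never merge into one
contig and every contig has an unambiguous truth feature.  The tRNA and
exon density is deliberately high relative to the piRNA clusters: in
the real data the count matrix used for contig-level differential
expression is dominated by features expressed in *all* samples (mainly
tRNA-derived), and the median-of-ratios normalization below is only
well-behaved when such stable features form the majority of the matrix.
With down-regulated features at ~30 % of the matrix the median ratio
slides into the tail of the stable bulk and absorbs part of the global
piRNA loss; at the default composition (~17 % down-regulated features)
this bias is ≲ 0.2 on the log2 scale.

Reads are emitted already aligned (BED6 + sequence); no aligner or
sequencing-error model is simulated, because the downstream analysis
consumes aligned reads and the contribution being exercised starts
there.  Counts are generated per feature: class mixture weights
(defaults: miRNA 0.18, piRNA 0.22, tRNA halves 0.27, tRFs 0.08, repeats
0.12, exons 0.05, other 0.08) define per-class read mass at the
configured depth (default 1e5 reads/sample); log-normal (σ = 1) weights
spread each class's mass over its features; NB noise with dispersion
α = 0.05 (typical inter-donor variability for a bulk tissue cohort;
α = 0 gives the Poisson limit) produces per-sample counts, and that
many reads are placed uniformly within the feature.  Read lengths
follow per-class discrete distributions with modes at 22 nt (miRNA),
30 nt (piRNA/repeat), 33 nt (tRNA halves) and 20 nt (tRFs).

Sequence content is random uniform over ACGT except at the forced
positions: piRNA- and repeat-class reads carry 5'U with probability
0.70 and position-10 A with probability 0.35 (the ping-pong signature);
32–34 nt reads carry 5'G with probability 0.55.  The forcing draws the
signature base with exactly the stated probability and otherwise draws
uniformly from the other three bases, so the empirical signature
fraction is an unbiased binomial estimate of the parameter.  Read
sequences are *not* copied from the toy genome — only coordinates
matter downstream, and the signature model lives in the read sequences
themselves.

Tumor groups scale the piRNA mass by 2^-5 and the repeat mass by
2^-2.5 (partial repeat loss), set the position-1/10 probabilities to
the random 0.25, up-regulate a designated subset of 23 miRNAs by 2^11
from a baseline of ~1 expected count per sample in normals, and
down-regulate 3 tRFs by 2^-2.5.  CIS (carcinoma in situ) is modelled
as a linear cell mixture of the normal and tumor expectations (default
fraction 0.5), with signature probabilities interpolated the same way —
the transitional-state reading.  A configurable fraction (10 %) of
piRNA reads is multi-mapped: each emits 2–4 alignment records with
identical name and sequence at random piRNA clusters (capped at 100),
and all alignment-level operations count each record once.

What the generator does *not* emulate: sequencing errors and quality
scores, adapter remnants, isotype-level tRNA biology (CCA tails,
anticodon families beyond a carried label), genuine genomic sequence at
read positions, strand-mixed piRNA clusters, and library-preparation
biases.  Passing tests therefore demonstrate that the *analysis*
recovers what was injected under NB sampling noise — not that it would
be robust to artifacts of real libraries.

## Signatures

Length histograms run over all reads in the closed 18–36 nt range
(out-of-range reads are tallied separately); signature fractions and
positional profiles run on *unique* sequences only — the two
denominators are deliberately different, matching how the per-sample
normalized histograms and the per-group unique-sequence logos are
conventionally computed.  T and U are interchangeable on input and
{A,C,G,U} is the canonical alphabet; position numbering is 1-based from
the 5' end.  Per-position entropy is H = −Σ p log2 p (0 log 0 ≡ 0) and
information content IC = 2 − H; no small-sample correction is applied
(the correction is not what a raw entropy logo shows), and lengths with
zero unique sequences report NaN fractions rather than 0.

## Contigs and intervals

All coordinates are 0-based half-open; two intervals overlap iff
`startA < endB and startB < endA`.  Contig construction takes reads of
length 24–36 nt (a 24–35 variant is available via `max_read_len`),
processes strands independently, and merges alignments whose gap
(`start2 − end1`) is at most 100 bp — boundary inclusive.  Contigs
supported by fewer than 100 alignment records are discarded; support
counts alignment records, not distinct reads, so multi-mapped reads
contribute one unit per alignment.  The merge is a sorted sweep with a
running maximum end; idempotence and non-adjacency within the gap
tolerance are property-tested, and the merge, intersection and
counting engines are verified against quadratic brute-force oracles and
against `bedtools merge -d` on random instances.

## Differential expression

The two-condition NB workflow is implemented from scratch:

* **Size factors** — median over features (restricted to those with a
  positive geometric mean, i.e. nonzero in every sample) of
  `count_ij / geomean_i`.
* **Dispersions** — "pooled" method of moments: the within-condition
  sum of squares over all replicated conditions, divided by (m − k)
  degrees of freedom, gives a per-feature variance `w_i` on the common
  scale; the raw dispersion is `(w_i − ξ q̄_i)/q̄_i²` with
  `ξ = mean(1/s_j)` removing the shot-noise term.  Negative raw
  estimates are floored at 0.  The mean–dispersion trend is either
  parametric, `α(q) = a1/q + a0`, fitted by a Gamma-family GLM with
  identity link (least-squares fallback, coefficients clipped
  non-negative), or "local": a running median of log α̂ against log q̄
  with a window of 10 % of features — a deliberate simplification of
  the original locfit smoother that preserves the contract (a smooth
  decreasing trend) without reproducing its implementation.  The final
  dispersion is `max(raw, fitted)` — maximum sharing — floored at
  1e-8.
* **Exact test** — conditions on the total K of the two group sums,
  modelled as independent NB variables with means `q·s_g` and variances
  `q·s_g + α q² Σ s_j²`; the p-value sums the probability of all splits
  no more likely than the observed one, normalized by the total.
  Computation is in log space with `logsumexp`, so extreme splits do
  not underflow.  All-zero features get p = 1.  Against enumeration
  oracles the p-values agree to 1e-10, and on an all-null NB matrix
  (2,000 features, 10 vs 10) the empirical type-I error at 0.05 sits
  within 3 binomial SE when the true dispersion is supplied — the
  calibration statement is about the test, not about the dispersion
  estimator, whose maximum-sharing rule is intentionally conservative.
* **Fold changes** — log2 of the ratio of group means of normalized
  counts; `+Inf`/`-Inf` (rendered literally in TSV output) when exactly
  one mean is zero, missing when both are.  BH adjustment is the
  step-up procedure (via statsmodels, cross-checked against a textbook
  implementation); the significance threshold (default 1e-6) applies to
  the adjusted p-value, with a raw-p mode available.
* **VST** — integrating `1/√(q + α(q) q²)` along the fitted trend.  The
  parametric trend has the closed form
  `vst(q) = log2((2 a0 q + b + 2 √(a0 (a0 q² + b q))) / (4 a0))` with
  `b = 1 + a1`, which approaches `log2 q` plus a constant for large q
  and degrades gracefully to √q (Anscombe-type) behaviour as a0 → 0;
  the local trend is integrated by quadrature on a square-root-spaced
  grid and rescaled to the log2 slope at the top of the data range.

Zero-total features stay in the matrix but never enter the geometric
means or the dispersion fit.  Later refinements of this workflow
(GLM designs, fold-change shrinkage, independent filtering, outlier
replacement) are deliberately out of scope.

## Classification and tRNA fragments

Each alignment gets exactly one class by precedence (default
miRNA > tRNA > piRNA cluster > repeat > exon > unannotated — most
specific annotation first; the order is configurable and only affects
multi-overlap alignments, which is property-tested) and one length
window (18–24 / 25–31 / 32–36 nt, named after the three peaks).
Overlap requires ≥ 1 bp; miRNA and tRNA lookups are strand-specific,
repeat/exon/piRNA-cluster lookups are not.  tRNA-overlapping reads are
typed by length alone — ≤ 24 nt tRF, ≥ 28 nt tRNA half, 25–27 nt
ambiguous (boundaries bracket the ~20 nt and ~30 nt descriptors and are
configurable) — and by 5'/3'/internal origin with a 2 nt tolerance
against the gene ends on the gene's strand.

## Reporting and qPCR

Samples are clustered on variance-stabilized expression of the top-N
features (highest mean VST; ties broken lexicographically on the id)
with Euclidean distances and complete linkage (scipy agglomeration;
merge heights equal the maximum inter-cluster pair distance and are
verified against an exhaustive oracle — exact ties may be ordered
differently than a lowest-index rule, which random-data tests never
hit).  Heatmap output is an ordered matrix, the dendrogram a Newick
string with quoted labels; volcano tables clamp infinite fold changes
to ±(max finite |log2FC| + 1) with an `is_infinite` marker and flag
significance at padj < 1e-8 and |log2FC| > 5 by default.

qPCR quantification averages replicate CTs arithmetically, computes
ΔCT against the endogenous control (default RNU6B), ΔΔCT against a
single designated calibrator sample, and RQ = 2^−ΔΔCT.  The > 35 cycle
negativity cutoff applies to the replicate mean by default (the
per-replicate reading is available by flag); negative measurements
report no RQ.  A sample missing its control is error-flagged; a missing
calibrator is a hard error.  Amplification-efficiency correction and
standard curves are out of scope.

## Numerical and design notes

* Determinism: every stochastic routine takes an explicit seed;
  experiment simulation spawns independent child seeds per sample, and
  a pipeline rerun with the same config is byte-identical (checksummed
  manifest).
* Problem sizes: the study-scale configuration used by the acceptance
  checks is 12 normal vs 10 tumor samples at 1e5 expected reads each
  (~2.2 M alignments); unit tests run a 2-chromosome miniature.  These
  sizes keep the full suite under a minute while leaving the group-sum
  counts in the exact test large enough to resolve the injected
  effects.
* Known limitations: the local dispersion trend is a running median,
  not locfit; the cluster-count used in tie-breaking follows scipy's
  ordering; contig-level normalization assumes stable features dominate
  the matrix (see above); and the CIS cell-mixture model makes the
  case-group mean a poor estimator of the pure-tumor fold change
  whenever CIS samples are included in the case group — the
  parameter-recovery checks therefore use the 12 vs 10 design without
  CIS, while the analysis drivers include CIS to show the transitional
  behaviour.
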