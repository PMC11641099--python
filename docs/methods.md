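# Methods

This note documents the models, conventions and design choices behind
`circrpl`, and what its synthetic-data tests do and do not demonstrate
about real data.

## Coordinate conventions and detector harmonization

All genomic intervals are held internally as 1-based fully closed
(`BSJKey`: chrom, start, end, strand; start ≤ end). This matches the
CIRI2-style dialect, which is read unchanged; the DCC-style dialect is
declared as 0-based start / 1-based end and shifted by +1 on the start at
read time. One fixed internal convention avoids the classical off-by-one
ambiguity when intersecting detectors; the dialect declaration lives in the
reader, not scattered through the analysis.

Detector intersection is **exact**: a BSJ survives only if both detectors
report identical (chrom, start, end) — and identical strand when
`match_strand` is on (the default). Whether the original analysis required
strand agreement is unknowable from the outputs alone, so it is a flag
rather than a hard-coded guess. With strand matching off, detector strand
disagreements resolve by majority vote and tie to `.`. No ±nt fuzz is
applied at intersection; positional tolerance exists only in the
conservation and exon-boundary matching steps, where it reflects splice
site wobble rather than detector dialect. Duplicate calls for the same BSJ
within one detector collapse to the per-sample maximum with a warning.

Counts for all downstream analysis come from a single quantification table
(the re-alignment-based quantifier's role); detector-internal counts are
retained as provenance only. Consolidated BSJs missing from the
quantification get explicit zero counts and a warning — dropping them
silently would bias the expression filter.

## Nomenclature

Exonic circRNAs are named `hsa-circGENE-NNN`, intronic `hsa-ciGENE` (a
serial suffix only when one gene hosts more than one intronic circRNA),
intergenic `hsa-circChromK-NNN`. Serial numbers are assigned by (start,
end) position within the gene (or chromosome, for intergenic), so naming
is a pure function of the record *set*: input order can never change a
name. A positional rather than discovery-order numbering was chosen
because discovery order is an artifact of file layout; this also means the
numbers are per-run and are not comparable to any external registry's
serials. Classification is: exonic when both termini fall within ±2 nt of
exon boundaries of one gene; intronic when the span lies inside a single
intron; intergenic when no gene body is overlapped; remaining
gene-overlapping cases default to exonic with the gene of largest overlap
(alphabetical tie-break). Multi-gene loci therefore always resolve
deterministically, if arbitrarily.

## Conservation classification

Each BSJ's 5′ and 3′ splice positions (orientation follows the transcribed
strand; unstranded records use start/end as 5′/3′) are lifted through an
interval map — equal-length source/target intervals with optional
orientation flip, the functional core of chain-based liftOver without the
chain file format. A catalogued circRNA in the target species *uses* a
lifted site when either of its boundaries on that chromosome lies within
±2 nt (configurable). Categories:

| category | condition |
|---|---|
| not-aligned | at least one site failed to lift |
| homologous | one catalogued circRNA uses both sites |
| both sites utilized | both sites used, but by different circRNAs |
| 5′ / 3′ site utilized | only that site used |
| no homologous | neither site used |

Matching by boundary *set* rather than by oriented 5′/3′ role keeps the
classification invariant under strand-flipping lifts, at the cost of not
distinguishing which role the target circRNA's boundary plays; with
realistic (≫ window) circRNA lengths the distinction is immaterial.
Enlarging the window can only grow the matched sets, so a homologous call
can never be demoted by widening — a property the tests assert.

## Expression filter and normalization

A circRNA is expressed in a project when it has ≥ `min_count` (default 5)
junction reads in at least ⌈`min_fraction` · n⌉ samples (default half;
9 samples → 5). Size factors are the raw per-sample library sizes (total
sequenced reads), so normalized counts are junction reads per sequenced
read and baseMeans land at the 10⁻⁶–10⁻⁷ scale; a median-of-ratios mode is
available for comparison but junction-spanning reads are so sparse
(< 0.1% of a total-RNA library) that the full library size is the more
stable denominator. PCA operates on log2(normalized + 10⁻⁸); the
pseudocount sits an order of magnitude below typical normalized values so
zeros separate cleanly without dominating the variance. Component signs
are fixed by making the largest-magnitude loading positive.

## Negative-binomial Wald test

Per project, for circRNA *i*: K_ij ~ NB(μ_ij, α_i) with
μ_ij = s_j·q_i·2^(β_i x_j) and Var = μ + αμ². Estimation:

* **Dispersion.** Method of moments on the two-group fit:
  α̂ = Σ[(k−μ̂)² − μ̂] · n/(n−2) / Σμ̂², floored at 10⁻⁸. The per-feature
  estimate at n ≤ 20 is noisy and collapses to the floor for a
  non-trivial fraction of truly overdispersed features, which understates
  the Wald SE; each feature's dispersion is therefore floored at the same
  estimator pooled over all features in the project. This is a floor, not
  shrinkage toward a trend: features with larger-than-pooled dispersion
  keep their own estimate. Without the pooled floor the null rejection
  fraction at p < 0.05 was ~0.11; with it ~0.05.
* **Fold change.** β̂ by Newton–Raphson maximum likelihood in
  (log q, β·ln2) with the library-size offset; SE from the observed Fisher
  information; Wald statistic β̂/SE against the standard normal,
  two-sided. No shrinkage of β̂, no outlier handling, no independent
  filtering — this is deliberately a transparent, documented simplification
  of the fuller machinery in dedicated DE packages, validated by
  calibration and recovery on planted truth rather than by numerical
  equality with any of them.
* **Degenerate rows.** All-zero rows are reported with p = 1, not dropped.
  When one group is all zeros, group means get a 0.5 pseudo-count so the
  log2FC stays finite; such rows are flagged `zero_group`.
* **Multiplicity.** Benjamini–Hochberg step-up over all tested circRNAs in
  the project; significance requires padj < 0.05 **and** |log2FC| > 0.58,
  both strict.

A consequence of FDR control worth stating: with no true effects the
expected *proportion* of false discoveries is bounded, not the probability
of any discovery, so a small null project can legitimately produce a
handful of significant calls. Tests assert a bounded false-positive
fraction rather than exactly zero.

The signed Wald statistic always carries the sign of the fold change here;
reference outputs in the field sometimes mix likelihood-ratio-style
(always-positive) and Wald-style statistics across runs, so the `stat`
column is only sign-comparable within a single run of this package.

## Over-representation analysis

Query = host genes of expressed circRNAs; background = the supplied
expressed-gene universe (host-gene level, not transcript level). Sets are
restricted to 5–400 members *measured within the background*, tested with
the hypergeometric upper tail, BH-adjusted. Significant sets cluster by
single-linkage over Jaccard ≥ 0.5 (configurable); components under three
sets are dropped, and clusters are labelled by their lexicographically
smallest member — a flat-table stand-in for network-based term maps.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes: a
multi-chromosome genome of non-overlapping genes with realistic exon and
intron sizes (80–200 nt exons, 200–500 nt introns); exonic, intronic and
intergenic circRNAs (85/10/5% by default) whose splice sites are pairwise
separated by more than twice the conservation window, so planted
categories are exactly recoverable; NB junction counts with a shared
dispersion (α = 0.1), log-normal base expression around 50 junction reads
at the reference depth, linear library-size scaling across 20–60 million
reads, and planted log2 fold changes in RPL samples; two detectors that
each miss a circRNA with small probability (5% dropout split between them)
or jitter one splice site by ±1 nt (2%); a lift map with single-base holes
at the 5′ sites of planted not-aligned circRNAs; a target-species
catalogue constructed per category (decoy boundaries are placed in a
reserved coordinate band far from all lifted sites, so categories cannot
cross-contaminate); a known-circRNA catalogue containing 90% of planted
circRNAs plus decoys; and GMT gene sets with one set enriched by
construction (80% of its members are hosts of expressed circRNAs). The
default sample layout mirrors a four-project reproductive-tissue design:
5v5, 3v6, 3v3, 3v3 controls/RPL.

The gene universe (default 1000 genes) is kept several times larger than
the set of circRNA host genes, as in real total RNA-seq where
circRNA-producing genes are a minority of expressed genes; without this
the enrichment background saturates and no set can be enriched.

**What passing tests do not show about real data:** the generator draws
independent counts per circRNA (no correlation structure, no batch effects
beyond library size, no sample outliers), uses one shared dispersion, and
plants a single effect size; detector errors are independent and
symmetric. Calibration and recovery results on this world demonstrate the
implementation is correct under its own model, not that the model captures
every pathology of real junction-count data.

## Problem sizes and numerical choices

Simulation-based checks use: 2000 circRNAs with 5v5 samples for null
calibration and 10v10 with 500 planted effects for recovery; 1200 circRNAs
across all six conservation categories for the classifier cross-check; 30
seeded replicates for the enrichment ranking; 50 randomized pairs of up to
500 BSJs for the intersection oracle. These sizes give tight Monte-Carlo
bands while keeping the full suite and the acceptance script in the
tens-of-seconds range. Newton iterations stop at gradient ∞-norm < 10⁻¹⁰
(max 60 iterations, steps damped to ‖step‖∞ ≤ 5); BH uses a stable
mergesort so ties are deterministic; all file writers sort their records
and fix float formatting, making every output byte-reproducible from a
seed.

## Known limitations

* Internal exon structure of circRNAs is not modelled; BSJs alone cannot
  recover it, so exon-count statistics are out of scope.
* Real chain-file parsing is not implemented; lift maps are the documented
  TSV interval format.
* The DE model is single-factor (condition within one project); no
  covariates, batch terms or meta-analysis across projects.
* Catalogue matching is exact-coordinate; a known circRNA reported 1 nt
  off by a detector counts as novel.
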