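# Methods

## Coordinate conventions

All genomic coordinates are 0-based half-open (BED convention) everywhere
inside the package. Readers convert at the boundary: narrowPeak/BED files
are native; TSS catalog TSVs carry a per-row `coordinate_base` column (0 or
1) and 1-based positions are shifted on load. Chromosome names are matched
by exact string equality, with an optional load-time normalization map
("1" → "chr1") because the Ensembl/UCSC naming clash is the most common
silent failure in this class of pipeline. Strand is carried on every
interval but never affects overlap computation — promoter windows are
symmetric around the TSS, so binding assignment is strand-blind.

## Promoter windows

A promoter is the window `[max(0, TSS − h), min(chrom_len, TSS + h))` with
half-width `h = 2500` bp, giving an unclipped length of exactly 5000 bp.
The half-open reading of "−2500 to +2500" keeps lengths round and composes
with BED. Promoters are built per transcript, duplicates are not removed
(the run report states both raw and unique window counts), and a gene is
called bound when **any** of its transcript promoters collects a passing
peak — merging happens on hits, not on windows. Mature miRNAs attach to
the union of their pri-miRNA precursors' promoters; matures whose
precursors are absent from the TSS catalog are flagged and map to the
empty set.

## Peak assignment

A peak counts for a promoter iff `−log10(p) > 3` **and** overlap
`> 100 bp`; both inequalities are strict, taking the thresholds literally.
The overlap filter is applied per peak–promoter pair *before* the
gene-level merge (the conservative reading where merge order is ambiguous;
the summed-overlap variant is available through `total_overlap`, which the
annotation also reports). A peak overlapping several promoters of one gene
counts once, with its maximal overlap. The best peak per gene maximises
(score, overlap, leftmost start), a deterministic tie-break. Histone-mark
presence uses any-overlap (≥ 1 bp) against the promoter window, and a
mature miRNA inherits the OR over its promoters.

## Motif scanning

The position frequency matrix is turned into a log2-odds matrix with a
background-distributed pseudo-count (default 0.8):

    LO(b, j) = log2( (n(b,j) + c·bg(b)) / (N(j) + c) / bg(b) ).

Both strands are scanned; a window is a hit when its relative score
`(S − S_min) / (S_max − S_min)` is at least 0.80, a common JASPAR-scan
convention (the relative score is pinned to [0, 1], so the consensus
always scores 1). Windows containing `N` are skipped, and minus-strand
hits are reported at their forward-strand window start.

## Expression filters and aggregation

TPM is the standard length-normalised rate rescaled to 10^6 per column;
all-zero columns stay zero. The expressed filters are strict: a gene needs
TPM > 1 in at least one replicate, a mature miRNA a normalized count > 1
in at least one sample. Mature-arm expression is the arithmetic mean over
the mature's precursor rows, per sample. Differential testing of miRNAs
runs on the aggregated **raw** counts rounded to the nearest integer (the
aggregate-then-normalize alternative is the same data flow with the
normalization first; the raw-path is the default because the DE test does
its own normalization).

## Stand-in differential-expression test

DESeq2 is deliberately **not** reimplemented — no dispersion shrinkage,
Wald test, independent filtering or outlier handling. Real-data users
plug externally produced DE tables in (`de_mode: external`; status is
recomputed from the thresholds). For the synthetic path the package
provides `lognormal_t`:

1. median-of-ratios size factors against a geometric-mean pseudo-reference
   (features containing any zero are excluded from the median);
2. `log2FC = log2((mean_silenced + c0) / (mean_control + c0))` on
   normalized group means, pseudo-count `c0 = 0.5`, sign convention
   silenced-vs-control (up = higher after knockdown);
3. a two-sample t statistic on `log2(normalized + c0)` with
   **variance moderation**: per-feature pooled variances are shrunk toward
   a lowess trend of variance against mean expression with a fixed prior
   weight of d0 = 50 degrees of freedom, and the statistic is referred to
   a t distribution with d0 + n1 + n2 − 2 df.

Moderation is the deliberate design choice here: with two replicates per
condition a plain per-feature t has 2 residual df, its p-values cannot
fall much below ~10^−2, and no BH threshold at FDR 0.05 over thousands of
features is ever reachable — every two-replicate design would return zero
calls regardless of effect size. Borrowing variance information across
features (the limma-trend idea) is the field-standard remedy and keeps
the test well calibrated: under a planted null (NB counts, dispersion 0.1,
3 vs 3 replicates, 2,000 features) the raw p < 0.05 fraction sits near
0.05 and BH at FDR < 0.05 yields essentially no calls — both checked by
the acceptance suite. The prior df of 50 makes a 2 + 2 design borrow most
of its variance estimate from the trend while per-feature information
still dominates once replicate numbers reach double digits.

Classification is strict on both sides: up iff `log2FC > t` and
`FDR < q`, down iff `log2FC < −t` and `FDR < q`, else ns — with
(t, q) = (1, 0.05) for genes and (0.5, 0.1) for miRNAs. BH adjustment is
the standard step-up procedure (statsmodels), with NaN p-values passed
through untouched.

## Network rules

Anti-correlation is pure sign opposition on log2 fold changes, strict on
both sides — a fold change of exactly 0 never forms an edge. Two gene
strata are computed: the broad one (all *expressed* genes with a
sign-opposed fold change that are predicted targets of a bound DEM) and
the differential one (its intersection with classified DEGs); the bound
network additionally requires the target gene's own promoter to be
TF-bound and adds TF→gene edges for those genes. Exports (SIF, GraphML,
node/edge TSVs) are lexicographically ordered, so identical inputs give
byte-identical files.

## Synthetic data

What the generator emulates: two chromosomes with evenly spaced,
non-colliding promoter windows (genes on chr1, pri-miRNAs on chr2);
a fraction of genes with a second, TSS-jittered transcript; mature pairs
(-5p/-3p) per precursor with a fraction of 5p matures shared between two
precursors; NB counts (variance = μ + αμ²) with log-normal baseline means;
planted effects as multiplicative 2^effect scalings of the
silenced-condition mean; repression as an additional multiplicative
scaling of the target's silenced mean by 2^(−sign(DEM)·|effect|·coupling),
which makes sign opposition hold in expectation; TF peaks of 400 bp
centred on bound TSSs with scores drawn in (5, 50); three decoy peak
kinds, each violating exactly one acceptance rule (sub-threshold score,
80 bp edge overlap, intergenic placement); histone-mark peaks on active
promoters; promoter sequences with the motif consensus embedded in bound
DEM promoters; and a target map containing all planted repression pairs
plus random decoys.

Replicate numbers default to 2 per condition for mRNA and 3 for miRNA,
matching the emulated study design. Remaining defaults are chosen once as
realistic for bulk knockdown data: dispersion 0.1, log-normal means with
(meanlog 5, sdlog 1.5) for genes and (5.5, 1.2) for matures, 5% of genes
and 10% of precursors planted, effect magnitudes uniform in [1.5, 3], 5
targets per planted mature, and extra (non-differential) bound promoters
at 30% to mirror the observation that far more promoters are bound than
respond. Planted features have their baseline mean floored at 200 so that
planted truth is never lost to the expression filters. One global seed
drives a fixed named substream per generator component, so any component
can be regenerated independently.

The `strong_signal` preset is the noise-free reference regime: effects
≥ 2, dispersion 0.05, no decoys of any kind, binding restricted to the
planted network, and every repression target bound. In this regime the
recovered bound network equals the planted network exactly (precision =
recall = 1 for all edge types), which the acceptance suite asserts.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: GC/mappability biases, peak-width and summit
structure, alternative and intronic miRNA promoters, overdispersion
heterogeneity across features, correlated replicates, isoform-level
quantification noise, and sequence composition beyond uniform background
with an embedded consensus. Recovery at precision/recall 1 demonstrates
the correctness of the integration rules, not expected performance on
real sequencing data.

## Problem sizes and numerics

The shipped study sizes (2,000 genes, 100 precursors / 200 matures) are
the package's reference scale; all end-to-end runs and the acceptance
script complete in seconds on one core. Degenerate inputs are handled
explicitly: empty peak files produce an all-unbound annotation; all-zero
count columns give zero TPM; zero-variance features with zero observed
difference get p = 1; sequences shorter than the motif yield no hits;
an empty inferred network reports precision as undefined (NA) rather
than 0.

## Known limitations

* The stand-in DE test assumes approximate log-normality of normalized
  counts; very low counts are handled only through the pseudo-count.
* Distal/enhancer binding is out of scope — only promoter-window
  assignment is implemented, so TF targets regulated through distal
  elements are invisible by construction.
* The 100 bp overlap rule is applied per peak; a gene whose binding is
  split into several sub-100 bp fragments is called unbound even if the
  summed overlap is large (the summed value is reported for inspection).
* Mature-to-precursor aggregation assumes the provided map is complete;
  matures missing from the map are silently absent from the miRNA layer.
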