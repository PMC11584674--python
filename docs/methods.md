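# Methods

This note records the statistical model behind each stage, the default
parameter values and why they were chosen, what the synthetic data
generator does and does not cover, the numerical conventions, and the
known limitations.

## 1. Promoter-isoform annotation

**Model.** A promoter-isoform is the set of a gene's transcripts that
share a strand-aware TSS (exon-interval start on `+`, end on `-`).
Promoters are ranked in transcription direction; rank 1 is the 5′-most.
Identifiers are `<gene_id>.P<zero-padded rank>` so they sort correctly
as strings. Genes with transcripts on multiple strands or chromosomes
are rejected with a warning rather than silently mis-grouped.

**Identifiability.** A promoter is quantifiable only through reads that
span its members' first introns (the intron adjacent to the first exon
in transcription direction). If any edge of such a junction coincides
with an edge of a *non-first* intron of another transcript of the same
gene, junction reads are ambiguous — they could come from internal
splicing of a different isoform — and the promoter is classed
`internal`. The comparison is within-gene only: a coincidental shared
coordinate in another gene does not affect quantifiability because gene
assignment of a junction read is unambiguous. Promoters whose members
are all single-exon are `single_exon_only` and cannot be quantified
from junctions at all.

**Promoter OCR assignment.** Each promoter is matched to the nearest
open-chromatin peak whose interval intersects the window
(TSS − 1000, TSS + 1000), exclusive at the edges; distance is 0 when
the TSS lies inside the peak, ties break by smaller peak start then
lexicographic peak id.

## 2. Quantification and normalization

**Counts.** A promoter's count in a sample is the sum of junction reads
over its first-intron junctions. Only `unique` promoters are
quantified for differential analysis; `internal` promoters are added
back for the ABC activity gate (section 4), where ambiguity affects
precision but not whether the TSS is in use.

**TMM.** Library normalization follows edgeR's published trimmed mean
of M-values: reference sample = the one whose 75th-percentile/library
ratio is closest to the mean; per sample, a doubly trimmed (30% on M,
5% on A) weighted mean of M-values with inverse-binomial precision
weights; samples with `max |M| < 1e-6` against the reference get
factor 1 exactly; factors are rescaled to geometric mean 1. The
implementation was cross-checked at development time against
edgeR 4.0.16 `calcNormFactors(method="TMM")` to 10 decimal places, and
the test suite holds it to an independent Python oracle at 1e-6.

**Detection filters.** Genes and OCRs: ≥ 1 CPM in ≥ 20% of samples.
Promoter-isoforms: ≥ 2 CPM in strictly more than 40% of samples — a
stricter rule because junction counts are sparser and low-count
promoters produce unstable within-gene ratios. CPM thresholds are
inclusive (≥), the promoter fraction exclusive (>).

**Major promoter.** Per gene, the detected promoter with the highest
mean CPM across all samples; ties break toward the smaller rank.

## 3. Differential statistics

**Model.** For each feature and each pair of groups (default grouping
column: `broad_region`), `log2(CPM + 0.5)` is fit by weighted least
squares on group + donor (+ optional covariates). Precision weights
come from a LOWESS fit of residual standard deviation against fitted
mean, mirroring the voom/limma mean–variance approach without its
empirical-Bayes shrinkage (reasonable at the n ≥ 8 per group of the
intended designs). Two-sided t-tests on the group coefficient give
p-values; Benjamini–Hochberg is applied *globally*, pooling all
features and all contrasts, so "FDR < 0.05" means the same thing
everywhere. Zero-variance features return (t = 0, p = 1) rather than
NaN.

**Isoform-specific DEGs.** A promoter-contrast call with promoter
FDR < 0.05 whose parent gene, in the same contrast, has p > 0.1
(strictly) or a strictly opposite log2 fold-change sign. This isolates
promoter switching that gene-level analysis misses: when one promoter
rises and its siblings compensate, the gene total is flat.

**Broad-region specificity.** A feature is specific to region R when
every pairwise contrast involving R is significant at the global FDR
cut with the direction favoring R. Requiring *all* contrasts (not a
majority) keeps the null pipeline clean.

**Storey π1.** π0 is estimated on the λ grid 0.05–0.95 (step 0.05) as
`#{p > λ} / ((1 − λ) n)`, smoothed with a natural cubic smoothing
spline and read off at the largest λ; π1 = 1 − π0, clamped to [0, 1].
Fewer than 5 usable grid points (or an ill-conditioned spline) falls
back to the fixed λ = 0.5 estimate. π1 of a contrast's p-values is the
region-pair dissimilarity; the matrix is symmetric with zero diagonal.

## 4. ABC links at promoter resolution

**Activity gate.** A promoter is link-eligible in a region when its
CPM exceeds 1 in ≥ 20% of the region's samples *and* it has an
assigned OCR within 1 kb — expression plus open chromatin.

**Score.** For each active promoter, candidates are all elements whose
interval intersects (TSS − 5 Mb, TSS + 5 Mb). Raw score = element
accessibility (mean CPM over the region's samples) × contact between
the element midpoint and the TSS. ABC = raw normalized to sum 1 over
all candidates, promoter-proximal elements included in the denominator.
Links at ABC ≥ 0.02 are reported, flagged `distal` or
`promoter_proximal` (element intersects any promoter's ±1 kb window).
The 0.02 threshold and 5 Mb window are the conventional ABC constants.

**Contact.** Contact maps are sparse dictionaries of binned counts
(default 5 kb bins). Observed bin pairs are returned directly; absent
pairs fall back to a power law `scale · (d + resolution)^(−γ)` with
γ = 1 (the canonical Hi-C distance-decay exponent), where `scale` is
calibrated so the fallback matches the map's mean stored contact at the
100 kb reference distance. Same-bin queries return the self-contact
convention `max(map maximum, scale · resolution^(−γ))`, which dominates
every cross-bin contact — promoter-proximal elements always get the
largest contact. Cross-chromosome queries return 0 with a warning.

## 5. Fine-mapping with ABC-Max

SNPs with PIP > 0.01 (strict) lying inside a linked element
(half-open peak intervals; SNP positions are 1-based and converted
internally) are candidates; by default only `distal` elements count,
since promoter-proximal assignment is trivial. Per (SNP, region) — or
globally with `per_region=False` — the assignment is the link with the
maximum ABC; ties break by smaller TSS distance, then lexicographic
promoter id, making results deterministic. Each assignment carries
`promoter_type` (`five_prime` for rank 1, else `non_five_prime`) and is
compared to the closest-gene baseline (minimum TSS distance over all
promoters; ties keep all tied genes). GWAS hits can be condensed to
±10 kb merged lead-SNP windows before overlap.

## 6. Validation utilities

One-tailed Fisher's exact test (hypergeometric upper tail) for
enrichment of validated links; one-tailed Wilcoxon signed-rank /
rank-sum with exact nulls for n ≤ 25 without ties, normal
approximation with continuity and tie correction otherwise; tie-aware
Spearman (Pearson on mid-ranks, pairwise-complete, NaN for degenerate
input); basepair Jaccard on merged interval sets. Reference
comparisons use ±500 bp element flanks, and LD proxies with r² > 0.8
(strict) can stand in for reference variants.

## 7. Synthetic data generator

**Scope.** The generator produces the full input bundle — transcripts,
junction/gene/peak count matrices, contact maps, SNPs, per-gene
priority scores — with planted truth for promoter switching, loops,
major promoters, and causal SNPs. It exists to validate the pipeline's
statistical behavior, not to imitate real sequencing artifacts: no
mapping bias, batch effects, GC content, or read-level simulation.

**Design.** Defaults: 50 genes on one chromosome (spacing 150 kb, span
50 kb), 1–3 promoters per gene (probabilities 0.2/0.5/0.3, offset
12 kb between adjacent promoters so distinct promoters occupy distinct
5 kb contact bins), 3 regions × 4 donors × 2 samples. Counts are
negative binomial (dispersion 0.1) around lognormal gene means, with
lognormal donor (sd 0.25) and library (sd 0.3) effects; promoter
shares are Dirichlet. In 30% of genes one unique promoter is switched
(×2^2 in one region) while sibling promoters compensate so the gene
total stays constant — exactly the signal the isoform-specific DEG
rule targets. 25% of multi-promoter genes have a non-5′ major
promoter (share forced ≥ 0.55).

**Regulatory layer.** Each gene gets 3 enhancers 20–75 kb from its
rank-1 TSS (rejection-sampled to stay > 2.5 kb from every same-gene
TSS so they remain distal), plus 40 background peaks. Half the genes
get a loop (contact ×10 over the power-law baseline) between one
enhancer and one promoter at least two bins away; 30% of loops are
region-specific. Contact maps store only deviations from the power-law
baseline (diagonal, calibration entries, loop entries), keeping files
small while `contact()` reproduces the full decay. 30% of SNPs are
causal: placed uniformly inside a looped enhancer of a score-inflated
gene with PIP > 0.01; the rest fall outside all peaks.

## 8. Numerical conventions

- Coordinates are 0-based half-open internally; GTF is written/read
  1-based closed, BED 0-based half-open, SNP positions 1-based.
- The log2 pseudocount is 0.5 and is used only for log transforms,
  never added to stored counts or CPM.
- All tie-breaks are deterministic (documented per function above), so
  identical seed + config give byte-identical outputs; `promlink run`
  writes a SHA-256 manifest to make this checkable.
- Randomness flows exclusively from explicit seeds through
  `numpy.random.default_rng` / `SeedSequence`.

## 9. Limitations

- Junction-based quantification cannot measure `internal` or
  `single_exon_only` promoters; analyses that include them (the ABC
  activity gate) trade precision for coverage.
- The WLS engine does not do empirical-Bayes variance shrinkage; with
  very small groups (n < 4 per group) its p-values are less stable
  than limma/dream's.
- The contact model is 1-D intra-chromosomal with a single γ; trans
  contacts and locus-specific decay are out of scope.
- ABC scores are relative per promoter; they support ranking and
  thresholding, not cross-promoter comparison of absolute regulatory
  strength.
- Validation statistics assume links are exchangeable within a
  region/promoter-type stratum; structured confounders (e.g. distance)
  should be matched upstream by the caller.
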