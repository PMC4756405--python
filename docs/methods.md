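# Methods

## Design

The package analyses the two-inbred-parent / F1-hybrid design: two
homozygous lines (P1, P2) and their hybrid, each measured for
phenotypes, bulk RNA-seq (one library per line), SNP-level pileups and
hormone panels. All bespoke statistics operate on plain pandas tables;
standard tests are delegated to scipy/statsmodels.

## Heterosis statistics

For a trait with group means x̄_P1, x̄_P2, x̄_F1:

* MPV = (x̄_P1 + x̄_P2)/2, BPV = max(x̄_P1, x̄_P2);
* ratios F1/MPV and F1/BPV are computed on unrounded means and only
  then rounded **half-up** to two decimals (`round_half_up`), matching
  how published tables round; Python's default banker's rounding would
  disagree on boundary values.
* Pairwise comparisons use the two-sided equal-variance Student
  *t*-test at α = 0.05 (Welch available via `equal_var=False`). The
  compact letter display enumerates the maximal cliques of the
  non-significance graph (Bron–Kerbosch; group counts are tiny), so
  the shared-letter relation equals the non-significance relation
  exactly — the property the brute-force oracle in the test suite
  checks. Letters are ordered by descending group mean, ties broken
  by name. Two constant, equal groups are treated as non-significant
  (p = 1); groups of fewer than two observations are an error.

Hormone dominance: the F1 is "above-both" (overdominant) only when its
mean exceeds each parent *and* both t-tests are significant;
symmetrically "below-both"; otherwise "within-parental-range".
Concentrations below the detection limit count as zero for this range
classification, as missing for clustering distances, and an analyte
undetected everywhere is excluded. These conventions for non-detects
are package choices; the alternatives (e.g. imputing half the
detection limit) are easy to apply upstream of the same functions.

Profile clustering is agglomerative average linkage (UPGMA, scipy) on
Euclidean distances over per-analyte median-centered values. Missing
values are handled pairwise-complete with the d² · p/m rescaling (p
columns total, m jointly observed); because two rows with disjoint
support have no defined distance, `hormone_matrix` keeps only analytes
observed in more than half of the conditions — any two such rows
necessarily overlap. Merge heights are non-decreasing and the result
is invariant to row order; the dendrogram exports to Newick.

Chlorophyll: total chlorophyll (µg/mL) = 17.76·A₆₄₆.₆ + 7.34·A₆₆₃.₆
for 80% (v/v) acetone extracts, with optional normalisation to µg/mg
fresh weight given extract volume and tissue mass.

## Expression quantification and differential expression

FPKM uses the per-sample total of uniquely mapped reads as the library
size (a stored scalar, not the column sum). The mid-parent expression
sample merges the two parental libraries — counts and library sizes
summed — so at equal depths the merged FPKM is the arithmetic mean of
the parental FPKMs, and at unequal depths the depth-weighted mean.

With one library per condition, DE testing conditions on the total
count of a gene: under the null of equal relative expression,
a ~ Binomial(a + b, L_a/(L_a + L_b)). The two-sided p-value sums all
outcomes whose probability does not exceed the observed one (minlike,
with a 10⁻⁷ relative tie tolerance); this is the Audic–Claverie-style
exact test for two-library comparisons. A gene is flagged DE when
|log₂ FPKM ratio| ≥ 1 and p < 0.05. Genes silent in both samples are
skipped; genes silent in exactly one sample have infinite fold change,
so the p-value alone decides. Raw p governs the flag (mirroring the
source analysis); BH q-values are reported alongside. The test models
sampling noise only: biological overdispersion between libraries
inflates its rejection rate, which is why the type-I calibration
property is stated under Poisson sampling (measured 0.038 at
α = 0.05 over 2,000 genes) and why the desk-scale default dispersion
(0.05) yields more flagged genes than the true DE fraction — the
known behaviour of this test class, not a defect of the
implementation. An alternative 2×2 chi-squared route would share the
same limitation.

## Allele-specific expression

SNP discovery requires, per site, coverage ≥ 8 in each parent, major
allele ≥ 95% of reads in each parent (homozygosity filter for inbred
lines), and differing major alleles. Coordinates are 0-based
half-open internally; the VCF export (two homozygous samples, 0/0 and
1/1) converts to 1-based.

Per gene, F1 reads matching each parental allele are summed across the
gene's SNP sites; reads matching neither allele go to a QC tally. The
"five-fold difference" rule is applied to these gene-level aggregated
counts (per-site normalisation cancels in the ratio); a per-site
reading of the rule is possible but not implemented. Significance is
the exact binomial test against 0.5 — this null ignores
reference-mapping bias (out of scope). When only one allele is
observed the mono-allelic rule 0.5ⁿ < 0.001 applies *instead of* the
fold rule; consequently e.g. 0 vs 8 reads stays unclassified even
though its two-sided binomial p would pass 0.05.

The AEL/REL concordance test compares the F1 allelic split to the
parents' own read counts at the same SNP sites (so both margins are
counts of the same kind) in a 2×2 independence test: chi-squared
without continuity correction, replaced by Fisher's exact test when
any expected cell is below 5. Genes with a zero margin are excluded.
No multiple-testing correction is applied to any of the classification
thresholds (q-values are reported).

## Enrichment

Overrepresentation is the upper hypergeometric tail
P(X ≥ k | N, K, n) — the one-sided Fisher exact test — for every term
with at least one hit in the list, with BH q-values across tested
terms and the star convention (`***` < 0.001, `**` < 0.01) on raw p.
The default universe is the expressed-gene set of the comparison that
produced the list. No GO-graph propagation or term trimming is done.

## Synthetic data generator

One global seed drives fixed substreams (`SeedSequence([seed, k])`
with k = 1…5 for phenotypes, transcriptome, F1, annotation,
hormones), so components regenerate independently and identical
(seed, config) pairs are byte-identical.

* **Phenotypes**: Gaussian per individual, truncated at zero by
  redraw; defaults are the published cotyledon/leaf area and fresh
  weight group means with SD = SE·√n recovered from the printed
  standard errors, 30 individuals per line.
* **Counts**: gamma-Poisson with lognormal baseline expression
  (σ = 1) and lognormal library sizes (5% CV) around 500k reads.
  Defaults: 2,000 genes (desk scale versus 41,174 annotated genes at
  ~16M reads in the motivating study; chosen so the full test suite
  and pipeline run in seconds), dispersion 0.05 (a 22% biological CV,
  realistic for isogenic lines), 5% of genes DE at |log₂FC| = 2 split
  symmetrically between the parents (≈100 genes, comparable to the
  ≈200 DE genes of the full-scale study).
* **SNPs and F1 alleles**: 31% of genes carry 3 fixed differences
  (the published fraction of SNP-bearing genes); site coverages are
  Poisson(40) per sample, parents purely homozygous. 3% of SNP genes
  are allele-biased with true P1-allele ratio fold/(1+fold) (5/6 at
  the default fold 5), the rest 0.5; F1 allelic reads are binomial
  per site, independent across sites (read-level linkage between
  sites is not modelled). F1 gene totals are additive (mid-parent)
  except a 0.5% non-additive fraction.
* **Hormones**: 13 analytes with per-line means/SDs at one stage,
  4 replicates, detection limit 1; the pattern plants a salicylic-acid
  overdominance, gibberellin excess in P2, and analytes undetected in
  some or all lines.
* **Annotation**: 50 terms of 5–10% universe size; 10% of terms are
  "enriched" and recruit true-DE genes at odds 8; at odds 1 the
  generator is exactly null (tested by a one-sided uniformity check —
  small discrete terms make hypergeometric p-values super-uniform, so
  a two-sided KS test against the uniform would reject for the
  harmless, conservative reason).

What the generator does **not** emulate: read-level data (FASTQ,
alignment, mapping bias), isoform structure, GC/length biases,
correlated gene modules, batch effects. Passing recovery tests on
this generator therefore demonstrates the correctness of the
statistics under their own sampling assumptions, not robustness to
real-data artefacts.

## Numerical choices and degenerate inputs

* Half-up decimal rounding via `decimal.Decimal` on the `repr` of the
  float, so printed decimals behave as decimals.
* Exact-test ties use a 1 + 10⁻⁷ relative tolerance on pmf
  comparisons (both the DE test and the test-suite oracles).
* Zero-variance t-test inputs: p = 1 for identical constants, p = 0
  for distinct constants; fewer than two observations per group is an
  error.
* Genes/sites that cannot be evaluated (no reads anywhere, zero 2×2
  margin, missing F1 site) are excluded with a warning or error
  rather than imputed.

## Known limitations

* The exact DE test is anti-conservative under biological
  overdispersion (see above); dispersion-moderated models
  (negative-binomial GLMs) are deliberately out of scope.
* The ASE null of 0.5 ignores reference-mapping bias.
* One classifier boundary is worth noting for power planning: a true
  allelic ratio of exactly fold/(1+fold) sits on the ≥ fold-observed
  call threshold, so sensitivity for genes at precisely the
  five-fold effect size is ~50% at any depth; genes beyond the
  threshold are recovered with rapidly increasing probability.
* The letter display gives a valid, canonical cover but does not
  attempt the minimum number of letters for >5 groups (irrelevant at
  the three-line design).
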