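# Methods

## Design and data model

The analysis targets the standard reciprocal-hybrid design: parents P1 and
P2, hybrids H12 (P1 × P2) and H21 (P2 × P1), organs shoot and root, three
biological replicates per genotype × organ × assay. A library is a vector
of per-feature read counts plus its total mapped reads. All coordinates are
0-based half-open internally (BED convention); GFF3 output converts to
1-based closed at the file boundary.

## Statistical procedures

**Normalization.** RPKM = count × 10⁹ / (feature length in bp × total
mapped reads). For expression the length is the exon model; for epigenetic
marks the genic or genomic region. RPKM is linear in counts and
inverse-linear in library size, asserted as a property test.

**Active genes.** Intron coverage measures the read-through background of
a library, so a gene is called transcribed when its mean exon coverage
exceeds the *q*-th quantile (default 0.95) of the pooled intron-coverage
distribution. The quantile is the one free parameter; 0.95 balances the
background's right tail against sensitivity for weakly expressed genes.
With no intron-bearing genes at all, the caller falls back to a fixed
coverage cutoff and warns.

**Modification calls by randomization.** The null places the library's
reads uniformly on the genome; per randomization, genic counts are drawn
as one multinomial over (gene₁ … geneₙ, intergenic remainder), which is
exactly the uniform-placement distribution but costs O(n) per replicate.
Genes are stratified into length deciles and the threshold is the
(1 − α) linearly-interpolated quantile of the pooled null counts within
each stratum (default α = 0.01, 1000 randomizations). Stratification stops
long genes from being called merely for being long; the interpolated
quantile keeps the false-positive rate close to α despite count
discreteness. A fully uniform simulated library of 5,000 genes yields an
observed FPR within two standard errors of 1%.

**Differential test.** Pairwise comparisons use the two-sided Fisher exact
test on the 2×2 table [[a, A−a], [b, B−b]] of counts against library
sizes. The test is exact but assumes Poisson-level sampling noise; with
biological overdispersion it is anticonservative, which is why replicate
concordance is screened first (below) and why the planted-truth recovery
results are read at the simulated dispersion (0.01), not as a general
guarantee. Fold changes add 0.5 to both counts when either is zero, so a
double-zero comparison reports FC = 1 at equal library sizes rather than
an infinity.

**Replicate filter.** A gene is excluded when any replicate pair differs
at P < 0.05 under the same Fisher test; replicates are pooled afterwards.
Pooling matches an analysis that reports per-genotype values rather than a
replicate-level model.

**Mode of gene action.** The expected mid-parent count is the mean of the
two parental rates times the hybrid's library size; the hybrid count is
tested against it at P < 0.001. Significant above → up, below → down.
A non-significant hybrid is *additive* only when the parents themselves
differ at the same cutoff — additivity is unobservable for identical
parents, and those genes are labeled *conserved* instead. Reciprocal
hybrids must carry the same label, else *discordant* (dropped from mode
lists). The classification is exactly symmetric under swapping the parent
labels, asserted as a test. No multiple-testing correction is applied
inside the pairwise tests (the cutoffs are raw P values); instead a
Benjamini–Hochberg FDR for each resulting mode list is reported
descriptively.

**Allelic bias.** The two-sided binomial p-value sums the probability of
every outcome whose Binomial(n, ½) likelihood does not exceed the observed
one (minimum-likelihood rule). This is exact, symmetric in the two
alleles, and never exceeds 1, unlike doubling the smaller tail. Gene-level
calls sum allele counts across the gene's SNPs before testing — the
sufficient statistic when all SNPs of a gene share one bias — rather than
combining per-SNP p-values. Concordance between two call sets counts
direction agreement over genes biased in *both* sets only, and correlates
their allelic log2 ratios (+0.5 continuity).

**siRNA clusters.** Single-linkage chaining per size class: consecutive
reads (sorted by start) join one chain iff the start-to-start gap is
≤ 200 nt; chains of ≥ 6 reads become clusters. Start-based spacing is the
common dialect and differs from end-to-start spacing by at most a read
length (21–24 nt); a config flag (`gap_mode`) switches to end-to-start.
Duplicate-position reads each count toward the minimum. Clusters are
disjoint and maximal by construction, and the caller is verified against
an independent graph-connected-components oracle.

**TE assignment and enrichment.** Same-class TE annotations are merged
before overlap is measured. A region is assigned the class covering ≥ 50%
of the *region's* length (the region, not the TE, anchors the fraction);
the largest overlap wins among qualifying classes, with exact ties broken
alphabetically for determinism. Enrichment per class is a 1-df two-cell χ²
(class vs rest) against the class's share of genomic TE bp; classes with
expected counts below 5 are flagged rather than suppressed.

## The synthetic-data generator

The generator emulates the features the analysis depends on, with defaults
fixed once:

* **Genome** — uniform-length chromosomes; non-overlapping genes of
  1–6 kb with 1–10 exons, 85% placed in the outer two thirds of each
  chromosome (euchromatin), mirroring a heterochromatin-rich cereal
  genome; TE classes at a Gypsy/Copia-dominated mix, with Gypsy (RLG)
  confined to the pericentromeric middle third, hAT/PIF-Harbinger
  (DTA/DTH) gene-proximal, and the rest uniform. TE annotations may
  overlap, as real repeat annotations do.
* **Counts** — negative binomial with var = m + d·m² and d = 0.01 by
  default, the low end of biological-replicate dispersion appropriate for
  inbred lines under controlled growth; a `poisson` flag gives the d → 0
  limit. Per-gene rates are lognormal (σ = 1) and normalized per parent;
  hybrids take the mid-parent rate, times/divided by the mode fold
  (default 4) for planted up/down genes; both reciprocal hybrids share
  every planted mode. Additive genes get parents 4-fold apart, because
  additivity is only detectable when parents differ. Expected genic counts
  sum to 70% of the library size, leaving headroom so total mapped reads
  bound the genic sum. Replicates share one mean (no replicate-level
  effects).
* **Allelic counts** — per-SNP binomial draws at the gene's bias fraction.
* **sRNA reads** — emitted from TEs of designated classes per size class;
  80% of reads arrive in bursts of 6–25 reads spaced ≤ 150 nt (callable
  clusters), the rest as scattered singletons.
* **Methylated regions** — log-normal lengths (median 500 bp); each
  region lands inside a (merged) Gypsy element with probability
  w·f / (w·f + 1 − f) for weight w and Gypsy genomic fraction f, so w = 1
  reproduces the genomic fraction exactly and w = 10 plants strong
  enrichment.

What the generator does **not** emulate: sequence content (no FASTA/FASTQ,
no mapping bias), replicate-level batch effects, GC or length biases in
counting, linkage between SNPs, or chromatin-state autocorrelation beyond
the planted spatial patterns. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
noise model, not robustness to alignment artifacts in real libraries.

## Problem sizes used by the acceptance script

Concordance percentages are recomputed from the study's printed
same-direction/biased-in-both gene counts (333/354, 222/249, 146/170,
261/284). Simulated checks run at: 10,000 balanced SNPs at depth 30 for
the binomial null; 10,000 genes on 2 × 50 Mb at library depth 10⁶,
fold 4, dispersion 0.01 for mode recovery; 5,000 genes for the
randomization-caller FPR; 2 × 10 Mb at 60% TE density with 150,000 sRNA
reads for the TE-class enrichment split; 10,000 reads × 20 seeds for the
cluster-caller oracle; 2,000 random 2×2 tables with margins up to 200 for
the Fisher oracle (the exhaustive sweep in the test suite covers all
tables with margins ≤ 20).

## Known limitations

* Fisher's exact test on pooled counts understates biological variance;
  with strongly overdispersed data the replicate filter becomes aggressive
  and mode calls anticonservative. A dispersion-aware test (e.g.
  negative-binomial GLM) would be the natural extension.
* The randomization null models uniform read placement only; mappability
  and copy-number structure are not represented.
* Gene-level allelic calls assume a shared bias across a gene's SNPs;
  antagonistic SNP-level biases within one gene partially cancel.
* `chromosomal_density` reports covered-bp fraction per bin; overlapping
  features are merged, so it is a coverage track, not an abundance track
  (abundance-weighted windows are used for the siRNA–methylation
  correlation instead).
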