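# Methods

## Scope and data model

The package analyses stranded RNA-seq of a small multi-tissue design.
All coordinates are 0-based half-open internally; GFF3, SAM and VCF
conversions happen only at the format boundary. The in-memory objects
are: `GeneModel` (merged, disjoint exons with a strand), a `CountMatrix`
with two layers (sense, antisense) over genes x samples, `AllelicCount`
(ref/alt/other tallies per sample x site), per-animal `GenotypeCall`
posteriors, and per-test `AseRecord`s. The two statistical cores are
exposed statsmodels-style: `DifferentialExpression(matrix, samples).fit()`
returns a `DEResults` with per-contrast tables, dispersion, MDS and
correlation methods, and a `summary()`; `AseAnalysis(counts, meta).fit()`
returns an `AseResults` with records, genotypes and classification
tables.

## Read assignment

A primary alignment with NH = 1 is oriented by the protocol (reverse:
orientation = opposite of alignment strand) and intersected with the
exon interval index. Genes on the matching strand are sense candidates;
one candidate yields a sense count, several yield `ambiguous`. Only if no
sense candidate exists is a single opposite-strand gene counted
antisense; this sense priority prevents a read from being counted
antisense to a neighbour while it is explained by a same-strand gene.
The per-sample assignment log (sense/antisense/ambiguous/no_feature/
multimapper) always sums to the number of primary records; this
conservation is asserted on every run.

Antisense CPM uses the sense library size as denominator: antisense
totals are one to two orders of magnitude smaller and would make
unstable denominators. The expressed filter (CPM > 1 in >= 2 animals) is
evaluated within tissue, so per-tissue expressed sets match the design's
per-tissue summaries; the union across tissues defines the DE universe.

## Normalisation and differential expression

TMM: reference sample = the one whose 75th-percentile scaled count is
closest to the mean of those; genes with a zero in either sample are
dropped; M and A ranks are doubly trimmed (30% / 5%); the factor is the
2-power of the inverse-variance weighted mean M (delta-method binomial
weights); all factors are centred to geometric mean 1. Fewer than 20
usable genes after trimming triggers a warning and factor 1. The
implementation reproduces edgeR's `calcNormFactors` within ~1e-6 on
random matrices (kept as a cross-check test).

The NB GLM is fitted per gene by IRLS with working weights
mu/(1 + phi mu), batched across genes (one small linear solve per gene
per iteration), step-halving on the log-likelihood, convergence when the
relative log-likelihood change drops below 1e-8 (50 iterations max).
All-zero genes are flagged and returned at baseline. At phi = 0 the fit
reduces exactly to a Poisson GLM (checked against statsmodels).

Dispersion: the common value maximises the summed Cox–Reid adjusted
profile likelihood (APL = loglik − ½ log det X'WX) by golden-section
search on log phi in [1e-6, 10]. Per-gene values maximise
APL_g(phi) + prior_df x mean-APL(phi) on a log grid with quadratic
refinement (prior_df = 10); this is a deliberate simplification of
trended empirical-Bayes shrinkage — acceptance is by parameter recovery
(estimate within a factor of 2 at phi = 0.1, near 0 on Poisson data),
not by matching any external package's output.

Each tissue pair is tested on the union expressed set with design
intercept + tissue + animal against the reduced design without the
tissue column (LRT, chi-square df 1); BH runs per contrast. log2FC is
the fitted tissue coefficient / ln 2; `mean_log_cpm` uses log2 CPM with
the standard 0.25-per-library pseudo-count. Smear tables (log2FC vs mean
log CPM) are emitted per contrast; under a global null the bulk centres
at |median log2FC| < 0.05.

MDS uses the leading-log-fold-change distance (RMS of the top-500
absolute log2-CPM differences per pair) and classical eigendecomposition
of the double-centred squared-distance matrix; axes are sign-fixed so
the first sample has non-negative coordinates. The cross-tissue Spearman
matrix defaults to per-tissue mean profiles (a per-sample variant is
available by flag); the sense set is genes with mean CPM > 1 in at least
one tissue, the antisense set additionally requires >= 10 pooled
antisense reads in that tissue.

## ASE inference

Site discovery is a naive pooled pileup, a declared stand-in for
haplotype-based calling: the downstream contract needs only biallelic
sites and counts. Positions qualify with total base-quality-filtered
coverage > 10 and exactly two alleles supported by >= 3 reads, one being
the reference base. At deep pooled coverage a uniform error rate
produces error-supported sites; these are genotyped homozygous and never
reach the imbalance tests, so they cost masking only. The reference is
N-masked at all sites (idempotent); within the pipeline allelic counts
are computed directly from the simulated reads, which carry no mapping
bias, so the masking path is exercised for byte-level correctness rather
than for bias removal.

Allelic counting keeps primary unique reads with MAPQ > 10 and bases
with quality > 2, counts a read id once per site, and drops
(sample, site) records below depth 10. "Other" bases count toward depth
but not the test. A vectorised pileup-based counter is used by the
pipeline for speed; the record-based counter is the reference
implementation and both are asserted equal on simulated data.

Genotyping pools an animal's counts across tissues and runs an EM with
a single per-animal error rate eps shared across sites (read model:
P(ref) = 1 − eps / ½ / eps under homRef/het/homAlt; uniform genotype
prior; init eps = 0.01; stop at |delta eps| < 1e-6 or 100 iterations).
When essentially no reads are posterior-assigned to homozygous classes
the update is skipped — with no homozygous sites eps is unidentifiable
and chasing it degenerates the calls. Calls need pooled coverage >= 5
and posterior >= 0.99.

The imbalance test is the exact two-sided binomial of ref_count out of
ref+alt against 0.5 via the minimum-likelihood tail (equal to tail
doubling for a symmetric null; the definition is kept general so an
eps-adjusted null remains an option). Only het-called animals with >= 10
informative reads in the tissue are tested; BH runs within each tissue
over all (animal, site) tests — the family choice is logged and
switchable. Sites map to genes whose merged span ± 5 kb contains them,
inclusive at exactly 5,000 bases (a deterministic reading of a "< 5 kb"
annotation convention). Per tissue: an ASE SNP is significant for >= 1
het animal; a consistent ASE SNP for every het animal tested; ASE genes
collect assigned sites. Across tissues: shared ASE genes are ASE
wherever tested; a tissue-specific ASE gene is ASE in exactly one tissue
with no significant imbalance elsewhere while expressed elsewhere.

## Synthetic data

The generator emulates the study design: 4 animals x 4 tissues, stranded
single-end 100 bp reads (reverse protocol), ~1e5 fragments per sample,
2,000 exon-structured genes (1–3 exons of 300–1,200 bp) packed without
overlap on alternating strands of a random ~50% GC genome. Expression:
log-normal baselines; 30% of genes carry a tissue effect of |log2FC|
uniform in [1, 3] with random sign, applied to a tissue subset — mostly
{IPP, JPP} together (weight 0.35), else MLN (0.2), PB (0.3), or a single
PP (0.075 each) — so the two Peyer's patch types stay each other's
nearest neighbours while still differing at a smaller gene set. Animal
replicates are negative-binomial at dispersion 0.1. Antisense
transcription (22% of genes) is an independent opposite-strand stream
with its own baseline and tissue effects, scaled to 5% of the sense
library; independence (rather than antisense proportional to sense) is
what makes the within-tissue sense/antisense correlation a null the
analysis should measure as near zero. Heterozygous sites sit in exons at
0.5 het SNPs/kb/animal (HWE-style genotypes at het probability 0.5);
10% of sites are imbalanced with reference-allele share 0.7; reads carry
haplotype alleles (per-site Bernoulli draws; reads spanning several het
sites share one uniform draw) and uniform substitution errors at 0.005
per base. Truth tables record every draw: baselines, per-tissue log2FC,
antisense flags, genotypes, allelic ratios, realized per-sample counts.

Not emulated: mapping bias and mappability structure (all reads align
perfectly and uniquely at MAPQ 60 with NH 1), fragment-length and
positional coverage biases, intron-spanning reads, paired-end inserts,
indels, and any batch or sampling-time effects (the blood sampling of
the emulated design predates tissue sampling; tissues are treated as
exchangeable conditions). Passing tests therefore validate the
statistical machinery and the counting semantics, not robustness to
alignment artefacts. An optional blood mode (off by default) lets two
globin-like genes absorb ~70% of the PB library to emulate the
compositional sink of un-depleted blood.

## Problem sizes and numerical choices

Benchmarks run at sizes chosen to make Monte-Carlo error small relative
to the thresholds they feed: null calibration at 2,000 genes (8
samples), power at 400 genes, dispersion recovery at 500 genes x 16
samples, genotyping at 1,500 sites, imbalance recovery at 600 sites x 16
samples, structure recovery over 100 count-level replicates of the full
2,000-gene design, and the end-to-end study at the default 2,000 genes x
1e5 fragments x 16 samples. Imbalance recall is a site-level quantity
(a site is recalled when significant for >= 1 het animal in >= 1
tissue — the ASE-SNP definition); error control is measured at the test
level, the level BH actually controls. Degenerate inputs are handled
explicitly: all-zero genes are flagged at baseline, zero-library samples
make CPM raise, empty ASE runs produce empty-but-typed tables, and
factors/posteriors are guarded against log-of-zero by clamping
(mu >= 1e-10, eps in [1e-6, 0.49]).

## Known limitations

Per-gene dispersion shrinkage uses a global common curve, not an
abundance trend; the discovery filter is deliberately naive (no
haplotype assembly, indels, or strand-bias filters); the genotyping EM
assumes one error rate per animal; the binomial test ignores
overdispersion of allelic counts across tissues (each tissue is tested
separately rather than jointly); and the 5 kb gene window can span
neighbouring genes in the compact synthetic genome, so synthetic "ASE
gene" tallies include nearby-gene assignments exactly as a real
annotation window would in gene-dense regions.
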