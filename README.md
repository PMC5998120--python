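# galtase

Strand-aware RNA-seq analysis of multi-tissue designs: sense/antisense
gene quantification, TMM-normalised negative-binomial differential
expression, cross-tissue expression structure, and allele-specific
expression (ASE) inference — with a truth-tracked synthetic-data
generator so every stage can be validated end to end.

The package targets the kind of study where a small number of animals is
sequenced across several immune tissues — by default four animals x four
tissues: mesenteric lymph nodes (MLN), ileal and jejunal Peyer's patches
(IPP, JPP) and peripheral blood (PB) — with a stranded library protocol,
and the questions are (i) which genes differ between tissues, (ii) how
much opposite-strand (antisense) transcription annotated genes carry, and
(iii) which heterozygous sites show cis-regulatory allelic imbalance, in
which tissues.

## Models and statistics

**Counting.** Each primary, uniquely-mapped read is assigned by exon
overlap with strand awareness: under the reverse (dUTP) protocol the read
orientation is the opposite of its alignment strand; a read whose
orientation matches the overlapped gene's strand counts *sense*,
otherwise *antisense* to that gene. Multi-mappers (NH > 1) are discarded;
sense assignment takes priority and ties are ambiguous. CPM uses the
sense library size for both layers; a gene is *expressed* in a tissue
when CPM > 1 in at least two animals.

**Differential expression.** Per gene a negative-binomial GLM with log
link, Var(y) = mu + phi mu^2, offsets log(library x TMM factor) and design
`~ tissue + animal`. TMM factors are doubly-trimmed (30% on M, 5% on A)
inverse-variance-weighted mean log-ratios against a reference sample,
centred to geometric mean 1 (matches edgeR's `calcNormFactors` to ~1e-6).
Dispersion phi is estimated by Cox–Reid adjusted profile likelihood: a
common maximizer, then per-gene values shrunk towards the common curve
(prior weight 10). Each tissue pair is tested by a likelihood-ratio test
(chi-square, df 1), BH-corrected per contrast; genes with FDR < 0.05 and
|log2FC| >= 1 are flagged *strong*.

**Structure.** Classical MDS on leading-log-fold-change distances (root
mean square of the top-500 absolute log2-CPM differences per sample pair)
and a cross-tissue Spearman matrix: sense profiles below the diagonal,
antisense above, within-tissue sense-vs-antisense on it.

**ASE.** Biallelic SNVs are discovered by a naive pooled pileup (base
quality > 10, coverage > 10, both alleles supported by >= 3 reads), the
reference is N-masked at the sites, and quality-filtered allelic counts
(depth >= 10, MAPQ > 10, base quality > 2) feed a per-animal genotyping
EM: reads follow P(ref | homRef) = 1 − eps, P(ref | het) = 1/2,
P(ref | homAlt) = eps with one error rate eps per animal shared across
sites and tissues (pooled coverage >= 5, posterior call threshold 0.99).
At heterozygous sites with >= 10 informative reads, allelic imbalance is
an exact two-sided binomial test against 0.5 (minimum-likelihood tail),
BH-corrected within each tissue. A *consistent* ASE SNP is significant
for every heterozygous animal tested; ASE genes collect sites within
5 kb of a gene span.

## Worked example

```python
from galtase import pipeline

cfg = pipeline.load_config({
    "seed": 7,
    "simulate": {"n_genes": 200, "library_size": 20000, "het_density": 1.0},
})
pipeline.run_all(cfg, "demo_run")
print(open("demo_run/report/report.md").read())
```

The run simulates 16 stranded libraries (4 animals x MLN/IPP/JPP/PB) from
a diploid synthetic genome, counts them, and prints a report whose
differential-expression table looks like:

```
| contrast   |   de |   over |   under |   de_strong |   over_strong |   under_strong |
|:-----------|-----:|-------:|--------:|------------:|--------------:|---------------:|
| MLN vs IPP |   38 |     20 |      18 |          37 |            19 |             18 |
| MLN vs JPP |   40 |     21 |      19 |          39 |            21 |             18 |
| IPP vs JPP |    5 |      3 |       2 |           5 |             3 |              2 |
```

i.e. far fewer genes separate the two Peyer's patch types than separate
either from the lymph node — the biological signature the generator
encodes (most tissue effects are shared by IPP and JPP) and the analysis
recovers. The correlation table shows the same structure
(corr(IPP,JPP) = 0.97 sense, vs ~0.87 against MLN) with near-zero
sense/antisense diagonals, and the ASE summary tallies heterozygous SNPs
tested, ASE SNPs, consistent ASE SNPs and ASE genes per tissue.

The same stages are available from the shell:

```bash
galtase simulate --config cfg.yaml --outdir run
galtase quantify --config cfg.yaml --outdir run
galtase de       --config cfg.yaml --outdir run
galtase ase      --config cfg.yaml --outdir run
galtase report   --config cfg.yaml --outdir run
```

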