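"""Truth-tracked synthetic data with the structure the pipeline assumes.

The generator emulates a four-animal, four-tissue (MLN, IPP, JPP, PB)
stranded RNA-seq design: a random reference genome with non-overlapping
exon-structured genes on alternating strands; diploid individuals with
heterozygous SNPs in exons, a fraction of which carry a true allelic
imbalance; per-gene negative-binomial expression with tissue effects
(ileal and jejunal Peyer's patches share most of their differential
signal, mirroring the tight PP pairing the analysis is meant to recover);
independent opposite-strand transcription at a subset of genes; and
stranded single-end reads carrying haplotype alleles and uniform
sequencing errors, written as one SAM per sample.

Every stochastic choice is recorded in truth tables so downstream
estimates can be scored against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from galtase.io import (
    GeneModel,
    SampleMeta,
    VariantSite,
    write_fasta,
    write_gff3,
    write_sample_sheet,
    write_vcf,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; ``seed`` is mandatory.

    Defaults describe the emulated study design: 4 animals x 4 tissues,
    stranded reverse-protocol 100 bp single-end reads, |log2FC| uniform in
    [1, 3] for DE genes, antisense at ~22% of genes at 5% of the sense
    level, heterozygous sites in exons with 10% of them imbalanced at a
    reference-allele share of 0.7, and NB dispersion 0.1 across animals.
    """

    seed: int
    n_animals: int = 4
    tissues: tuple[str, ...] = ("MLN", "IPP", "JPP", "PB")
    n_genes: int = 2000
    genome_length: int | None = None
    fraction_de: float = 0.3
    logfc_range: tuple[float, float] = (1.0, 3.0)
    fraction_antisense: float = 0.22
    antisense_level: float = 0.05
    het_density: float = 0.5  # het SNPs per exonic kb per animal
    het_probability: float = 0.5
    fraction_ase_sites: float = 0.1
    ase_ratio: float = 0.7
    seq_error: float = 0.005
    library_size: int = 100_000
    read_length: int = 100
    protocol: str = "reverse"
    dispersion: float = 0.1
    exons_per_gene: tuple[int, int] = (1, 3)
    exon_length: tuple[int, int] = (300, 1200)
    intron_length: tuple[int, int] = (100, 400)
    intergenic: tuple[int, int] = (200, 800)
    blood_globins: bool = False
    globin_share: float = 0.7

    def __post_init__(self) -> None:
        for name in ("fraction_de", "fraction_antisense", "het_probability", "fraction_ase_sites"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.ase_ratio < 1.0:
            raise ValueError("ase_ratio must be in (0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.protocol not in ("forward", "reverse"):
            raise ValueError("protocol must be 'forward' or 'reverse'")

    @property
    def animals(self) -> list[str]:
        return [f"A{i + 1}" for i in range(self.n_animals)]

    @property
    def samples(self) -> list[SampleMeta]:
        return [
            SampleMeta(sample_id=f"{a}_{t}", animal_id=a, tissue=t)
            for a in self.animals
            for t in self.tissues
        ]


def nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with variance mu + phi*mu^2 (Poisson at phi=0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * np.maximum(mean, 0.0))
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Reference and gene models


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random ~50% GC genome with non-overlapping alternating-strand genes."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    genes: list[GeneModel] = []
    cursor = 0
    for i in range(config.n_genes):
        cursor += int(rng.integers(*config.intergenic, endpoint=True))
        n_exons = int(rng.integers(*config.exons_per_gene, endpoint=True))
        exons = []
        pos = cursor
        for e in range(n_exons):
            if e > 0:
                pos += int(rng.integers(*config.intron_length, endpoint=True))
            length = int(rng.integers(*config.exon_length, endpoint=True))
            exons.append((pos, pos + length))
            pos += length
        genes.append(
            GeneModel(
                gene_id=f"G{i + 1:05d}",
                chrom="chr1",
                strand="+" if i % 2 == 0 else "-",
                exons=tuple(exons),
            )
        )
        cursor = pos
    total = cursor + int(rng.integers(*config.intergenic, endpoint=True))
    length = config.genome_length if config.genome_length is not None else total
    if length < total:
        raise ValueError(
            f"infeasible packing: {config.n_genes} genes need {total} bp "
            f"but genome_length={length}"
        )
    seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    return {"chr1": seq}, genes


# ---------------------------------------------------------------------------
# Individuals and variant sites


@dataclass
class IndividualTruth:
    sites: list[VariantSite]
    genotypes: pd.DataFrame  # animals x sites, values in {homRef, het, homAlt}
    ratios: np.ndarray  # per-site true reference-allele share at het sites


def simulate_individuals(
    config: SimulationConfig,
    reference: dict[str, str],
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> IndividualTruth:
    """Place exonic SNP sites and draw per-animal genotypes.

    Site density is het_density / het_probability per exonic kb, so each
    animal is heterozygous at ~het_density sites per kb.  A fraction of
    sites is flagged imbalanced with reference-allele share ``ase_ratio``;
    the rest are balanced at 0.5.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    exonic = np.concatenate(
        [np.arange(s, e) for g in genes for (s, e) in g.exons]
    ) if genes else np.array([], dtype=int)
    density = config.het_density / max(config.het_probability, 1e-12)
    n_sites = int(round(len(exonic) / 1000.0 * density))
    n_sites = min(n_sites, len(exonic))
    if n_sites == 0 or config.het_density == 0:
        return IndividualTruth(
            sites=[],
            genotypes=pd.DataFrame(index=config.animals),
            ratios=np.array([]),
        )
    positions = np.sort(rng.choice(exonic, size=n_sites, replace=False))
    chrom_seq = reference["chr1"]
    sites = []
    for pos in positions:
        ref = chrom_seq[pos]
        alt = _BASE_STR[(_BASE_STR.index(ref) + int(rng.integers(1, 4))) % 4]
        sites.append(VariantSite(chrom="chr1", pos=int(pos), ref_allele=ref, alt_allele=alt))
    u = rng.random((config.n_animals, n_sites))
    v = rng.random((config.n_animals, n_sites))
    genotype = np.where(
        u < config.het_probability, "het", np.where(v < 0.5, "homRef", "homAlt")
    )
    geno = pd.DataFrame(
        genotype, index=config.animals, columns=[s.pos for s in sites]
    )
    imbalanced = rng.random(n_sites) < config.fraction_ase_sites
    ratios = np.where(imbalanced, config.ase_ratio, 0.5)
    return IndividualTruth(sites=sites, genotypes=geno, ratios=ratios)


# ---------------------------------------------------------------------------
# Expression structure


def _de_patterns(config: SimulationConfig) -> list[tuple[frozenset, float]]:
    """Tissue subsets receiving a shared expression shift, with weights.

    With the default tissue set most DE genes shift the two Peyer's patch
    tissues together, so IPP and JPP stay each other's nearest neighbours
    while still differing at a smaller set of genes.
    """
    tissues = set(config.tissues)
    if {"IPP", "JPP"}.issubset(tissues):
        patterns = [(frozenset({"IPP", "JPP"}), 0.35)]
        patterns += [(frozenset({t}), 0.0) for t in ()]
        if "MLN" in tissues:
            patterns.append((frozenset({"MLN"}), 0.2))
        if "PB" in tissues:
            patterns.append((frozenset({"PB"}), 0.3))
        patterns.append((frozenset({"IPP"}), 0.075))
        patterns.append((frozenset({"JPP"}), 0.075))
    else:
        patterns = [(frozenset({t}), 1.0) for t in config.tissues]
    total = sum(w for _, w in patterns)
    return [(p, w / total) for p, w in patterns if w > 0]


@dataclass
class ExpressionTruth:
    samples: list[SampleMeta]
    baseline: np.ndarray  # per-gene relative abundance
    log2fc: pd.DataFrame  # genes x tissues
    antisense_flag: np.ndarray
    sense_mean: np.ndarray  # genes x samples expected counts
    antisense_mean: np.ndarray
    sense_counts: np.ndarray  # genes x samples realized counts
    antisense_counts: np.ndarray


def simulate_expression(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> ExpressionTruth:
    """Expected and realized sense/antisense counts per (gene, sample).

    Baselines are log-normal; DE genes shift a tissue subset by a log2
    fold change of magnitude uniform in ``logfc_range`` with random sign;
    tissue profiles are renormalised so each sample's expected sense total
    is ``library_size``; per-animal counts are NB draws at the configured
    dispersion.  Antisense transcription at flagged genes is an
    independent opposite-strand stream: its own log-normal baseline and
    its own tissue effects, scaled so the expected antisense total is
    ``antisense_level`` x the sense library — so sense and antisense
    levels of a gene are uncoupled across genes, the regime the analysis
    is meant to detect.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 3])
    G = len(genes)
    tissues = list(config.tissues)
    baseline = rng.lognormal(mean=0.0, sigma=1.2, size=G)
    lfc = np.zeros((G, len(tissues)))
    is_de = rng.random(G) < config.fraction_de
    patterns = _de_patterns(config)
    weights = np.array([w for _, w in patterns])
    choice = rng.choice(len(patterns), size=G, p=weights)
    mag = rng.uniform(*config.logfc_range, size=G)
    sign = np.where(rng.random(G) < 0.5, 1.0, -1.0)
    for g in range(G):
        if not is_de[g]:
            continue
        subset = patterns[choice[g]][0]
        for t_idx, t in enumerate(tissues):
            if t in subset:
                lfc[g, t_idx] = sign[g] * mag[g]
    anti_flag = rng.random(G) < config.fraction_antisense
    # independent antisense stream: own baseline, own tissue effects
    anti_baseline = rng.lognormal(mean=0.0, sigma=1.2, size=G) * anti_flag
    anti_lfc = np.zeros((G, len(tissues)))
    anti_is_de = rng.random(G) < config.fraction_de
    anti_choice = rng.choice(len(patterns), size=G, p=weights)
    anti_mag = rng.uniform(*config.logfc_range, size=G)
    anti_sign = np.where(rng.random(G) < 0.5, 1.0, -1.0)
    for g in range(G):
        if not (anti_is_de[g] and anti_flag[g]):
            continue
        subset = patterns[anti_choice[g]][0]
        for t_idx, t in enumerate(tissues):
            if t in subset:
                anti_lfc[g, t_idx] = anti_sign[g] * anti_mag[g]

    mean_gt = baseline[:, None] * 2.0 ** lfc  # genes x tissues
    if config.blood_globins and "PB" in tissues and G >= 2:
        pb = tissues.index("PB")
        rest = 1.0 - config.globin_share
        mean_gt[:, pb] *= rest / mean_gt[:, pb].sum()
        top2 = [0, 1]
        mean_gt[top2[0], pb] += config.globin_share * 0.6
        mean_gt[top2[1], pb] += config.globin_share * 0.4
    mean_gt = mean_gt / mean_gt.sum(axis=0, keepdims=True) * config.library_size

    anti_gt = anti_baseline[:, None] * 2.0 ** anti_lfc
    total = anti_gt.sum(axis=0, keepdims=True)
    total[total == 0] = 1.0
    anti_gt = anti_gt / total * (config.antisense_level * config.library_size)

    samples = config.samples
    sense_mean = np.column_stack([mean_gt[:, tissues.index(s.tissue)] for s in samples])
    anti_mean = np.column_stack([anti_gt[:, tissues.index(s.tissue)] for s in samples])
    sense_counts = nb_draw(rng, sense_mean, config.dispersion)
    anti_counts = nb_draw(rng, anti_mean, config.dispersion)
    return ExpressionTruth(
        samples=samples,
        baseline=baseline,
        log2fc=pd.DataFrame(lfc, index=[g.gene_id for g in genes], columns=tissues),
        antisense_flag=anti_flag,
        sense_mean=sense_mean,
        antisense_mean=anti_mean,
        sense_counts=sense_counts,
        antisense_counts=anti_counts,
    )


# ---------------------------------------------------------------------------
# Read simulation


def _sam_header(reference: dict[str, str]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, seq in reference.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    return "\n".join(lines) + "\n"


def _gene_reads(
    rng: np.random.Generator,
    ref_arr: np.ndarray,
    gene: GeneModel,
    n: int,
    read_length: int,
    sites_pos: np.ndarray,
    sites_ref: np.ndarray,
    sites_alt: np.ndarray,
    site_geno: np.ndarray,  # 0 homRef, 1 het, 2 homAlt for this animal
    site_ratio: np.ndarray,
    seq_error: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Start positions and base matrices for n fragments of one gene."""
    usable = [(s, e) for s, e in gene.exons if e - s >= read_length]
    if not usable:
        raise ValueError(
            f"gene {gene.gene_id}: read length {read_length} exceeds every exon span"
        )
    lens = np.array([e - s - read_length + 1 for s, e in usable], dtype=float)
    exon_idx = rng.choice(len(usable), size=n, p=lens / lens.sum())
    offs = (rng.random(n) * lens[exon_idx]).astype(int)
    starts = np.array([usable[i][0] for i in exon_idx]) + offs
    reads = ref_arr[starts[:, None] + np.arange(read_length)[None, :]].copy()
    if sites_pos.size:
        hap_u = rng.random(n)
        lo, hi = gene.span
        in_gene = (sites_pos >= lo) & (sites_pos < hi)
        for k in np.where(in_gene)[0]:
            pos = sites_pos[k]
            rows = np.where((starts <= pos) & (pos < starts + read_length))[0]
            if rows.size == 0:
                continue
            g = site_geno[k]
            if g == 0:
                continue  # reference allele already in place
            col = pos - starts[rows]
            if g == 2:
                reads[rows, col] = sites_alt[k]
            else:  # het: reference haplotype with probability ratio
                take_alt = hap_u[rows] >= site_ratio[k]
                reads[rows[take_alt], col[take_alt]] = sites_alt[k]
                reads[rows[~take_alt], col[~take_alt]] = sites_ref[k]
    if seq_error > 0 and n > 0:
        err = rng.random((n, read_length)) < seq_error
        if err.any():
            # map each base to one of the other three, uniformly
            lut = np.zeros(256, dtype=np.uint8)
            lut[_BASES] = np.arange(4)
            codes = lut[reads[err]]
            shift = rng.integers(1, 4, size=codes.shape)
            reads[err] = _BASES[(codes + shift) % 4]
    return starts, reads


def simulate_reads(
    config: SimulationConfig,
    reference: dict[str, str],
    genes: Sequence[GeneModel],
    individuals: IndividualTruth,
    expression: ExpressionTruth,
    outdir,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Write one SAM per sample; return the per-sample emission truth.

    Sense fragments start uniformly within an exon of their gene; at
    heterozygous sites of the sample's animal the read carries the
    reference allele with the site's true reference share; per-base
    substitution errors occur at ``seq_error`` (uniform over the other
    three bases).  Under the reverse protocol the alignment strand is the
    opposite of the transcript strand.  Antisense fragments use the same
    exon span on the opposite transcript strand.  All reads are primary,
    MAPQ 60, NH:i:1.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 4])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_arr = np.frombuffer(reference["chr1"].encode("ascii"), dtype=np.uint8)
    header = _sam_header(reference)
    L = config.read_length
    qual = "I" * L
    sites_pos = np.array([s.pos for s in individuals.sites], dtype=int)
    sites_ref = np.array(
        [ord(s.ref_allele) for s in individuals.sites], dtype=np.uint8
    )
    sites_alt = np.array(
        [ord(s.alt_allele) for s in individuals.sites], dtype=np.uint8
    )
    geno_code = {"homRef": 0, "het": 1, "homAlt": 2}
    rows = []
    for s_idx, sample in enumerate(expression.samples):
        if sites_pos.size:
            site_geno = np.array(
                [geno_code[g] for g in individuals.genotypes.loc[sample.animal_id]]
            )
        else:
            site_geno = np.array([], dtype=int)
        emitted = 0
        path = outdir / f"{sample.sample_id}.sam"
        with open(path, "w") as fh:
            fh.write(header)
            for layer, counts_col in (
                ("sense", expression.sense_counts[:, s_idx]),
                ("antisense", expression.antisense_counts[:, s_idx]),
            ):
                for g_idx, gene in enumerate(genes):
                    n = int(counts_col[g_idx])
                    if n == 0:
                        continue
                    starts, reads = _gene_reads(
                        rng, ref_arr, gene, n, L,
                        sites_pos, sites_ref, sites_alt, site_geno,
                        individuals.ratios, config.seq_error,
                    )
                    transcript_strand = gene.strand if layer == "sense" else (
                        "-" if gene.strand == "+" else "+"
                    )
                    if config.protocol == "reverse":
                        align_strand = "-" if transcript_strand == "+" else "+"
                    else:
                        align_strand = transcript_strand
                    flag = 16 if align_strand == "-" else 0
                    tag = "s" if layer == "sense" else "a"
                    for i in range(n):
                        seq = reads[i].tobytes().decode("ascii")
                        fh.write(
                            f"{sample.sample_id}:{gene.gene_id}:{tag}{i}\t{flag}\tchr1\t"
                            f"{starts[i] + 1}\t60\t{L}M\t*\t0\t0\t{seq}\t{qual}\tNH:i:1\n"
                        )
                    emitted += n
        rows.append(
            {
                "sample": sample.sample_id,
                "animal": sample.animal_id,
                "tissue": sample.tissue,
                "true_sense_fragments": int(expression.sense_counts[:, s_idx].sum()),
                "true_antisense_fragments": int(expression.antisense_counts[:, s_idx].sum()),
                "emitted_reads": emitted,
                "sam": path.name,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-dataset driver


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: dict[str, str]
    genes: list[GeneModel]
    individuals: IndividualTruth
    expression: ExpressionTruth
    sample_truth: pd.DataFrame
    outdir: Path = field(default=None)  # type: ignore[assignment]

    @property
    def samples(self) -> list[SampleMeta]:
        return self.expression.samples

    def sam_path(self, sample_id: str) -> Path:
        return Path(self.outdir) / f"{sample_id}.sam"


def simulate_dataset(config: SimulationConfig, outdir) -> SimulatedDataset:
    """Run the full generator and write FASTA/GFF3/VCF/SAM/truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, genes = simulate_reference(config)
    write_fasta(reference, outdir / "genome.fasta")
    write_gff3(genes, outdir / "genes.gff3")
    individuals = simulate_individuals(config, reference, genes)
    gt_code = {"homRef": "0/0", "het": "0/1", "homAlt": "1/1"}
    write_vcf(
        individuals.sites,
        outdir / "truth_sites.vcf",
        samples=config.animals,
        genotypes={
            a: [gt_code[g] for g in individuals.genotypes.loc[a]] for a in config.animals
        }
        if individuals.sites
        else None,
        contigs=[(n, len(s)) for n, s in reference.items()],
    )
    expression = simulate_expression(config, genes)
    write_sample_sheet(expression.samples, outdir / "sample_sheet.tsv")
    sample_truth = simulate_reads(config, reference, genes, individuals, expression, outdir)
    # truth tables
    truth_genes = expression.log2fc.copy()
    truth_genes.insert(0, "baseline", expression.baseline)
    truth_genes["antisense"] = expression.antisense_flag
    truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index_label="gene_id")
    if individuals.sites:
        site_rows = pd.DataFrame(
            {
                "chrom": [s.chrom for s in individuals.sites],
                "pos": [s.pos for s in individuals.sites],
                "ref": [s.ref_allele for s in individuals.sites],
                "alt": [s.alt_allele for s in individuals.sites],
                "ref_share": individuals.ratios,
            }
        )
        for a in config.animals:
            site_rows[a] = list(individuals.genotypes.loc[a])
        site_rows.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    sample_truth.to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)
    gene_ids = [g.gene_id for g in genes]
    sample_ids = [s.sample_id for s in expression.samples]
    pd.DataFrame(expression.sense_counts, index=gene_ids, columns=sample_ids).to_csv(
        outdir / "truth_counts_sense.tsv", sep="\t", index_label="gene_id"
    )
    pd.DataFrame(expression.antisense_counts, index=gene_ids, columns=sample_ids).to_csv(
        outdir / "truth_counts_antisense.tsv", sep="\t", index_label="gene_id"
    )
    return SimulatedDataset(
        config=config,
        reference=reference,
        genes=genes,
        individuals=individuals,
        expression=expression,
        sample_truth=sample_truth,
        outdir=outdir,
    )
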