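"""Allele-specific expression (ASE) inference from stranded RNA-seq.

Stages: naive pileup discovery of biallelic substitution sites across all
samples (a declared stand-in for haplotype-based calling — the downstream
contract needs only biallelic sites and counts), N-masking of the
reference at the discovered sites to remove reference mapping bias,
quality-filtered allelic counting per sample, per-animal genotyping by an
EM error model over the animal's pooled tissues, exact binomial tests of
allelic imbalance at heterozygous sites, per-tissue Benjamini-Hochberg
correction, and gene-level classification (consistent ASE, shared and
tissue-specific ASE genes).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.stats import binomtest

from galtase.de import bh_fdr
from galtase.io import AlignmentRecord, GeneModel, VariantSite

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class AllelicCount:
    """Reference/alternative read tallies at one site in one sample."""

    sample_id: str
    site: VariantSite
    ref_count: int
    alt_count: int
    other_count: int = 0

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count + self.other_count


@dataclass(frozen=True)
class GenotypeCall:
    """Posterior over {homRef, het, homAlt} for one animal at one site."""

    animal_id: str
    site: VariantSite
    posterior: tuple[float, float, float]
    call: str  # homRef / het / homAlt / no_call
    pooled_coverage: int


@dataclass
class AseRecord:
    """One binomial allelic-imbalance test (animal x tissue x het site)."""

    animal_id: str
    tissue: str
    site: VariantSite
    ref_count: int
    alt_count: int
    p_value: float
    fdr: float = math.nan
    significant: bool = False
    gene_ids: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Pileup and site discovery


def pileup_base_counts(
    sam_paths: Sequence,
    min_base_quality: int = 10,
    min_mapq: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-chromosome (4, L) base counts over primary unique alignments.

    Bases with quality <= ``min_base_quality`` or outside ACGT are
    ignored, as are reads at or below ``min_mapq`` when set.  Reads whose
    CIGAR is a single match block take a vectorised path; any other read
    is piled up via its aligned pairs.
    """
    counts: dict[str, np.ndarray] = {}
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)

    def flush(chrom: str, starts: list[int], seqs: list[str], quals: list[str]) -> None:
        # uniform-length reads: one (R, L) matrix per chunk
        arr = counts[chrom]
        length = len(seqs[0])
        codes = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
        codes = codes.reshape(len(seqs), length)
        qarr = np.frombuffer(b"".join(quals), dtype=np.uint8).reshape(
            len(seqs), length
        ).astype(np.int16)
        pos = np.asarray(starts, dtype=np.int64)[:, None] + np.arange(length)[None, :]
        keep = qarr > min_base_quality
        for b_idx, byte in enumerate(base_bytes):
            sel = keep & (codes == byte)
            if sel.any():
                arr[b_idx] += np.bincount(pos[sel], minlength=arr.shape[1])

    for path in sam_paths:
        buf: dict[tuple[str, int], tuple[list[int], list[str], list[str]]] = {}
        with pysam.AlignmentFile(str(path), "r") as fh:
            for chrom, length in zip(fh.references, fh.lengths):
                counts.setdefault(chrom, np.zeros((4, length), dtype=np.int64))
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.has_tag("NH") and aln.get_tag("NH") > 1:
                    continue
                if min_mapq is not None and aln.mapping_quality <= min_mapq:
                    continue
                chrom = aln.reference_name
                seq = aln.query_sequence
                cig = aln.cigartuples
                if len(cig) == 1 and cig[0][0] == 0:  # single M block
                    key = (chrom, len(seq))
                    starts, seqs, quals = buf.setdefault(key, ([], [], []))
                    starts.append(aln.reference_start)
                    seqs.append(seq.upper())
                    qq = aln.query_qualities
                    quals.append(bytes(qq) if qq is not None else b"\x5d" * len(seq))
                    if len(starts) >= 20000:
                        flush(chrom, starts, seqs, quals)
                        buf[key] = ([], [], [])
                else:
                    arr = counts[chrom]
                    quals_arr = aln.query_qualities
                    for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                        base = seq[qpos].upper()
                        if base not in _BASE_INDEX:
                            continue
                        if quals_arr is not None and quals_arr[qpos] <= min_base_quality:
                            continue
                        arr[_BASE_INDEX[base], rpos] += 1
        for (chrom, _), (starts, seqs, quals) in buf.items():
            if starts:
                flush(chrom, starts, seqs, quals)
    return counts


def discover_sites(
    sam_paths: Sequence,
    reference: Mapping[str, str],
    min_base_quality: int = 10,
    min_coverage: int = 10,
    min_minor_count: int = 3,
) -> list[VariantSite]:
    """Naive biallelic SNV discovery from the pooled pileup of all samples.

    A position becomes a site when its total high-quality coverage exceeds
    ``min_coverage``, exactly two bases reach ``min_minor_count`` support,
    and one of them is the reference base (the other becomes the
    alternative allele).
    """
    counts = pileup_base_counts(sam_paths, min_base_quality)
    sites: list[VariantSite] = []
    for chrom in sorted(counts):
        arr = counts[chrom]
        ref_seq = reference[chrom]
        coverage = arr.sum(axis=0)
        supported = (arr >= min_minor_count).sum(axis=0)
        cand = np.where((coverage > min_coverage) & (supported == 2))[0]
        for pos in cand:
            col = arr[:, pos]
            alleles = [b for b in _BASES if col[_BASE_INDEX[b]] >= min_minor_count]
            ref_base = ref_seq[pos].upper()
            if ref_base not in alleles:
                continue
            alt = alleles[0] if alleles[1] == ref_base else alleles[1]
            sites.append(VariantSite(chrom=chrom, pos=int(pos), ref_allele=ref_base, alt_allele=alt))
    return sites


def mask_reference(reference: Mapping[str, str], sites: Iterable[VariantSite]) -> dict[str, str]:
    """Place an N at every site position; all other bases unchanged.

    Idempotent: masking an already-masked reference changes nothing.
    """
    out = {name: bytearray(seq, "ascii") for name, seq in reference.items()}
    for site in sites:
        if site.chrom not in out or not (0 <= site.pos < len(out[site.chrom])):
            raise ValueError(f"site {site.chrom}:{site.pos} outside reference bounds")
        out[site.chrom][site.pos] = ord("N")
    return {name: seq.decode("ascii") for name, seq in out.items()}


# ---------------------------------------------------------------------------
# Allelic counting


def count_alleles(
    alignments: Iterable[AlignmentRecord],
    sites: Sequence[VariantSite],
    sample_id: str,
    min_depth: int = 10,
    min_mapq: int = 10,
    min_base_quality: int = 2,
) -> list[AllelicCount]:
    """Quality-filtered ref/alt/other tallies per site for one sample.

    Reads must be primary and unique (multi-mappers skipped), exceed
    ``min_mapq``, and each counted base must exceed ``min_base_quality``;
    a read id is counted at most once per site.  Sites whose passing depth
    falls below ``min_depth`` yield no record.
    """
    by_pos: dict[tuple[str, int], VariantSite] = {(s.chrom, s.pos): s for s in sites}
    tallies: dict[tuple[str, int], list[int]] = defaultdict(lambda: [0, 0, 0])
    seen: dict[tuple[str, int], set[str]] = defaultdict(set)
    for read in alignments:
        if read.hit_count > 1 or read.mapq <= min_mapq:
            continue
        for rpos, base, bq in read.base_calls:
            key = (read.chrom, rpos)
            site = by_pos.get(key)
            if site is None or bq <= min_base_quality:
                continue
            if read.read_id in seen[key]:
                continue
            seen[key].add(read.read_id)
            if base == site.ref_allele:
                tallies[key][0] += 1
            elif base == site.alt_allele:
                tallies[key][1] += 1
            else:
                tallies[key][2] += 1
    out = []
    for site in sites:
        key = (site.chrom, site.pos)
        if key not in tallies:
            continue
        ref_n, alt_n, other_n = tallies[key]
        if ref_n + alt_n + other_n < min_depth:
            continue
        out.append(
            AllelicCount(
                sample_id=sample_id,
                site=site,
                ref_count=ref_n,
                alt_count=alt_n,
                other_count=other_n,
            )
        )
    return out


def count_alleles_pileup(
    sam_path,
    sites: Sequence[VariantSite],
    sample_id: str,
    min_depth: int = 10,
    min_mapq: int = 10,
    min_base_quality: int = 2,
) -> list[AllelicCount]:
    """Vectorised allelic counting for one sample via the pileup path.

    Equivalent to :func:`count_alleles` on primary unique single-end
    alignments with distinct read ids (it cannot deduplicate repeated read
    ids, so paired or duplicated inputs should use the record-based
    counter).
    """
    counts = pileup_base_counts([sam_path], min_base_quality, min_mapq=min_mapq)
    out = []
    for site in sites:
        arr = counts.get(site.chrom)
        if arr is None:
            continue
        if not 0 <= site.pos < arr.shape[1]:
            raise ValueError(f"site {site.chrom}:{site.pos} outside reference bounds")
        col = arr[:, site.pos]
        ref_n = int(col[_BASE_INDEX[site.ref_allele]])
        alt_n = int(col[_BASE_INDEX[site.alt_allele]])
        other_n = int(col.sum() - ref_n - alt_n)
        if ref_n + alt_n + other_n < min_depth:
            continue
        out.append(
            AllelicCount(
                sample_id=sample_id,
                site=site,
                ref_count=ref_n,
                alt_count=alt_n,
                other_count=other_n,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Multi-sample genotyping (EM over a shared per-animal error rate)


def genotype_animal(
    counts: Iterable[AllelicCount],
    animal_id: str,
    min_pooled_coverage: int = 5,
    call_threshold: float = 0.99,
    init_error: float = 0.01,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[list[GenotypeCall], float]:
    """Genotype one animal from its allelic counts pooled across tissues.

    Per read the model gives P(ref base) = 1 - eps under homRef, 1/2 under
    het and eps under homAlt, with a single error rate eps per animal
    shared across sites and estimated jointly by EM under a uniform
    genotype prior.  The call is the posterior argmax when it reaches
    ``call_threshold``; sites pooled below ``min_pooled_coverage`` are
    no-calls.  Returns the calls and the estimated eps.
    """
    pooled: dict[VariantSite, list[int]] = defaultdict(lambda: [0, 0])
    for c in counts:
        pooled[c.site][0] += c.ref_count
        pooled[c.site][1] += c.alt_count
    sites = sorted(pooled)
    r = np.array([pooled[s][0] for s in sites], dtype=float)
    a = np.array([pooled[s][1] for s in sites], dtype=float)

    eps = init_error
    post = np.full((len(sites), 3), 1.0 / 3.0)
    for _ in range(max_iter):
        log_l = np.column_stack(
            [
                r * math.log(1 - eps) + a * math.log(eps),  # homRef
                -(r + a) * math.log(2.0),  # het
                r * math.log(eps) + a * math.log(1 - eps),  # homAlt
            ]
        )
        log_l -= log_l.max(axis=1, keepdims=True)
        post = np.exp(log_l)
        post /= post.sum(axis=1, keepdims=True)
        num = np.sum(post[:, 0] * a + post[:, 2] * r)
        den = np.sum((post[:, 0] + post[:, 2]) * (r + a))
        # without hom-assigned reads the error rate is unidentifiable;
        # keep the current estimate rather than chasing numerical noise
        new_eps = num / den if den > 0.5 else eps
        new_eps = min(max(new_eps, 1e-6), 0.49)
        if abs(new_eps - eps) < tol:
            eps = new_eps
            break
        eps = new_eps

    calls = []
    labels = ("homRef", "het", "homAlt")
    for i, site in enumerate(sites):
        cov = int(r[i] + a[i])
        if cov < min_pooled_coverage:
            calls.append(GenotypeCall(animal_id, site, tuple(post[i]), "no_call", cov))
            continue
        best = int(np.argmax(post[i]))
        call = labels[best] if post[i, best] >= call_threshold else "no_call"
        calls.append(GenotypeCall(animal_id, site, tuple(post[i]), call, cov))
    return calls, eps


# ---------------------------------------------------------------------------
# Binomial imbalance testing and classification


def ase_test(
    count: AllelicCount,
    animal_id: str,
    tissue: str,
    min_reads: int = 10,
    null_ratio: float = 0.5,
) -> AseRecord | None:
    """Two-sided exact binomial test of allelic imbalance at a het site.

    Tests ref_count out of ref+alt against ``null_ratio`` using the
    minimum-likelihood tail definition (for a symmetric null this equals
    doubling the smaller tail).  Returns None below ``min_reads``
    informative reads.
    """
    n = count.ref_count + count.alt_count
    if n < min_reads:
        return None
    p = binomtest(count.ref_count, n, null_ratio, alternative="two-sided").pvalue
    return AseRecord(
        animal_id=animal_id,
        tissue=tissue,
        site=count.site,
        ref_count=count.ref_count,
        alt_count=count.alt_count,
        p_value=float(p),
    )


def correct_and_flag(
    records: Sequence[AseRecord], fdr_threshold: float = 0.05
) -> list[AseRecord]:
    """BH correction over one tissue's (animal, site) tests; flags fdr < 0.05."""
    if not records:
        return []
    q = bh_fdr(np.array([r.p_value for r in records]))
    for rec, qv in zip(records, q):
        rec.fdr = float(qv)
        rec.significant = bool(qv < fdr_threshold)
    return list(records)


def assign_genes(
    sites: Sequence[VariantSite], genes: Sequence[GeneModel], window: int = 5000
) -> dict[VariantSite, tuple[str, ...]]:
    """Map each site to all genes whose merged span +- window contains it.

    The window boundary is inclusive: a site exactly ``window`` bases from
    a gene span end is assigned.
    """
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)
    out: dict[VariantSite, tuple[str, ...]] = {}
    for site in sites:
        hits = []
        for g in by_chrom.get(site.chrom, []):
            start, end = g.span
            if start - window <= site.pos <= end - 1 + window:
                hits.append(g.gene_id)
        out[site] = tuple(sorted(hits))
    return out


@dataclass
class AseSummary:
    """Per-tissue and cross-tissue ASE tallies."""

    per_tissue: pd.DataFrame
    shared_ase_genes: set[str]
    tissue_specific_ase_genes: dict[str, set[str]]


def summarize_ase(
    records: Sequence[AseRecord],
    genotype_calls: Sequence[GenotypeCall],
    expressed_genes: Mapping[str, set[str]] | None = None,
) -> AseSummary:
    """Classify ASE results per tissue and across tissues.

    Per tissue: a site is an ASE SNP when significant for at least one het
    animal, a consistent ASE SNP when significant for every het animal
    tested at it; ASE genes collect sites through their gene assignment.
    Across tissues: shared ASE genes are ASE in every tissue where they
    were tested; a tissue-specific ASE gene is ASE in exactly one tissue,
    with no significant imbalance in any other tissue, while expressed
    there (``expressed_genes`` maps tissue -> expressed gene ids; when
    omitted the expression condition is dropped).
    """
    tissues = sorted({r.tissue for r in records})
    by_tissue: dict[str, list[AseRecord]] = defaultdict(list)
    for r in records:
        by_tissue[r.tissue].append(r)

    rows = []
    ase_genes_by_tissue: dict[str, set[str]] = {}
    tested_genes_by_tissue: dict[str, set[str]] = {}
    for tissue in tissues:
        recs = by_tissue[tissue]
        sites = {r.site for r in recs}
        sig_by_site: dict[VariantSite, list[bool]] = defaultdict(list)
        for r in recs:
            sig_by_site[r.site].append(r.significant)
        ase_snps = {s for s, flags in sig_by_site.items() if any(flags)}
        consistent = {s for s in ase_snps if all(sig_by_site[s])}
        site_genes = {r.site: r.gene_ids for r in recs}
        tested_genes = {g for s in sites for g in site_genes[s]}
        gene_sites: dict[str, set[VariantSite]] = defaultdict(set)
        for s in ase_snps:
            for g in site_genes[s]:
                gene_sites[g].add(s)
        ase_genes = set(gene_sites)
        multi = {g for g, ss in gene_sites.items() if len(ss) > 1}
        ase_genes_by_tissue[tissue] = ase_genes
        tested_genes_by_tissue[tissue] = tested_genes
        rows.append(
            {
                "tissue": tissue,
                "het_snps_tested": len(sites),
                "genes_tested": len(tested_genes),
                "ase_snps": len(ase_snps),
                "consistent_ase_snps": len(consistent),
                "ase_genes": len(ase_genes),
                "ase_genes_multi_snp": len(multi),
            }
        )

    all_ase = set().union(*ase_genes_by_tissue.values()) if ase_genes_by_tissue else set()
    shared = {
        g
        for g in all_ase
        if all(
            g in ase_genes_by_tissue[t]
            for t in tissues
            if g in tested_genes_by_tissue[t]
        )
    }
    specific: dict[str, set[str]] = {}
    for tissue in tissues:
        others = [t for t in tissues if t != tissue]
        sel = set()
        for g in ase_genes_by_tissue[tissue]:
            if any(g in ase_genes_by_tissue[t] for t in others):
                continue
            if expressed_genes is not None:
                if not any(g in expressed_genes.get(t, set()) for t in others):
                    continue
            sel.add(g)
        specific[tissue] = sel
    columns = [
        "tissue", "het_snps_tested", "genes_tested", "ase_snps",
        "consistent_ase_snps", "ase_genes", "ase_genes_multi_snp",
    ]
    return AseSummary(
        per_tissue=pd.DataFrame(rows, columns=columns),
        shared_ase_genes=shared,
        tissue_specific_ase_genes=specific,
    )


# ---------------------------------------------------------------------------
# Model / Results facade


class AseAnalysis:
    """Allele-specific expression analysis over per-sample allelic counts.

    Parameters
    ----------
    counts_by_sample : mapping of sample_id -> list of AllelicCount
    sample_meta : mapping of sample_id -> (animal_id, tissue)
    genes : gene models used to annotate sites (span +- window)
    expressed_genes : optional tissue -> expressed gene-id sets, used for
        the tissue-specific ASE classification
    """

    def __init__(
        self,
        counts_by_sample: Mapping[str, Sequence[AllelicCount]],
        sample_meta: Mapping[str, tuple[str, str]],
        genes: Sequence[GeneModel] = (),
        expressed_genes: Mapping[str, set[str]] | None = None,
        min_pooled_coverage: int = 5,
        call_threshold: float = 0.99,
        min_test_reads: int = 10,
        fdr_threshold: float = 0.05,
        gene_window: int = 5000,
        null_ratio: float = 0.5,
    ):
        self.counts_by_sample = counts_by_sample
        self.sample_meta = dict(sample_meta)
        self.genes = list(genes)
        self.expressed_genes = expressed_genes
        self.min_pooled_coverage = min_pooled_coverage
        self.call_threshold = call_threshold
        self.min_test_reads = min_test_reads
        self.fdr_threshold = fdr_threshold
        self.gene_window = gene_window
        self.null_ratio = null_ratio

    def fit(self) -> "AseResults":
        """Genotype animals, test het sites per tissue, correct, classify."""
        by_animal: dict[str, list[AllelicCount]] = defaultdict(list)
        for sample_id, counts in self.counts_by_sample.items():
            animal, _ = self.sample_meta[sample_id]
            by_animal[animal].extend(counts)
        genotypes: dict[str, dict[VariantSite, GenotypeCall]] = {}
        error_rates: dict[str, float] = {}
        for animal in sorted(by_animal):
            calls, eps = genotype_animal(
                by_animal[animal],
                animal,
                min_pooled_coverage=self.min_pooled_coverage,
                call_threshold=self.call_threshold,
            )
            genotypes[animal] = {c.site: c for c in calls}
            error_rates[animal] = eps

        all_sites = sorted({c.site for counts in self.counts_by_sample.values() for c in counts})
        gene_map = assign_genes(all_sites, self.genes, window=self.gene_window)

        by_tissue: dict[str, list[AseRecord]] = defaultdict(list)
        for sample_id, counts in self.counts_by_sample.items():
            animal, tissue = self.sample_meta[sample_id]
            for c in counts:
                call = genotypes[animal].get(c.site)
                if call is None or call.call != "het":
                    continue
                rec = ase_test(
                    c, animal, tissue, min_reads=self.min_test_reads, null_ratio=self.null_ratio
                )
                if rec is None:
                    continue
                rec.gene_ids = gene_map.get(c.site, ())
                by_tissue[tissue].append(rec)
        records: list[AseRecord] = []
        for tissue in sorted(by_tissue):
            records.extend(correct_and_flag(by_tissue[tissue], self.fdr_threshold))
        flat_calls = [c for calls in genotypes.values() for c in calls.values()]
        summary = summarize_ase(records, flat_calls, self.expressed_genes)
        return AseResults(self, records, genotypes, error_rates, summary)


@dataclass
class AseResults:
    """Fitted ASE results: records, genotype calls, and the summary tables."""

    model: AseAnalysis
    records: list[AseRecord]
    genotypes: dict[str, dict[VariantSite, GenotypeCall]]
    error_rates: dict[str, float]
    ase_summary: AseSummary = field(repr=False)

    def records_frame(self) -> pd.DataFrame:
        rows = [
            {
                "animal": r.animal_id,
                "tissue": r.tissue,
                "chrom": r.site.chrom,
                "pos": r.site.pos,
                "ref": r.site.ref_allele,
                "alt": r.site.alt_allele,
                "ref_count": r.ref_count,
                "alt_count": r.alt_count,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "significant": r.significant,
                "genes": ",".join(r.gene_ids),
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "animal", "tissue", "chrom", "pos", "ref", "alt",
                "ref_count", "alt_count", "p_value", "fdr", "significant", "genes",
            ],
        )

    def het_site_count(self, animal_id: str) -> int:
        return sum(1 for c in self.genotypes[animal_id].values() if c.call == "het")

    def summary(self) -> str:
        eps = ", ".join(f"{a}={e:.4g}" for a, e in sorted(self.error_rates.items()))
        lines = [
            "Allele-specific expression (binomial imbalance tests at het sites)",
            f"  animals genotyped: {len(self.genotypes)} (error rates: {eps})",
            f"  tests: {len(self.records)}; "
            f"significant: {sum(r.significant for r in self.records)} "
            f"(FDR < {self.model.fdr_threshold})",
            "",
            self.ase_summary.per_tissue.to_string(index=False),
        ]
        return "\n".join(lines)
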