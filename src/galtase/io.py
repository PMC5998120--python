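"""Readers and writers for the formats the pipeline touches.

All internal coordinates are 0-based half-open; conversions to and from the
1-based closed conventions of GFF3, SAM and VCF happen only here, at the
format boundary.
"""

from __future__ import annotations

import bisect
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam

_STRANDS = ("+", "-")


class FormatError(ValueError):
    """A malformed record in one of the supported text formats."""


@dataclass(frozen=True)
class GeneModel:
    """A stranded, exon-structured gene used for sense/antisense assignment.

    Exons are stored 0-based half-open, sorted, and merged so that they are
    pairwise disjoint.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"gene {self.gene_id}: empty exon ({start},{end})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"gene {self.gene_id}: exons overlap after merge")

    @property
    def span(self) -> tuple[int, int]:
        """Merged genomic span (first exon start, last exon end)."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class AlignmentRecord:
    """One primary alignment, reduced to what counting and ASE need.

    ``blocks`` are the aligned reference intervals (0-based half-open,
    sorted, disjoint); ``base_calls`` carries (ref_pos, base, base_quality)
    for read positions overlapping the variant sites the caller asked for.
    """

    read_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    align_strand: str
    mapq: int
    hit_count: int
    base_calls: tuple[tuple[int, str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.hit_count < 1:
            raise ValueError("hit_count must be >= 1")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    animal_id: str
    tissue: str


@dataclass(frozen=True, order=True)
class VariantSite:
    """A biallelic single-base substitution site (0-based position)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("only single-base alleles are supported")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Merge possibly-overlapping half-open intervals into disjoint ones."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


# ---------------------------------------------------------------------------
# GFF3


def _gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gene_models(stream) -> list[GeneModel]:
    """Parse gene models from a GFF3 stream (path or file object).

    Features of type ``gene`` define gene id/strand/location; ``exon``
    features attach to their gene via the ``Parent`` (or ``gene_id``)
    attribute.  GFF3 1-based closed coordinates become 0-based half-open;
    exons are merged per gene.  A gene without exon children contributes its
    own span as a single exon.
    """
    close = False
    if isinstance(stream, (str, os.PathLike)):
        stream = open(stream)
        close = True
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"GFF3 line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"GFF3 line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise FormatError(f"GFF3 line {lineno}: bad interval {start}..{end}")
            attrs = _gff3_attributes(attr_s)
            interval = (start - 1, end)  # to 0-based half-open
            if ftype == "gene":
                gene_id = attrs.get("ID") or attrs.get("gene_id")
                if not gene_id:
                    raise FormatError(f"GFF3 line {lineno}: gene without ID/gene_id")
                genes[gene_id] = {"chrom": chrom, "strand": strand, "span": interval}
            elif ftype == "exon":
                parent = attrs.get("Parent") or attrs.get("gene_id")
                if not parent:
                    raise FormatError(f"GFF3 line {lineno}: exon without Parent/gene_id")
                exons.setdefault(parent, []).append(interval)
    finally:
        if close:
            stream.close()
    orphans = set(exons) - set(genes)
    if orphans:
        raise FormatError(f"exons reference unknown gene(s): {sorted(orphans)}")
    models = []
    for gene_id, info in genes.items():
        parts = exons.get(gene_id) or [info["span"]]
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=info["chrom"],
                strand=info["strand"],
                exons=merge_intervals(parts),
            )
        )
    return models


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene + exon features, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\tgaltase\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tgaltase\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# SAM


def read_alignments(
    sam_path,
    site_positions: dict[str, Sequence[int]] | None = None,
) -> Iterator[AlignmentRecord]:
    """Iterate primary alignments of a SAM file as AlignmentRecords.

    Secondary (0x100) and supplementary (0x800) records and unmapped reads
    are skipped; multi-mapping is carried on the record via the NH tag
    (``hit_count``) and judged downstream.  When ``site_positions`` maps
    chromosomes to sorted 0-based positions, each record carries the base
    and base quality it aligns over those positions.
    """
    with pysam.AlignmentFile(os.fspath(sam_path), "r", check_sq=True) as fh:
        if not fh.header.get("SQ"):
            raise FormatError(f"{sam_path}: SAM header lacks @SQ lines")
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            try:
                blocks = tuple(aln.get_blocks())
            except (ValueError, SystemError) as exc:
                raise FormatError(f"unparsable CIGAR for read {aln.query_name}") from exc
            if not blocks:
                raise FormatError(f"unparsable CIGAR for read {aln.query_name}")
            chrom = aln.reference_name
            base_calls: tuple[tuple[int, str, int], ...] = ()
            if site_positions is not None:
                positions = site_positions.get(chrom)
                if positions is not None and len(positions) > 0:
                    wanted = []
                    for bs, be in blocks:
                        lo = bisect.bisect_left(positions, bs)
                        hi = bisect.bisect_left(positions, be)
                        wanted.extend(positions[lo:hi])
                    if wanted:
                        base_calls = _extract_base_calls(aln, set(wanted))
            yield AlignmentRecord(
                read_id=aln.query_name,
                chrom=chrom,
                blocks=tuple(merge_intervals(blocks)),
                align_strand="-" if aln.is_reverse else "+",
                mapq=aln.mapping_quality,
                hit_count=aln.get_tag("NH") if aln.has_tag("NH") else 1,
                base_calls=base_calls,
            )


def _extract_base_calls(aln, wanted: Iterable[int]) -> tuple[tuple[int, str, int], ...]:
    seq = aln.query_sequence
    quals = aln.query_qualities
    cig = aln.cigartuples
    calls = []
    if cig is not None and len(cig) == 1 and cig[0][0] == 0:
        # ungapped read: query offset is position minus reference start
        start = aln.reference_start
        for rpos in wanted:
            qpos = rpos - start
            q = quals[qpos] if quals is not None else 0
            calls.append((rpos, seq[qpos].upper(), q))
        return tuple(calls)
    wanted_set = set(wanted)
    for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
        if rpos in wanted_set:
            q = quals[qpos] if quals is not None else 0
            calls.append((rpos, seq[qpos].upper(), q))
    return tuple(calls)


# ---------------------------------------------------------------------------
# Sample sheet


def read_sample_sheet(stream) -> list[SampleMeta]:
    """Read a TSV with header ``sample\tanimal\ttissue``.

    Raises on duplicate (animal, tissue) pairs or duplicate sample ids.
    """
    close = False
    if isinstance(stream, (str, os.PathLike)):
        stream = open(stream)
        close = True
    try:
        header = next(stream, None)
        if header is None:
            return []
        cols = header.rstrip("\n").split("\t")
        required = {"sample", "animal", "tissue"}
        if not required.issubset(cols):
            raise FormatError(f"sample sheet must have columns {sorted(required)}")
        idx = {c: cols.index(c) for c in required}
        out = []
        seen_pairs: set[tuple[str, str]] = set()
        seen_samples: set[str] = set()
        for lineno, line in enumerate(stream, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            meta = SampleMeta(
                sample_id=fields[idx["sample"]],
                animal_id=fields[idx["animal"]],
                tissue=fields[idx["tissue"]],
            )
            pair = (meta.animal_id, meta.tissue)
            if pair in seen_pairs:
                raise FormatError(f"sample sheet line {lineno}: duplicate (animal, tissue) {pair}")
            if meta.sample_id in seen_samples:
                raise FormatError(f"sample sheet line {lineno}: duplicate sample {meta.sample_id}")
            seen_pairs.add(pair)
            seen_samples.add(meta.sample_id)
            out.append(meta)
        return out
    finally:
        if close:
            stream.close()


def write_sample_sheet(samples: Sequence[SampleMeta], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tanimal\ttissue\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.animal_id}\t{s.tissue}\n")


# ---------------------------------------------------------------------------
# VCF (minimal: biallelic SNV sites, optional per-sample GT and posteriors)


def read_vcf(stream) -> tuple[list[VariantSite], list[str], dict[str, list[str]]]:
    """Read a VCF into (sites, sample names, genotypes per sample).

    Genotypes are the raw GT strings (``0/0``, ``0/1``, ``1/1``, ``./.``);
    positions are converted to 0-based.  Only single-base biallelic
    substitutions are accepted.
    """
    close = False
    if isinstance(stream, (str, os.PathLike)):
        stream = open(stream)
        close = True
    sites: list[VariantSite] = []
    samples: list[str] = []
    genotypes: dict[str, list[str]] = {}
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                samples = cols[9:]
                genotypes = {s: [] for s in samples}
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"VCF line {lineno}: expected >=8 fields")
            chrom, pos_s, _, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if len(ref) != 1 or len(alt) != 1 or "," in alt:
                raise FormatError(f"VCF line {lineno}: only biallelic SNVs supported")
            sites.append(VariantSite(chrom=chrom, pos=int(pos_s) - 1, ref_allele=ref, alt_allele=alt))
            if samples:
                if len(fields) < 9 + len(samples):
                    raise FormatError(f"VCF line {lineno}: missing sample columns")
                fmt = fields[8].split(":")
                try:
                    gt_i = fmt.index("GT")
                except ValueError as exc:
                    raise FormatError(f"VCF line {lineno}: FORMAT lacks GT") from exc
                for s, cell in zip(samples, fields[9:]):
                    genotypes[s].append(cell.split(":")[gt_i])
    finally:
        if close:
            stream.close()
    return sites, samples, genotypes


def write_vcf(
    sites: Sequence[VariantSite],
    path,
    samples: Sequence[str] = (),
    genotypes: dict[str, Sequence[str]] | None = None,
    posteriors: dict[str, Sequence[tuple[float, float, float]]] | None = None,
    contigs: Sequence[tuple[str, int]] = (),
) -> None:
    """Write biallelic SNV sites (and optional GT / genotype posterior GP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=galtase\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if posteriors is not None:
            fh.write(
                '##FORMAT=<ID=GP,Number=3,Type=Float,Description='
                '"Posterior over homRef,het,homAlt">\n'
            )
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            header.append("FORMAT")
            header.extend(samples)
        fh.write("\t".join(header) + "\n")
        fmt = "GT:GP" if posteriors is not None else "GT"
        for i, site in enumerate(sites):
            row = [site.chrom, str(site.pos + 1), ".", site.ref_allele, site.alt_allele, ".", "PASS", "."]
            if samples:
                row.append(fmt)
                for s in samples:
                    gt = genotypes[s][i] if genotypes else "./."
                    if posteriors is not None:
                        gp = posteriors[s][i]
                        row.append(f"{gt}:{gp[0]:.4g},{gp[1]:.4g},{gp[2]:.4g}")
                    else:
                        row.append(gt)
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Tables and tracks


def write_table(rows: Sequence[dict], path, columns: Sequence[str] | None = None) -> None:
    """Write a list of dict rows as a TSV with a stable header."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def write_bedgraph(track: Sequence[tuple[str, int, int, float]], path, name: str = "track") -> None:
    """Write (chrom, start, end, value) intervals as bedGraph (0-based half-open)."""
    rows = sorted(track)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: sequence} (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
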