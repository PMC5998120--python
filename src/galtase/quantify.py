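"""Strand-aware gene-level quantification.

Reads are assigned to genes by exon overlap with a strand-aware rule: the
read orientation (alignment strand, flipped under a reverse-stranded
protocol) is compared with the gene strand, yielding a sense or an
antisense assignment.  Sense assignment has priority — a read overlapping
a same-strand gene is never counted antisense to another gene — and reads
reported at multiple genomic locations are discarded outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from galtase.io import AlignmentRecord, GeneModel

SENSE = "sense"
ANTISENSE = "antisense"
AMBIGUOUS = "ambiguous"
NO_FEATURE = "no_feature"
MULTIMAPPER = "discarded_multimapper"


@dataclass
class CountMatrix:
    """Genes x samples integer counts in two strand layers.

    ``library_sizes`` are the sense-layer column sums and serve as the CPM
    denominator for both layers; ``norm_factors`` default to 1 until TMM
    normalisation fills them in.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    sense: np.ndarray
    antisense: np.ndarray
    library_sizes: np.ndarray
    norm_factors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sense = np.asarray(self.sense)
        self.antisense = np.asarray(self.antisense)
        shape = (len(self.gene_ids), len(self.sample_ids))
        if self.sense.shape != shape or self.antisense.shape != shape:
            raise ValueError("count layer shapes do not match gene/sample ids")
        if np.any(self.sense < 0) or np.any(self.antisense < 0):
            raise ValueError("counts must be non-negative")
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.norm_factors is None:
            self.norm_factors = np.ones(len(self.sample_ids))
        self.norm_factors = np.asarray(self.norm_factors, dtype=float)

    def layer(self, name: str) -> np.ndarray:
        if name == SENSE:
            return self.sense
        if name == ANTISENSE:
            return self.antisense
        raise KeyError(f"unknown layer {name!r}")

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


class GeneIndex:
    """Interval index over the merged exons of a set of gene models."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for i, gene in enumerate(self.genes):
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            for start, end in gene.exons:
                tree.addi(start, end, i)

    def overlapping(self, chrom: str, blocks: Iterable[tuple[int, int]]) -> set[int]:
        """Indices of genes whose exons intersect any block."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        hits: set[int] = set()
        for start, end in blocks:
            for iv in tree.overlap(start, end):
                hits.add(iv.data)
        return hits


def assign_read(
    read: AlignmentRecord, index: GeneIndex, protocol: str = "reverse"
) -> tuple[str, str | None]:
    """Assign one primary alignment to a (category, gene_id) pair.

    Category is one of sense/antisense/ambiguous/no_feature/
    discarded_multimapper; gene_id is set only for sense and antisense.
    Under ``protocol="reverse"`` (dUTP-style stranded libraries) the read
    orientation is the opposite of its alignment strand.
    """
    if protocol not in ("forward", "reverse"):
        raise ValueError("protocol must be 'forward' or 'reverse'")
    if read.hit_count > 1:
        return MULTIMAPPER, None
    orientation = read.align_strand
    if protocol == "reverse":
        orientation = "-" if orientation == "+" else "+"
    hits = index.overlapping(read.chrom, read.blocks)
    if not hits:
        return NO_FEATURE, None
    sense_hits = [i for i in hits if index.genes[i].strand == orientation]
    if sense_hits:
        if len(sense_hits) > 1:
            return AMBIGUOUS, None
        return SENSE, index.genes[sense_hits[0]].gene_id
    anti_hits = sorted(hits)
    if len(anti_hits) > 1:
        return AMBIGUOUS, None
    return ANTISENSE, index.genes[anti_hits[0]].gene_id


def count_samples(
    alignments_by_sample: Mapping[str, Iterable[AlignmentRecord]],
    genes: Sequence[GeneModel],
    protocol: str = "reverse",
    on_read=None,
) -> tuple[CountMatrix, dict[str, dict[str, int]]]:
    """Tally sense/antisense counts per gene for each sample.

    Returns the CountMatrix and a per-sample assignment log with the
    sense/antisense/ambiguous/no_feature/multimapper tallies; their sum
    equals the number of primary records seen (conservation is asserted).
    ``on_read(sample_id, read)``, when given, is invoked once per record
    (used to build genome tracks in the same pass).
    """
    index = GeneIndex(genes)
    gene_ids = [g.gene_id for g in genes]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    sample_ids = list(alignments_by_sample)
    sense = np.zeros((len(gene_ids), len(sample_ids)), dtype=np.int64)
    anti = np.zeros_like(sense)
    stats: dict[str, dict[str, int]] = {}
    for s_idx, sample in enumerate(sample_ids):
        log = {SENSE: 0, ANTISENSE: 0, AMBIGUOUS: 0, NO_FEATURE: 0, MULTIMAPPER: 0, "total": 0}
        for read in alignments_by_sample[sample]:
            log["total"] += 1
            if on_read is not None:
                on_read(sample, read)
            category, gene_id = assign_read(read, index, protocol)
            log[category] += 1
            if category == SENSE:
                sense[gene_pos[gene_id], s_idx] += 1
            elif category == ANTISENSE:
                anti[gene_pos[gene_id], s_idx] += 1
        assert (
            log[SENSE] + log[ANTISENSE] + log[AMBIGUOUS] + log[NO_FEATURE] + log[MULTIMAPPER]
            == log["total"]
        )
        stats[sample] = log
    matrix = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        sense=sense,
        antisense=anti,
        library_sizes=sense.sum(axis=0).astype(float),
    )
    return matrix, stats


def cpm(
    matrix: CountMatrix,
    layer: str = SENSE,
    use_norm_factors: bool = False,
    prior_count: float = 0.0,
) -> np.ndarray:
    """Counts per million over the sense-library denominator.

    With ``use_norm_factors`` the effective library is library x TMM
    factor.  ``prior_count`` adds a pseudo-count before scaling (used for
    log-CPM).  Samples with zero library size raise.
    """
    counts = matrix.layer(layer).astype(float)
    denom = matrix.library_sizes.copy()
    if use_norm_factors:
        denom = denom * matrix.norm_factors
    if np.any(denom <= 0):
        bad = [matrix.sample_ids[i] for i in np.where(denom <= 0)[0]]
        raise ValueError(f"CPM undefined for zero-library sample(s): {bad}")
    return (counts + prior_count) / denom[None, :] * 1e6


def log2_cpm(matrix: CountMatrix, layer: str = SENSE, use_norm_factors: bool = True) -> np.ndarray:
    """log2 CPM with the standard 0.25-per-library pseudo-count."""
    return np.log2(cpm(matrix, layer, use_norm_factors, prior_count=0.25))


def filter_expressed(
    matrix: CountMatrix,
    layer: str,
    samples_of_tissue: Mapping[str, Sequence[str]],
    min_cpm: float = 1.0,
    min_animals: int = 2,
    min_reads: int = 0,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-tissue expressed flags: CPM > min_cpm in >= min_animals samples.

    With ``min_reads > 0`` the qualifying samples must also have at least
    that many raw reads.  Returns per-tissue boolean vectors over genes and
    their union across tissues.
    """
    values = cpm(matrix, layer)
    raw = matrix.layer(layer)
    flags: dict[str, np.ndarray] = {}
    union = np.zeros(len(matrix.gene_ids), dtype=bool)
    for tissue, samples in samples_of_tissue.items():
        if len(samples) < min_animals:
            raise ValueError(f"tissue {tissue}: fewer than {min_animals} samples")
        cols = [matrix.sample_index(s) for s in samples]
        ok = values[:, cols] > min_cpm
        if min_reads > 0:
            ok &= raw[:, cols] >= min_reads
        flag = ok.sum(axis=1) >= min_animals
        flags[tissue] = flag
        union |= flag
    return flags, union


def top_mass_genes(matrix: CountMatrix, layer: str, sample_cols: Sequence[int]) -> int:
    """Smallest k such that the k highest-count genes carry >= 50% of reads.

    ``sample_cols`` selects the columns pooled before ranking (one sample,
    or a tissue's samples).  Ties break by gene order.
    """
    totals = matrix.layer(layer)[:, list(sample_cols)].sum(axis=1).astype(float)
    grand = totals.sum()
    if grand == 0:
        return 0
    order = np.argsort(-totals, kind="stable")
    cum = np.cumsum(totals[order])
    return int(np.searchsorted(cum, grand / 2.0) + 1)


def genome_track(
    alignments: Iterable[AlignmentRecord], window_size: int = 10_000
) -> dict[str, list[tuple[str, int, int, int]]]:
    """Strand-resolved read density along the genome.

    Each primary unique read is attributed to the window containing its
    leftmost aligned base.  Returns {"+": intervals, "-": intervals} with
    (chrom, start, end, count) rows; windows with zero reads are omitted.
    """
    counts: dict[tuple[str, str, int], int] = {}
    for read in alignments:
        if read.hit_count > 1:
            continue
        w = read.blocks[0][0] // window_size
        key = (read.align_strand, read.chrom, w)
        counts[key] = counts.get(key, 0) + 1
    tracks: dict[str, list[tuple[str, int, int, int]]] = {"+": [], "-": []}
    for (strand, chrom, w), n in sorted(counts.items()):
        tracks[strand].append((chrom, w * window_size, (w + 1) * window_size, n))
    return tracks
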