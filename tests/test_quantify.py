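"""Strand-aware counting, CPM, expression filters, mass ranking, tracks."""

import numpy as np
import pytest

from galtase.io import AlignmentRecord, GeneModel
from galtase.quantify import (
    AMBIGUOUS,
    ANTISENSE,
    MULTIMAPPER,
    NO_FEATURE,
    SENSE,
    CountMatrix,
    GeneIndex,
    assign_read,
    count_samples,
    cpm,
    filter_expressed,
    genome_track,
    top_mass_genes,
)


def read(chrom="chr1", blocks=((100, 200),), strand="+", mapq=60, nh=1, rid="r"):
    return AlignmentRecord(
        read_id=rid, chrom=chrom, blocks=tuple(blocks), align_strand=strand,
        mapq=mapq, hit_count=nh,
    )


class TestAssignRead:
    @pytest.fixture
    def index(self, two_gene_models):
        return GeneIndex(two_gene_models)

    def test_forward_protocol_matching_strand_is_sense(self, index):
        assert assign_read(read(strand="+"), index, "forward") == (SENSE, "gplus")

    def test_forward_protocol_opposite_strand_is_antisense(self, index):
        assert assign_read(read(strand="-"), index, "forward") == (ANTISENSE, "gplus")

    def test_reverse_protocol_flips_orientation(self, index):
        assert assign_read(read(strand="-"), index, "reverse") == (SENSE, "gplus")
        assert assign_read(read(strand="+"), index, "reverse") == (ANTISENSE, "gplus")

    def test_multimapper_discarded_regardless_of_overlap(self, index):
        assert assign_read(read(nh=2), index, "forward") == (MULTIMAPPER, None)

    def test_no_overlap_is_no_feature(self, index):
        assert assign_read(read(blocks=((900, 950),)), index, "forward") == (NO_FEATURE, None)

    def test_sense_priority_over_antisense(self):
        # overlapping genes on both strands: the same-orientation gene wins
        genes = [
            GeneModel("fwd", "chr1", "+", ((100, 300),)),
            GeneModel("rev", "chr1", "-", ((150, 400),)),
        ]
        idx = GeneIndex(genes)
        assert assign_read(read(blocks=((160, 260),), strand="+"), idx, "forward") == (SENSE, "fwd")

    def test_two_sense_candidates_ambiguous(self):
        genes = [
            GeneModel("a", "chr1", "+", ((100, 300),)),
            GeneModel("b", "chr1", "+", ((250, 500),)),
        ]
        idx = GeneIndex(genes)
        assert assign_read(read(blocks=((260, 290),), strand="+"), idx, "forward") == (AMBIGUOUS, None)


def brute_force_counts(reads, genes, protocol):
    """Independent nested-loop oracle for sense/antisense counting."""
    sense = {g.gene_id: 0 for g in genes}
    anti = {g.gene_id: 0 for g in genes}
    for r in reads:
        if r.hit_count > 1:
            continue
        o = r.align_strand
        if protocol == "reverse":
            o = "-" if o == "+" else "+"
        hits = []
        for g in genes:
            if g.chrom != r.chrom:
                continue
            if any(
                bs < ee and es < be
                for bs, be in r.blocks
                for es, ee in g.exons
            ):
                hits.append(g)
        same = [g for g in hits if g.strand == o]
        if len(same) == 1:
            sense[same[0].gene_id] += 1
        elif not same and len(hits) == 1:
            anti[hits[0].gene_id] += 1
    return sense, anti


class TestCountSamples:
    @pytest.fixture
    def random_reads(self, two_gene_models):
        rng = np.random.default_rng(12)
        reads = []
        for i in range(90):
            start = int(rng.integers(0, 900))
            reads.append(
                read(
                    blocks=((start, start + 80),),
                    strand="+" if rng.random() < 0.5 else "-",
                    nh=2 if rng.random() < 0.1 else 1,
                    rid=f"r{i}",
                )
            )
        return reads

    @pytest.mark.parametrize("protocol", ["forward", "reverse"])
    def test_matches_brute_force_oracle(self, two_gene_models, random_reads, protocol):
        matrix, stats = count_samples({"s": random_reads}, two_gene_models, protocol)
        sense_o, anti_o = brute_force_counts(random_reads, two_gene_models, protocol)
        for i, g in enumerate(matrix.gene_ids):
            assert matrix.sense[i, 0] == sense_o[g]
            assert matrix.antisense[i, 0] == anti_o[g]

    def test_strand_flip_swaps_layers_exactly(self, two_gene_models, random_reads):
        flipped = [
            AlignmentRecord(
                r.read_id, r.chrom, r.blocks,
                "-" if r.align_strand == "+" else "+", r.mapq, r.hit_count,
            )
            for r in random_reads
        ]
        m1, _ = count_samples({"s": random_reads}, two_gene_models, "forward")
        m2, _ = count_samples({"s": flipped}, two_gene_models, "forward")
        assert np.array_equal(m1.sense, m2.antisense)
        assert np.array_equal(m1.antisense, m2.sense)

    def test_conservation_of_assignments(self, two_gene_models, random_reads):
        matrix, stats = count_samples({"s": random_reads}, two_gene_models, "forward")
        log = stats["s"]
        assert (
            log[SENSE] + log[ANTISENSE] + log[AMBIGUOUS] + log[NO_FEATURE] + log[MULTIMAPPER]
            == log["total"]
            == len(random_reads)
        )
        assert matrix.sense[:, 0].sum() == log[SENSE]

    def test_empty_sample_gives_zero_column(self, two_gene_models):
        matrix, stats = count_samples({"s": []}, two_gene_models)
        assert matrix.sense.sum() == 0
        assert matrix.library_sizes[0] == 0
        assert stats["s"]["total"] == 0


def make_matrix(sense, lib=None, factors=None):
    sense = np.asarray(sense)
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(sense.shape[0])],
        sample_ids=[f"s{j}" for j in range(sense.shape[1])],
        sense=sense,
        antisense=np.zeros_like(sense),
        library_sizes=lib if lib is not None else sense.sum(axis=0).astype(float),
        norm_factors=factors,
    )


class TestCpm:
    def test_basic_value(self):
        m = make_matrix([[100]], lib=np.array([1e6]))
        assert cpm(m)[0, 0] == pytest.approx(100.0)

    def test_scale_invariance(self):
        m1 = make_matrix([[10], [30]])
        m2 = make_matrix([[20], [60]])
        assert np.allclose(cpm(m1), cpm(m2))

    def test_norm_factor_halves(self):
        m = make_matrix([[100]], lib=np.array([1e6]), factors=np.array([2.0]))
        assert cpm(m, use_norm_factors=True)[0, 0] == pytest.approx(50.0)

    def test_zero_library_raises(self):
        m = make_matrix([[0]], lib=np.array([0.0]))
        with pytest.raises(ValueError, match="zero-library"):
            cpm(m)


class TestFilterExpressed:
    def samples(self):
        return {"T": ["s0", "s1", "s2", "s3"]}

    def _matrix_with_cpm(self, cpms):
        # library 1e6 makes counts equal CPM
        return make_matrix(np.array([cpms]) , lib=np.full(4, 1e6))

    def test_expressed_when_two_animals_pass(self):
        m = self._matrix_with_cpm([1.2e0, 1.1, 0.5, 0.0])
        flags, union = filter_expressed(m, SENSE, self.samples())
        assert flags["T"][0] and union[0]

    def test_not_expressed_with_single_passing_animal(self):
        m = self._matrix_with_cpm([1.2, 0.9, 0.9, 0.9])
        flags, _ = filter_expressed(m, SENSE, self.samples())
        assert not flags["T"][0]

    def test_min_reads_excludes_low_count_genes(self):
        m = make_matrix(np.array([[9, 9, 9, 9]]), lib=np.full(4, 1e6))
        flags_loose, _ = filter_expressed(m, SENSE, self.samples(), min_cpm=1e-9)
        flags_strict, _ = filter_expressed(m, SENSE, self.samples(), min_cpm=1e-9, min_reads=10)
        assert flags_loose["T"][0] and not flags_strict["T"][0]

    def test_too_few_samples_raises(self):
        m = self._matrix_with_cpm([1, 1, 1, 1])
        with pytest.raises(ValueError, match="fewer"):
            filter_expressed(m, SENSE, {"T": ["s0"]})


class TestTopMassGenes:
    @pytest.mark.parametrize(
        "counts,expected",
        [([60, 30, 10], 1), ([10] * 10, 5), ([50, 50], 1), ([0, 0], 0)],
    )
    def test_examples(self, counts, expected):
        m = make_matrix(np.array(counts)[:, None])
        assert top_mass_genes(m, SENSE, [0]) == expected


class TestGenomeTrack:
    def test_window_attribution_and_conservation(self):
        reads = [
            read(blocks=((5, 85),), strand="+", rid="a"),
            read(blocks=((150, 230),), strand="+", rid="b"),
            read(blocks=((7, 87),), strand="-", rid="c"),
            read(blocks=((7, 87),), strand="-", rid="d", nh=2),  # multimapper skipped
        ]
        tracks = genome_track(reads, window_size=100)
        assert tracks["+"] == [("chr1", 0, 100, 1), ("chr1", 100, 200, 1)]
        assert tracks["-"] == [("chr1", 0, 100, 1)]
        total = sum(n for t in tracks.values() for *_, n in t)
        assert total == 3

    def test_empty_input(self):
        assert genome_track([]) == {"+": [], "-": []}
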