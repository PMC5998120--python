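"""Site discovery, masking, allelic counting, genotyping, imbalance tests."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from galtase.ase import (
    AllelicCount,
    AseAnalysis,
    ase_test,
    assign_genes,
    correct_and_flag,
    count_alleles,
    count_alleles_pileup,
    discover_sites,
    genotype_animal,
    mask_reference,
    summarize_ase,
)
from galtase.io import AlignmentRecord, GeneModel, VariantSite, read_alignments


def make_read(rid, pos, base, bq=40, mapq=60, nh=1, chrom="chr1"):
    return AlignmentRecord(
        read_id=rid, chrom=chrom, blocks=((pos, pos + 1),), align_strand="+",
        mapq=mapq, hit_count=nh, base_calls=((pos, base, bq),),
    )


SITE = VariantSite("chr1", 100, "A", "G")


class TestDiscoverSites:
    def _write_sam(self, tmp_path, bases_quals, pos0=50):
        # one read per base call, 1bp reads at 0-based pos0
        lines = ["@HD\tVN:1.6", "@SQ\tSN:chr1\tLN:1000"]
        for i, (b, q) in enumerate(bases_quals):
            lines.append(
                f"r{i}\t0\tchr1\t{pos0 + 1}\t60\t1M\t*\t0\t0\t{b}\t{chr(q + 33)}"
            )
        path = tmp_path / "d.sam"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_monoallelic_position_not_a_site(self, tmp_path):
        sam = self._write_sam(tmp_path, [("A", 40)] * 20)
        ref = {"chr1": "A" * 1000}
        assert discover_sites([sam], ref) == []

    def test_three_alt_reads_emit_site(self, tmp_path):
        sam = self._write_sam(tmp_path, [("A", 40)] * 15 + [("G", 40)] * 3)
        ref = {"chr1": "A" * 1000}
        (site,) = discover_sites([sam], ref)
        assert (site.pos, site.ref_allele, site.alt_allele) == (50, "A", "G")

    def test_low_quality_alt_bases_ignored(self, tmp_path):
        sam = self._write_sam(tmp_path, [("A", 40)] * 15 + [("G", 5)] * 3)
        ref = {"chr1": "A" * 1000}
        assert discover_sites([sam], ref) == []

    def test_coverage_threshold_is_strict(self, tmp_path):
        # coverage exactly 10 (> filter requires 11+)
        sam = self._write_sam(tmp_path, [("A", 40)] * 7 + [("G", 40)] * 3)
        ref = {"chr1": "A" * 1000}
        assert discover_sites([sam], ref) == []


class TestMaskReference:
    def test_no_sites_identity(self):
        ref = {"chr1": "ACGTACGT"}
        assert mask_reference(ref, []) == ref

    def test_sites_become_n(self):
        ref = {"chr1": "ACGTACGT"}
        out = mask_reference(ref, [VariantSite("chr1", 1, "C", "T"), VariantSite("chr1", 5, "C", "A")])
        assert out["chr1"] == "ANGTANGT"

    def test_idempotent(self):
        ref = {"chr1": "ACGTACGT"}
        sites = [VariantSite("chr1", 2, "G", "A")]
        once = mask_reference(ref, sites)
        assert mask_reference(once, sites) == once

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            mask_reference({"chr1": "ACGT"}, [VariantSite("chr1", 10, "A", "G")])


class TestCountAlleles:
    def test_fixture_tallies(self):
        reads = [make_read(f"ref{i}", 100, "A") for i in range(12)]
        reads += [make_read(f"alt{i}", 100, "G") for i in range(8)]
        (rec,) = count_alleles(reads, [SITE], "s1")
        assert (rec.ref_count, rec.alt_count, rec.other_count) == (12, 8, 0)

    def test_below_min_depth_no_record(self):
        reads = [make_read(f"r{i}", 100, "A") for i in range(9)]
        assert count_alleles(reads, [SITE], "s1") == []

    def test_low_mapq_and_multimappers_excluded(self):
        reads = [make_read(f"r{i}", 100, "A") for i in range(10)]
        reads.append(make_read("low", 100, "G", mapq=5))
        reads.append(make_read("multi", 100, "G", nh=2))
        (rec,) = count_alleles(reads, [SITE], "s1")
        assert rec.alt_count == 0 and rec.ref_count == 10

    def test_duplicate_read_id_counted_once(self):
        reads = [make_read(f"r{i}", 100, "A") for i in range(10)]
        reads.append(make_read("r0", 100, "A"))  # same id again
        (rec,) = count_alleles(reads, [SITE], "s1")
        assert rec.ref_count == 10

    def test_other_allele_counts_to_depth_not_test(self):
        reads = [make_read(f"r{i}", 100, "A") for i in range(8)]
        reads += [make_read(f"o{i}", 100, "T") for i in range(4)]
        (rec,) = count_alleles(reads, [SITE], "s1")
        assert (rec.ref_count, rec.other_count, rec.depth) == (8, 4, 12)

    def test_pileup_counter_agrees_with_record_counter(self, tmp_path):
        from galtase.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(seed=21, n_genes=20, library_size=8000, het_density=2.0)
        ds = simulate_dataset(cfg, tmp_path / "sim")
        sites = ds.individuals.sites
        positions = {"chr1": sorted(s.pos for s in sites)}
        sam = ds.sam_path("A1_MLN")
        slow = count_alleles(
            read_alignments(sam, site_positions=positions), sites, "A1_MLN"
        )
        fast = count_alleles_pileup(sam, sites, "A1_MLN")
        key = lambda c: (c.site.pos, c.ref_count, c.alt_count, c.other_count)
        assert sorted(map(key, slow)) == sorted(map(key, fast))


class TestGenotypeAnimal:
    def test_pure_reference_counts_call_homref(self):
        calls, _ = genotype_animal([AllelicCount("s", SITE, 30, 0)], "A1", init_error=0.01)
        (call,) = calls
        assert call.call == "homRef" and call.posterior[0] > 0.999

    def test_balanced_counts_call_het(self):
        calls, _ = genotype_animal([AllelicCount("s", SITE, 11, 10)], "A1")
        (call,) = calls
        assert call.call == "het" and call.posterior[1] > 0.99

    def test_pooling_across_tissues(self):
        counts = [AllelicCount(f"t{i}", SITE, 3, 3) for i in range(4)]
        calls, _ = genotype_animal(counts, "A1")
        (call,) = calls
        assert call.pooled_coverage == 24 and call.call == "het"

    def test_low_pooled_coverage_is_no_call(self):
        calls, _ = genotype_animal([AllelicCount("s", SITE, 2, 2)], "A1")
        assert calls[0].call == "no_call"

    def test_em_recovers_error_rate_and_genotypes(self):
        g = np.random.default_rng(17)
        n, eps_true = 1500, 0.01
        geno = g.choice(3, n, p=[0.25, 0.5, 0.25])
        p_ref = np.where(geno == 0, 1 - eps_true, np.where(geno == 1, 0.5, eps_true))
        r = g.binomial(25, p_ref)
        counts = [
            AllelicCount("s", VariantSite("chr1", i * 10, "A", "G"), int(r[i]), int(25 - r[i]))
            for i in range(n)
        ]
        calls, eps = genotype_animal(counts, "A1")
        assert abs(eps - eps_true) < 0.01
        labels = {"homRef": 0, "het": 1, "homAlt": 2}
        called = [(c, gi) for c, gi in zip(calls, geno) if c.call != "no_call"]
        acc = np.mean([labels[c.call] == gi for c, gi in called])
        assert acc >= 0.98


def enumeration_binomial_p(k, n, p0=0.5):
    """Minimum-likelihood two-sided p by full enumeration over 0..n."""
    probs = [binom.pmf(i, n, p0) for i in range(n + 1)]
    obs = probs[k]
    return min(1.0, sum(pi for pi in probs if pi <= obs * (1 + 1e-12)))


class TestAseTest:
    def test_balanced_counts_give_p_one(self):
        rec = ase_test(AllelicCount("s", SITE, 10, 10), "A1", "MLN")
        assert rec.p_value == pytest.approx(1.0)

    def test_fifteen_five_matches_enumeration(self):
        rec = ase_test(AllelicCount("s", SITE, 15, 5), "A1", "MLN")
        assert rec.p_value == pytest.approx(enumeration_binomial_p(15, 20), rel=1e-9)
        assert rec.p_value == pytest.approx(0.04139, abs=5e-6)

    def test_extreme_imbalance(self):
        rec = ase_test(AllelicCount("s", SITE, 0, 10), "A1", "MLN")
        assert rec.p_value == pytest.approx(2 * 0.5**10 / 1, rel=1e-9) or rec.p_value == pytest.approx(0.001953125)

    def test_below_min_reads_skipped(self):
        assert ase_test(AllelicCount("s", SITE, 5, 4), "A1", "MLN") is None


class TestCorrectAndFlag:
    def test_single_test_keeps_p_as_fdr(self):
        rec = ase_test(AllelicCount("s", SITE, 16, 4), "A1", "MLN")
        (out,) = correct_and_flag([rec])
        assert out.fdr == pytest.approx(out.p_value)
        assert out.significant

    def test_uniform_half_never_significant(self):
        recs = [ase_test(AllelicCount("s", SITE, 10, 10), "A1", "MLN") for _ in range(20)]
        assert not any(r.significant for r in correct_and_flag(recs))


class TestAssignGenes:
    GENES = [
        GeneModel("g1", "chr1", "+", ((10_000, 12_000),)),
        GeneModel("g2", "chr1", "-", ((18_000, 20_000),)),
    ]

    def _hit(self, pos):
        site = VariantSite("chr1", pos, "A", "G")
        return assign_genes([site], self.GENES)[site]

    def test_site_inside_exon(self):
        assert self._hit(11_000) == ("g1",)

    def test_window_boundary_inclusive_at_5kb(self):
        assert self._hit(10_000 - 4_999) == ("g1",)
        assert self._hit(10_000 - 5_000) == ("g1",)
        assert self._hit(10_000 - 5_001) == ()

    def test_site_between_two_genes_assigned_to_both(self):
        # 12_000..18_000 gap: midpoint within 5 kb of both spans
        assert self._hit(15_000) == ("g1", "g2")


class TestSummarize:
    def _rec(self, animal, tissue, pos, significant, genes=("g1",)):
        r = ase_test(
            AllelicCount("s", VariantSite("chr1", pos, "A", "G"), 18, 2), animal, tissue
        )
        r.significant = significant
        r.fdr = 0.01 if significant else 0.5
        r.gene_ids = genes
        return r

    def test_single_het_significant_is_consistent(self):
        recs = [self._rec("A1", "MLN", 100, True)]
        summary = summarize_ase(recs, [])
        row = summary.per_tissue.iloc[0]
        assert row.ase_snps == 1 and row.consistent_ase_snps == 1

    def test_partial_significance_not_consistent(self):
        recs = [self._rec("A1", "MLN", 100, True), self._rec("A2", "MLN", 100, False)]
        summary = summarize_ase(recs, [])
        row = summary.per_tissue.iloc[0]
        assert row.ase_snps == 1 and row.consistent_ase_snps == 0

    def test_consistent_subset_of_ase(self):
        g = np.random.default_rng(23)
        recs = []
        for pos in range(0, 400, 10):
            for animal in ("A1", "A2"):
                recs.append(self._rec(animal, "MLN", pos, bool(g.random() < 0.4)))
        summary = summarize_ase(recs, [])
        row = summary.per_tissue.iloc[0]
        assert row.consistent_ase_snps <= row.ase_snps

    def test_tissue_specific_requires_expression_elsewhere(self):
        recs = [
            self._rec("A1", "MLN", 100, True, genes=("g1",)),
            self._rec("A1", "IPP", 200, False, genes=("g2",)),
        ]
        expressed = {"MLN": {"g1", "g2"}, "IPP": {"g2"}}  # g1 not expressed in IPP
        summary = summarize_ase(recs, [], expressed)
        assert summary.tissue_specific_ase_genes["MLN"] == set()
        expressed2 = {"MLN": {"g1", "g2"}, "IPP": {"g1", "g2"}}
        summary2 = summarize_ase(recs, [], expressed2)
        assert summary2.tissue_specific_ase_genes["MLN"] == {"g1"}


class TestAseAnalysisFacade:
    def test_null_simulation_controls_significance(self):
        g = np.random.default_rng(29)
        animals = [f"A{i}" for i in range(4)]
        tissues = ["MLN", "IPP"]
        sites = [VariantSite("chr1", i * 50, "A", "G") for i in range(300)]
        counts = {}
        meta = {}
        for a in animals:
            for t in tissues:
                sid = f"{a}_{t}"
                meta[sid] = (a, t)
                counts[sid] = [
                    AllelicCount(sid, s, int(r), int(40 - r))
                    for s, r in zip(sites, g.binomial(40, 0.5, len(sites)))
                ]
        res = AseAnalysis(counts, meta).fit()
        assert len(res.records) > 500
        sig_frac = np.mean([r.significant for r in res.records])
        assert sig_frac <= 0.02
        # het calls should dominate under balanced counts
        assert all(e < 0.05 for e in res.error_rates.values())
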