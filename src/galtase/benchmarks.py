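"""Truth-recovery benchmarks for the statistical core.

Each function simulates data with known truth under the study's default
conditions (4 animals, NB dispersion 0.1, allelic ratio 0.7 at imbalanced
sites, ...), runs the corresponding estimator, and returns scalar recovery
metrics: null calibration and power of the NB-GLM likelihood-ratio test,
dispersion recovery, genotyping accuracy, allelic-imbalance recall and
error control, and cross-tissue structure recovery.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from galtase.ase import AllelicCount, AseAnalysis
from galtase.de import (
    build_design,
    correlation_matrix,
    estimate_dispersion,
    lrt_de,
    mds_coordinates,
    tmm_factors,
)
from galtase.io import GeneModel, SampleMeta, VariantSite
from galtase.quantify import CountMatrix, log2_cpm
from galtase.simulate import SimulationConfig, simulate_expression


def _two_tissue_design(n_animals: int = 4):
    animals = [f"A{i}" for i in range(n_animals)]
    samples = [SampleMeta(f"{a}_{t}", a, t) for a in animals for t in ("T1", "T2")]
    X_full, _ = build_design(samples, ["T1", "T2"])
    X_red = np.delete(X_full, 1, axis=1)
    return samples, X_full, X_red


def null_de_calibration(seed: int, n_genes: int = 2000, dispersion: float = 0.1) -> dict:
    """Null NB-GLM LRT: 2 tissues x 4 animals, no true effects.

    Returns the KS uniformity p-value of the raw p-values, the fraction
    flagged at FDR < 0.05 (the empirical false-positive rate under a
    global null), the median log2FC, and the recovered common dispersion.
    """
    rng = np.random.default_rng([seed, 101])
    _, X_full, X_red = _two_tissue_design()
    n = X_full.shape[0]
    base = rng.lognormal(4.5, 1.0, n_genes)
    mu = np.outer(base, np.ones(n))
    y = rng.poisson(rng.gamma(1.0 / dispersion, dispersion * mu))
    offsets = np.zeros(n)
    dm = estimate_dispersion(y, X_full, offsets)
    tab = lrt_de(
        y, [f"g{i}" for i in range(n_genes)], X_full, X_red, offsets,
        dm.per_gene_dispersion, 1, "T1_vs_T2", np.zeros(n_genes),
    )
    return {
        "ks_uniform_p": float(stats.kstest(tab.p_value, "uniform").pvalue),
        "false_positive_fraction": float(tab.significant.mean()),
        "median_log2fc": float(np.median(tab.log2fc)),
        "common_dispersion": float(dm.common_dispersion),
        "n_genes": n_genes,
    }


def de_power(
    seed: int,
    n_genes: int = 400,
    log2fc: float = 2.0,
    min_mean: float = 50.0,
    dispersion: float = 0.1,
) -> dict:
    """Fraction of true |log2FC| = 2 genes flagged strong (FDR + |lfc| >= 1)."""
    rng = np.random.default_rng([seed, 102])
    samples, X_full, X_red = _two_tissue_design()
    n = len(samples)
    base = rng.uniform(min_mean, 10 * min_mean, n_genes)
    mu = np.empty((n_genes, n))
    sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    for j, s in enumerate(samples):
        mu[:, j] = base * np.where(s.tissue == "T2", 2.0 ** (sign * log2fc), 1.0)
    y = rng.poisson(rng.gamma(1.0 / dispersion, dispersion * mu))
    offsets = np.zeros(n)
    dm = estimate_dispersion(y, X_full, offsets)
    tab = lrt_de(
        y, [f"g{i}" for i in range(n_genes)], X_full, X_red, offsets,
        dm.per_gene_dispersion, 1, "c", np.zeros(n_genes),
    )
    return {"power_strong": float(tab.strong.mean()), "n_genes": n_genes}


def dispersion_recovery(seed: int, true_phi: float = 0.1, n_genes: int = 500) -> dict:
    """Ratio of estimated to true common dispersion at phi = 0.1."""
    rng = np.random.default_rng([seed, 103])
    n = 16
    X = np.column_stack([np.ones(n), np.repeat([0, 1], n // 2)])
    mu = np.outer(rng.lognormal(4.0, 1.0, n_genes), np.ones(n))
    y = rng.poisson(rng.gamma(1.0 / true_phi, true_phi * mu))
    dm = estimate_dispersion(y, X, np.zeros(n))
    return {
        "estimated_dispersion": float(dm.common_dispersion),
        "ratio_to_truth": float(dm.common_dispersion / true_phi),
        "n_genes": n_genes,
    }


# ---------------------------------------------------------------------------
# ASE benchmarks (allelic-count level, study design: 4 animals x 4 tissues)


def _simulate_allelic_design(
    rng: np.random.Generator,
    n_sites: int,
    coverage: int,
    fraction_imbalanced: float,
    ratio: float,
    error: float = 0.005,
    tissues: tuple[str, ...] = ("MLN", "IPP", "JPP", "PB"),
    n_animals: int = 4,
):
    animals = [f"A{i}" for i in range(n_animals)]
    sites = [VariantSite("chr1", i * 100, "A", "G") for i in range(n_sites)]
    imbalanced = rng.random(n_sites) < fraction_imbalanced
    geno = rng.choice(3, (n_animals, n_sites), p=[0.25, 0.5, 0.25])
    counts = {}
    meta = {}
    for ai, a in enumerate(animals):
        for t in tissues:
            sid = f"{a}_{t}"
            meta[sid] = (a, t)
            p_ref = np.where(
                geno[ai] == 0, 1.0 - error,
                np.where(geno[ai] == 2, error, np.where(imbalanced, ratio, 0.5)),
            )
            r = rng.binomial(coverage, p_ref)
            counts[sid] = [
                AllelicCount(sid, s, int(r[i]), int(coverage - r[i]))
                for i, s in enumerate(sites)
            ]
    return sites, imbalanced, geno, counts, meta


def genotyping_accuracy(seed: int, coverage_per_sample: int = 5, n_sites: int = 1500) -> dict:
    """Genotype-call accuracy with tissues pooled (4 x per-sample coverage).

    With the default 4 tissues at 5 reads each, pooled coverage is 20 per
    animal x site; the simulated sequencing error rate is 0.01 per read.
    """
    rng = np.random.default_rng([seed, 104])
    sites, _, geno, counts, meta = _simulate_allelic_design(
        rng, n_sites, coverage_per_sample, 0.0, 0.5, error=0.01
    )
    model = AseAnalysis(counts, meta, min_test_reads=10)
    res = model.fit()
    labels = {"homRef": 0, "het": 1, "homAlt": 2}
    n_ok = n_called = 0
    for ai, a in enumerate(sorted(res.genotypes)):
        for i, s in enumerate(sites):
            call = res.genotypes[a].get(s)
            if call is None or call.call == "no_call":
                continue
            n_called += 1
            n_ok += labels[call.call] == geno[ai, i]
    return {
        "accuracy": n_ok / n_called if n_called else float("nan"),
        "called_fraction": n_called / (len(sites) * 4),
        "pooled_coverage": coverage_per_sample * 4,
    }


def ase_recovery(
    seed: int,
    coverage: int = 50,
    ratio: float = 0.7,
    fraction_imbalanced: float = 0.1,
    n_sites: int = 600,
) -> dict:
    """Recall of truly imbalanced het sites and test-level error control.

    A site is recalled when flagged significant for at least one
    heterozygous animal in at least one tissue (the ASE-SNP definition);
    the empirical FDR is measured at the level BH controls, over
    individual (animal, tissue, site) tests.
    """
    rng = np.random.default_rng([seed, 105])
    sites, imbalanced, geno, counts, meta = _simulate_allelic_design(
        rng, n_sites, coverage, fraction_imbalanced, ratio
    )
    res = AseAnalysis(counts, meta).fit()
    site_index = {s: i for i, s in enumerate(sites)}
    detected = {r.site for r in res.records if r.significant}
    truly = {
        s for i, s in enumerate(sites) if imbalanced[i] and (geno[:, i] == 1).any()
    }
    n_sig = sum(r.significant for r in res.records)
    n_fp = sum(
        1 for r in res.records if r.significant and not imbalanced[site_index[r.site]]
    )
    return {
        "site_recall": len(detected & truly) / len(truly) if truly else float("nan"),
        "test_level_fdr": n_fp / n_sig if n_sig else 0.0,
        "n_significant_tests": int(n_sig),
        "n_true_sites": len(truly),
    }


def ase_null_control(seed: int, coverage: int = 40, n_sites: int = 500) -> dict:
    """All ratios 0.5: fraction of tests flagged must sit at the BH level."""
    rng = np.random.default_rng([seed, 106])
    _, _, _, counts, meta = _simulate_allelic_design(rng, n_sites, coverage, 0.0, 0.5)
    res = AseAnalysis(counts, meta).fit()
    n = len(res.records)
    frac = float(np.mean([r.significant for r in res.records])) if n else 0.0
    return {"significant_fraction": frac, "n_tests": n}


def ase_power_grid(
    seed: int,
    coverages: tuple[int, ...] = (20, 50, 100),
    ratios: tuple[float, ...] = (0.6, 0.7, 0.8),
    n_sites: int = 300,
) -> dict:
    """Per-test detection rate over the coverage x effect-size grid.

    All simulated sites are imbalanced, so BH acts within a family of
    uniformly non-null tests and the detection rate isolates power.
    """
    grid = {}
    for ci, cov in enumerate(coverages):
        for ri, ratio in enumerate(ratios):
            rng = np.random.default_rng([seed, 107, ci, ri])
            _, _, _, counts, meta = _simulate_allelic_design(
                rng, n_sites, cov, 1.0, ratio, tissues=("T1",), n_animals=2
            )
            res = AseAnalysis(counts, meta).fit()
            grid[(cov, ratio)] = (
                float(np.mean([r.significant for r in res.records])) if res.records else 0.0
            )
    return grid


# ---------------------------------------------------------------------------
# Structure recovery (count level, full 4-tissue design)


def structure_recovery(seed: int, n_replicates: int = 100, n_genes: int = 2000) -> dict:
    """How often the PP pairing is recovered, plus the antisense diagonal.

    For each replicate the default generator's count layer is produced,
    TMM-normalised, and summarised: the Spearman win is
    corr(IPP, JPP) > corr(IPP, MLN) on sense profiles; the MDS win is a
    smaller mean embedded IPP-JPP distance than IPP-MLN; the diagonal is
    the within-tissue sense-vs-antisense correlation (near zero when
    antisense is independent).
    """
    genes = [GeneModel(f"G{i}", "chr1", "+", ((0, 100),)) for i in range(n_genes)]
    corr_wins = mds_wins = 0
    diagonals = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(seed=int(seed % 2**20) * 1000 + rep, n_genes=n_genes)
        ex = simulate_expression(cfg, genes)
        matrix = CountMatrix(
            gene_ids=[g.gene_id for g in genes],
            sample_ids=[s.sample_id for s in ex.samples],
            sense=ex.sense_counts,
            antisense=ex.antisense_counts,
            library_sizes=ex.sense_counts.sum(axis=0).astype(float),
        )
        matrix.norm_factors = tmm_factors(matrix.sense, matrix.library_sizes)
        samples_of_tissue: dict[str, list[str]] = {}
        for s in ex.samples:
            samples_of_tissue.setdefault(s.tissue, []).append(s.sample_id)
        corr = correlation_matrix(matrix, samples_of_tissue, list(cfg.tissues))
        corr_wins += corr.loc["JPP", "IPP"] > corr.loc["IPP", "MLN"]
        diagonals.append([corr.loc[t, t] for t in cfg.tissues])
        coords = mds_coordinates(log2_cpm(matrix), top_genes=500)
        idx = {s.sample_id: k for k, s in enumerate(ex.samples)}

        def tissue_dist(t1: str, t2: str) -> float:
            pairs = [
                np.linalg.norm(coords[idx[f"A{a}_{t1}"]] - coords[idx[f"A{b}_{t2}"]])
                for a in range(1, 5)
                for b in range(1, 5)
            ]
            return float(np.mean(pairs))

        mds_wins += tissue_dist("IPP", "JPP") < tissue_dist("IPP", "MLN")
    diag = np.abs(np.asarray(diagonals, dtype=float))
    return {
        "correlation_win_fraction": corr_wins / n_replicates,
        "mds_win_fraction": mds_wins / n_replicates,
        "mean_abs_diagonal": float(np.nanmean(diag)),
        "n_replicates": n_replicates,
    }
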