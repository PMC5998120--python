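"""Normalisation, NB GLM, dispersion, LRT, BH, MDS, correlation structure."""

import shutil
import subprocess

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from galtase.de import (
    DifferentialExpression,
    bh_fdr,
    build_design,
    correlation_matrix,
    estimate_dispersion,
    fit_nb_glm,
    lrt_de,
    mds_coordinates,
    tmm_factors,
)
from galtase.io import SampleMeta
from galtase.quantify import CountMatrix, log2_cpm

rng = np.random.default_rng(2024)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(rng.integers(1, 200, size=(300, 1)), (1, 5)).astype(float)
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_scaling_removed(self):
        base = rng.negative_binomial(5, 0.05, size=500).astype(float) + 1
        scaled = np.column_stack([base, base * 3.0, base * 0.25])
        f = tmm_factors(scaled)
        lib = scaled.sum(axis=0)
        norm_cpm = scaled / (lib * f)[None, :]
        assert np.abs(norm_cpm[:, 1] / norm_cpm[:, 0] - 1.0).max() < 0.01

    def test_trimming_robust_to_inflated_minority(self):
        # inflating 5% of genes 10x must not distort the *effective*
        # library (size x factor): the trimmed factor absorbs the
        # composition shift the inflated genes cause
        base = rng.negative_binomial(5, 0.05, size=(1000, 2)).astype(float) + 1
        inflated = base.copy()
        idx = rng.choice(1000, size=50, replace=False)
        inflated[idx, 1] *= 10
        f_clean = tmm_factors(base)
        f_infl = tmm_factors(inflated)
        eff_clean = base.sum(axis=0) * f_clean
        eff_infl = inflated.sum(axis=0) * f_infl
        assert abs((eff_infl[1] / eff_infl[0]) / (eff_clean[1] / eff_clean[0]) - 1.0) < 0.05

    def test_factors_multiply_to_one(self):
        for seed in range(5):
            counts = np.random.default_rng(seed).integers(0, 500, size=(200, 6)).astype(float)
            counts += 1
            f = tmm_factors(counts)
            assert np.prod(f) == pytest.approx(1.0, abs=1e-10)

    def test_matches_edger_reference(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable: edgeR cross-check cannot run")
        counts = np.random.default_rng(42).negative_binomial(2, 0.02, size=(2000, 6)).astype(float)
        de = np.random.default_rng(43).random(2000) < 0.05
        counts[de, 0] *= 8
        path = tmp_path / "counts.tsv"
        np.savetxt(path, counts, fmt="%d", delimiter="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.table("{path}"));'
            'cat(calcNormFactors(x, method="TMM"), sep="\\n")'
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        ref = np.array([float(v) for v in res.stdout.split()])
        ours = tmm_factors(counts)
        assert np.max(np.abs(ours / ref - 1.0)) < 1e-4


class TestNbGlm:
    def setup_method(self):
        self.n = 8
        self.X = np.column_stack(
            [np.ones(self.n), np.repeat([0, 1], 4), np.tile([0, 1], 4)]
        )
        self.offsets = np.log(np.full(self.n, 1e4))

    def test_poisson_limit_matches_statsmodels(self):
        mu = np.exp(self.X @ np.array([-5.0, 1.0, -0.5]) + self.offsets)
        y = np.random.default_rng(0).poisson(mu)
        fit = fit_nb_glm(y[None, :], self.X, self.offsets, 0.0)
        ref = sm.GLM(y, self.X, family=sm.families.Poisson(), offset=self.offsets).fit()
        assert np.abs(fit.coef[0] - ref.params).max() < 1e-6
        assert fit.loglik[0] == pytest.approx(ref.llf, abs=1e-6)

    def test_known_dispersion_matches_statsmodels_nb(self):
        phi = 0.2
        mu = np.exp(self.X @ np.array([-5.0, 1.0, -0.5]) + self.offsets)
        g = np.random.default_rng(1)
        y = g.negative_binomial(1 / phi, (1 / phi) / (1 / phi + mu))
        fit = fit_nb_glm(y[None, :], self.X, self.offsets, phi)
        ref = sm.GLM(
            y, self.X, family=sm.families.NegativeBinomial(alpha=phi), offset=self.offsets
        ).fit()
        assert np.abs(fit.coef[0] - ref.params).max() < 1e-4

    def test_offset_shift_moves_only_intercept(self):
        y = np.random.default_rng(2).poisson(100, self.n)
        f1 = fit_nb_glm(y[None, :], self.X, self.offsets, 0.1)
        f2 = fit_nb_glm(y[None, :], self.X, self.offsets + 2.0, 0.1)
        assert f1.coef[0, 0] - f2.coef[0, 0] == pytest.approx(2.0, abs=1e-6)
        assert np.abs(f1.coef[0, 1:] - f2.coef[0, 1:]).max() < 1e-6

    def test_intercept_only_fit_is_mean(self):
        y = np.array([[3, 7, 5, 9, 4, 6, 8, 2]], dtype=float)
        X = np.ones((8, 1))
        fit = fit_nb_glm(y, X, np.zeros(8), 0.0)
        assert np.exp(fit.coef[0, 0]) == pytest.approx(y.mean(), rel=1e-6)

    def test_all_zero_gene_flagged(self):
        y = np.zeros((1, 8))
        fit = fit_nb_glm(y, self.X, self.offsets, 0.1)
        assert fit.all_zero[0]

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(8), np.ones(8)])
        with pytest.raises(ValueError, match="full rank"):
            fit_nb_glm(np.ones((1, 8)), X, np.zeros(8), 0.1)


class TestDispersion:
    def test_recovery_at_phi_0p1(self):
        g = np.random.default_rng(7)
        G, n = 200, 16
        X = np.column_stack([np.ones(n), np.repeat([0, 1], 8)])
        mu = np.outer(g.lognormal(4, 1, G), np.ones(n))
        y = g.poisson(g.gamma(1 / 0.1, 0.1 * mu))
        dm = estimate_dispersion(y, X, np.zeros(n))
        assert 0.05 <= dm.common_dispersion <= 0.2

    def test_poisson_data_near_zero(self):
        g = np.random.default_rng(8)
        G, n = 200, 16
        X = np.ones((n, 1))
        y = g.poisson(np.outer(g.lognormal(4, 1, G), np.ones(n)))
        dm = estimate_dispersion(y, X, np.zeros(n))
        assert dm.common_dispersion < 0.01

    def test_infinite_prior_shrinks_to_common(self):
        g = np.random.default_rng(9)
        y = g.poisson(50, size=(50, 8))
        X = np.ones((8, 1))
        dm = estimate_dispersion(y, X, np.zeros(8), prior_df=np.inf)
        assert np.all(dm.per_gene_dispersion == dm.common_dispersion)


def brute_force_bh(p):
    """Independent step-up reference implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestBhFdr:
    def test_hand_computed_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_fdr(np.ones(5)), 1.0)

    def test_matches_brute_force_on_random_vectors(self):
        g = np.random.default_rng(123)
        for _ in range(1000):
            p = g.random(int(g.integers(1, 40)))
            assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    @given(st.permutations(list(range(8))))
    @settings(deadline=None, max_examples=50)
    def test_order_equivariance(self, perm):
        p = np.array([0.9, 0.01, 0.2, 0.04, 0.5, 0.03, 0.6, 0.11])
        perm = np.array(perm)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))


class TestLrt:
    def test_equal_counts_give_null_result(self):
        n = 8
        animals = [f"A{i}" for i in range(4)]
        samples = [SampleMeta(f"{a}_{t}", a, t) for a in animals for t in ("T1", "T2")]
        Xf, _ = build_design(samples, ["T1", "T2"])
        Xr = np.delete(Xf, 1, axis=1)
        y = np.full((1, n), 60.0)
        tab = lrt_de(y, ["g"], Xf, Xr, np.zeros(n), np.array([0.1]), 1, "c", np.zeros(1))
        assert abs(tab.log2fc[0]) < 1e-6
        assert tab.p_value[0] > 0.99

    def test_non_nested_reduced_design_rejected(self):
        Xf = np.column_stack([np.ones(6), np.repeat([0, 1], 3)])
        Xr = np.column_stack([np.ones(6), np.tile([0, 1], 3)])
        with pytest.raises(ValueError, match="nested"):
            lrt_de(np.ones((1, 6)), ["g"], Xf, Xr, np.zeros(6), 0.1, 1, "c", np.zeros(1))

    def test_invariant_to_animal_baseline_relabelling(self):
        g = np.random.default_rng(3)
        animals = [f"A{i}" for i in range(4)]
        samples = [SampleMeta(f"{a}_{t}", a, t) for a in animals for t in ("T1", "T2")]
        y = g.poisson(100, size=(5, 8)).astype(float)
        Xf1, _ = build_design(samples, ["T1", "T2"])
        relabel = {"A0": "Z9", "A1": "A1", "A2": "A2", "A3": "A3"}
        samples2 = [
            SampleMeta(s.sample_id, relabel[s.animal_id], s.tissue) for s in samples
        ]
        Xf2, _ = build_design(samples2, ["T1", "T2"])
        t1 = lrt_de(y, list("abcde"), Xf1, np.delete(Xf1, 1, 1), np.zeros(8),
                    np.full(5, 0.1), 1, "c", np.zeros(5))
        t2 = lrt_de(y, list("abcde"), Xf2, np.delete(Xf2, 1, 1), np.zeros(8),
                    np.full(5, 0.1), 1, "c", np.zeros(5))
        assert np.allclose(t1.lr_statistic, t2.lr_statistic, atol=1e-5)


class TestMds:
    def test_duplicated_sample_coincides(self):
        g = np.random.default_rng(4)
        L = g.normal(size=(300, 4))
        L[:, 3] = L[:, 0]
        coords = mds_coordinates(L, top_genes=100)
        assert np.linalg.norm(coords[0] - coords[3]) < 1e-8

    def test_three_sample_embedding_is_exact(self):
        g = np.random.default_rng(5)
        L = g.normal(size=(400, 3))
        coords = mds_coordinates(L, top_genes=200)
        import itertools

        for i, j in itertools.combinations(range(3), 2):
            diff = np.sort(np.abs(L[:, i] - L[:, j]))[-200:]
            expected = np.sqrt(np.mean(diff**2))
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(expected, rel=1e-9)

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            mds_coordinates(np.ones((10, 2)))


def _matrix_from_counts(sense, anti, samples):
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(sense.shape[0])],
        sample_ids=[s.sample_id for s in samples],
        sense=sense,
        antisense=anti,
        library_sizes=sense.sum(axis=0).astype(float),
    )


class TestCorrelationMatrix:
    def test_identical_profiles_correlate_perfectly(self):
        g = np.random.default_rng(6)
        samples = [
            SampleMeta(f"A{a}_{t}", f"A{a}", t) for t in ("T1", "T2") for a in range(2)
        ]
        profile = g.integers(20, 2000, size=500)
        sense = np.tile(profile[:, None], (1, 4)).astype(float)
        anti = g.poisson(30, size=(500, 4)).astype(float)
        m = _matrix_from_counts(sense, anti, samples)
        sot = {"T1": ["A0_T1", "A1_T1"], "T2": ["A0_T2", "A1_T2"]}
        corr = correlation_matrix(m, sot, ["T1", "T2"])
        assert corr.loc["T2", "T1"] == pytest.approx(1.0)


class TestDifferentialExpressionFacade:
    def test_fit_recovers_strong_de_and_reports_summary(self):
        g = np.random.default_rng(11)
        G = 300
        animals = [f"A{i}" for i in range(4)]
        samples = [SampleMeta(f"{a}_{t}", a, t) for a in animals for t in ("T1", "T2")]
        base = g.lognormal(4.5, 0.8, G)
        lfc = np.zeros(G)
        lfc[:30] = 2.0  # first 30 genes up in T2
        mu = np.empty((G, 8))
        for j, s in enumerate(samples):
            mu[:, j] = base * (2.0 ** (lfc * (s.tissue == "T2")))
        y = g.poisson(g.gamma(1 / 0.05, 0.05 * mu))
        m = _matrix_from_counts(y, np.zeros_like(y), samples)
        res = DifferentialExpression(m, samples, tissues=["T1", "T2"]).fit()
        tab = res.table("T1", "T2").set_index("gene_id")
        truly = [f"g{i}" for i in range(30)]
        assert tab.loc[truly, "strong"].mean() >= 0.8
        null = tab.drop(index=truly)
        assert null.significant.mean() < 0.05
        text = res.summary()
        assert "common dispersion" in text and "T1 vs T2" in text
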