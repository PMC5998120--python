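"""Differential expression and expression-structure analysis.

The model is a negative-binomial generalized linear model per gene with a
log link, variance mu + phi * mu^2, offsets log(library x TMM factor), and
a design of intercept + tissue + individual.  Differential expression
between a pair of tissues is a likelihood-ratio test of the tissue term
against a chi-square null, corrected per contrast by Benjamini-Hochberg.
Dispersion is estimated by Cox-Reid adjusted profile likelihood: a common
value maximizing the summed APL, then per-gene values shrunk towards the
common curve with a fixed prior weight.

Between-sample normalisation is the trimmed mean of M-values (TMM):
pairwise log-ratios against a reference sample are doubly trimmed (30% on
M, 5% on A), inverse-variance weighted, and the resulting factors are
centred to geometric mean 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, xlogy
from statsmodels.stats.multitest import multipletests

from galtase.io import SampleMeta
from galtase.quantify import ANTISENSE, SENSE, CountMatrix, cpm, filter_expressed, log2_cpm

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# TMM normalisation


def tmm_factors(
    counts: np.ndarray,
    lib_sizes: np.ndarray | None = None,
    ref_sample: int | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    min_genes: int = 20,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalisation factors, centred to product 1.

    For each sample k against the reference r, over genes with nonzero
    counts in both: M = log2 relative abundance ratio, A = average log
    abundance; the top/bottom ``trim_m`` of M-ranks and ``trim_a`` of
    A-ranks are discarded and the factor is 2**(weighted mean M) with
    delta-method binomial weights.  The reference defaults to the sample
    whose 75th-percentile scaled count is closest to the mean of those.
    """
    counts = np.asarray(counts, dtype=float)
    n_samples = counts.shape[1]
    if n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise ValueError("TMM needs positive library sizes")
    if ref_sample is None:
        q75 = np.array(
            [np.quantile(counts[:, j] / lib_sizes[j], 0.75) for j in range(n_samples)]
        )
        ref_sample = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.ones(n_samples)
    xr, nr = counts[:, ref_sample], lib_sizes[ref_sample]
    for k in range(n_samples):
        if k == ref_sample:
            continue
        xk, nk = counts[:, k], lib_sizes[k]
        use = (xk > 0) & (xr > 0)
        if use.sum() < min_genes:
            import warnings

            warnings.warn(f"TMM: sample {k} has <{min_genes} usable genes; factor set to 1")
            continue
        pk, pr = xk[use] / nk, xr[use] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = (nk - xk[use]) / (nk * xk[use]) + (nr - xr[use]) / (nr * xr[use])
        n = m.size
        # double trimming by rank, keeping the central band on both axes
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0:
            continue
        factors[k] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# Negative binomial GLM (batched IRLS across genes)


@dataclass
class GlmFit:
    """Per-gene NB GLM fit: coefficients, fitted means, log-likelihoods."""

    coef: np.ndarray  # (G, p)
    mu: np.ndarray  # (G, n)
    loglik: np.ndarray  # (G,)
    converged: np.ndarray  # (G,) bool
    cr_adjustment: np.ndarray  # (G,) 0.5*logdet(X'WX)
    all_zero: np.ndarray  # (G,) bool


def nb_loglik(y: np.ndarray, mu: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """NB log-likelihood summed over samples; Poisson at dispersion ~ 0."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (y.shape[0],)).copy()
    out = np.empty(y.shape[0])
    pois = phi < 1e-10
    if np.any(pois):
        yy, mm = y[pois], mu[pois]
        out[pois] = np.sum(xlogy(yy, mm) - mm - gammaln(yy + 1), axis=1)
    if np.any(~pois):
        yy, mm, pp = y[~pois], mu[~pois], phi[~pois][:, None]
        r = 1.0 / pp
        out[~pois] = np.sum(
            gammaln(yy + r) - gammaln(r) - gammaln(yy + 1)
            + xlogy(yy, pp * mm / (1 + pp * mm))
            - r * np.log1p(pp * mm),
            axis=1,
        )
    return out


def fit_nb_glm(
    counts: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    dispersion: float | np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> GlmFit:
    """Fit an NB GLM with log link to every gene (row) of ``counts``.

    ``offsets`` is length-n (log effective library sizes); ``dispersion``
    is a scalar or per-gene vector.  IRLS with working weights
    mu/(1 + phi*mu), converged when the relative deviance change drops
    below ``tol``.  All-zero genes are flagged and returned at the
    baseline (mu -> 0).
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    X = np.asarray(design, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    if X.shape[0] != n:
        raise ValueError("design rows must match sample count")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not full rank")
    offsets = np.asarray(offsets, dtype=float)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (G,))

    all_zero = y.sum(axis=1) == 0
    # initialise from a least-squares fit on shifted log counts
    z0 = np.log(y + 0.5) - offsets[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, p)

    eta = beta @ X.T + offsets[None, :]
    mu = np.clip(np.exp(eta), 1e-10, 1e12)
    last = nb_loglik(y, mu, phi)
    active = ~all_zero
    converged = np.zeros(G, dtype=bool)
    eye = np.eye(p) * 1e-8
    for _ in range(max_iter):
        if not np.any(active):
            break
        w = mu[active] / (1.0 + phi[active][:, None] * mu[active])
        z = (eta[active] - offsets[None, :]) + (y[active] - mu[active]) / mu[active]
        XtWX = np.einsum("gn,ni,nj->gij", w, X, X) + eye[None, :, :]
        XtWz = np.einsum("gn,ni,gn->gi", w, X, z)
        beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        # step-halving guard against divergence of the working update
        idx = np.where(active)[0]
        step = beta_new - beta[idx]
        scale = np.ones((idx.size, 1))
        for _half in range(8):
            trial = beta[idx] + scale * step
            eta_t = trial @ X.T + offsets[None, :]
            with np.errstate(over="ignore"):
                mu_t = np.clip(np.exp(eta_t), 1e-10, 1e12)
            ll_t = nb_loglik(y[idx], mu_t, phi[idx])
            bad = ll_t < last[idx] - 1e-8
            if not np.any(bad):
                break
            scale[bad] /= 2.0
        beta[idx] = trial
        eta[idx] = eta_t
        mu[idx] = mu_t
        rel = np.abs(ll_t - last[idx]) / (np.abs(last[idx]) + 1.0)
        last[idx] = ll_t
        done = rel < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    # Cox-Reid adjustment at the final weights
    w = mu / (1.0 + phi[:, None] * mu)
    XtWX = np.einsum("gn,ni,nj->gij", w, X, X) + eye[None, :, :]
    sign, logdet = np.linalg.slogdet(XtWX)
    converged |= all_zero
    return GlmFit(
        coef=beta,
        mu=mu,
        loglik=nb_loglik(y, mu, phi),
        converged=converged,
        cr_adjustment=0.5 * logdet,
        all_zero=all_zero,
    )


# ---------------------------------------------------------------------------
# Dispersion estimation (Cox-Reid adjusted profile likelihood)


@dataclass
class DispersionModel:
    common_dispersion: float
    per_gene_dispersion: np.ndarray
    prior_df: float


def _apl(counts, design, offsets, phi) -> np.ndarray:
    fit = fit_nb_glm(counts, design, offsets, phi)
    return fit.loglik - fit.cr_adjustment


def estimate_dispersion(
    counts: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    prior_df: float = 10.0,
    grid_size: int = 21,
    span: tuple[float, float] = (1e-6, 10.0),
) -> DispersionModel:
    """Common + shrunken per-gene NB dispersions.

    The common dispersion maximizes the summed Cox-Reid APL over genes
    (golden-section search on log phi).  Per-gene dispersions maximize
    gene APL + prior_df x (mean APL per gene), evaluated on a log-spaced
    grid with quadratic refinement; genes with no information inherit the
    common value.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    G = counts.shape[0]
    lo, hi = np.log(span[0]), np.log(span[1])

    def total_apl(log_phi: float) -> float:
        return float(np.sum(_apl(counts, design, offsets, np.exp(log_phi))))

    # golden-section maximisation on log phi
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = total_apl(c), total_apl(d)
    for _ in range(40):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = total_apl(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = total_apl(d)
        if b - a < 1e-4:
            break
    common = float(np.exp((a + b) / 2.0))

    if prior_df == np.inf:
        return DispersionModel(common, np.full(G, common), prior_df)

    grid = np.exp(np.linspace(lo, hi, grid_size))
    apl_grid = np.column_stack([_apl(counts, design, offsets, g) for g in grid])  # (G, K)
    common_curve = apl_grid.mean(axis=0)  # per-gene-scale common APL
    objective = apl_grid + prior_df * common_curve[None, :]
    best = np.argmax(objective, axis=1)
    log_grid = np.log(grid)
    per_gene = np.empty(G)
    for g in range(G):
        k = best[g]
        if 0 < k < grid_size - 1:
            # quadratic interpolation on log phi
            x0, x1, x2 = log_grid[k - 1 : k + 2]
            y0, y1, y2 = objective[g, k - 1 : k + 2]
            denom = y0 - 2 * y1 + y2
            if denom < -1e-12:
                h = x1 - x0
                per_gene[g] = np.exp(x1 + 0.5 * h * (y0 - y2) / denom)
            else:
                per_gene[g] = grid[k]
        else:
            per_gene[g] = grid[k]
    no_info = counts.sum(axis=1) == 0
    per_gene[no_info] = common
    return DispersionModel(common, per_gene, prior_df)


# ---------------------------------------------------------------------------
# Likelihood-ratio DE testing


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-equivariant)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def lrt_de(
    counts: np.ndarray,
    gene_ids: list[str],
    design_full: np.ndarray,
    design_reduced: np.ndarray,
    offsets: np.ndarray,
    dispersion: np.ndarray,
    lfc_coef: int,
    contrast: str,
    mean_log_cpm: np.ndarray,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene likelihood-ratio test of a nested design pair.

    ``design_reduced`` columns must be a subset of ``design_full``'s span
    (checked by rank); ``lfc_coef`` names the full-design column whose
    natural-log coefficient is reported as log2 fold change.
    """
    p_full = np.linalg.matrix_rank(design_full)
    combined = np.hstack([design_full, design_reduced])
    if np.linalg.matrix_rank(combined) > p_full:
        raise ValueError("reduced design is not nested in the full design")
    p_red = np.linalg.matrix_rank(design_reduced)
    df = p_full - p_red
    if df <= 0:
        raise ValueError("reduced design must drop at least one degree of freedom")
    full = fit_nb_glm(counts, design_full, offsets, dispersion)
    red = fit_nb_glm(counts, design_reduced, offsets, dispersion)
    lr = np.maximum(2.0 * (full.loglik - red.loglik), 0.0)
    pvals = stats.chi2.sf(lr, df)
    pvals[full.all_zero] = 1.0
    qvals = bh_fdr(pvals)
    log2fc = full.coef[:, lfc_coef] / LN2
    log2fc[full.all_zero] = 0.0
    significant = qvals < fdr_threshold
    strong = significant & (np.abs(log2fc) >= lfc_threshold)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "contrast": contrast,
            "log2fc": log2fc,
            "mean_log_cpm": mean_log_cpm,
            "lr_statistic": lr,
            "p_value": pvals,
            "fdr": qvals,
            "significant": significant,
            "strong": strong,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
            "converged": full.converged & red.converged,
        }
    )


# ---------------------------------------------------------------------------
# MDS and correlation structure


def mds_coordinates(
    log_expr: np.ndarray, top_genes: int = 500, n_dim: int = 2
) -> np.ndarray:
    """Classical MDS of samples on leading-log-fold-change distances.

    The distance between two samples is the root mean square of their
    ``top_genes`` largest absolute log-expression differences.  Axes are
    oriented so the first sample has non-negative coordinates.
    """
    n = log_expr.shape[1]
    if n < 3:
        raise ValueError("MDS needs at least 3 samples")
    top = min(top_genes, log_expr.shape[0])
    D2 = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        diff = np.abs(log_expr[:, i] - log_expr[:, j])
        sel = np.partition(diff, diff.size - top)[diff.size - top :]
        D2[i, j] = D2[j, i] = np.mean(sel**2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:n_dim]
    lam = np.maximum(evals[order], 0.0)
    coords = evecs[:, order] * np.sqrt(lam)[None, :]
    for k in range(coords.shape[1]):
        if coords[0, k] < 0:
            coords[:, k] *= -1
    return coords


def correlation_matrix(
    matrix: CountMatrix,
    samples_of_tissue: dict[str, list[str]],
    tissues: list[str] | None = None,
    min_cpm: float = 1.0,
    min_antisense_reads: int = 10,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Cross-tissue Spearman structure of sense and antisense expression.

    Layout follows the field's two-triangle convention: below the diagonal
    the Spearman correlation of tissue-mean sense profiles (genes with
    mean CPM > ``min_cpm`` in at least one tissue); above the diagonal the
    same for antisense profiles (mean CPM > ``min_cpm`` with at least
    ``min_antisense_reads`` pooled reads in some tissue); on the diagonal
    the within-tissue sense-vs-antisense correlation over the antisense
    gene set.  With ``per_sample`` profiles are per-sample and averaged
    after correlating.
    """
    if tissues is None:
        tissues = list(samples_of_tissue)
    sense_cpm = cpm(matrix, SENSE, use_norm_factors=True)
    anti_cpm = cpm(matrix, ANTISENSE, use_norm_factors=True)
    cols = {t: [matrix.sample_index(s) for s in samples_of_tissue[t]] for t in tissues}
    sense_prof = {t: sense_cpm[:, cols[t]].mean(axis=1) for t in tissues}
    anti_prof = {t: anti_cpm[:, cols[t]].mean(axis=1) for t in tissues}
    anti_reads = {t: matrix.antisense[:, cols[t]].sum(axis=1) for t in tissues}
    sense_set = np.zeros(len(matrix.gene_ids), dtype=bool)
    anti_set = np.zeros_like(sense_set)
    for t in tissues:
        sense_set |= sense_prof[t] > min_cpm
        anti_set |= (anti_prof[t] > min_cpm) & (anti_reads[t] >= min_antisense_reads)

    def rho(x, y, sel):
        if sel.sum() < 3:
            return np.nan
        return stats.spearmanr(x[sel], y[sel]).statistic

    out = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    for i, ti in enumerate(tissues):
        for j, tj in enumerate(tissues):
            if i > j:  # below diagonal: sense
                if per_sample:
                    vals = [
                        rho(sense_cpm[:, a], sense_cpm[:, b], sense_set)
                        for a in cols[ti]
                        for b in cols[tj]
                    ]
                    out.iloc[i, j] = float(np.nanmean(vals))
                else:
                    out.iloc[i, j] = rho(sense_prof[ti], sense_prof[tj], sense_set)
            elif i < j:  # above diagonal: antisense
                if per_sample:
                    vals = [
                        rho(anti_cpm[:, a], anti_cpm[:, b], anti_set)
                        for a in cols[ti]
                        for b in cols[tj]
                    ]
                    out.iloc[i, j] = float(np.nanmean(vals))
                else:
                    out.iloc[i, j] = rho(anti_prof[ti], anti_prof[tj], anti_set)
            else:  # diagonal: sense vs antisense within tissue
                out.iloc[i, j] = rho(sense_prof[ti], anti_prof[ti], anti_set)
    return out


# ---------------------------------------------------------------------------
# Model / Results facade


def build_design(
    samples: list[SampleMeta], tissues: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + tissue + animal dummy design (first levels as baseline)."""
    animals = sorted({s.animal_id for s in samples})
    cols = ["intercept"] + [f"tissue[{t}]" for t in tissues[1:]] + [
        f"animal[{a}]" for a in animals[1:]
    ]
    X = np.zeros((len(samples), len(cols)))
    X[:, 0] = 1.0
    for r, s in enumerate(samples):
        if s.tissue != tissues[0]:
            X[r, 1 + tissues[1:].index(s.tissue)] = 1.0
        if s.animal_id != animals[0]:
            X[r, 1 + len(tissues) - 1 + animals[1:].index(s.animal_id)] = 1.0
    return X, cols


class DifferentialExpression:
    """Tissue-pair differential expression on a sense count matrix.

    Parameters
    ----------
    matrix : CountMatrix
        Gene x sample counts with library sizes (sense column sums).
    samples : list of SampleMeta
        One entry per matrix column, matching ``matrix.sample_ids``.
    tissues : list of str, optional
        The tissues entering the DE analysis (default: every tissue in the
        sample sheet, in first-appearance order).  All ordered pairs are
        tested.
    """

    def __init__(
        self,
        matrix: CountMatrix,
        samples: list[SampleMeta],
        tissues: list[str] | None = None,
        fdr_threshold: float = 0.05,
        lfc_threshold: float = 1.0,
        min_cpm: float = 1.0,
        min_animals: int = 2,
        prior_df: float = 10.0,
    ):
        by_id = {s.sample_id: s for s in samples}
        missing = [sid for sid in matrix.sample_ids if sid not in by_id]
        if missing:
            raise ValueError(f"samples missing from sheet: {missing}")
        self.matrix = matrix
        self.samples = [by_id[sid] for sid in matrix.sample_ids]
        seen: list[str] = []
        for s in self.samples:
            if s.tissue not in seen:
                seen.append(s.tissue)
        self.tissues = tissues if tissues is not None else seen
        self.fdr_threshold = fdr_threshold
        self.lfc_threshold = lfc_threshold
        self.min_cpm = min_cpm
        self.min_animals = min_animals
        self.prior_df = prior_df

    def fit(self) -> "DEResults":
        """TMM-normalise, estimate dispersion, and LRT-test every tissue pair."""
        m = self.matrix
        m.norm_factors = tmm_factors(m.sense, m.library_sizes)
        analysis_samples = [s for s in self.samples if s.tissue in self.tissues]
        samples_of_tissue = {
            t: [s.sample_id for s in analysis_samples if s.tissue == t] for t in self.tissues
        }
        flags, union = filter_expressed(
            m, SENSE, samples_of_tissue, min_cpm=self.min_cpm, min_animals=self.min_animals
        )
        keep = np.where(union)[0]
        cols = [m.sample_index(s.sample_id) for s in analysis_samples]
        counts = m.sense[np.ix_(keep, cols)]
        gene_ids = [m.gene_ids[i] for i in keep]
        offsets = np.log(m.library_sizes[cols] * m.norm_factors[cols])
        design, _ = build_design(analysis_samples, self.tissues)
        dispersion = estimate_dispersion(counts, design, offsets, prior_df=self.prior_df)
        logcpm = log2_cpm(m, SENSE)[np.ix_(keep, cols)]

        tables: dict[tuple[str, str], pd.DataFrame] = {}
        for t_a, t_b in itertools.combinations(self.tissues, 2):
            sel = [i for i, s in enumerate(analysis_samples) if s.tissue in (t_a, t_b)]
            sub = [analysis_samples[i] for i in sel]
            X_full, _ = build_design(sub, [t_b, t_a])  # coef 1 = t_a vs t_b
            X_red = np.delete(X_full, 1, axis=1)
            tables[(t_a, t_b)] = lrt_de(
                counts[:, sel],
                gene_ids,
                X_full,
                X_red,
                offsets[sel],
                dispersion.per_gene_dispersion,
                lfc_coef=1,
                contrast=f"{t_a}_vs_{t_b}",
                mean_log_cpm=logcpm[:, sel].mean(axis=1),
                fdr_threshold=self.fdr_threshold,
                lfc_threshold=self.lfc_threshold,
            )
        return DEResults(self, dispersion, flags, union, gene_ids, tables)


@dataclass
class DEResults:
    """Fitted differential-expression results for every tissue pair."""

    model: DifferentialExpression
    dispersion: DispersionModel
    expressed_flags: dict[str, np.ndarray]
    expressed_union: np.ndarray
    tested_genes: list[str] = field(default_factory=list)
    tables: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def table(self, tissue_a: str, tissue_b: str) -> pd.DataFrame:
        return self.tables[(tissue_a, tissue_b)]

    def de_counts(self) -> pd.DataFrame:
        """Per contrast: DE gene tallies at FDR and FDR+|log2FC| thresholds."""
        rows = []
        for (t_a, t_b), tab in self.tables.items():
            sig = tab[tab.significant]
            strong = tab[tab.strong]
            rows.append(
                {
                    "contrast": f"{t_a} vs {t_b}",
                    "de": len(sig),
                    "over": int((sig.log2fc > 0).sum()),
                    "under": int((sig.log2fc < 0).sum()),
                    "de_strong": len(strong),
                    "over_strong": int((strong.log2fc > 0).sum()),
                    "under_strong": int((strong.log2fc < 0).sum()),
                }
            )
        return pd.DataFrame(rows)

    def mds(self, layer: str = SENSE, top_genes: int = 500) -> pd.DataFrame:
        logcpm = log2_cpm(self.model.matrix, layer)
        coords = mds_coordinates(logcpm, top_genes=top_genes)
        return pd.DataFrame(
            coords, index=self.model.matrix.sample_ids, columns=["dim1", "dim2"]
        )

    def correlation_matrix(self, tissues: list[str] | None = None, **kw) -> pd.DataFrame:
        samples_of_tissue: dict[str, list[str]] = {}
        for s in self.model.samples:
            samples_of_tissue.setdefault(s.tissue, []).append(s.sample_id)
        return correlation_matrix(self.model.matrix, samples_of_tissue, tissues, **kw)

    def smear(self, tissue_a: str, tissue_b: str) -> pd.DataFrame:
        tab = self.table(tissue_a, tissue_b)
        return tab[["gene_id", "mean_log_cpm", "log2fc", "significant", "strong"]]

    def summary(self) -> str:
        lines = [
            "Differential expression (NB GLM, tissue + individual, LRT)",
            f"  tissues: {', '.join(self.model.tissues)}",
            f"  genes tested (expressed union): {len(self.tested_genes)}",
            f"  common dispersion: {self.dispersion.common_dispersion:.4g}",
            f"  thresholds: FDR < {self.model.fdr_threshold}, "
            f"|log2FC| >= {self.model.lfc_threshold}",
            "",
            self.de_counts().to_string(index=False),
        ]
        return "\n".join(lines)
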