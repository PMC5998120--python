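"""Summary report: the four result-table analogues plus MDS/smear plots.

Every number in the report is recomputed from the stage TSVs it cites, so
the document is reproducible from the run directory alone.  When truth
tables from the simulator are present a recovery appendix compares
estimates against the simulated truth.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from galtase import io as io_mod
from galtase import quantify as quant_mod
from galtase.quantify import ANTISENSE, SENSE


def _expression_overview(outdir: Path) -> pd.DataFrame:
    """Per tissue: expressed / antisense gene tallies and 50%-mass counts."""
    qdir = outdir / "quantify"
    sense = pd.read_csv(qdir / "counts_sense.tsv", sep="\t", index_col=0)
    anti = pd.read_csv(qdir / "counts_antisense.tsv", sep="\t", index_col=0)
    sflags = pd.read_csv(qdir / "expressed_flags_sense.tsv", sep="\t", index_col=0)
    aflags = pd.read_csv(qdir / "expressed_flags_antisense.tsv", sep="\t", index_col=0)
    samples = io_mod.read_sample_sheet(outdir / "sim" / "sample_sheet.tsv")
    matrix = quant_mod.CountMatrix(
        gene_ids=list(sense.index),
        sample_ids=list(sense.columns),
        sense=sense.to_numpy(),
        antisense=anti.to_numpy(),
        library_sizes=sense.to_numpy().sum(axis=0).astype(float),
    )
    tissues = []
    for s in samples:
        if s.tissue not in tissues:
            tissues.append(s.tissue)
    rows = []
    for t in tissues:
        cols = [matrix.sample_index(s.sample_id) for s in samples if s.tissue == t]
        expressed = sflags[t].to_numpy()
        with_anti = aflags[t].to_numpy()
        rows.append(
            {
                "tissue": t,
                "expressed_genes": int(expressed.sum()),
                "genes_half_sense_reads": quant_mod.top_mass_genes(matrix, SENSE, cols),
                "antisense_genes": int(with_anti.sum()),
                "genes_half_antisense_reads": quant_mod.top_mass_genes(matrix, ANTISENSE, cols),
                "both_sense_and_antisense": int((expressed & with_anti).sum()),
                "antisense_only": int((~expressed & with_anti).sum()),
            }
        )
    return pd.DataFrame(rows)


def _plot_mds(outdir: Path, rdir: Path) -> list[str]:
    written = []
    samples = io_mod.read_sample_sheet(outdir / "sim" / "sample_sheet.tsv")
    tissue_of = {s.sample_id: s.tissue for s in samples}
    for layer in (SENSE, ANTISENSE):
        path = outdir / "de" / f"mds_coords_{layer}.tsv"
        if not path.exists():
            continue
        coords = pd.read_csv(path, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(5, 4))
        tissues = sorted({tissue_of[s] for s in coords.index})
        for t in tissues:
            sel = [s for s in coords.index if tissue_of[s] == t]
            ax.scatter(coords.loc[sel, "dim1"], coords.loc[sel, "dim2"], label=t)
        ax.set_xlabel("dim 1")
        ax.set_ylabel("dim 2")
        ax.set_title(f"MDS ({layer})")
        ax.legend(fontsize=8)
        fig.tight_layout()
        for ext in ("png", "svg"):
            fig.savefig(rdir / f"mds_{layer}.{ext}")
            written.append(f"mds_{layer}.{ext}")
        plt.close(fig)
    return written


def _plot_smears(outdir: Path, rdir: Path) -> list[str]:
    written = []
    for path in sorted((outdir / "de").glob("smear_*.tsv")):
        tab = pd.read_csv(path, sep="\t")
        contrast = path.stem.replace("smear_", "")
        fig, ax = plt.subplots(figsize=(5, 4))
        bg = ~tab.significant
        ax.scatter(tab.mean_log_cpm[bg], tab.log2fc[bg], s=4, c="grey", alpha=0.5)
        ax.scatter(
            tab.mean_log_cpm[tab.significant], tab.log2fc[tab.significant], s=6, c="red"
        )
        ax.axhline(0.0, lw=0.6, c="black")
        ax.set_xlabel("mean log2 CPM")
        ax.set_ylabel("log2 fold change")
        ax.set_title(contrast)
        fig.tight_layout()
        for ext in ("png", "svg"):
            fig.savefig(rdir / f"smear_{contrast}.{ext}")
            written.append(f"smear_{contrast}.{ext}")
        plt.close(fig)
    return written


def _recovery_appendix(outdir: Path) -> list[str]:
    from scipy.stats import spearmanr

    lines: list[str] = []
    truth_counts = outdir / "sim" / "truth_counts_sense.tsv"
    if not truth_counts.exists():
        return lines
    truth = pd.read_csv(truth_counts, sep="\t", index_col=0)
    est = pd.read_csv(outdir / "quantify" / "counts_sense.tsv", sep="\t", index_col=0)
    common = truth.index.intersection(est.index)
    rhos = [
        spearmanr(truth.loc[common, c], est.loc[common, c]).statistic for c in truth.columns
    ]
    lines.append(
        f"- Spearman(truth realized counts, recovered sense counts): "
        f"median {np.median(rhos):.4f} across {len(rhos)} samples"
    )
    truth_sites = outdir / "sim" / "truth_sites.tsv"
    geno_vcf = outdir / "ase" / "genotypes.vcf"
    if truth_sites.exists() and geno_vcf.exists():
        tdf = pd.read_csv(truth_sites, sep="\t")
        sites, animals, gts = io_mod.read_vcf(geno_vcf)
        gt_label = {"0/0": "homRef", "0/1": "het", "1/1": "homAlt", "./.": "no_call"}
        truth_by_pos = tdf.set_index("pos")
        n_ok = n_called = 0
        for a in animals:
            if a not in truth_by_pos.columns:
                continue
            for site, gt in zip(sites, gts[a]):
                label = gt_label.get(gt, "no_call")
                if label == "no_call" or site.pos not in truth_by_pos.index:
                    continue
                n_called += 1
                n_ok += label == truth_by_pos.loc[site.pos, a]
        if n_called:
            lines.append(
                f"- Genotype call accuracy vs truth: {n_ok / n_called:.4f} "
                f"({n_ok}/{n_called} called genotypes)"
            )
    return lines


def render_report(outdir: Path) -> Path:
    outdir = Path(outdir)
    rdir = outdir / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    overview = _expression_overview(outdir)
    overview.to_csv(rdir / "table_expression_overview.tsv", sep="\t", index=False)
    corr = pd.read_csv(outdir / "de" / "correlation_matrix.tsv", sep="\t", index_col=0)
    corr.to_csv(rdir / "table_correlations.tsv", sep="\t")
    de_counts = pd.read_csv(outdir / "de" / "de_counts.tsv", sep="\t")
    de_counts.to_csv(rdir / "table_de_counts.tsv", sep="\t", index=False)
    ase_path = outdir / "ase" / "ase_summary.tsv"
    if ase_path.exists():
        ase_summary = pd.read_csv(ase_path, sep="\t")
    else:
        ase_summary = pd.DataFrame(
            columns=[
                "tissue", "het_snps_tested", "genes_tested", "ase_snps",
                "consistent_ase_snps", "ase_genes", "ase_genes_multi_snp",
            ]
        )
    ase_summary.to_csv(rdir / "table_ase_summary.tsv", sep="\t", index=False)
    plots = _plot_mds(outdir, rdir) + _plot_smears(outdir, rdir)
    recovery = _recovery_appendix(outdir)

    md = ["# Run report", ""]
    md += ["## Expression overview (per tissue)", "", overview.to_markdown(index=False), ""]
    md += [
        "## Cross-tissue Spearman structure",
        "",
        "Sense below the diagonal, antisense above, sense-vs-antisense on it.",
        "",
        corr.round(3).to_markdown(),
        "",
    ]
    md += ["## Differential expression between tissue pairs", "", de_counts.to_markdown(index=False), ""]
    md += ["## Allele-specific expression summary", ""]
    md += [ase_summary.to_markdown(index=False) if len(ase_summary) else "(no ASE results)", ""]
    if plots:
        md += ["## Plots", ""] + [f"- {p}" for p in plots] + [""]
    if recovery:
        md += ["## Truth recovery (simulated data)", ""] + recovery + [""]
    (rdir / "report.md").write_text("\n".join(md))
    return rdir
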