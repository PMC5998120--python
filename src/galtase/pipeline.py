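"""Stage drivers: simulate -> quantify -> de -> ase -> report.

Each stage reads the previous stage's text outputs from the run directory
and writes its own under a stage subdirectory, plus a manifest recording
the configuration hash and seed so reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from galtase import ase as ase_mod
from galtase import de as de_mod
from galtase import io as io_mod
from galtase import quantify as quant_mod
from galtase import simulate as sim_mod
from galtase.quantify import ANTISENSE, SENSE


class MissingUpstream(RuntimeError):
    """A stage was invoked before the stage it depends on."""


DEFAULT_CONFIG = {
    "seed": None,  # required
    "simulate": {},
    "quantify": {"protocol": "reverse", "min_cpm": 1.0, "min_animals": 2, "window_size": 10000},
    "de": {"fdr": 0.05, "lfc": 1.0, "tissues": None, "prior_df": 10.0},
    "ase": {
        "min_base_quality_discovery": 10,
        "min_coverage": 10,
        "min_minor_count": 3,
        "min_depth": 10,
        "min_mapq": 10,
        "min_base_quality": 2,
        "min_pooled_coverage": 5,
        "call_threshold": 0.99,
        "min_test_reads": 10,
        "fdr": 0.05,
        "gene_window": 5000,
    },
}


def load_config(config: dict | str | Path) -> dict:
    if not isinstance(config, dict):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in config.items():
        if isinstance(value, dict) and key in merged:
            merged[key].update(value)
        else:
            merged[key] = value
    if merged.get("seed") is None:
        raise ValueError("config must set an explicit seed")
    return merged


def write_manifest(outdir: Path, stage: str, config: dict) -> None:
    from galtase import __version__

    blob = json.dumps(config, sort_keys=True).encode()
    manifest = {
        "stage": stage,
        "seed": config["seed"],
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "version": __version__,
        "decisions": [
            "sense-priority overlap resolution; multi-mappers discarded via NH",
            "CPM denominator = sense library for both layers",
            "expressed filter evaluated within tissue",
            "BH family: per contrast (DE); per tissue over (animal, site) tests (ASE)",
            "5 kb gene window inclusive at the boundary",
        ],
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingUpstream(
            f"missing {path.name}: run the '{stage}' stage first"
        )
    return path


def run_simulate(config: dict, outdir: Path) -> Path:
    outdir = Path(outdir)
    sim_dir = outdir / "sim"
    sim_cfg = sim_mod.SimulationConfig(seed=config["seed"], **config.get("simulate", {}))
    sim_mod.simulate_dataset(sim_cfg, sim_dir)
    write_manifest(outdir, "simulate", config)
    return sim_dir


def run_quantify(config: dict, outdir: Path) -> Path:
    outdir = Path(outdir)
    sim_dir = outdir / "sim"
    _require(sim_dir / "genes.gff3", "simulate")
    opts = config["quantify"]
    genes = io_mod.read_gene_models(sim_dir / "genes.gff3")
    samples = io_mod.read_sample_sheet(_require(sim_dir / "sample_sheet.tsv", "simulate"))
    streams = {}
    for s in samples:
        sam = sim_dir / f"{s.sample_id}.sam"
        if not sam.exists():
            raise MissingUpstream(f"sample {s.sample_id} has no SAM; run 'simulate' first")
        streams[s.sample_id] = io_mod.read_alignments(sam)
    window = opts["window_size"]
    pooled: dict[str, dict] = {"+": {}, "-": {}}

    def track_read(_sample: str, read) -> None:
        if read.hit_count > 1:
            return
        w = read.blocks[0][0] // window
        key = (read.chrom, w * window, (w + 1) * window)
        strand = pooled[read.align_strand]
        strand[key] = strand.get(key, 0) + 1

    matrix, stats = quant_mod.count_samples(
        streams, genes, protocol=opts["protocol"], on_read=track_read
    )
    qdir = outdir / "quantify"
    qdir.mkdir(parents=True, exist_ok=True)
    gene_ids = matrix.gene_ids
    pd.DataFrame(matrix.sense, index=gene_ids, columns=matrix.sample_ids).to_csv(
        qdir / "counts_sense.tsv", sep="\t", index_label="gene_id"
    )
    pd.DataFrame(matrix.antisense, index=gene_ids, columns=matrix.sample_ids).to_csv(
        qdir / "counts_antisense.tsv", sep="\t", index_label="gene_id"
    )
    io_mod.write_table(
        [{"sample": s, **log} for s, log in stats.items()],
        qdir / "assignment_stats.tsv",
    )
    samples_of_tissue: dict[str, list[str]] = {}
    for s in samples:
        samples_of_tissue.setdefault(s.tissue, []).append(s.sample_id)
    flag_frames = {}
    for layer in (SENSE, ANTISENSE):
        flags, union = quant_mod.filter_expressed(
            matrix, layer, samples_of_tissue,
            min_cpm=opts["min_cpm"], min_animals=opts["min_animals"],
        )
        df = pd.DataFrame(flags, index=gene_ids)
        df["union"] = union
        flag_frames[layer] = df
        df.to_csv(qdir / f"expressed_flags_{layer}.tsv", sep="\t", index_label="gene_id")
    tracks_dir = qdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for strand, name in (("+", "plus"), ("-", "minus")):
        io_mod.write_bedgraph(
            [(c, s, e, v) for (c, s, e), v in sorted(pooled[strand].items())],
            tracks_dir / f"{name}.bedGraph",
            name=f"reads_{name}",
        )
    write_manifest(outdir, "quantify", config)
    return qdir


def _load_matrix(outdir: Path) -> tuple[quant_mod.CountMatrix, list[io_mod.SampleMeta]]:
    qdir = outdir / "quantify"
    sense = pd.read_csv(_require(qdir / "counts_sense.tsv", "quantify"), sep="\t", index_col=0)
    anti = pd.read_csv(qdir / "counts_antisense.tsv", sep="\t", index_col=0)
    samples = io_mod.read_sample_sheet(outdir / "sim" / "sample_sheet.tsv")
    matrix = quant_mod.CountMatrix(
        gene_ids=list(sense.index),
        sample_ids=list(sense.columns),
        sense=sense.to_numpy(),
        antisense=anti.to_numpy(),
        library_sizes=sense.to_numpy().sum(axis=0).astype(float),
    )
    return matrix, samples


def run_de(config: dict, outdir: Path) -> Path:
    outdir = Path(outdir)
    opts = config["de"]
    matrix, samples = _load_matrix(outdir)
    tissues_present = []
    for s in samples:
        if s.tissue not in tissues_present:
            tissues_present.append(s.tissue)
    tissues = opts.get("tissues")
    if tissues is None:
        galt = [t for t in tissues_present if t != "PB"]
        tissues = galt if len(galt) >= 2 else tissues_present
    model = de_mod.DifferentialExpression(
        matrix, samples, tissues=tissues,
        fdr_threshold=opts["fdr"], lfc_threshold=opts["lfc"], prior_df=opts["prior_df"],
    )
    results = model.fit()
    ddir = outdir / "de"
    ddir.mkdir(parents=True, exist_ok=True)
    io_mod.write_table(
        [
            {"sample": sid, "library_size": int(ls), "norm_factor": f"{nf:.6f}"}
            for sid, ls, nf in zip(matrix.sample_ids, matrix.library_sizes, matrix.norm_factors)
        ],
        ddir / "norm_factors.tsv",
    )
    for (t_a, t_b), tab in results.tables.items():
        tab.to_csv(ddir / f"de_{t_a}_vs_{t_b}.tsv", sep="\t", index=False)
        results.smear(t_a, t_b).to_csv(ddir / f"smear_{t_a}_vs_{t_b}.tsv", sep="\t", index=False)
    for layer in (SENSE, ANTISENSE):
        results.mds(layer).to_csv(ddir / f"mds_coords_{layer}.tsv", sep="\t", index_label="sample")
    results.correlation_matrix(tissues=tissues_present).to_csv(
        ddir / "correlation_matrix.tsv", sep="\t", index_label="tissue"
    )
    results.de_counts().to_csv(ddir / "de_counts.tsv", sep="\t", index=False)
    (ddir / "dispersion.txt").write_text(
        f"common_dispersion\t{results.dispersion.common_dispersion:.6g}\n"
        f"prior_df\t{results.dispersion.prior_df}\n"
    )
    write_manifest(outdir, "de", config)
    return ddir


def run_ase(config: dict, outdir: Path) -> Path:
    outdir = Path(outdir)
    sim_dir = outdir / "sim"
    opts = config["ase"]
    reference = io_mod.read_fasta(_require(sim_dir / "genome.fasta", "simulate"))
    genes = io_mod.read_gene_models(sim_dir / "genes.gff3")
    samples = io_mod.read_sample_sheet(sim_dir / "sample_sheet.tsv")
    sam_paths = [sim_dir / f"{s.sample_id}.sam" for s in samples]
    for p in sam_paths:
        _require(p, "simulate")
    adir = outdir / "ase"
    adir.mkdir(parents=True, exist_ok=True)

    sites = ase_mod.discover_sites(
        sam_paths, reference,
        min_base_quality=opts["min_base_quality_discovery"],
        min_coverage=opts["min_coverage"],
        min_minor_count=opts["min_minor_count"],
    )
    io_mod.write_vcf(sites, adir / "sites.vcf", contigs=[(n, len(s)) for n, s in reference.items()])
    masked = ase_mod.mask_reference(reference, sites)
    io_mod.write_fasta(masked, adir / "masked_genome.fasta")

    counts_by_sample = {}
    for s, path in zip(samples, sam_paths):
        counts_by_sample[s.sample_id] = ase_mod.count_alleles_pileup(
            path,
            sites,
            s.sample_id,
            min_depth=opts["min_depth"],
            min_mapq=opts["min_mapq"],
            min_base_quality=opts["min_base_quality"],
        )
    io_mod.write_table(
        [
            {
                "sample": c.sample_id, "chrom": c.site.chrom, "pos": c.site.pos,
                "ref": c.site.ref_allele, "alt": c.site.alt_allele,
                "ref_count": c.ref_count, "alt_count": c.alt_count,
                "other_count": c.other_count,
            }
            for counts in counts_by_sample.values()
            for c in counts
        ],
        adir / "allelic_counts.tsv",
        columns=["sample", "chrom", "pos", "ref", "alt", "ref_count", "alt_count", "other_count"],
    )

    expressed: dict[str, set[str]] | None = None
    flags_path = outdir / "quantify" / "expressed_flags_sense.tsv"
    if flags_path.exists():
        df = pd.read_csv(flags_path, sep="\t", index_col=0)
        expressed = {
            t: set(df.index[df[t]]) for t in df.columns if t != "union"
        }
    model = ase_mod.AseAnalysis(
        counts_by_sample,
        {s.sample_id: (s.animal_id, s.tissue) for s in samples},
        genes=genes,
        expressed_genes=expressed,
        min_pooled_coverage=opts["min_pooled_coverage"],
        call_threshold=opts["call_threshold"],
        min_test_reads=opts["min_test_reads"],
        fdr_threshold=opts["fdr"],
        gene_window=opts["gene_window"],
    )
    results = model.fit()

    animals = sorted(results.genotypes)
    gt_str = {"homRef": "0/0", "het": "0/1", "homAlt": "1/1", "no_call": "./."}
    io_mod.write_vcf(
        sites,
        adir / "genotypes.vcf",
        samples=animals,
        genotypes={
            a: [
                gt_str[results.genotypes[a][s].call] if s in results.genotypes[a] else "./."
                for s in sites
            ]
            for a in animals
        },
        posteriors={
            a: [
                results.genotypes[a][s].posterior
                if s in results.genotypes[a]
                else (np.nan, np.nan, np.nan)
                for s in sites
            ]
            for a in animals
        },
        contigs=[(n, len(s)) for n, s in reference.items()],
    )
    frame = results.records_frame()
    for tissue, sub in frame.groupby("tissue"):
        sub.to_csv(adir / f"ase_records_{tissue}.tsv", sep="\t", index=False)
    results.ase_summary.per_tissue.to_csv(adir / "ase_summary.tsv", sep="\t", index=False)
    n_tested = len({(r.site, r.animal_id) for r in results.records})
    funnel = {
        "sites_discovered": len(sites),
        "sites_with_counts": len({c.site for cc in counts_by_sample.values() for c in cc}),
        "het_calls": int(
            sum(1 for a in animals for c in results.genotypes[a].values() if c.call == "het")
        ),
        "animal_site_tests": n_tested,
        "tests": len(results.records),
        "significant": int(sum(r.significant for r in results.records)),
        "error_rates": {a: round(e, 5) for a, e in results.error_rates.items()},
        "shared_ase_genes": len(results.ase_summary.shared_ase_genes),
        "tissue_specific_ase_genes": {
            t: len(v) for t, v in results.ase_summary.tissue_specific_ase_genes.items()
        },
    }
    (adir / "funnel.json").write_text(json.dumps(funnel, indent=2) + "\n")
    write_manifest(outdir, "ase", config)
    return adir


def run_report(config: dict, outdir: Path) -> Path:
    from galtase import report as report_mod

    outdir = Path(outdir)
    _require(outdir / "quantify" / "counts_sense.tsv", "quantify")
    _require(outdir / "de" / "de_counts.tsv", "de")
    rdir = report_mod.render_report(outdir)
    write_manifest(outdir, "report", config)
    return rdir


STAGES = {
    "simulate": run_simulate,
    "quantify": run_quantify,
    "de": run_de,
    "ase": run_ase,
    "report": run_report,
}


def run_all(config: dict, outdir: Path) -> None:
    for stage in ("simulate", "quantify", "de", "ase", "report"):
        STAGES[stage](config, Path(outdir))
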