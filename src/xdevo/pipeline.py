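"""End-to-end orchestration: simulate -> normalise -> DE -> cluster ->
integrate -> conservation, as one seeded, logged, byte-reproducible run.

A single global seed is expanded into named per-stage substreams
(``SeedSequence([seed, stage_index])``) so any stage can be re-run in
isolation with identical randomness.  All artifacts are plain text (TSV,
Newick, JSON); figures are produced separately by :func:`report` so the
computational outputs stay byte-comparable.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossspecies, io, normalize
from .cluster import DEFAULT_SCALES, kmeans_profiles, multiscale_bootstrap_support
from .diffexp import intensity_difference_filter
from .errors import ConfigError, DataError
from .simulate import SimulationConfig, generate_timecourse_pair, write_simulation

log = logging.getLogger(__name__)

_STAGES = ("simulate", "de_a", "de_b", "kmeans", "bootstrap")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (below 2**31)."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything a full run needs; YAML-serialisable."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    pseudocount: float = 1.0
    background_quantile: float = 0.05
    de_alpha: float = 0.05
    de_window_fraction: float = 0.01
    de_mode: str = "pairwise"
    kmeans_k: int = 4
    scales: tuple[float, ...] = DEFAULT_SCALES
    n_boot: int = 200
    loading_component: int = 2
    loading_threshold: float = 0.04
    conservation_thresholds: tuple[float, float] = (0.8, 0.9)
    seed: int = 0

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: run config must be a mapping")
        sim_raw = raw.pop("sim", {})
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        try:
            sim = SimulationConfig(**sim_raw)
            cfg = RunConfig(sim=sim, **raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = [float(s) for s in self.scales]
        d["conservation_thresholds"] = [float(t) for t in self.conservation_thresholds]
        d["sim"]["fractions"] = {k: float(v) for k, v in self.sim.fractions.items()}
        d["sim"]["baseline_range"] = [float(v) for v in self.sim.baseline_range]
        return d


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full analysis; returns the summary dict (also written
    to ``summary.json``).  Any stage error aborts with the stage named."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    def _stage(name):
        log.info("pipeline stage: %s", name)
        return name

    stage = _stage("simulate")
    try:
        sim_cfg = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
        mat_a, mat_b, omap, truth = generate_timecourse_pair(sim_cfg)
        write_simulation(outdir, mat_a, mat_b, omap, truth)
        summary["n_genes_a"] = mat_a.n_genes
        summary["n_genes_b"] = mat_b.n_genes
        summary["n_ortholog_pairs_input"] = len(omap)

        stage = _stage("normalize")
        norm = {}
        for tag, mat in (("a", mat_a), ("b", mat_b)):
            logm = normalize.log_transform(mat, config.pseudocount)
            logm = normalize.background_correct(logm, config.background_quantile)
            logm = normalize.center_samples(logm)
            centered = normalize.center_genes_by_species(logm)
            norm[tag] = {"log": logm, "centered": centered}
            io.write_expression_tsv(
                logm,
                outdir / f"{tag}_norm.tsv",
                header=f"stage=normalize steps=log,background,center-samples "
                f"pseudocount={config.pseudocount} quantile={config.background_quantile}",
            )
            io.write_expression_tsv(
                centered, outdir / f"{tag}_centered.tsv", header="stage=normalize steps=+center-genes"
            )

        stage = _stage("diffexp")
        de = {}
        de_phase = {}
        for tag in ("a", "b"):
            logm = norm[tag]["log"]
            res = intensity_difference_filter(
                logm,
                group_key="replicate_group",
                window_fraction=config.de_window_fraction,
                alpha=config.de_alpha,
                mode=config.de_mode,
            )
            de[tag] = res
            hdr = (
                f"stage=diffexp alpha={config.de_alpha} window={res.window} mode={res.mode}"
            )
            with (outdir / f"de_{tag}.tsv").open("w") as fh:
                fh.write(f"# {hdr}\n")
                res.table.to_csv(fh, sep="\t", index_label="gene_id")
            summary[f"n_de_{tag}"] = res.n_significant
            # phase-grouped screen feeding the conservation prefilter:
            # comparing developmental phases pools the sparse per-age
            # samples and matches the phase-averaged correlation step
            phases_sp = crossspecies.phases_by_rank(logm)
            phased = logm.with_values(logm.values)
            phased.meta["phase"] = [phases_sp[s] for s in phased.sample_ids]
            res_phase = intensity_difference_filter(
                phased,
                group_key="phase",
                window_fraction=config.de_window_fraction,
                alpha=config.de_alpha,
                mode=config.de_mode,
            )
            de_phase[tag] = res_phase
            summary[f"n_de_phase_{tag}"] = res_phase.n_significant

        stage = _stage("kmeans")
        de_genes_a = de["a"].significant_genes
        if len(de_genes_a) >= config.kmeans_k:
            km = kmeans_profiles(
                norm["a"]["centered"].subset_genes(de_genes_a),
                k=config.kmeans_k,
                seed=stage_seed(config.seed, "kmeans"),
            )
            km.labels.to_frame().to_csv(outdir / "kmeans_a.tsv", sep="\t", index_label="gene_id")
            summary["kmeans_cluster_sizes"] = {str(k): v for k, v in km.sizes().items()}
        else:
            log.warning("too few DE genes in species A for k=%d; skipping k-means", config.kmeans_k)
            summary["kmeans_cluster_sizes"] = {}

        stage = _stage("integrate")
        b_avg = normalize.average_replicates(norm["b"]["centered"])
        combined = crossspecies.combine_by_orthologs(norm["a"]["centered"], b_avg, omap)
        io.write_expression_tsv(
            combined, outdir / "combined.tsv", outdir / "combined_meta.tsv", header="stage=integrate"
        )
        summary["n_ortholog_pairs_used"] = combined.n_genes

        stage = _stage("pca")
        pres = crossspecies.pca(combined)
        pres.scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index_label="sample_id")
        pres.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t", index_label="gene_id")
        pd.DataFrame(
            {"component": pres.scores.columns, "variance_explained": pres.variance_explained}
        ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)
        summary["variance_explained_pc1"] = float(pres.variance_explained[0])
        summary["variance_explained_pc2"] = (
            float(pres.variance_explained[1]) if len(pres.variance_explained) > 1 else 0.0
        )
        retrieved = crossspecies.retrieve_pc_loading_genes(
            pres, component=config.loading_component, threshold=config.loading_threshold
        )
        pd.Series(retrieved, name="gene_id").to_csv(outdir / "pc_loading_genes.tsv", sep="\t", index=False)
        summary["n_pc_loading_genes"] = len(retrieved)

        stage = _stage("cluster_bootstrap")
        tree = multiscale_bootstrap_support(
            combined,
            axis="samples",
            scales=config.scales,
            n_boot=config.n_boot,
            seed=stage_seed(config.seed, "bootstrap"),
        )
        io.write_newick_annotated(tree, outdir / "samples_tree.nwk")
        clades = tree.clades()
        rows = []
        for k in sorted(clades):
            sup = tree.support[k]
            rows.append(
                {
                    "clade": ",".join(sorted(clades[k])),
                    "height": tree.heights()[k],
                    "bp": sup.bp,
                    "au": sup.au,
                    "v": sup.v,
                    "c": sup.c,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "clade_support.tsv", sep="\t", index=False)
        summary["n_clades"] = len(rows)

        stage = _stage("conservation")
        phases = crossspecies.phases_by_rank(combined)
        # "temporally differential" = flagged by either grouping: the phase
        # screen is powered for gradual trends, the per-age screen for
        # localised peaks
        cons = crossspecies.conservation_screen(
            combined,
            phases,
            de_a=set(de["a"].significant_genes) | set(de_phase["a"].significant_genes),
            de_b=set(de["b"].significant_genes) | set(de_phase["b"].significant_genes),
        )
        cons.to_csv(outdir / "conservation.tsv", sep="\t", index_label="pair_id")
        t_lo, t_hi = config.conservation_thresholds
        summary[f"n_conserved_{t_lo}"] = int(cons["conserved_call"].sum())
        summary[f"n_conserved_{t_hi}"] = int(cons["conserved_strict_call"].sum())
        summary["n_de_both_species"] = int(cons["de_both"].sum())
    except (ConfigError, DataError) as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (outdir / "params.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
    return summary


def report(outdir, figures: bool = True) -> Path:
    """Render ``report.md`` (plus illustrative figures) from a completed
    artifacts directory.  Regeneration is idempotent."""
    outdir = Path(outdir)
    summary_path = outdir / "summary.json"
    if not summary_path.exists():
        raise DataError(f"missing artifact {summary_path}; run the pipeline first")
    summary = json.loads(summary_path.read_text())
    lines = ["# xdevo run report", "", "## Summary", "", "| quantity | value |", "| --- | --- |"]
    for key in sorted(summary):
        lines.append(f"| {key} | {summary[key]} |")
    n_cons = summary.get("n_conserved_0.8", 0)
    lines += [
        "",
        f"Conserved temporal profiles (r > 0.8 among genes DE in both species): {n_cons}"
        + (" — no conserved genes detected." if n_cons == 0 else "."),
    ]
    if figures:
        try:
            _figures(outdir)
            lines += ["", "## Figures", "", "![PCA](figures/pca.png)", "![Dendrogram](figures/dendrogram.png)"]
        except Exception as exc:  # figures are illustrative only
            log.warning("figure generation failed: %s", exc)
    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path


def _figures(outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    scores = pd.read_csv(outdir / "pca_scores.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(outdir / "combined_meta.tsv", sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(5, 4))
    for species, marker in zip(meta["species"].unique(), "os^v"):
        sel = meta["species"] == species
        ax.scatter(scores.loc[sel.index[sel], "PC1"], scores.loc[sel.index[sel], "PC2"], label=species, marker=marker)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.savefig(figdir / "pca.png", dpi=100)
    plt.close(fig)

    tree = io.read_newick_annotated(outdir / "samples_tree.nwk")
    fig, ax = plt.subplots(figsize=(7, 4))
    dendrogram(tree.to_linkage(), labels=tree.leaves, ax=ax, leaf_rotation=90)
    fig.tight_layout()
    fig.savefig(figdir / "dendrogram.png", dpi=100)
    plt.close(fig)
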