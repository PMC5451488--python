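"""End-to-end orchestration: simulate-or-load, classify, alpha, beta,
network, richness null, taxa — with a reproducible artifact layout.

Every stage writes TSV/JSON artifacts into the output directory; a manifest
records each file with a SHA-256 checksum, the seed and a hash of the
configuration, so identical (config, seed) runs produce identical
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import network as net_mod
from . import nullmodel, taxa as taxa_mod
from .errors import AridnetError, ConfigurationError
from .io import Dataset, load_dataset, write_dataset
from .synthetic import GradientDesign, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run."""

    # input files; if None, a synthetic dataset is generated
    otu_table: str | None = None
    metadata: str | None = None
    tree: str | None = None
    taxonomy: str | None = None
    # synthetic design overrides (field name -> value)
    design: dict = field(default_factory=dict)
    # thresholds and depths
    min_reads: int = 16660
    beta_rarefaction_depth: int = 17212
    null_depth: int = 300
    null_reps: int = 500
    rare_otu_fraction: float = 1e-4
    q_cutoff: float = 0.01
    rmt_grid: tuple[float, float, float] = (0.50, 0.99, 0.01)
    fixed_threshold: float | None = None
    mantel_permutations: int = 9999
    anosim_permutations: int = 999
    alpha_rarefaction_depth: int | None = None
    best_max_variables: int = 12
    seed: int = 0
    out_dir: str = "aridnet_out"

    def rmt_grid_array(self) -> np.ndarray:
        lo, hi, step = self.rmt_grid
        if not (0 < lo < hi <= 1) or step <= 0:
            raise ConfigurationError("invalid rmt_grid")
        return np.round(np.arange(lo, hi + step / 2, step), 4)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # location must not change content
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("rmt_grid",):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path, header: str):
    with path.open("w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"aridnet seed={config.seed} config={config.config_hash()}"
    files: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "load"
        dataset, truth = _obtain_dataset(config, out, header, files)
        meta = dataset.metadata
        classes = meta["aridity_class"]

        stage = "alpha"
        adf = alpha_mod.alpha_diversity_table(
            dataset.table, dataset.tree,
            rarefy_depth=config.alpha_rarefaction_depth,
            seed=config.seed + 11)
        _write_tsv(adf, out / "alpha.tsv", header)
        files["alpha"] = out / "alpha.tsv"
        env_report, ttest = alpha_mod.alpha_env_report(adf, meta)
        _write_tsv(env_report, out / "alpha_env.tsv", header)
        files["alpha_env"] = out / "alpha_env.tsv"

        stage = "beta"
        rarefied = alpha_mod.rarefy(
            dataset.table,
            min(config.beta_rarefaction_depth,
                int(dataset.table.sample_totals().min())),
            seed=config.seed + 13)
        dm_u = beta_mod.unifrac(rarefied, dataset.tree, weighted=False)
        dm_w = beta_mod.unifrac(rarefied, dataset.tree, weighted=True)
        _write_tsv(dm_u.to_data_frame(), out / "unweighted_unifrac.tsv",
                   header)
        files["unweighted_unifrac"] = out / "unweighted_unifrac.tsv"
        _write_tsv(dm_w.to_data_frame(), out / "weighted_unifrac.tsv",
                   header)
        files["weighted_unifrac"] = out / "weighted_unifrac.tsv"
        ord_res = beta_mod.pcoa(dm_u)
        coords = ord_res.samples.iloc[:, :4]
        coords.index = list(dm_u.ids)
        _write_tsv(coords, out / "pcoa_coords.tsv", header)
        files["pcoa_coords"] = out / "pcoa_coords.tsv"

        meta_beta = meta.loc[list(dm_u.ids)]
        mantel_report, wu_r = beta_mod.env_mantel_report(
            dm_u, dm_w, meta_beta, n_perm=config.mantel_permutations,
            seed=config.seed + 17)
        _write_tsv(mantel_report, out / "mantel_report.tsv", header)
        files["mantel_report"] = out / "mantel_report.tsv"
        veg = (meta_beta["vegetation_cover"] > 0).map(
            {True: "vegetated", False: "unvegetated"})
        try:
            R_anosim, p_anosim = beta_mod.anosim(
                dm_u, veg, n_perm=config.anosim_permutations,
                seed=config.seed + 19)
        except ConfigurationError:
            R_anosim, p_anosim = np.nan, np.nan
        best = beta_mod.best_bioenv(dm_u, meta_beta,
                                    max_variables=config.best_max_variables)
        _write_tsv(best.head(50), out / "best.tsv", header)
        files["best"] = out / "best.tsv"

        stage = "network"
        net = net_mod.network_pipeline(
            dataset.table, min_frac=config.rare_otu_fraction,
            q_cutoff=config.q_cutoff, threshold=config.fixed_threshold,
            rmt_grid=config.rmt_grid_array())
        net_mod.node_environment(net, dataset.table, meta)
        _write_tsv(net.edge_table(), out / "edges.tsv", header)
        files["edges"] = out / "edges.tsv"
        _write_tsv(net.node_table(), out / "nodes.tsv", header)
        files["nodes"] = out / "nodes.tsv"
        stats = net_mod.sample_level_stats(net, dataset.table)
        _write_tsv(stats, out / "sample_stats.tsv", header)
        files["sample_stats"] = out / "sample_stats.tsv"
        summary = net_mod.class_summary(stats, classes)
        _write_tsv(summary, out / "class_summary.tsv", header)
        files["class_summary"] = out / "class_summary.tsv"
        metric_corr = net_mod.node_metric_env_correlation(net, stats, meta)
        _write_tsv(metric_corr, out / "metric_env_corr.tsv", header)
        files["metric_env_corr"] = out / "metric_env_corr.tsv"

        class_thresholds = {}
        for cls in ("arid", "margin", "hyperarid"):
            try:
                sub = net_mod.class_subnetwork(
                    dataset.table, meta, cls,
                    min_frac=config.rare_otu_fraction,
                    q_cutoff=config.q_cutoff,
                    threshold=config.fixed_threshold,
                    rmt_grid=config.rmt_grid_array())
                class_thresholds[cls] = sub.threshold_used
            except (ConfigurationError, AridnetError) as exc:
                logger.warning("subnetwork %s failed: %s", cls, exc)

        report = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "global_threshold": net.threshold_used,
            "class_thresholds": class_thresholds,
            "fraction_positive_edges": net.fraction_positive,
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "anosim_vegetation": {"R": R_anosim, "p": p_anosim},
            "unifrac_weighted_vs_unweighted_mantel_r": wu_r,
            "richness_ttest": ttest,
        }
        (out / "network_report.json").write_text(
            json.dumps(report, indent=1, default=float))
        files["network_report"] = out / "network_report.json"

        stage = "null"
        hyper_stats = stats.loc[classes.loc[stats.index] == "hyperarid"]
        null_res = nullmodel.run_null(
            dataset.table, meta, n_reps=config.null_reps,
            depth=config.null_depth,
            thresholds=class_thresholds,
            min_frac=config.rare_otu_fraction, q_cutoff=config.q_cutoff,
            hyperarid_stats=hyper_stats, seed=config.seed + 23)
        null_table = pd.concat(
            [null_res.class_medians,
             null_res.hyperarid_reference.to_frame("hyperarid_original").T])
        _write_tsv(null_table, out / "null_summary.tsv", header)
        files["null_summary"] = out / "null_summary.tsv"
        _write_tsv(nullmodel.richness_check(null_res),
                   out / "null_richness_check.tsv", header)
        files["null_richness_check"] = out / "null_richness_check.tsv"

        stage = "taxa"
        collapsed = taxa_mod.collapse_taxonomy(dataset.table,
                                               dataset.taxonomy, "phylum")
        gradients = taxa_mod.taxon_env_correlation(collapsed, meta)
        _write_tsv(gradients, out / "taxa_gradients.tsv", header)
        files["taxa_gradients"] = out / "taxa_gradients.tsv"
        heat = taxa_mod.heatmap_matrix(gradients, collapsed, meta)
        _write_tsv(heat, out / "heatmap.tsv", header)
        files["heatmap"] = out / "heatmap.tsv"
        guilds = taxa_mod.nitrogen_guild_report(dataset.table,
                                                dataset.taxonomy, meta)
        _write_tsv(guilds, out / "nitrogen_guilds.tsv", header)
        files["nitrogen_guilds"] = out / "nitrogen_guilds.tsv"
    except AridnetError as exc:
        raise AridnetError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "files": {name: {"path": str(path.relative_to(out)),
                         "sha256": _sha256(path)}
                  for name, path in sorted(files.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _obtain_dataset(config: PipelineConfig, out: Path, header: str,
                    files: dict):
    if config.otu_table is None:
        design_kwargs = dict(config.design)
        design_kwargs.setdefault("seed", config.seed)
        design = GradientDesign(**design_kwargs)
        dataset, truth = simulate_dataset(design)
        paths = write_dataset(dataset, out / "data", header)
        files.update({f"data_{k}": v for k, v in paths.items()})
        truth_path = out / "data" / "truth.json"
        truth.to_json(truth_path)
        files["data_truth"] = truth_path
        return dataset, truth
    dataset = load_dataset(config.otu_table, config.metadata, config.tree,
                           config.taxonomy, min_reads=config.min_reads)
    return dataset, None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
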