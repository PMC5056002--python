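"""End-to-end orchestration: DEG screen → attractor → PCNs → RP/IF → core set.

The pipeline is configured from a :class:`PipelineConfig` (optionally
parsed from YAML) that names either four input files (expression
matrix, labels, GMT, PPI edges) or a synthetic-study block. Every
stage's table is written to the output directory, along with a
machine-readable ``manifest.json`` recording thresholds, the seed,
per-stage counts and the package version. Identical config + seed
yields byte-identical outputs; on any stage failure the partial
outputs are removed and the error is tagged with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, attractor, deg, integrate, io, network, synthetic
from .errors import ConfigurationError, CrosspathError

logger = logging.getLogger(__name__)

#: seed of the shipped demo study
DEMO_SEED = 7


@dataclass
class PipelineConfig:
    # exactly one of (input paths) / (synthetic block)
    expression: str | None = None
    labels: str | None = None
    gmt: str | None = None
    edges: str | None = None
    synthetic: synthetic.SyntheticStudyConfig | None = None

    # thresholds (printed defaults of the procedure)
    lfc_threshold: float = 1.5
    deg_p_threshold: float = 0.01
    delta_threshold: float = 0.5
    weight_threshold: int = 5
    p_cut: float = 0.05
    rp_cut: float = 0.05
    if_cut: float = 100.0

    # options
    deg_method: str = "moderated"       # or "welch"
    prior_df: float = 4.0
    pathway_test: str = "t"             # or "permutation"
    n_permutations: int = 10_000
    select_on_fdr: bool = False
    tie_method: str = "average"         # or "min"

    outdir: str = "crosspath_out"
    seed: int = 0

    def validate(self) -> None:
        paths = [self.expression, self.labels, self.gmt, self.edges]
        has_paths = any(p is not None for p in paths)
        if has_paths and self.synthetic is not None:
            raise ConfigurationError(
                "inputs", "give either input paths or a synthetic block, not both")
        if not has_paths and self.synthetic is None:
            raise ConfigurationError(
                "inputs", "one of input paths or a synthetic block is required")
        if has_paths and not all(p is not None for p in paths):
            raise ConfigurationError(
                "inputs", "expression, labels, gmt and edges paths are all required")
        for name in ("lfc_threshold", "deg_p_threshold", "delta_threshold",
                     "weight_threshold", "p_cut", "rp_cut", "if_cut"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(name, "must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(sorted(unknown)[0], "unknown configuration field")
        cfg = cls(**raw)
        if syn is not None:
            for key in ("n_samples_per_group", "pathway_size_range", "group_labels"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            cfg.synthetic = synthetic.SyntheticStudyConfig(**syn)
        return cfg


def demo_config(outdir: str | Path = "crosspath_demo") -> PipelineConfig:
    """The shipped planted demo: default synthetic study, fixed seed."""
    return PipelineConfig(
        synthetic=synthetic.SyntheticStudyConfig(seed=DEMO_SEED),
        outdir=str(outdir),
        seed=DEMO_SEED,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write tables + manifest, return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path)
        written.append(path)

    stage = "load"
    try:
        manifest: dict = {
            "version": __version__,
            "seed": config.seed,
            "thresholds": {
                "lfc": config.lfc_threshold, "deg_p": config.deg_p_threshold,
                "delta_r": config.delta_threshold, "weight": config.weight_threshold,
                "p_cut": config.p_cut, "rp_cut": config.rp_cut, "if_cut": config.if_cut,
            },
            "options": {
                "deg_method": config.deg_method, "pathway_test": config.pathway_test,
                "select_on_fdr": config.select_on_fdr, "tie_method": config.tie_method,
            },
            "counts": {},
        }
        counts = manifest["counts"]

        if config.synthetic is not None:
            stage = "simulate"
            study_bundle = synthetic.generate_study(config.synthetic)
            written.extend(synthetic.write_bundle(study_bundle, outdir).values())
            study = study_bundle.expression
            sets = study_bundle.gene_sets
            ppi = study_bundle.ppi
            manifest["truth"] = study_bundle.truth.to_dict()
        else:
            study = io.read_expression(config.expression, config.labels)
            sets = io.read_gmt(config.gmt)
            ppi = io.read_edges(config.edges)
        sets, n_removed = sets.drop_empty(study.gene_ids)
        counts.update(n_genes=study.n_genes, n_samples=study.n_samples,
                      n_pathways=len(sets), n_pathways_removed_empty=n_removed,
                      n_ppi_edges=len(ppi))

        stage = "deg"
        deg_table = deg.screen_degs(study, config.lfc_threshold, config.deg_p_threshold,
                                    method=config.deg_method, prior_df=config.prior_df)
        emit("deg.tsv", deg.write_deg_table, deg_table)
        degs = deg.deg_ids(deg_table)
        counts["n_degs"] = len(degs)
        logger.info("DEG screen: %d / %d genes flagged", len(degs), study.n_genes)

        stage = "attractor"
        f_table = attractor.gene_f_statistics(study)
        pathway_result = attractor.pathway_t_statistics(
            f_table, sets, method=config.pathway_test,
            n_permutations=config.n_permutations, seed=config.seed)
        emit("pathway_stats.tsv", attractor.write_pathway_table, pathway_result)
        counts["n_pathways_tested"] = len(pathway_result.table)
        counts["n_pathways_skipped"] = len(pathway_result.skipped)

        stage = "network"
        corr = network.edge_spearman(study, ppi)
        filtered = network.filter_dynamic_edges(corr, degs, config.delta_threshold)
        emit("edge_correlations.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.10g"),
             filtered)
        counts["n_edges_scored"] = len(corr)
        counts["n_edges_retained"] = len(filtered)

        background = network.build_crosstalk(ppi, sets, config.weight_threshold)
        disease = network.build_crosstalk(filtered, sets, config.weight_threshold)
        emit("background_network.tsv",
             lambda n, p: n.edge_table().to_csv(p, sep="\t", index=False), background)
        emit("disease_network.tsv",
             lambda n, p: n.edge_table().to_csv(p, sep="\t", index=False), disease)
        scores = network.pathway_scores(background, disease)
        emit("pathway_scores.tsv",
             lambda df, p: df.to_csv(p, sep="\t", float_format="%.10g"), scores)
        counts["n_background_edges"] = background.graph.number_of_edges()
        counts["n_disease_edges"] = disease.graph.number_of_edges()

        stage = "integrate"
        scorecard = integrate.build_scorecard(
            pathway_result.table, scores,
            p_cut=config.p_cut, rp_cut=config.rp_cut, if_cut=config.if_cut,
            use_fdr=config.select_on_fdr, ties=config.tie_method)
        emit("scorecard.tsv", integrate.write_scorecard, scorecard)
        core = integrate.select_core(scorecard)
        manifest["core_pathways"] = core
        counts["n_core"] = len(core)
        logger.info("core pathways: %s", core)

        stage = "manifest"
        manifest_path = outdir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(manifest_path)
        return manifest
    except CrosspathError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise CrosspathError(f"stage {stage!r} failed: {exc}") from exc
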