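"""End-to-end pipeline orchestration with validated YAML configuration.

Stages: accessibility matrix (FPKM → quantile normalization → CV partition →
z-score → PCA), trajectory clustering, gene linking (domains, fold-change
and ANOVA filters, associations, expression summaries, term enrichment),
motif analysis, and — when screen inputs are configured — dropout-screen hit
calling.  Identical config + inputs reproduce byte-identical tables; wall
clock timings go only to ``run.log`` so output directories can be compared
directly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Mapping

import pandas as pd
import yaml

from .clustering import condition_profiles, kmeans_cluster
from .intervals import GenomicIntervalSet, read_bed, read_genome
from .linking import (
    associate_regions,
    build_domains,
    cluster_expression_summary,
    peak_anova,
    read_gene_models,
    read_gmt,
    region_log2fc_filter,
    term_enrichment,
)
from .matrix import (
    SampleMatrix,
    cv_partition,
    fpkm,
    quantile_normalize,
    sample_pca,
    zscore_rows,
)
from .motifs import differential_enrichment, read_fasta, read_jaspar, scan_all, tf_concordance
from .screen import analyze_screen, read_screen_table

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a pipeline configuration is invalid; carries all errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


def _positive(x: Any) -> bool:
    return isinstance(x, (int, float)) and x > 0


def _nonnegative(x: Any) -> bool:
    return isinstance(x, (int, float)) and x >= 0


def _fraction(x: Any) -> bool:
    return isinstance(x, (int, float)) and 0 <= x <= 1


def _is_int(x: Any) -> bool:
    return isinstance(x, int) and not isinstance(x, bool)


# key -> (default, validator, reason).  None default = required for the
# stages that use the key; seeds are deliberately defaulted to None so a
# stochastic stage cannot run on a silent default.
_INPUT_KEYS = (
    "genome", "universe", "counts", "sample_metadata", "gene_models",
    "expression", "expression_metadata", "gene_sets", "sequences", "pfms",
    "screen_counts", "screen_metadata", "tf_map",
)

_PARAM_SCHEMA: dict[str, tuple[Any, Callable[[Any], bool], str]] = {
    "cv_threshold": (0.10, _fraction, "must be a fraction in [0, 1]"),
    "kmeans_k": (8, lambda x: _is_int(x) and x >= 1, "must be a positive integer"),
    "kmeans_n_init": (50, lambda x: _is_int(x) and x >= 1, "must be a positive integer"),
    "seed": (None, lambda x: x is None or (_is_int(x) and x >= 0), "must be a nonnegative integer"),
    "archetype_delta": (0.5, _positive, "must be > 0"),
    "domain_up": (5000, lambda x: _is_int(x) and x >= 0, "must be a nonnegative integer"),
    "domain_down": (1000, lambda x: _is_int(x) and x >= 0, "must be a nonnegative integer"),
    "domain_max_ext": (1_000_000, lambda x: _is_int(x) and x > 0, "must be a positive integer"),
    "lfc_min": (1.0, _nonnegative, "must be >= 0"),
    "lfc_pseudocount": (1.0, _positive, "must be > 0"),
    "anova_alpha": (0.05, _fraction, "must be a fraction in [0, 1]"),
    "motif_rel_threshold": (0.8, _fraction, "must be a fraction in [0, 1]"),
    "motif_z_display": (6.0, _positive, "must be > 0"),
    "tf_min_r": (0.9, lambda x: isinstance(x, (int, float)) and -1 <= x <= 1, "must be in [-1, 1]"),
    "screen_fdr": (0.05, _fraction, "must be a fraction in [0, 1]"),
    "screen_lfc": (-1.0, lambda x: isinstance(x, (int, float)), "must be a number"),
    "screen_B": (10_000, lambda x: _is_int(x) and x >= 100, "must be an integer >= 100"),
    "screen_pseudocount": (0.5, _positive, "must be > 0"),
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration: input paths + stage parameters."""

    inputs: dict[str, str]
    params: dict[str, Any]

    def normalized(self) -> dict[str, Any]:
        return {
            "inputs": dict(sorted(self.inputs.items())),
            "params": dict(sorted(self.params.items())),
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.normalized(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(source: str | Path | Mapping[str, Any]) -> PipelineConfig:
    """Parse, default-fill and validate a pipeline configuration.

    Unknown keys are rejected; every problem is reported (key + reason) in a
    single :class:`ConfigError` rather than failing at the first.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])

    unknown_top = set(raw) - {"inputs", "params"}
    for key in sorted(unknown_top):
        errors.append(f"{key}: unknown top-level section")

    raw_inputs = raw.get("inputs") or {}
    inputs: dict[str, str] = {}
    for key, value in sorted(raw_inputs.items()):
        if key not in _INPUT_KEYS:
            errors.append(f"inputs.{key}: unknown input key")
        elif not isinstance(value, str) or not value:
            errors.append(f"inputs.{key}: must be a non-empty path string")
        else:
            inputs[key] = value

    raw_params = raw.get("params") or {}
    params: dict[str, Any] = {}
    for key, (default, check, reason) in _PARAM_SCHEMA.items():
        if key in raw_params:
            value = raw_params[key]
            if not check(value):
                errors.append(f"params.{key}: {reason} (got {value!r})")
            else:
                params[key] = value
        else:
            params[key] = default
    for key in sorted(set(raw_params) - set(_PARAM_SCHEMA)):
        errors.append(f"params.{key}: unknown parameter")

    for required in ("counts", "sample_metadata"):
        if required not in inputs:
            errors.append(f"inputs.{required}: required path is missing")
    if "tf_map" in inputs and "expression" not in inputs:
        errors.append("inputs.expression: required when tf_map (TF concordance) is configured")
    if errors:
        raise ConfigError(errors)
    return PipelineConfig(inputs=inputs, params=params)


def _require(cfg: PipelineConfig, stage: str, *keys: str) -> None:
    missing = [k for k in keys if k not in cfg.inputs]
    if missing:
        raise ConfigError([f"inputs.{k}: required for stage {stage!r}" for k in missing])


def _require_seed(cfg: PipelineConfig, stage: str) -> int:
    seed = cfg.params.get("seed")
    if seed is None:
        raise ConfigError([f"params.seed: required to run stochastic stage {stage!r}"])
    return int(seed)


class PipelineRun:
    """Mutable state threaded through the pipeline stages."""

    def __init__(self, cfg: PipelineConfig, outdir: str | Path):
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.stages_run: list[str] = []
        self.timings: dict[str, float] = {}
        self.genome = read_genome(cfg.inputs["genome"]) if "genome" in cfg.inputs else None
        self.universe: GenomicIntervalSet | None = None
        self.counts: SampleMatrix | None = None
        self.qnorm: SampleMatrix | None = None
        self.partition = None
        self.zmat: SampleMatrix | None = None
        self.clusters = None
        self.domains = None
        self.associations: pd.DataFrame | None = None

    # ------------------------------------------------------------- stages
    def stage_matrix(self) -> None:
        cfg = self.cfg
        _require(cfg, "matrix", "counts", "sample_metadata")
        lengths = None
        if "universe" in cfg.inputs:
            self.universe = read_bed(cfg.inputs["universe"], dialect="bed6", genome=self.genome)
            lengths = pd.Series(
                {iv.id: float(len(iv)) for iv in self.universe}
            )
        self.counts = SampleMatrix.read(
            cfg.inputs["counts"], cfg.inputs["sample_metadata"], lengths=lengths
        )
        mat = fpkm(self.counts) if lengths is not None else self.counts
        self.qnorm = quantile_normalize(mat)
        self.partition = cv_partition(self.qnorm, threshold=cfg.params["cv_threshold"])
        dynamic = self.qnorm.subset_rows(self.partition.dynamic_ids)
        self.zmat = zscore_rows(dynamic)
        coords, expl = sample_pca(self.qnorm)
        part_df = pd.DataFrame(
            {
                "cv": self.partition.cv,
                "status": [
                    "dynamic" if p in set(self.partition.dynamic_ids) else "static"
                    for p in self.qnorm.values.index
                ],
            }
        )
        part_df.index.name = "peak_id"
        part_df.to_csv(self.outdir / "partition.tsv", sep="\t")
        out = self.qnorm.values.copy()
        out.index.name = "peak_id"
        out.to_csv(self.outdir / "normalized_fpkm.tsv", sep="\t")
        coords.index.name = "sample_id"
        coords.to_csv(self.outdir / "pca.tsv", sep="\t")
        pd.DataFrame(
            {"component": coords.columns, "explained_variance": expl}
        ).to_csv(self.outdir / "pca_variance.tsv", sep="\t", index=False)

    def stage_cluster(self) -> None:
        cfg = self.cfg
        seed = _require_seed(cfg, "cluster")
        profiles = condition_profiles(self.zmat)
        self.clusters = kmeans_cluster(
            profiles,
            k=cfg.params["kmeans_k"],
            seed=seed,
            n_init=cfg.params["kmeans_n_init"],
            delta=cfg.params["archetype_delta"],
        )
        self.clusters.write(
            self.outdir / "clusters.tsv", self.outdir / "centroids.tsv"
        )

    def stage_link(self) -> None:
        cfg = self.cfg
        _require(cfg, "link", "gene_models", "universe", "genome", "gene_sets")
        genes = read_gene_models(cfg.inputs["gene_models"])
        self.domains = build_domains(
            genes,
            self.genome,
            up=cfg.params["domain_up"],
            down=cfg.params["domain_down"],
            max_ext=cfg.params["domain_max_ext"],
        )
        anova = peak_anova(self.qnorm.subset_rows(self.partition.dynamic_ids))
        anova.index.name = "peak_id"
        anova.to_csv(self.outdir / "anova.tsv", sep="\t")
        kept = region_log2fc_filter(
            fpkm(self.counts),
            min_lfc=cfg.params["lfc_min"],
            pseudocount=cfg.params["lfc_pseudocount"],
        )
        kept_set = set(kept) & set(self.partition.dynamic_ids)
        sig = set(anova.index[anova["p"] < cfg.params["anova_alpha"]])
        id2iv = {iv.id: iv for iv in self.universe}
        dyn_regions = GenomicIntervalSet(
            [id2iv[p] for p in self.partition.dynamic_ids], genome=self.genome
        )
        self.associations = associate_regions(dyn_regions, self.domains, genome=self.genome)
        self.associations.to_csv(self.outdir / "associations.tsv", sep="\t", index=False)
        gene_sets = read_gmt(cfg.inputs["gene_sets"])
        all_gene_ids = [g.gene_id for g in genes]
        enr_frames = []
        for cluster in sorted(self.clusters.centroids.index):
            members = [
                p for p in self.clusters.members(cluster) if p in kept_set and p in sig
            ]
            if not members:
                continue
            regions = GenomicIntervalSet([id2iv[p] for p in members], genome=self.genome)
            enr = term_enrichment(
                regions, self.domains, gene_sets, self.genome, all_genes=all_gene_ids
            )
            enr.insert(0, "cluster", cluster)
            enr_frames.append(enr)
        if enr_frames:
            pd.concat(enr_frames).to_csv(
                self.outdir / "term_enrichment.tsv", sep="\t", index=False
            )
        if "expression" in cfg.inputs:
            expr = SampleMatrix.read(
                cfg.inputs["expression"],
                cfg.inputs.get("expression_metadata", cfg.inputs["sample_metadata"]),
            )
            summary = cluster_expression_summary(self.clusters, self.associations, expr)
            summary.to_csv(self.outdir / "expression_summary.tsv", sep="\t", index=False)

    def stage_motif(self) -> None:
        cfg = self.cfg
        _require(cfg, "motif", "sequences", "pfms")
        seqs = read_fasta(cfg.inputs["sequences"])
        pwms = read_jaspar(cfg.inputs["pfms"])
        dyn = [p for p in self.partition.dynamic_ids if p in seqs]
        hits = scan_all(
            {p: seqs[p] for p in dyn}, pwms, rel_threshold=cfg.params["motif_rel_threshold"]
        )
        hits.index.name = "region_id"
        hits.to_csv(self.outdir / "motif_hits.tsv", sep="\t")
        enr = differential_enrichment(hits, self.clusters)
        enr.to_csv(self.outdir / "motif_enrichment.tsv", sep="\t", index=False)
        if "tf_map" in cfg.inputs:
            tf_map = pd.read_csv(cfg.inputs["tf_map"], sep="\t")
            expr = SampleMatrix.read(
                cfg.inputs["expression"],
                cfg.inputs.get("expression_metadata", cfg.inputs["sample_metadata"]),
            )
            conc = tf_concordance(
                list(tf_map["gene_id"].unique()), expr, self.clusters,
                min_r=cfg.params["tf_min_r"],
            )
            conc.to_csv(self.outdir / "tf_concordance.tsv", sep="\t", index=False)

    def stage_screen(self) -> None:
        cfg = self.cfg
        _require(cfg, "screen", "screen_counts", "screen_metadata")
        seed = _require_seed(cfg, "screen")
        table = read_screen_table(cfg.inputs["screen_counts"], cfg.inputs["screen_metadata"])
        called = analyze_screen(
            table,
            fdr_threshold=cfg.params["screen_fdr"],
            lfc_threshold=cfg.params["screen_lfc"],
            B=cfg.params["screen_B"],
            seed=seed,
            pseudocount=cfg.params["screen_pseudocount"],
        )
        called.to_csv(self.outdir / "screen_results.tsv", sep="\t")

    def run(self, stages: list[str]) -> None:
        stage_fns = {
            "matrix": self.stage_matrix,
            "cluster": self.stage_cluster,
            "link": self.stage_link,
            "motif": self.stage_motif,
            "screen": self.stage_screen,
        }
        log_lines = []
        for name in stages:
            t0 = time.perf_counter()
            try:
                stage_fns[name]()
            except Exception as exc:
                (self.outdir / "INVALID").write_text(
                    f"pipeline aborted in stage {name!r}: {exc}\n"
                )
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            dt = time.perf_counter() - t0
            self.stages_run.append(name)
            self.timings[name] = dt
            log_lines.append(f"stage {name}: {dt:.2f}s")
        from . import __version__

        manifest = {
            "package": "chromdyn",
            "version": __version__,
            "config_hash": self.cfg.config_hash(),
            "config": self.cfg.normalized(),
            "stages": self.stages_run,
        }
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        with open(self.outdir / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        invalid = self.outdir / "INVALID"
        if invalid.exists():
            invalid.unlink()


#: stages of the full pipeline, in dependency order
ALL_STAGES = ["matrix", "cluster", "link", "motif", "screen"]


def run_pipeline(
    config: PipelineConfig | str | Path | Mapping[str, Any],
    outdir: str | Path,
    stages: list[str] | None = None,
) -> Path:
    """Execute pipeline stages against a validated configuration.

    With ``stages=None`` every stage whose inputs are configured runs (the
    ``all`` behavior): matrix and cluster always; link, motif and screen only
    when their input files are present in the config.
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    if stages is None:
        stages = ["matrix", "cluster"]
        if {"gene_models", "gene_sets"} <= set(cfg.inputs):
            stages.append("link")
        if {"sequences", "pfms"} <= set(cfg.inputs):
            stages.append("motif")
        if {"screen_counts", "screen_metadata"} <= set(cfg.inputs):
            stages.append("screen")
    else:
        known = set(ALL_STAGES)
        bad = [s for s in stages if s not in known]
        if bad:
            raise ConfigError([f"unknown stage {s!r}" for s in bad])
        stages = [s for s in ALL_STAGES if s in stages]
    run = PipelineRun(cfg, outdir)
    run.run(stages)
    return run.outdir
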