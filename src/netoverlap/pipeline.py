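"""Orchestrate the full overlap-analysis workflow from one YAML config.

Stages run in order: gene-set overlap (Fisher) → topology + localization →
network proximity → co-expression overlap (Fisher again, against a second
gene list) → EWCE → GMT enrichment.  A stage whose optional inputs are
missing is skipped with a warning; every executed stage writes a TSV (tabular
results) or JSON (scalar results) file, and the run ends with a manifest
recording the stages executed, per-stage seeds, input digests and package
version.

A single global seed deterministically derives per-stage seeds
(seed + stage index), so any stage can be rerun on its own and reproduce the
pipeline's output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from netoverlap.ewce import ewce_test, read_annotations, read_expression, specificity_matrix
from netoverlap.interactome import (
    load_edge_list,
    load_gene_set,
    load_ortholog_table,
    map_orthologs,
)
from netoverlap.localization import localization_test
from netoverlap.overlap_stats import fisher_overlap, gmt_enrichment
from netoverlap.proximity import proximity_test
from netoverlap.topology import topology_metrics

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

#: Stage names in execution order (stage index = position, used for seeds).
STAGES = ("overlap", "localization", "proximity", "coexpression", "ewce", "enrichment")


@dataclass
class PipelineConfig:
    """Paths, run sizes and thresholds for a full pipeline run."""

    network: str | None = None
    genes_a: str | None = None
    genes_b: str | None = None
    universe: str | None = None
    gmt: str | None = None
    expression: str | None = None
    annotations: str | None = None
    orthologs: str | None = None
    coexpression_genes: str | None = None
    n_perm_localization: int = 5000
    n_perm_proximity: int = 1000
    n_boot_ewce: int = 100_000
    enrichment_fdr: float = 0.01
    ewce_alpha: float = 0.05
    seed: int = 0
    outdir: str = "netoverlap_results"
    disabled_stages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.n_perm_localization, self.n_perm_proximity, self.n_boot_ewce) < 1:
            raise ValueError("permutation/bootstrap counts must be >= 1")
        for name in ("enrichment_fdr", "ewce_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        unknown = set(self.disabled_stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) in disabled_stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _stage_seed(cfg: PipelineConfig, stage: str) -> int:
    return cfg.seed + STAGES.index(stage)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all enabled stages; return (and write) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from netoverlap import __version__  # deferred: avoids import cycle

    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": [], "inputs": {}}
    for name in ("network", "genes_a", "genes_b", "universe", "gmt", "expression",
                 "annotations", "orthologs", "coexpression_genes"):
        p = getattr(cfg, name)
        if p:
            manifest["inputs"][name] = {"path": str(p), "sha256": _digest(p)}

    net = load_edge_list(cfg.network) if cfg.network else None
    genes_a = load_gene_set(cfg.genes_a, "genes_a") if cfg.genes_a else None
    genes_b = load_gene_set(cfg.genes_b, "genes_b") if cfg.genes_b else None
    universe = load_gene_set(cfg.universe, "universe") if cfg.universe else None
    combined = genes_a.union(genes_b, name="genes_ab") if genes_a and genes_b else None

    current = {"stage": "setup"}

    def enabled(stage: str, *required) -> bool:
        current["stage"] = stage
        if stage in cfg.disabled_stages:
            logger.info("stage %s disabled by config", stage)
            return False
        if any(r is None for r in required):
            logger.warning("stage %s skipped: missing input", stage)
            return False
        return True

    def record(stage: str, output: Path) -> None:
        manifest["stages"].append(
            {"name": stage, "seed": _stage_seed(cfg, stage), "output": output.name}
        )

    try:
        if enabled("overlap", genes_a, genes_b, universe):
            res = fisher_overlap(genes_a, genes_b, universe)
            out = outdir / "overlap.json"
            out.write_text(json.dumps(res.as_dict(), indent=2) + "\n")
            record("overlap", out)

        if enabled("localization", net, combined):
            obs = topology_metrics(net, combined)
            rows = [
                r.as_dict()
                for r in localization_test(
                    net, combined, n_perm=cfg.n_perm_localization,
                    seed=_stage_seed(cfg, "localization"),
                )
            ]
            out = outdir / "localization.tsv"
            pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
            (outdir / "topology.tsv").write_text(
                "metric\tvalue\n"
                + "".join(f"{k}\t{v}\n" for k, v in obs.as_dict().items())
            )
            record("localization", out)

        if enabled("proximity", net, genes_a, genes_b):
            res = proximity_test(
                net, genes_a, genes_b, n_perm=cfg.n_perm_proximity,
                seed=_stage_seed(cfg, "proximity"),
            )
            out = outdir / "proximity.json"
            out.write_text(json.dumps(res.as_dict(), indent=2) + "\n")
            record("proximity", out)

        if enabled("coexpression", genes_a, combined, universe, cfg.coexpression_genes):
            coexpr = load_gene_set(cfg.coexpression_genes, "coexpression")
            res = fisher_overlap(combined, coexpr, universe)
            out = outdir / "coexpression_overlap.json"
            out.write_text(json.dumps(res.as_dict(), indent=2) + "\n")
            record("coexpression", out)

        if enabled("ewce", combined, cfg.expression, cfg.annotations):
            expr = read_expression(cfg.expression)
            annot = read_annotations(cfg.annotations)
            spec = specificity_matrix(expr, annot)
            query = combined
            if cfg.orthologs:
                query = map_orthologs(query, load_ortholog_table(cfg.orthologs))
            res = ewce_test(
                spec, query, n_boot=cfg.n_boot_ewce, seed=_stage_seed(cfg, "ewce")
            )
            out = outdir / "ewce.tsv"
            res.table.to_csv(out, sep="\t")
            record("ewce", out)

        if enabled("enrichment", combined, cfg.gmt, universe):
            records = gmt_enrichment(combined, cfg.gmt, universe)
            out = outdir / "enrichment.tsv"
            df = pd.DataFrame([r.as_dict() for r in records])
            df["overlap_genes"] = df["overlap_genes"].map(";".join)
            df.to_csv(out, sep="\t", index=False)
            record("enrichment", out)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {current['stage']!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %d stage(s), outputs in %s", len(manifest["stages"]), outdir)
    return manifest
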