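"""End-to-end orchestration: simulate -> DE x2 -> DM -> pairs -> integrate -> enrich.

Stages communicate through plain TSV files so each can be rerun alone;
a manifest records every emitted file with its row count and checksum,
and identical config + seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from triomix import diffexp, enrichment, integration, methylation, mirna
from triomix.io_formats import (
    read_bed_intervals,
    read_beta_matrix,
    read_count_matrix,
    read_gene_annotation,
    read_gmt,
    read_interactions,
    read_sample_metadata,
    read_table,
    write_table,
)
from triomix.synthetic import SimConfig, generate_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; loadable from YAML."""

    outdir: str = "triomix_run"
    seed: int = 0
    alpha_de: float = 0.05
    alpha_dm: float = 0.05
    min_total: int = 10
    promoter_up: int = 1500
    promoter_down: int = 500
    combine_method: str = "fisher"
    k_range: tuple[int, int] = (8, 12)
    restarts: int = 100
    force_k: int | None = None
    theta: float = 0.25
    impute_missing: bool = True
    min_set_size: int = 3
    simulate: bool = True
    sim: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # paths when simulate is False

    def __post_init__(self):
        for a in (self.alpha_de, self.alpha_dm):
            if not 0 < a < 1:
                raise ValueError("alpha levels must lie in (0, 1)")
        lo, hi = self.k_range
        if lo > hi:
            raise ValueError("k_range must be ascending")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)


def stage_seed(root_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    return int((root_seed * 1_000_003 + stage_index) % 2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(stage: str, path: Path, rows: int) -> None:
        manifest.append(
            {"stage": stage, "file": path.name, "rows": int(rows), "sha256": _checksum(path)}
        )
        logger.info("stage=%s file=%s rows=%d", stage, path.name, rows)

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        def _simulate():
            sim_cfg = SimConfig.from_dict({**config.sim, "seed": stage_seed(config.seed, 0)})
            cohort = generate_cohort(sim_cfg, outdir / "cohort")
            for key, path in cohort.paths.items():
                n_rows = max(0, sum(1 for _ in open(path)) - 1)
                record("simulate", path, n_rows)
            return {k: str(v) for k, v in cohort.paths.items()}

        inputs = run_stage("simulate", _simulate)
    else:
        inputs = dict(config.inputs)

    meta = read_sample_metadata(inputs["samples"])

    # --- differential expression -----------------------------------------
    def _diffexp(counts_path, out_name):
        cm = diffexp.prefilter(read_count_matrix(counts_path), config.min_total)
        table = diffexp.wald_test(cm, meta, alpha=config.alpha_de)
        path = outdir / out_name
        write_table(table, path)
        record("diffexp", path, len(table))
        return cm, table

    mrna_cm, de_mrna = run_stage("diffexp-mrna", lambda: _diffexp(inputs["mrna_counts"], "de_mrna.tsv"))
    mirna_cm, de_mirna = run_stage("diffexp-mirna", lambda: _diffexp(inputs["mirna_counts"], "de_mirna.tsv"))

    # --- differential methylation ----------------------------------------
    def _methylate():
        beta = read_beta_matrix(inputs["beta"])
        cpgs = read_bed_intervals(inputs["cpgs"])
        islands = read_bed_intervals(inputs["islands"])
        genes = read_gene_annotation(inputs["genes"])
        sites = methylation.site_dm_test(beta, meta)
        dm = methylation.aggregate_islands(
            sites, islands, cpgs, method=config.combine_method, alpha=config.alpha_dm
        )
        promoters = methylation.promoter_intervals(
            genes, up=config.promoter_up, down=config.promoter_down
        )
        cgi_map = methylation.assign_cgi_to_genes(islands, promoters)
        dm_path = outdir / "dm_islands.tsv"
        write_table(dm, dm_path)
        record("methylate", dm_path, len(dm))
        map_rows = [
            {"gene_id": g, "island_id": i} for g in sorted(cgi_map) for i in cgi_map[g]
        ]
        map_df = pd.DataFrame(map_rows, columns=["gene_id", "island_id"])
        map_path = outdir / "cgi_gene_map.tsv"
        write_table(map_df, map_path)
        record("methylate", map_path, len(map_df))
        return dm, cgi_map

    dm_islands, cgi_gene_map = run_stage("methylate", _methylate)

    # --- miRNA-target pairs ----------------------------------------------
    def _pairs():
        interactions = read_interactions(inputs["interactions"])
        pairs = mirna.candidate_pairs(de_mrna, de_mirna, interactions)
        if len(pairs):
            pairs = mirna.spearman_fill(
                pairs,
                diffexp.normalized_counts(mrna_cm),
                diffexp.normalized_counts(mirna_cm),
            )
            pairs = mirna.reduce_pairs(pairs)
        path = outdir / "pairs.tsv"
        write_table(pairs, path)
        record("mirna-pairs", path, len(pairs))
        return pairs

    pairs = run_stage("mirna-pairs", _pairs)

    # --- integration -------------------------------------------------------
    def _integrate():
        table = integration.build_integrated_table(de_mrna, pairs, dm_islands, cgi_gene_map)
        counts, _ = integration.classify_regulation(table)
        path = outdir / "integrated.tsv"
        write_table(table, path)
        record("integrate", path, len(table))

        lo, hi = config.k_range
        model = integration.cluster_features(
            table,
            k_range=range(lo, hi + 1),
            restarts=config.restarts,
            seed=stage_seed(config.seed, 5),
            force_k=config.force_k,
            impute_missing=config.impute_missing,
        )
        dominance, index = integration.exclusivity_index(model, theta=config.theta)
        clusters = pd.DataFrame(
            {
                "gene_id": model.gene_ids,
                "cluster": model.assignments,
                "gene_log2fc_scaled": model.matrix[:, 0],
                "mirna_log2fc_scaled": model.matrix[:, 1],
                "log2_quotient_scaled": model.matrix[:, 2],
            }
        )
        cpath = outdir / "clusters.tsv"
        write_table(clusters, cpath)
        record("integrate", cpath, len(clusters))
        diagnostics = {
            "k": model.k,
            "within_ss": model.inertia,
            "silhouette_by_k": {str(k): v for k, v in model.silhouette_by_k.items()},
            "class_counts": counts,
            "cluster_dominance": [float(d) for d in dominance],
            "exclusivity_index": index,
        }
        dpath = outdir / "cluster_diagnostics.json"
        dpath.write_text(json.dumps(diagnostics, indent=2, allow_nan=True) + "\n")
        record("integrate", dpath, 1)
        return table, model, index

    table, model, index = run_stage("integrate", _integrate)

    # --- enrichment --------------------------------------------------------
    if inputs.get("gene_sets"):
        def _enrich():
            collection = read_gmt(inputs["gene_sets"])
            background = list(de_mrna["feature_id"])
            _, class_genes = integration.classify_regulation(table)
            frames = []
            for cls, genes in class_genes.items():
                if not genes:
                    continue
                res = enrichment.enrich(
                    genes, collection, background, min_set_size=config.min_set_size
                )
                res.insert(0, "reg_class", cls)
                frames.append(res)
            out = (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(columns=["reg_class", *enrichment.RESULT_COLUMNS])
            )
            path = outdir / "enrichment.tsv"
            write_table(out, path)
            record("enrich", path, len(out))
            return out

        run_stage("enrich", _enrich)

    manifest_obj = {"seed": config.seed, "artifacts": manifest}
    (outdir / "manifest.json").write_text(json.dumps(manifest_obj, indent=2) + "\n")
    return manifest_obj
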