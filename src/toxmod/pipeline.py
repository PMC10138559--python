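"""End-to-end pipeline: differential expression -> module scoring ->
pathway analysis -> cross-condition comparison, driven by a RunConfig.

Every run writes its outputs plus a JSON manifest capturing the effective
configuration, input checksums and per-stage warnings, so a run can be
reproduced bit-identically from its manifest.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparative import common_genes, overlap_matrix, pca_embed, rank_by_mean_fc
from .datatypes import Condition, InvalidInputError
from .expression import differential_expression
from .io import (
    cohort_pairs_from_sheet,
    file_sha256,
    read_expression_tsv,
    read_gmt,
    read_sample_sheet,
    write_manifest,
    write_profile_tsv,
    write_table,
)
from .pathways import score_pathways_directional
from .scoring import AAFC, NullConfig, results_to_frame, score_all_modules

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    matrix: str
    samples: str
    modules_gmt: str
    out_dir: str
    pathways_gmt: str | None = None
    categories_tsv: str | None = None
    seed: int = 0
    q_threshold: float = 0.1
    z_threshold: float = 2.0
    n_resamples: int = 10_000
    pseudocount: float = 1.0
    statistic: str = AAFC
    conditions: list[str] | None = None  # optional filter of condition labels

    def __post_init__(self) -> None:
        if self.q_threshold <= 0 or self.z_threshold <= 0:
            raise InvalidInputError("thresholds must be positive")
        if self.n_resamples < 100:
            raise InvalidInputError("n_resamples must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        from .io import load_config_yaml

        cfg = load_config_yaml(path)
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage over every condition in the sample sheet.

    Writes per-condition profiles and DEG lists, the module z-score table
    (wide and long form), directional pathway scores when a pathway GMT is
    supplied, DEG overlap counts, the common-gene mean-FC ranking, a PCA
    embedding of common-gene fold changes, and a manifest. Returns the
    manifest dict.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, p in [("matrix", cfg.matrix), ("samples", cfg.samples),
                    ("modules_gmt", cfg.modules_gmt)]:
        if not Path(p).exists():
            raise InvalidInputError(f"required input {name!r} not found: {p}")

    matrix = read_expression_tsv(cfg.matrix)
    sheet = read_sample_sheet(cfg.samples)
    modules = read_gmt(cfg.modules_gmt, kind="injury_module")
    pairs = cohort_pairs_from_sheet(sheet)
    if cfg.conditions:
        wanted = set(cfg.conditions)
        pairs = [p for p in pairs if p.condition.label in wanted]
        if not pairs:
            raise InvalidInputError("condition filter matched nothing")

    warnings: list[str] = []
    null_cfg = NullConfig(n_resamples=cfg.n_resamples, seed=cfg.seed)

    # stage 1: differential expression per condition
    profiles, deg_sets = [], []
    for pair in pairs:
        profile, degs = differential_expression(matrix, pair, cfg.q_threshold)
        profiles.append(profile)
        deg_sets.append(degs)
        write_profile_tsv(profile, out)
        deg_df = pd.DataFrame({"gene_id": sorted(degs.gene_ids)})
        write_table(deg_df, out / f"degs_{pair.condition.label}.tsv", index=False)
        if profile.n_dropped:
            warnings.append(
                f"{pair.condition.label}: dropped {profile.n_dropped} genes"
            )

    # stage 2: module activation scores
    z_table, results = score_all_modules(
        profiles, modules, cfg.statistic, null_cfg, cfg.z_threshold
    )
    write_table(z_table, out / "module_zscores.tsv", report=True)
    write_table(results_to_frame(results), out / "module_scores_long.tsv", index=False)

    # stage 3: directional pathway scores (optional)
    if cfg.pathways_gmt:
        pathways = read_gmt(cfg.pathways_gmt, kind="pathway")
        categories = None
        if cfg.categories_tsv:
            cat = pd.read_csv(cfg.categories_tsv, sep="\t", header=None,
                              names=["pathway", "category"], dtype=str)
            categories = dict(zip(cat["pathway"], cat["category"]))
        path_table = score_pathways_directional(
            profiles, pathways, categories, null_cfg, cfg.z_threshold
        )
        write_table(path_table, out / "pathway_directions.tsv", index=False)

    # stage 4: cross-condition comparison
    ov = overlap_matrix(deg_sets)
    write_table(ov.counts, out / "deg_overlap.tsv")
    if len(deg_sets) >= 2:
        core = sorted(common_genes(deg_sets))
        pd.DataFrame({"gene_id": core}).to_csv(
            out / "common_genes.tsv", sep="\t", index=False
        )
        if core:
            ranking = rank_by_mean_fc(core, profiles)
            write_table(ranking, out / "common_gene_ranking.tsv",
                        report=True, index=False)
            if len(profiles) >= 2 and len(core) >= 2:
                fc_table = pd.DataFrame(
                    {p.condition.label: p.table.loc[core, "log2_fc"] for p in profiles}
                ).T  # conditions x genes
                emb = pca_embed(fc_table, n_components=min(2, len(profiles)))
                write_table(emb.points, out / "common_gene_pca.tsv")
        else:
            warnings.append("common-gene intersection is empty")

    manifest = {
        "tool": "toxmod",
        "version": __version__,
        "config": asdict(cfg),
        "inputs": {
            k: file_sha256(v)
            for k, v in {
                "matrix": cfg.matrix,
                "samples": cfg.samples,
                "modules_gmt": cfg.modules_gmt,
                "pathways_gmt": cfg.pathways_gmt,
                "categories_tsv": cfg.categories_tsv,
            }.items()
            if v
        },
        "conditions": [p.condition.label for p in pairs],
        "warnings": warnings,
    }
    write_manifest(manifest, out / "manifest.json")
    return manifest
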