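"""Pathway-level analyses: directional AFC scoring and over-representation.

Directional scoring reuses the module-scoring engine with the signed AFC
statistic: a pathway is labelled "up" when its z-score exceeds the
activation threshold, "down" below the negated threshold, "neutral"
otherwise, and pathways can carry category labels (Metabolism, Cell and
Immune Signaling, Cell Cycle/Translation/Transcription) for grouped
reporting. Over-representation analysis (ORA) tests whether a gene list
is enriched in a pathway with the one-sided hypergeometric upper tail,
BH-adjusted across the batch. ORA here is the standard hypergeometric
test — unlike EASE-style variants it does not discount one hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    FoldChangeProfile,
    GeneSet,
    GeneSetCollection,
    InvalidInputError,
)
from .expression import bh_adjust
from .scoring import AFC, ModuleActivationResult, NullConfig, match_genes, score_module
from .synthetic import child_rng

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "OraResult",
    "ora_test",
    "ora_batch",
    "score_pathways_directional",
]

CATEGORIES = (
    "Metabolism",
    "Cell and Immune Signaling",
    "Cell Cycle/Translation/Transcription",
    "other",
)


@dataclass
class OraResult:
    """Hypergeometric over-representation result for one pathway."""

    pathway: str
    k_hits: int
    list_size: int
    pathway_size: int
    universe_size: int
    p_value: float
    q_value: float = float("nan")


def ora_test(gene_list: Iterable[str], pathway: Iterable[str], universe: Iterable[str]) -> OraResult:
    """One-sided hypergeometric test for >= k hits of the list in the pathway.

    With N universe genes, K pathway genes and a list of n genes of which
    k fall in the pathway, p = P[X >= k] for X ~ Hypergeom(N, K, n).
    """
    universe_set = {str(g).casefold() for g in universe}
    list_set = {str(g).casefold() for g in gene_list}
    path_set = {str(g).casefold() for g in pathway}
    if not list_set or not path_set:
        raise InvalidInputError("gene list and pathway must be non-empty")
    if not list_set <= universe_set:
        raise InvalidInputError("gene list contains genes outside the universe")
    if not path_set <= universe_set:
        raise InvalidInputError("pathway contains genes outside the universe")
    N, K, n = len(universe_set), len(path_set), len(list_set)
    k = len(list_set & path_set)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OraResult(
        pathway="", k_hits=k, list_size=n, pathway_size=K, universe_size=N,
        p_value=min(p, 1.0),
    )


def ora_batch(
    gene_list: Iterable[str],
    pathways: GeneSetCollection,
    universe: Iterable[str],
) -> list[OraResult]:
    """ORA across a pathway collection with BH adjustment, sorted by (q, p)."""
    universe = list(universe)
    results = []
    for ps in pathways:
        res = ora_test(gene_list, ps.gene_ids, universe)
        res.pathway = ps.name
        results.append(res)
    q = bh_adjust(np.array([r.p_value for r in results]))
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    results.sort(key=lambda r: (r.q_value, r.p_value, r.pathway))
    return results


def ora_results_to_frame(results: Sequence[OraResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "k_hits": [r.k_hits for r in results],
            "pathway_size": [r.pathway_size for r in results],
            "list_size": [r.list_size for r in results],
            "universe_size": [r.universe_size for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )


def score_pathways_directional(
    profiles: Sequence[FoldChangeProfile],
    pathways: GeneSetCollection,
    categories: Mapping[str, str] | None = None,
    cfg: NullConfig = NullConfig(),
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Signed AFC z-scores with up/down/neutral direction labels.

    Returns a long-form table (category, pathway, condition, score, z,
    direction) sorted by category then pathway. Categories are a pure
    relabelling — they never change the scores. Pathways with no measured
    genes become neutral rows flagged with NaN z.
    """
    categories = dict(categories or {})
    for cat in categories.values():
        if cat not in CATEGORIES:
            raise InvalidInputError(f"unknown pathway category {cat!r}")
    rows = []
    for prof in profiles:
        for ps in pathways:
            rng = child_rng(cfg.seed, ps.name, prof.condition.label)
            matched = match_genes(ps, prof)
            if not matched:
                logger.warning(
                    "pathway %s has no genes in %s", ps.name, prof.condition.label
                )
                rows.append(
                    dict(
                        category=categories.get(ps.name, "other"),
                        pathway=ps.name,
                        condition=prof.condition.label,
                        n_genes_matched=0,
                        score=float("nan"),
                        z=float("nan"),
                        direction="neutral",
                    )
                )
                continue
            res = score_module(
                prof, ps, statistic=AFC, cfg=cfg,
                activation_threshold=z_threshold, rng=rng,
            )
            z = res.z_score
            if np.isnan(z):
                direction = "neutral"
            elif z > z_threshold:
                direction = "up"
            elif z < -z_threshold:
                direction = "down"
            else:
                direction = "neutral"
            rows.append(
                dict(
                    category=categories.get(ps.name, "other"),
                    pathway=ps.name,
                    condition=prof.condition.label,
                    n_genes_matched=res.n_genes_matched,
                    score=res.score,
                    z=z,
                    direction=direction,
                )
            )
    frame = pd.DataFrame(rows)
    return frame.sort_values(["category", "pathway", "condition"], kind="stable").reset_index(
        drop=True
    )
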