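"""Cross-condition and cross-species comparisons.

Given per-condition DEG sets and fold-change profiles this module builds
pairwise overlap matrices, the common-gene intersection across all
conditions, mean-fold-change gene rankings, PCA embeddings of fold-change
or module-score tables, and Pearson R^2 correlations between module-score
vectors from different platforms or species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .datatypes import DegSet, FoldChangeProfile, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapMatrix",
    "PcaEmbedding",
    "overlap_matrix",
    "common_genes",
    "rank_by_mean_fc",
    "correlate_scores",
    "pca_embed",
    "cluster_separation_check",
]


@dataclass
class OverlapMatrix:
    """Symmetric pairwise DEG-overlap counts; diagonal = own set sizes."""

    conditions: list[str]
    counts: pd.DataFrame


@dataclass
class PcaEmbedding:
    """Column-centred SVD embedding with a deterministic sign convention."""

    points: pd.DataFrame  # items x components
    explained_variance_fraction: np.ndarray
    components: pd.DataFrame  # components x features (loadings)
    mean: pd.Series


def overlap_matrix(deg_sets: Sequence[DegSet]) -> OverlapMatrix:
    """Pairwise intersection counts between DEG sets."""
    if not deg_sets:
        raise InvalidInputError("need at least one DEG set")
    labels = [d.condition.label for d in deg_sets]
    if len(set(labels)) != len(labels):
        raise InvalidInputError("duplicate condition labels in DEG sets")
    n = len(deg_sets)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i, n):
            c = len(deg_sets[i].gene_ids & deg_sets[j].gene_ids)
            counts[i, j] = counts[j, i] = c
    return OverlapMatrix(
        conditions=labels,
        counts=pd.DataFrame(counts, index=labels, columns=labels),
    )


def common_genes(deg_sets: Sequence[DegSet]) -> frozenset[str]:
    """Intersection of all provided DEG sets (empty result is valid)."""
    if len(deg_sets) < 2:
        raise InvalidInputError("need at least two DEG sets to intersect")
    out = set(deg_sets[0].gene_ids)
    for d in deg_sets[1:]:
        out &= d.gene_ids
    return frozenset(out)


def rank_by_mean_fc(
    genes: Sequence[str],
    profiles: Sequence[FoldChangeProfile],
    top_k: int | None = None,
) -> pd.DataFrame:
    """Rank genes by their mean log2 fold change across conditions.

    Genes missing from any profile are dropped with a warning. Returns a
    table sorted descending by mean_log2_fc with 1-based ranks; when
    ``top_k`` is given, only the top and bottom k rows are kept (the
    strongest up- and downregulated genes).
    """
    if not profiles:
        raise InvalidInputError("need at least one profile")
    genes = list(dict.fromkeys(genes))
    keep = []
    for g in genes:
        if all(g in p.gene_ids for p in profiles):
            keep.append(g)
        else:
            logger.warning("gene %s missing from a profile; dropped from ranking", g)
    if not keep:
        raise InvalidInputError("no gene present in every profile")
    means = {
        g: float(np.mean([p.table.loc[g, "log2_fc"] for p in profiles])) for g in keep
    }
    table = pd.DataFrame(
        {"gene_id": keep, "mean_log2_fc": [means[g] for g in keep],
         "n_conditions": len(profiles)}
    ).sort_values("mean_log2_fc", ascending=False, kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    if top_k is not None and 2 * top_k < len(table):
        table = pd.concat([table.head(top_k), table.tail(top_k)]).reset_index(drop=True)
    return table


def correlate_scores(v1: Sequence[float], v2: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation and R^2 between two score vectors."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise InvalidInputError("vectors must be 1-D, equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise InvalidInputError("correlation undefined for a zero-variance vector")
    r = float(stats.pearsonr(a, b).statistic)
    return r, r * r


def pca_embed(feature_table: pd.DataFrame, n_components: int | None = None) -> PcaEmbedding:
    """Column-centred PCA of an items x features table.

    Sign convention: the largest-magnitude loading of each component is
    made positive, so embeddings are deterministic across runs and
    platforms. Features are centred but not scaled.
    """
    X = feature_table.to_numpy(dtype=float)
    n_items, n_feat = X.shape
    if n_items < 2 or n_feat < 2:
        raise InvalidInputError("need at least 2 items and 2 features")
    if np.allclose(X, X[0]):
        raise InvalidInputError("feature table has zero variance")
    max_comp = min(n_items, n_feat)
    k = max_comp if n_components is None else n_components
    if not 1 <= k <= max_comp:
        raise InvalidInputError(f"n_components must be in [1, {max_comp}]")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    # deterministic sign: flip each component so its dominant loading is positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PcaEmbedding(
        points=pd.DataFrame(scores, index=feature_table.index, columns=comp_names),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        components=pd.DataFrame(loadings, index=comp_names, columns=feature_table.columns),
        mean=pd.Series(pca.mean_, index=feature_table.columns),
    )


def cluster_separation_check(
    embedding: PcaEmbedding, grouping: Mapping[str, str]
) -> tuple[float, bool]:
    """Mean silhouette coefficient of the grouping in the first two PCs.

    Quantifies visually-claimed cluster separation. Returns (score,
    all_singletons_flag); when every group has a single member the
    silhouette is 0 by convention and the flag is set.
    """
    items = list(embedding.points.index)
    labels = [grouping[i] for i in items]
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise InvalidInputError("need at least two groups")
    coords = embedding.points.iloc[:, : min(2, embedding.points.shape[1])].to_numpy()
    sizes = pd.Series(labels).value_counts()
    if (sizes == 1).all():
        logger.warning("all groups are singletons; silhouette is 0 by convention")
        return 0.0, True
    if len(uniq) == len(items):
        return 0.0, True
    sil = silhouette_samples(coords, labels)
    return float(np.mean(sil)), False
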