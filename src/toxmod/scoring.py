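"""Gene-set activation scoring with AAFC/AFC statistics and permutation nulls.

A module's AAFC (aggregated absolute fold-change) score is the mean of
|log2 FC| over its genes — a direction-blind measure of how much the set
moved. The AFC (aggregate fold-change) score is the mean of the signed
log2 FC — positive for net upregulation. Each observed score is compared
with a null distribution built by repeatedly drawing random gene subsets
of the same size from the measured universe (10,000 draws by default);
the activation z-score is the number of null standard deviations the
observed score sits above the null mean, with z > 2 called activated.
Small instances switch automatically to exhaustive subset enumeration,
which makes the null exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    Condition,
    FoldChangeProfile,
    GeneSet,
    GeneSetCollection,
    InvalidInputError,
)
from .synthetic import child_rng

logger = logging.getLogger(__name__)

__all__ = [
    "NullConfig",
    "NullDistribution",
    "ModuleActivationResult",
    "match_genes",
    "aafc_score",
    "afc_score",
    "permutation_null",
    "score_module",
    "score_all_modules",
]

AAFC = "AAFC"
AFC = "AFC"
_STATS = {AAFC, AFC}


@dataclass(frozen=True)
class NullConfig:
    """Permutation-null settings.

    ``n_resamples`` random same-size gene subsets define the null
    (default 10,000). When the number of possible subsets is at most
    ``exhaustive_limit`` the null is enumerated exactly instead.
    """

    n_resamples: int = 10_000
    seed: int = 0
    exhaustive_limit: int = 200_000

    def __post_init__(self) -> None:
        if self.n_resamples < 100:
            raise InvalidInputError("n_resamples must be >= 100")


@dataclass
class NullDistribution:
    mean: float
    sd: float
    scores: np.ndarray
    exhaustive: bool


@dataclass
class ModuleActivationResult:
    """Activation read-out for one module under one condition.

    ``z_score`` and ``p_empirical`` are NaN when the null is degenerate
    (zero spread), in which case ``activated`` is False.
    """

    module: str
    condition: Condition | None
    statistic: str
    n_genes_in_set: int
    n_genes_matched: int
    score: float
    null_mean: float
    null_sd: float
    z_score: float
    p_empirical: float
    activated: bool


def match_genes(gene_set: GeneSet | Iterable[str], profile: FoldChangeProfile) -> list[str]:
    """Case-insensitive intersection of a gene set with the profile's genes.

    Returns the matching identifiers as they are spelled in the profile.
    """
    members = gene_set.gene_ids if isinstance(gene_set, GeneSet) else gene_set
    wanted = {str(g).casefold() for g in members}
    return [g for g in profile.gene_ids if str(g).casefold() in wanted]


def _matched_fc(profile: FoldChangeProfile, genes: Sequence[str]) -> np.ndarray:
    if len(genes) == 0:
        raise InvalidInputError("cannot score an empty gene list")
    return profile.table.loc[list(genes), "log2_fc"].to_numpy(dtype=float)


def aafc_score(profile: FoldChangeProfile, genes: Sequence[str]) -> float:
    """Mean absolute log2 fold change over the matched genes."""
    return float(np.mean(np.abs(_matched_fc(profile, genes))))


def afc_score(profile: FoldChangeProfile, genes: Sequence[str]) -> float:
    """Mean signed log2 fold change over the matched genes."""
    return float(np.mean(_matched_fc(profile, genes)))


def _stat_values(fc: np.ndarray, statistic: str) -> np.ndarray:
    if statistic == AAFC:
        return np.abs(fc)
    if statistic == AFC:
        return fc
    raise InvalidInputError(f"unknown statistic {statistic!r}")


def permutation_null(
    profile: FoldChangeProfile,
    set_size: int,
    statistic: str = AAFC,
    cfg: NullConfig = NullConfig(),
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Null distribution of the set statistic over random same-size subsets.

    Subsets are drawn without replacement from the profile's measured
    genes. Exhaustive enumeration replaces Monte-Carlo sampling when the
    number of distinct subsets is within ``cfg.exhaustive_limit``; the
    exhaustive spread uses the population standard deviation since the
    whole null population is in hand, while Monte-Carlo uses the n-1
    sample estimator.
    """
    fc = profile.log2_fc.to_numpy(dtype=float)
    m = fc.size
    if not 1 <= set_size <= m:
        raise InvalidInputError(f"set_size {set_size} outside [1, {m}]")
    vals = _stat_values(fc, statistic)

    n_subsets = math.comb(m, set_size)
    if n_subsets <= cfg.exhaustive_limit:
        idx = np.fromiter(
            (i for combo in combinations(range(m), set_size) for i in combo),
            dtype=np.int64,
            count=n_subsets * set_size,
        ).reshape(n_subsets, set_size)
        scores = vals[idx].mean(axis=1)
        return NullDistribution(
            mean=float(scores.mean()),
            sd=float(scores.std(ddof=0)),
            scores=scores,
            exhaustive=True,
        )

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    scores = np.empty(cfg.n_resamples)
    for i in range(cfg.n_resamples):
        scores[i] = vals[rng.choice(m, size=set_size, replace=False)].mean()
    return NullDistribution(
        mean=float(scores.mean()),
        sd=float(scores.std(ddof=1)),
        scores=scores,
        exhaustive=False,
    )


def _empirical_p(
    obs: float, null: NullDistribution, statistic: str
) -> float:
    """Empirical tail probability: upper-tailed for AAFC, two-sided around
    the null mean for AFC (both directions of regulation are meaningful).
    Ties count toward the tail; Monte-Carlo estimates carry the
    (r+1)/(N+1) correction, exhaustive nulls are exact."""
    if statistic == AAFC:
        r = int(np.sum(null.scores >= obs))
    else:
        r = int(np.sum(np.abs(null.scores - null.mean) >= abs(obs - null.mean)))
    n = null.scores.size
    if null.exhaustive:
        return r / n
    return (r + 1) / (n + 1)


def score_module(
    profile: FoldChangeProfile,
    gene_set: GeneSet,
    statistic: str = AAFC,
    cfg: NullConfig = NullConfig(),
    activation_threshold: float = 2.0,
    rng: np.random.Generator | None = None,
) -> ModuleActivationResult:
    """Score one module on one fold-change profile.

    z = (score - null_mean) / null_sd; activated when z exceeds the
    threshold (default 2). A degenerate null (sd = 0, e.g. the module is
    the whole universe or the profile is constant) yields NaN z and p and
    an unactivated call, with a warning.
    """
    matched = match_genes(gene_set, profile)
    if not matched:
        raise InvalidInputError(
            f"module {gene_set.name!r} shares no genes with the profile"
        )
    score_fn = aafc_score if statistic == AAFC else afc_score
    if statistic not in _STATS:
        raise InvalidInputError(f"unknown statistic {statistic!r}")
    obs = score_fn(profile, matched)
    null = permutation_null(profile, len(matched), statistic, cfg, rng=rng)
    if null.sd > 0:
        z = (obs - null.mean) / null.sd
        p = _empirical_p(obs, null, statistic)
        activated = bool(z > activation_threshold)
    else:
        logger.warning(
            "module %s: degenerate null (sd = 0); z undefined", gene_set.name
        )
        z, p, activated = float("nan"), float("nan"), False
    return ModuleActivationResult(
        module=gene_set.name,
        condition=profile.condition,
        statistic=statistic,
        n_genes_in_set=len(gene_set),
        n_genes_matched=len(matched),
        score=obs,
        null_mean=null.mean,
        null_sd=null.sd,
        z_score=z,
        p_empirical=p,
        activated=activated,
    )


def score_all_modules(
    profiles: Sequence[FoldChangeProfile],
    collection: GeneSetCollection,
    statistic: str = AAFC,
    cfg: NullConfig = NullConfig(),
    activation_threshold: float = 2.0,
) -> tuple[pd.DataFrame, list[ModuleActivationResult]]:
    """Score every module against every condition profile.

    Returns the module x condition z-score table plus the full result
    records. Each (module, condition) cell draws its null from an
    independent child stream derived from the top-level seed, so cells are
    reproducible regardless of evaluation order. Per-cell failures (e.g.
    a module with no measured genes) become NaN cells, not run failures.
    """
    results: list[ModuleActivationResult] = []
    cond_labels = [p.condition.label for p in profiles]
    table = pd.DataFrame(
        np.nan, index=pd.Index(collection.names, name="module"), columns=cond_labels
    )
    for prof in profiles:
        for gene_set in collection:
            rng = child_rng(cfg.seed, gene_set.name, prof.condition.label)
            try:
                res = score_module(
                    prof, gene_set, statistic, cfg, activation_threshold, rng=rng
                )
            except InvalidInputError as exc:
                logger.warning(
                    "skipping %s / %s: %s", gene_set.name, prof.condition.label, exc
                )
                continue
            results.append(res)
            table.loc[gene_set.name, prof.condition.label] = res.z_score
    return table, results


def results_to_frame(results: Sequence[ModuleActivationResult]) -> pd.DataFrame:
    """Long-form table of all fields of a batch of activation results."""
    return pd.DataFrame(
        {
            "module": [r.module for r in results],
            "condition": [r.condition.label if r.condition else "" for r in results],
            "statistic": [r.statistic for r in results],
            "n_genes_in_set": [r.n_genes_in_set for r in results],
            "n_genes_matched": [r.n_genes_matched for r in results],
            "score": [r.score for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "z_score": [r.z_score for r in results],
            "p_empirical": [r.p_empirical for r in results],
            "activated": [r.activated for r in results],
        }
    )
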