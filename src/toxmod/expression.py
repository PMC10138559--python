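"""Per-gene differential expression: fold changes, Welch tests, FDR, DEG calls.

The fold change of a gene is the difference between the mean log2
expression of the treated and control cohorts. Significance uses a Welch
unequal-variance two-sample t-test on the log2 values, with
Benjamini-Hochberg FDR adjustment; genes at q <= 0.1 (default) are called
differentially expressed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    CohortPair,
    DegSet,
    ExpressionMatrix,
    FoldChangeProfile,
    InvalidInputError,
    StateError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "log_transform",
    "fold_changes",
    "de_test",
    "bh_adjust",
    "call_degs",
    "differential_expression",
]


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Return a log2(x + pseudocount) copy of a raw abundance matrix.

    Applying this to an already-log2 matrix is a state error, not a silent
    no-op: double-transformed values would corrupt every downstream fold
    change.
    """
    if m.is_log2:
        raise StateError("matrix is already log2-transformed")
    arr = m.values.to_numpy()
    if np.nanmin(arr) < 0:
        raise InvalidInputError("raw abundance values must be >= 0")
    out = np.log2(arr + m.pseudocount)
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        is_log2=True,
        pseudocount=m.pseudocount,
    )


def _cohort_arrays(
    m: ExpressionMatrix, pair: CohortPair
) -> tuple[pd.Index, np.ndarray, np.ndarray, int]:
    """Split the matrix into control/treated arrays, dropping genes with
    missing values in either cohort."""
    if not m.is_log2:
        raise StateError("fold changes require a log2-transformed matrix")
    pair.validate_against(m)
    ctrl = m.values[list(pair.control_samples)].to_numpy(dtype=float)
    trt = m.values[list(pair.treated_samples)].to_numpy(dtype=float)
    usable = (~np.isnan(ctrl)).all(axis=1) & (~np.isnan(trt)).all(axis=1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d gene(s) with missing values", pair.condition.label, n_dropped
        )
    genes = m.gene_ids[usable]
    if len(genes) == 0:
        raise InvalidInputError("no genes with complete data in both cohorts")
    return genes, ctrl[usable], trt[usable], n_dropped


def fold_changes(m: ExpressionMatrix, pair: CohortPair) -> FoldChangeProfile:
    """Per-gene log2 fold change: mean(treated) - mean(control)."""
    genes, ctrl, trt, n_dropped = _cohort_arrays(m, pair)
    fc = trt.mean(axis=1) - ctrl.mean(axis=1)
    table = pd.DataFrame({"log2_fc": fc}, index=genes)
    return FoldChangeProfile(condition=pair.condition, table=table, n_dropped=n_dropped)


def de_test(m: ExpressionMatrix, pair: CohortPair) -> FoldChangeProfile:
    """Fold changes plus two-sided Welch t-test p-values.

    Degenerate genes (zero variance in both cohorts) get p = 1 when the
    cohort means are equal — no evidence of change — and p = 0 when they
    differ, the limit of the t statistic as the pooled variance vanishes.
    """
    genes, ctrl, trt, n_dropped = _cohort_arrays(m, pair)
    fc = trt.mean(axis=1) - ctrl.mean(axis=1)
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate (zero-variance) genes are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(trt, ctrl, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = (ctrl.var(axis=1, ddof=1) == 0) & (trt.var(axis=1, ddof=1) == 0)
    p[zero_var & (fc == 0)] = 1.0
    p[zero_var & (fc != 0)] = 0.0
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    table = pd.DataFrame({"log2_fc": fc, "p_value": p}, index=genes)
    return FoldChangeProfile(condition=pair.condition, table=table, n_dropped=n_dropped)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(profile: FoldChangeProfile, q_threshold: float = 0.1) -> DegSet:
    """Genes with q-value at or below the threshold (inclusive cut)."""
    if not profile.has_q_values:
        raise StateError("profile has no q-values; run de_test + bh_adjust first")
    q = profile.table["q_value"]
    genes = frozenset(profile.gene_ids[(q <= q_threshold).to_numpy()])
    return DegSet(condition=profile.condition, gene_ids=genes, q_threshold=q_threshold)


def differential_expression(
    m: ExpressionMatrix, pair: CohortPair, q_threshold: float = 0.1
) -> tuple[FoldChangeProfile, DegSet]:
    """Convenience: Welch test, BH adjustment and DEG call in one step."""
    profile = de_test(m, pair)
    profile.table["q_value"] = bh_adjust(profile.table["p_value"].to_numpy())
    return profile, call_degs(profile, q_threshold)
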