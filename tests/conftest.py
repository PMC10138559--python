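import numpy as np
import pandas as pd
import pytest

from toxmod.datatypes import Condition, FoldChangeProfile


def make_profile(fc_by_gene: dict[str, float], condition: Condition | None = None,
                 p_values: dict[str, float] | None = None) -> FoldChangeProfile:
    """Build a FoldChangeProfile from a gene -> log2 FC mapping."""
    cond = condition or Condition("in_vivo", "high", "long")
    table = pd.DataFrame({"log2_fc": pd.Series(fc_by_gene, dtype=float)})
    table.index.name = "gene_id"
    if p_values is not None:
        table["p_value"] = pd.Series(p_values, dtype=float)
    return FoldChangeProfile(condition=cond, table=table)


def random_profile(n_genes: int, rng: np.random.Generator,
                   scale: float = 1.0) -> FoldChangeProfile:
    genes = [f"G{i:05d}" for i in range(n_genes)]
    return make_profile(dict(zip(genes, rng.normal(0, scale, n_genes))))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_profile() -> FoldChangeProfile:
    return make_profile({"g1": 1.0, "g2": 2.0, "g3": 3.0, "g4": 4.0})
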