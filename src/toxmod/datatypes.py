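"""Core containers shared across the pipeline.

Everything downstream operates on log2-scale expression values: an
:class:`ExpressionMatrix` holds gene x sample abundances, a
:class:`CohortPair` names the control and treated samples of one
experimental condition, and a :class:`FoldChangeProfile` carries the
per-gene log2 fold changes (and, once testing has run, p- and q-values)
for that condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd


class ToxmodError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ToxmodError, ValueError):
    """Raised when an input value violates an operation's contract."""


class StateError(ToxmodError, RuntimeError):
    """Raised when an operation is applied to an object in the wrong state."""


class Condition(NamedTuple):
    """One experimental condition: (platform, dose, time)."""

    platform: str
    dose: str
    time: str

    @property
    def label(self) -> str:
        return f"{self.platform}_{self.dose}_{self.time}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        parts = label.split("_")
        if len(parts) < 3:
            raise InvalidInputError(f"cannot parse condition label {label!r}")
        # platform may itself contain underscores (e.g. "in_vivo")
        return cls("_".join(parts[:-2]), parts[-2], parts[-1])


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
    is_log2
        True when values are already on the log2 scale.
    pseudocount
        Offset added before log-transforming raw abundances.
    """

    values: pd.DataFrame
    is_log2: bool = False
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise InvalidInputError(f"duplicate gene identifiers: {dups[:5]}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise InvalidInputError(f"duplicate sample identifiers: {dups[:5]}")
        arr = self.values.to_numpy()
        if self.is_log2:
            if not np.isfinite(arr[~np.isnan(arr)]).all():
                raise InvalidInputError("log2 matrix contains non-finite values")
        else:
            if np.nanmin(arr) < 0 if arr.size else False:
                raise InvalidInputError("raw abundance matrix contains negative values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class CohortPair:
    """Control and treated sample IDs for one condition."""

    condition: Condition
    control_samples: tuple[str, ...]
    treated_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        ctrl, trt = set(self.control_samples), set(self.treated_samples)
        if ctrl & trt:
            raise InvalidInputError("control and treated sample sets overlap")
        if len(ctrl) < 2 or len(trt) < 2:
            raise InvalidInputError("each cohort needs at least 2 samples")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = (set(self.control_samples) | set(self.treated_samples)) - set(
            matrix.sample_ids
        )
        if missing:
            raise InvalidInputError(f"samples absent from matrix: {sorted(missing)}")


@dataclass
class FoldChangeProfile:
    """Per-gene log2 fold changes for one condition.

    ``table`` is indexed by gene identifier with a ``log2_fc`` column and,
    after differential-expression testing, ``p_value`` and ``q_value``
    columns. ``n_dropped`` counts genes excluded for missing values.
    """

    condition: Condition
    table: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if "log2_fc" not in self.table.columns:
            raise InvalidInputError("profile table must have a log2_fc column")
        if not np.isfinite(self.table["log2_fc"].to_numpy()).all():
            raise InvalidInputError("log2_fc must be finite for every tested gene")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def log2_fc(self) -> pd.Series:
        return self.table["log2_fc"]

    @property
    def genes_tested(self) -> int:
        return len(self.table)

    @property
    def has_q_values(self) -> bool:
        return "q_value" in self.table.columns


@dataclass(frozen=True)
class DegSet:
    """Differentially expressed genes of one condition at a q cutoff."""

    condition: Condition
    gene_ids: frozenset[str]
    q_threshold: float

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise InvalidInputError(f"gene set {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidInputError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets: injury modules or pathways."""

    sets: list[GeneSet]
    kind: str = "injury_module"  # or "pathway"

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise InvalidInputError("gene set names must be unique")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]
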