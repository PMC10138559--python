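"""Readers and writers for the pipeline's plain-text formats.

Formats: expression matrix TSV (first column ``gene_id``), sample sheet
CSV (``sample_id,platform,dose,time,cohort``), GMT gene-set files,
fold-change profile TSV, module score tables, JSON run manifests and YAML
configs. Data files serialise floats at 6 significant digits; report
tables round to 2 decimals.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    CohortPair,
    Condition,
    ExpressionMatrix,
    FoldChangeProfile,
    GeneSet,
    GeneSetCollection,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "cohort_pairs_from_sheet",
    "read_gmt",
    "write_gmt",
    "read_profile_tsv",
    "write_profile_tsv",
    "write_table",
    "write_manifest",
    "load_config_yaml",
    "load_reference_module_scores",
    "file_sha256",
]

_FLOAT_FMT = "%.6g"


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Parse a gene x sample TSV into an (assumed log2) expression matrix."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise InvalidInputError(f"expression file missing or empty: {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise InvalidInputError(f"{path}: need a gene_id column plus >= 1 sample")
    gene_col = df.columns[0]
    dup = df[gene_col][df[gene_col].duplicated()]
    if not dup.empty:
        raise InvalidInputError(f"{path}: duplicated gene id(s): {dup.tolist()[:5]}")
    df = df.set_index(gene_col)
    df.index.name = "gene_id"
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise InvalidInputError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
    return ExpressionMatrix(values=df.astype(float), is_log2=True)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    # full shortest-roundtrip precision: expression values must survive
    # write -> read bit-identically so reruns from disk reproduce results
    matrix.values.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet CSV: sample_id, platform, dose, time, cohort."""
    sheet = pd.read_csv(path, dtype=str)
    required = {"sample_id", "platform", "dose", "time", "cohort"}
    missing = required - set(sheet.columns)
    if missing:
        raise InvalidInputError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(sheet["cohort"]) - {"control", "treated"}
    if bad:
        raise InvalidInputError(f"cohort must be control/treated; found {sorted(bad)}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def cohort_pairs_from_sheet(sheet: pd.DataFrame) -> list[CohortPair]:
    """One CohortPair per treated (platform, dose, time) condition.

    Control samples carry dose ``control`` in the sheet and are shared by
    every treated dose of the same (platform, time).
    """
    treated = sheet[sheet["cohort"] == "treated"]
    ctrl = sheet[sheet["cohort"] == "control"]
    pairs = []
    for (platform, dose, time), grp in treated.groupby(
        ["platform", "dose", "time"], sort=True
    ):
        matching = ctrl[(ctrl["platform"] == platform) & (ctrl["time"] == time)]
        pairs.append(
            CohortPair(
                condition=Condition(platform, dose, time),
                control_samples=tuple(matching["sample_id"]),
                treated_samples=tuple(grp["sample_id"]),
            )
        )
    return pairs


def read_gmt(path: str | Path, kind: str = "injury_module") -> GeneSetCollection:
    """Parse a GMT file: name, description, then tab-separated gene IDs.

    Duplicate genes within a set are dropped with a warning; duplicate set
    names are an error.
    """
    path = Path(path)
    sets = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidInputError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in seen:
                raise InvalidInputError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                logger.warning("%s:%d: set %s has duplicate genes; deduplicated",
                               path, lineno, name)
            sets.append(GeneSet(name=name, description=desc, gene_ids=tuple(uniq)))
    return GeneSetCollection(sets=sets, kind=kind)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.gene_ids]) + "\n")


def read_profile_tsv(path: str | Path) -> FoldChangeProfile:
    """Read a per-condition fold-change profile written by this package."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    if "log2_fc" not in df.columns:
        raise InvalidInputError(f"{path}: missing log2_fc column")
    condition = Condition.from_label(path.stem.replace("profile_", ""))
    return FoldChangeProfile(condition=condition, table=df)


def write_profile_tsv(profile: FoldChangeProfile, out_dir: str | Path) -> Path:
    out = Path(out_dir) / f"profile_{profile.condition.label}.tsv"
    profile.table.to_csv(out, sep="\t", float_format=_FLOAT_FMT)
    return out


def write_table(df: pd.DataFrame, path: str | Path, report: bool = False,
                index: bool = True) -> None:
    """Write a TSV; report tables use 2-decimal floats, data tables 6 s.f."""
    fmt = "%.2f" if report else _FLOAT_FMT
    df.to_csv(path, sep="\t", float_format=fmt, index=index)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InvalidInputError(f"{path}: config must be a flat YAML mapping")
    return cfg


def load_reference_module_scores() -> pd.DataFrame:
    """Bundled kidney injury-module activation z-scores from a published
    guinea-pig mercuric-chloride study (in vivo and in vitro platforms,
    two doses x two exposure times). Rows are the eight injury modules;
    columns are condition labels like ``invivo_33h_HD``."""
    ref = resources.files("toxmod") / "data" / "guineapig_kidney_module_zscores.tsv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", index_col=0)
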