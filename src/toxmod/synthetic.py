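"""Synthetic toxicogenomic experiment generator.

Emulates a two-platform (in vivo / in vitro) dose-response design: for each
(platform, dose, time) condition a small control cohort and a small treated
cohort are drawn from a ~10^4-gene universe. A minority of genes — organised
into injury-module-like sets — carry planted log2 shifts whose size scales
with dose and exposure-time multipliers; all other genes are null. Noise is
additive Gaussian on the log2 scale, the simplest model under which the
mean-difference fold change is unbiased, so every planted effect is exactly
recoverable in expectation and the generator can serve as ground truth for
the differential-expression and module-scoring stages.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    CohortPair,
    Condition,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    InvalidInputError,
)

__all__ = [
    "SimulationDesign",
    "PlantedEffect",
    "SyntheticTruth",
    "generate_gene_sets",
    "simulate_experiment",
    "default_effects",
]


def child_rng(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic child RNG stream for a (seed, labels...) key.

    Streams depend only on the key, never on call order, so results are
    identical whichever order conditions or modules are processed in.
    """
    key = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(lb.encode()) for lb in labels]
    return np.random.default_rng(np.random.SeedSequence(key))


@dataclass(frozen=True)
class SimulationDesign:
    """Design of the simulated experiment.

    Dose and time multipliers scale planted effect sizes; a control cohort
    always has multiplier 0. Defaults follow the emulated study layout:
    two platforms x two doses x two exposure times with cohorts of three.
    """

    n_genes: int = 10_000
    platforms: tuple[str, ...] = ("in_vivo", "in_vitro")
    doses: tuple[tuple[str, float], ...] = (("low", 1.0), ("high", 1.5))
    times: tuple[tuple[str, float], ...] = (("short", 1.0), ("long", 1.5))
    n_control: int = 3
    n_treated: int = 3
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidInputError("n_genes must be >= 1")
        if self.n_control < 2 or self.n_treated < 2:
            raise InvalidInputError("cohort sizes must be >= 2")
        for name, mult in list(self.doses) + list(self.times):
            if not np.isfinite(mult) or mult < 0:
                raise InvalidInputError(f"multiplier for {name!r} must be finite and >= 0")
            if name == "control" and mult != 0:
                raise InvalidInputError("control multiplier must be 0")
        if self.noise_sd < 0 or self.baseline_log_sd < 0:
            raise InvalidInputError("standard deviations must be >= 0")

    @property
    def universe(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    @property
    def conditions(self) -> list[Condition]:
        return [
            Condition(p, d, t)
            for p in self.platforms
            for d, _ in self.doses
            for t, _ in self.times
        ]

    def multiplier(self, dose: str, time: str) -> float:
        dm = dict(self.doses).get(dose)
        tm = dict(self.times).get(time)
        if dm is None or tm is None:
            raise InvalidInputError(f"unknown dose/time: {dose!r}/{time!r}")
        return dm * tm


@dataclass(frozen=True)
class PlantedEffect:
    """A module-linked perturbation planted into the simulation.

    ``effect_log2`` is the base shift at multiplier 1; ``direction_mix`` is
    the fraction of member genes shifted in the effect's own direction (the
    rest are flipped), defaulting to mostly-upregulated modules.
    """

    module_name: str
    gene_ids: tuple[str, ...]
    effect_log2: float
    direction_mix: float = 0.8

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect_log2):
            raise InvalidInputError("effect_log2 must be finite")
        if not 0.0 <= self.direction_mix <= 1.0:
            raise InvalidInputError("direction_mix must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the simulated matrices."""

    design: SimulationDesign
    effects: list[PlantedEffect]
    realized_effect_table: pd.DataFrame  # genes x condition labels, signed log2 shifts
    seed: int

    @property
    def planted_genes(self) -> frozenset[str]:
        return frozenset(g for e in self.effects for g in e.gene_ids)

    @property
    def null_genes(self) -> frozenset[str]:
        return frozenset(self.design.universe) - self.planted_genes


def generate_gene_sets(
    n_modules: int,
    sizes: list[int],
    universe: list[str],
    seed: int,
    kind: str = "injury_module",
    prefix: str = "module",
) -> GeneSetCollection:
    """Sample ``n_modules`` named gene sets of the given sizes from ``universe``.

    Sets are drawn independently (they may overlap). Reproducible: the same
    seed yields the identical collection.
    """
    if len(sizes) != n_modules:
        raise InvalidInputError("sizes must have one entry per module")
    universe = list(universe)
    for sz in sizes:
        if sz < 1 or sz > len(universe):
            raise InvalidInputError(f"set size {sz} outside [1, {len(universe)}]")
    rng = np.random.default_rng(seed)
    sets = []
    for i, sz in enumerate(sizes):
        members = rng.choice(len(universe), size=sz, replace=False)
        sets.append(
            GeneSet(
                name=f"{prefix}_{i + 1}",
                description=f"synthetic {kind} of {sz} genes",
                gene_ids=tuple(universe[j] for j in sorted(members)),
            )
        )
    return GeneSetCollection(sets=sets, kind=kind)


def _effect_signs(effect: PlantedEffect, seed: int) -> np.ndarray:
    """Deterministic +1/-1 sign per member gene honouring direction_mix."""
    n = len(effect.gene_ids)
    n_flip = int(round((1.0 - effect.direction_mix) * n))
    rng = child_rng(seed, "signs", effect.module_name)
    signs = np.ones(n)
    if n_flip > 0:
        flip = rng.choice(n, size=n_flip, replace=False)
        signs[flip] = -1.0
    return signs


def realized_effects(
    design: SimulationDesign, effects: list[PlantedEffect]
) -> pd.DataFrame:
    """Gene x condition table of planted signed log2 shifts.

    The shift of gene g in condition c is
    ``sign(g) * effect_log2 * dose_multiplier(c) * time_multiplier(c)``;
    genes in no planted effect shift by 0 everywhere. Shifts are fixed per
    gene (not resampled per sample) so the truth is exact.
    """
    universe = design.universe
    known = set(universe)
    conditions = design.conditions
    table = pd.DataFrame(
        0.0, index=pd.Index(universe, name="gene_id"), columns=[c.label for c in conditions]
    )
    for eff in effects:
        unknown = set(eff.gene_ids) - known
        if unknown:
            raise InvalidInputError(
                f"effect {eff.module_name!r} references unknown genes: {sorted(unknown)[:5]}"
            )
        signs = _effect_signs(eff, design.seed)
        base = signs * eff.effect_log2
        for cond in conditions:
            mult = design.multiplier(cond.dose, cond.time)
            table.loc[list(eff.gene_ids), cond.label] += base * mult
    return table


def simulate_experiment(
    design: SimulationDesign, effects: list[PlantedEffect]
) -> tuple[dict[Condition, tuple[ExpressionMatrix, CohortPair]], SyntheticTruth]:
    """Simulate log2 expression matrices for every condition of the design.

    For each (platform, dose, time) condition the returned matrix holds
    ``n_control + n_treated`` samples; gene g's log2 expression is
    ``baseline(g) + shift(g, condition) [treated only] + N(0, noise_sd)``.
    Baselines are drawn once and shared across conditions, mimicking a
    common transcriptome. Fully reproducible from ``design.seed``.
    """
    shifts = realized_effects(design, effects)
    universe = design.universe
    base_rng = child_rng(design.seed, "baseline")
    baseline = design.baseline_log_mean + design.baseline_log_sd * base_rng.standard_normal(
        design.n_genes
    )
    gene_index = pd.Index(universe, name="gene_id")
    n_c, n_t = design.n_control, design.n_treated

    # one control cohort per (platform, time), shared across doses
    controls: dict[tuple[str, str], pd.DataFrame] = {}
    for platform in design.platforms:
        for time, _ in design.times:
            rng = child_rng(design.seed, "control", platform, time)
            noise = rng.standard_normal((design.n_genes, n_c)) * design.noise_sd
            ids = [f"{platform}_control_{time}_c{i + 1}" for i in range(n_c)]
            controls[(platform, time)] = pd.DataFrame(
                baseline[:, None] + noise, index=gene_index, columns=ids
            )

    out: dict[Condition, tuple[ExpressionMatrix, CohortPair]] = {}
    for cond in design.conditions:
        rng = child_rng(design.seed, "noise", cond.label)
        noise = rng.standard_normal((design.n_genes, n_t)) * design.noise_sd
        treated = baseline[:, None] + noise + shifts[cond.label].to_numpy()[:, None]
        trt_ids = [f"{cond.label}_t{i + 1}" for i in range(n_t)]
        ctrl = controls[(cond.platform, cond.time)]
        df = pd.concat(
            [ctrl, pd.DataFrame(treated, index=gene_index, columns=trt_ids)], axis=1
        )
        matrix = ExpressionMatrix(values=df, is_log2=True)
        pair = CohortPair(
            condition=cond,
            control_samples=tuple(ctrl.columns),
            treated_samples=tuple(trt_ids),
        )
        out[cond] = (matrix, pair)

    truth = SyntheticTruth(
        design=design, effects=list(effects), realized_effect_table=shifts, seed=design.seed
    )
    return out, truth


def default_effects(
    design: SimulationDesign,
    n_modules: int = 8,
    module_size: int = 50,
    effect_log2: float = 2.0,
    n_active: int = 5,
    direction_mix: float = 0.8,
) -> tuple[GeneSetCollection, list[PlantedEffect]]:
    """Build a stand-in injury-module collection with the first ``n_active``
    modules planted and the rest left null — the typical test-bed layout.

    Modules are drawn from the upper half of the gene universe index range
    only in the sense of random sampling; planted and null modules are
    disjointly sampled so null modules contain no perturbed genes.
    """
    universe = design.universe
    rng = np.random.default_rng(design.seed + 1)
    order = rng.permutation(design.n_genes)
    needed = n_modules * module_size
    if needed > design.n_genes:
        raise InvalidInputError("gene universe too small for requested modules")
    sets = []
    effects = []
    for i in range(n_modules):
        members = tuple(
            universe[j] for j in sorted(order[i * module_size : (i + 1) * module_size])
        )
        name = f"module_{i + 1}"
        sets.append(
            GeneSet(name=name, description="synthetic injury module", gene_ids=members)
        )
        if i < n_active:
            effects.append(
                PlantedEffect(
                    module_name=name,
                    gene_ids=members,
                    effect_log2=effect_log2,
                    direction_mix=direction_mix,
                )
            )
    return GeneSetCollection(sets=sets, kind="injury_module"), effects
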