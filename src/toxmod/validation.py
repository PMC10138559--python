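"""Self-validation experiments for the scoring pipeline.

Each function runs a seeded synthetic experiment through the package's
own stages and measures a calibration or recovery property: type-I error
of the permutation null, power on planted injury modules, agreement of
the Monte-Carlo null with exhaustive enumeration, uniformity of the DE
p-values under the null, the dose monotonicity of DEG counts and module
z-scores, and end-to-end determinism. These back the package's claims
about its own statistics and double as reproducible benchmarks.
"""

from __future__ import annotations

import filecmp
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .comparative import correlate_scores
from .datatypes import GeneSet
from .expression import bh_adjust, de_test, differential_expression, fold_changes
from .io import load_reference_module_scores
from .pipeline import RunConfig, run_pipeline
from .scoring import AAFC, NullConfig, permutation_null, score_all_modules, score_module
from .synthetic import (
    SimulationDesign,
    child_rng,
    default_effects,
    generate_gene_sets,
    simulate_experiment,
)

__all__ = [
    "reference_score_correlation",
    "null_calibration",
    "planted_recovery",
    "mc_vs_exhaustive",
    "de_null_uniformity",
    "bh_vs_reference_stepup",
    "dose_monotonicity",
    "pipeline_determinism",
]


def _single_condition_design(n_genes: int, seed: int, noise_sd: float = 0.5,
                             n: int = 3) -> SimulationDesign:
    return SimulationDesign(
        n_genes=n_genes, platforms=("in_vivo",), doses=(("low", 1.0),),
        times=(("short", 1.0),), n_control=n, n_treated=n,
        noise_sd=noise_sd, seed=seed,
    )


def reference_score_correlation() -> tuple[float, float]:
    """R^2 between the bundled in vivo 33-h high-dose and in vitro 24-h
    high-dose module z-score columns of the published guinea-pig study."""
    ref = load_reference_module_scores()
    return correlate_scores(ref["invivo_33h_HD"], ref["invitro_24h_HD"])


def null_calibration(
    seed: int,
    n_genes: int = 5000,
    n_modules: int = 100,
    module_size: int = 50,
    n_resamples: int = 10_000,
) -> dict[str, float]:
    """Type-I behaviour: score random modules on a no-effect profile.

    Returns the fraction of modules with empirical p < 0.05 and with
    z > 2; both should sit near the nominal 5% level.
    """
    design = _single_condition_design(n_genes, seed)
    data, _ = simulate_experiment(design, [])
    matrix, pair = data[design.conditions[0]]
    profile = fold_changes(matrix, pair)
    coll = generate_gene_sets(n_modules, [module_size] * n_modules,
                              design.universe, seed=seed + 1)
    cfg = NullConfig(n_resamples=n_resamples, seed=seed + 2)
    _, results = score_all_modules([profile], coll, AAFC, cfg)
    p = np.array([r.p_empirical for r in results])
    z = np.array([r.z_score for r in results])
    return {
        "p_lt_05_rate": float((p < 0.05).mean()),
        "z_gt_2_rate": float((z > 2).mean()),
        "n_modules": n_modules,
    }


def planted_recovery(
    seed: int,
    n_replicates: int = 100,
    n_genes: int = 5000,
    module_size: int = 50,
    effect_log2: float = 2.0,
    n_resamples: int = 10_000,
) -> dict[str, float]:
    """Power: replicates with one planted module (and one null module)
    at cohort size 3v3, noise 0.5 log2 units; counts activation calls."""
    activated_planted = activated_null = 0
    for rep in range(n_replicates):
        design = _single_condition_design(n_genes, seed + rep)
        modules, effects = default_effects(
            design, n_modules=2, module_size=module_size,
            effect_log2=effect_log2, n_active=1,
        )
        data, _ = simulate_experiment(design, effects)
        matrix, pair = data[design.conditions[0]]
        profile = fold_changes(matrix, pair)
        cfg = NullConfig(n_resamples=n_resamples, seed=seed + 10_000 + rep)
        for name, counter in (("module_1", "planted"), ("module_2", "null")):
            res = score_module(profile, modules[name], AAFC, cfg,
                               rng=child_rng(cfg.seed, name))
            if res.activated:
                if counter == "planted":
                    activated_planted += 1
                else:
                    activated_null += 1
    return {
        "planted_activation_count": activated_planted,
        "unplanted_activation_count": activated_null,
        "n_replicates": n_replicates,
    }


def mc_vs_exhaustive(
    seed: int, n_cases: int = 20, n_resamples: int = 10_000
) -> dict[str, float]:
    """Monte-Carlo vs exhaustive-enumeration z on small universes (<= 15
    genes); reports the largest |Delta z| over the random cases."""
    rng = np.random.default_rng(seed)
    from .datatypes import Condition, FoldChangeProfile
    import pandas as pd

    deltas = []
    for case in range(n_cases):
        m = int(rng.integers(8, 16))
        k = int(rng.integers(2, m - 1))
        fc = rng.normal(0, 1.5, m)
        genes = [f"g{i}" for i in range(m)]
        table = pd.DataFrame({"log2_fc": fc},
                             index=pd.Index(genes, name="gene_id"))
        profile = FoldChangeProfile(Condition("sim", "d", "t"), table)
        gene_set = GeneSet("case", "", tuple(rng.choice(genes, k, replace=False)))
        exact = score_module(profile, gene_set, AAFC,
                             NullConfig(n_resamples=n_resamples, seed=seed))
        mc = score_module(
            profile, gene_set, AAFC,
            NullConfig(n_resamples=n_resamples, seed=seed + case,
                       exhaustive_limit=0),
        )
        deltas.append(abs(mc.z_score - exact.z_score))
    return {"max_abs_delta_z": float(max(deltas)), "n_cases": n_cases}


def de_null_uniformity(seed: int, n_genes: int = 5000) -> dict[str, float]:
    """Kolmogorov-Smirnov distance of null-simulation Welch p-values from
    Uniform(0,1)."""
    design = _single_condition_design(n_genes, seed)
    data, _ = simulate_experiment(design, [])
    matrix, pair = data[design.conditions[0]]
    profile = de_test(matrix, pair)
    ks = stats.kstest(profile.table["p_value"], "uniform").statistic
    return {"ks_statistic": float(ks), "n_genes": n_genes}


def bh_vs_reference_stepup(seed: int, n_vectors: int = 1000) -> dict[str, float]:
    """Largest deviation of the package's BH adjustment from an
    independently coded step-up implementation on random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(0, 1, int(rng.integers(1, 200)))
        m = p.size
        order = np.argsort(p, kind="mergesort")
        scaled = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        ref = np.empty(m)
        ref[order] = np.minimum(q_sorted, 1.0)
        worst = max(worst, float(np.max(np.abs(bh_adjust(p) - ref))))
    return {"max_abs_diff": worst, "n_vectors": n_vectors}


def dose_monotonicity(
    seed: int,
    n_replicates: int = 50,
    n_genes: int = 4000,
    n_resamples: int = 10_000,
) -> dict[str, float]:
    """Fraction of replicates in which the high dose (multiplier 1.5)
    yields more DEGs and a higher planted-module z than the low dose
    (multiplier 1.0)."""
    deg_up = z_up = 0
    for rep in range(n_replicates):
        design = SimulationDesign(
            n_genes=n_genes, platforms=("in_vivo",),
            doses=(("low", 1.0), ("high", 1.5)), times=(("short", 1.0),),
            noise_sd=0.5, seed=seed + rep,
        )
        modules, effects = default_effects(
            design, n_modules=6, module_size=50, effect_log2=2.0, n_active=5
        )
        data, _ = simulate_experiment(design, effects)
        deg_counts, z_scores = {}, {}
        cfg = NullConfig(n_resamples=n_resamples, seed=seed + 20_000 + rep)
        for cond in design.conditions:
            matrix, pair = data[cond]
            profile, degs = differential_expression(matrix, pair)
            deg_counts[cond.dose] = len(degs)
            res = score_module(profile, modules["module_1"], AAFC, cfg,
                               rng=child_rng(cfg.seed, "module_1", cond.dose))
            z_scores[cond.dose] = res.z_score
        deg_up += deg_counts["high"] > deg_counts["low"]
        z_up += z_scores["high"] > z_scores["low"]
    return {
        "deg_monotonic_fraction": deg_up / n_replicates,
        "z_monotonic_fraction": z_up / n_replicates,
        "n_replicates": n_replicates,
    }


def pipeline_determinism(
    work_dir: str | Path,
    seed: int,
    n_genes: int = 1000,
    n_resamples: int = 2000,
) -> dict[str, float]:
    """Run the full pipeline twice with one config; compare output bytes.

    Returns the number of compared files and of mismatches (0 when the
    run is bit-reproducible).
    """
    from .cli import main as cli_main
    from click.testing import CliRunner

    work = Path(work_dir)
    sim = work / "sim"
    runner = CliRunner()
    cfg_file = work / "design.yaml"
    work.mkdir(parents=True, exist_ok=True)
    cfg_file.write_text(f"n_genes: {n_genes}\n")
    res = runner.invoke(cli_main, ["simulate", "--config", str(cfg_file),
                                   "--out", str(sim), "--seed", str(seed)])
    if res.exit_code != 0:
        raise RuntimeError(f"simulate failed: {res.output}")

    outputs = []
    for run_dir in (work / "run_a", work / "run_b"):
        cfg = RunConfig(
            matrix=str(sim / "matrix.tsv"),
            samples=str(sim / "samples.csv"),
            modules_gmt=str(sim / "modules.gmt"),
            out_dir=str(run_dir),
            seed=seed,
            n_resamples=n_resamples,
        )
        run_pipeline(cfg)
        outputs.append(run_dir)
    a, b = outputs
    names = sorted(p.name for p in a.iterdir())
    mismatches = [
        n for n in names
        if n != "manifest.json" and not filecmp.cmp(a / n, b / n, shallow=False)
    ]
    # manifests differ only in the out_dir path they echo; compare the rest
    import json

    ma = json.loads((a / "manifest.json").read_text())
    mb = json.loads((b / "manifest.json").read_text())
    ma["config"]["out_dir"] = mb["config"]["out_dir"] = ""
    if ma != mb:
        mismatches.append("manifest.json")
    return {"n_files": len(names), "n_mismatched": len(mismatches)}
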