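"""Calibration and power experiments run on the package's own pipeline.

These functions execute the full simulate -> bootstrap-Z -> BH-in-Z chain on
synthetic screens with known ground truth and summarize its operating
characteristics: the false discovery proportion under a fully-null screen and
the detection power for planted effects.  They are the package's built-in
self-diagnostics; the study conditions (n = 15 replicates per cell, FDR 5%
tier at |adjusted Z| > 2) are the defaults throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AssaySpec
from .harmonize import adjust_matrix
from .pipeline import build_zmatrix
from .simulate import AssayDesign, SimConfig, simulate_dataset

__all__ = ["null_fdp_experiment", "power_experiment"]

_TIER_AT_LEAST_FDR5 = ("fdr5", "fdr1")


def _screen_config(n_lines: int, assay_families: list[str], effects: pd.DataFrame | None,
                   n_per_cell: int, seed: int) -> SimConfig:
    genes = [f"G{i:03d}" for i in range(n_lines)]
    allele_map = {f"g{i:03d}": genes[i] for i in range(n_lines)}
    assays = [
        AssayDesign(f"assay{j}", fam, n_blocks=1)
        for j, fam in enumerate(assay_families)
    ]
    if effects is None:
        effects = pd.DataFrame(0.0, index=genes, columns=[a.assay_id for a in assays])
    return SimConfig(allele_map=allele_map, assays=assays, effect_matrix=effects,
                     block_sd=0.0, n_per_cell=n_per_cell, seed=seed)


def _specs_for(config: SimConfig) -> list[AssaySpec]:
    from .config import FAMILY_ADAPTERS
    return [AssaySpec(a.assay_id, adapter=FAMILY_ADAPTERS[a.family])
            for a in config.assays]


def null_fdp_experiment(
    n_datasets: int = 200,
    n_lines: int = 50,
    assay_families: tuple[str, ...] = ("endpoint_continuous",) * 4 + ("ordinal_score",) * 2,
    b: int = 50,
    n_per_cell: int = 15,
    seed: int = 0,
) -> dict:
    """Mean false discovery proportion of the fdr5 tier under the full null.

    Simulates ``n_datasets`` screens with no planted effects, runs the whole
    bootstrap/BH pipeline, and computes the FDP per BH family (each
    assay-endpoint column is its own family, matching the adjustment scope);
    every discovery is false by construction, so the family FDP is 1 when the
    family makes any call and 0 otherwise.  Returns the mean over all
    families x datasets, which BH should hold near the tier's nominal level.
    """
    rng = np.random.SeedSequence(seed)
    fdps = []
    for d in range(n_datasets):
        ds_seed = int((seed * 1_000_003 + d) % 2**31)
        config = _screen_config(n_lines, list(assay_families), None, n_per_cell, ds_seed)
        table = simulate_dataset(config)
        zm = build_zmatrix(table, _specs_for(config), b=b, seed=ds_seed)
        adj = adjust_matrix(zm)
        for col in adj.tier.columns:
            calls = adj.tier[col].isin(_TIER_AT_LEAST_FDR5).sum()
            fdps.append(1.0 if calls > 0 else 0.0)
    return {
        "mean_fdp": float(np.mean(fdps)),
        "n_families": len(fdps),
        "n_datasets": n_datasets,
    }


def power_experiment(
    n_datasets: int = 50,
    n_lines: int = 20,
    n_assays: int = 3,
    effect: float = 2.0,
    planted_every: int = 5,
    b: int = 50,
    n_per_cell: int = 15,
    seed: int = 0,
) -> dict:
    """Empirical power of the fdr5 tier for planted effects.

    Plants ``effect`` (in residual SDs) on a deterministic subset of
    (line, assay) cells — every ``planted_every``-th cell — runs the full
    pipeline, and reports the fraction of planted cells called at tier fdr5
    or better with the correct sign.
    """
    genes = [f"G{i:03d}" for i in range(n_lines)]
    cols = [f"assay{j}" for j in range(n_assays)]
    eff = pd.DataFrame(0.0, index=genes, columns=cols)
    planted = []
    for i in range(n_lines):
        for j in range(n_assays):
            if (i * n_assays + j) % planted_every == 0:
                eff.iloc[i, j] = effect
                planted.append((f"g{i:03d}", cols[j]))
    hits = total = 0
    for d in range(n_datasets):
        ds_seed = int((seed * 2_000_003 + d) % 2**31)
        config = _screen_config(n_lines, ["endpoint_continuous"] * n_assays, eff,
                                n_per_cell, ds_seed)
        table = simulate_dataset(config)
        zm = build_zmatrix(table, _specs_for(config), b=b, seed=ds_seed)
        adj = adjust_matrix(zm)
        for line, col in planted:
            called = adj.tier.loc[line, col] in _TIER_AT_LEAST_FDR5
            correct_sign = np.sign(adj.z_adj.loc[line, col]) == np.sign(effect)
            hits += bool(called and correct_sign)
            total += 1
    return {"power": hits / total, "n_planted": total, "n_datasets": n_datasets}
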