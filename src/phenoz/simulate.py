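"""Synthetic multi-assay mutant-collection generator with planted effects.

The screen this emulates phenotypes a reference genotype (Col-0) plus ~39
T-DNA insertion lines (some genes represented by two independent alleles)
across heterogeneous assay families:

* ``endpoint_continuous`` — one continuous endpoint per plant, replicated
  over independent experiment blocks (e.g. root length, bolting time);
* ``timecourse_continuous`` — a continuous trajectory sampled at fixed
  timepoints (e.g. relative electrolyte leakage after ozone exposure);
* ``ordinal_score`` — 0-3 severity scores from thresholding a latent
  Gaussian (bacterial disease symptoms);
* ``germination_curve`` — per-dish percent germinated at 5 h intervals,
  monotone within a dish, genotype shifting the logistic half-time;
* ``burst_total`` — positive totals on a log scale (ROS burst RLU sums).

Ground truth is the gene x assay ``effect_matrix`` in units of residual SD,
so every downstream stage can be validated against planted signs and sizes.
A single global seed is split per assay by stable hashing of the assay id:
adding or removing an assay never perturbs the draws of the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FAMILIES = (
    "endpoint_continuous",
    "timecourse_continuous",
    "ordinal_score",
    "germination_curve",
    "burst_total",
)

#: Latent-Gaussian cutpoints mapping to ordinal scores 0/1/2/3.
ORDINAL_CUTPOINTS = (-1.0, 0.0, 1.0)

#: Seeds per germination dish (replicate).
SEEDS_PER_DISH = 30

REFERENCE = "Col-0"

__all__ = [
    "AssayDesign",
    "SimConfig",
    "simulate_dataset",
    "make_missingness",
    "study_default_config",
    "REFERENCE",
    "FAMILIES",
]


@dataclass
class AssayDesign:
    """Design of one assay: family, timepoints, arms, noise and replication."""

    assay_id: str
    family: str
    timepoints: tuple[float, ...] = ()
    arms: tuple[str, ...] = ("trt",)
    noise_sd: float = 1.0
    n_blocks: int = 3
    baseline: float = 10.0

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown assay family {self.family!r} for {self.assay_id!r}; "
                f"expected one of {FAMILIES}"
            )
        if self.family in ("timecourse_continuous", "germination_curve") and not self.timepoints:
            raise ValueError(f"{self.assay_id!r}: time-structured family needs timepoints")
        if self.noise_sd <= 0:
            raise ValueError(f"{self.assay_id!r}: noise_sd must be positive")
        if self.n_blocks < 1:
            raise ValueError(f"{self.assay_id!r}: need at least one block")


@dataclass
class SimConfig:
    """Full data-generating configuration for one synthetic screen.

    ``allele_map`` maps each mutant line to its gene (at least one gene
    should carry two alleles to exercise allele averaging); ``effect_matrix``
    is gene x assay with signed effects in units of the assay's residual SD;
    ``block_sd`` is the SD of the additive between-experiment random effect
    in the same units; ``n_per_cell`` is the number of replicates per
    genotype x arm x timepoint cell within each block.
    """

    allele_map: dict[str, str]
    assays: list[AssayDesign]
    effect_matrix: pd.DataFrame
    block_sd: float = 0.5
    n_per_cell: int = 15
    seed: int = 0
    baseline: float = 10.0

    def validate(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        if self.block_sd < 0:
            raise ValueError("block_sd must be nonnegative")
        if not self.allele_map:
            raise ValueError("allele_map is empty")
        for a in self.assays:
            a.validate()
        ids = [a.assay_id for a in self.assays]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate assay_id in design")
        genes = set(self.allele_map.values())
        missing = genes - set(self.effect_matrix.index)
        if missing:
            raise ValueError(f"effect_matrix rows missing genes: {sorted(missing)}")
        missing_cols = {a.assay_id for a in self.assays} - set(self.effect_matrix.columns)
        if missing_cols:
            raise ValueError(f"effect_matrix columns missing assays: {sorted(missing_cols)}")

    @property
    def lines(self) -> list[str]:
        return list(self.allele_map)


def _assay_rng(seed: int, assay_id: str) -> np.random.Generator:
    """Per-assay generator from the global seed by stable hashing of the id."""
    digest = hashlib.sha256(assay_id.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _effect(config: SimConfig, genotype: str, assay_id: str) -> float:
    if genotype == REFERENCE:
        return 0.0
    gene = config.allele_map[genotype]
    return float(config.effect_matrix.loc[gene, assay_id])


def simulate_dataset(config: SimConfig) -> pd.DataFrame:
    """Generate the long-format phenotype table for a configuration.

    For continuous families the cell mean is baseline + effect x noise_sd +
    block effect; ordinal scores threshold a unit-SD latent Gaussian shifted
    by the effect; germination curves arise from logistic per-seed
    germination times whose half-time is shifted by the genotype; burst
    totals are log-normal with the effect acting on the log scale.  Output is
    byte-identical for identical configurations (including seed).
    """
    config.validate()
    genotypes = [REFERENCE] + config.lines
    frames = []
    for design in config.assays:
        rng = _assay_rng(config.seed, design.assay_id)
        blocks = [f"b{i + 1}" for i in range(design.n_blocks)]
        block_eff = rng.normal(0.0, config.block_sd, size=design.n_blocks)
        acc = _Rows(design)
        _SIMULATORS[design.family](config, design, genotypes, blocks, block_eff, rng, acc)
        frames.append(acc.frame())
    table = pd.concat(frames, ignore_index=True)
    table["replicate"] = table.groupby(
        ["assay_id", "genotype", "block_id", "timepoint", "arm"], dropna=False
    ).cumcount() + 1
    return table[
        ["assay_id", "genotype", "allele_id", "block_id", "timepoint", "arm",
         "value", "unit", "replicate"]
    ]


class _Rows:
    """Column-wise accumulator for one assay's measurements."""

    def __init__(self, design: AssayDesign):
        self.design = design
        self.meta: list[tuple] = []   # (genotype, block, timepoint, arm, unit)
        self.chunks: list[np.ndarray] = []

    def add(self, genotype, block, timepoint, arm, values, unit):
        values = np.atleast_1d(np.asarray(values, dtype=float))
        self.meta.append((genotype, block, timepoint, arm, unit, values.size))
        self.chunks.append(values)

    def frame(self) -> pd.DataFrame:
        sizes = [m[5] for m in self.meta]
        rep = lambda i: np.repeat([m[i] for m in self.meta], sizes)
        gts = rep(0)
        return pd.DataFrame({
            "assay_id": np.repeat(self.design.assay_id, sum(sizes)),
            "genotype": gts,
            "allele_id": gts,  # the line id doubles as the allele id
            "block_id": rep(1),
            "timepoint": np.repeat([m[2] for m in self.meta], sizes).astype(float),
            "arm": rep(3),
            "value": np.concatenate(self.chunks),
            "unit": rep(4),
        })


def _sim_continuous(config, design, genotypes, blocks, block_eff, rng, acc,
                    timepoints=None):
    tps = timepoints if timepoints is not None else [np.nan]
    for gt in genotypes:
        eff = _effect(config, gt, design.assay_id) * design.noise_sd
        for ib, block in enumerate(blocks):
            for arm in design.arms:
                for tp in tps:
                    vals = design.baseline + eff + block_eff[ib] * design.noise_sd \
                        + rng.normal(0.0, design.noise_sd, size=config.n_per_cell)
                    acc.add(gt, block, tp, arm, vals, "au")


def _sim_timecourse(config, design, genotypes, blocks, block_eff, rng, acc):
    _sim_continuous(config, design, genotypes, blocks, block_eff, rng, acc,
                    timepoints=design.timepoints)


def _sim_ordinal(config, design, genotypes, blocks, block_eff, rng, acc):
    # latent ~ N(effect + block, 1); fixed cutpoints -> scores 0..3
    cut = np.asarray(ORDINAL_CUTPOINTS)
    for gt in genotypes:
        eff = _effect(config, gt, design.assay_id)
        for ib, block in enumerate(blocks):
            for arm in design.arms:
                latent = eff + block_eff[ib] + rng.normal(0.0, 1.0, size=config.n_per_cell)
                scores = np.searchsorted(cut, latent).astype(float)
                acc.add(gt, block, np.nan, arm, scores, "score")


def _sim_germination(config, design, genotypes, blocks, block_eff, rng, acc):
    # per-seed germination times ~ Logistic(t50, scale); a positive planted
    # effect advances the half-time (faster germination, higher percentages)
    t50_base = float(np.median(design.timepoints))
    scale = 5.0
    hours_per_sd = 2.5
    tps = np.asarray(design.timepoints, dtype=float)
    for gt in genotypes:
        shift = -_effect(config, gt, design.assay_id) * hours_per_sd
        for ib, block in enumerate(blocks):
            for arm in design.arms:
                t50 = t50_base + shift + block_eff[ib] * hours_per_sd
                times = rng.logistic(t50, scale, size=(config.n_per_cell, SEEDS_PER_DISH))
                pct = 100.0 * (times[:, :, None] <= tps[None, None, :]).mean(axis=1)
                for tp, col in zip(tps, pct.T):
                    acc.add(gt, block, tp, arm, col, "%")


def _sim_burst(config, design, genotypes, blocks, block_eff, rng, acc):
    # totals are log-normal: effects and noise act on the log scale
    log_base = np.log(1000.0)
    for gt in genotypes:
        eff = _effect(config, gt, design.assay_id) * design.noise_sd
        for ib, block in enumerate(blocks):
            for arm in design.arms:
                logs = log_base + eff + block_eff[ib] * design.noise_sd \
                    + rng.normal(0.0, design.noise_sd, size=config.n_per_cell)
                acc.add(gt, block, np.nan, arm, np.exp(logs), "RLU")


_SIMULATORS = {
    "endpoint_continuous": _sim_continuous,
    "timecourse_continuous": _sim_timecourse,
    "ordinal_score": _sim_ordinal,
    "germination_curve": _sim_germination,
    "burst_total": _sim_burst,
}


def make_missingness(table: pd.DataFrame, mask_spec) -> pd.DataFrame:
    """Remove the listed (line, assay) cells, emulating unmeasured entries.

    ``mask_spec`` is an iterable of (genotype, assay_id) pairs.  Masking the
    reference genotype of an assay is an error: without it no comparison can
    be formed for that assay.
    """
    masked = set(map(tuple, mask_spec))
    for gt, assay in masked:
        if gt == REFERENCE:
            raise ValueError(f"cannot mask reference genotype in assay {assay!r}")
    if not masked:
        return table.copy()
    drop = table.apply(lambda r: (r["genotype"], r["assay_id"]) in masked, axis=1)
    return table[~drop].reset_index(drop=True)


def study_default_config(
    seed: int = 0,
    n_genes: int = 33,
    n_twin_allele_genes: int = 6,
    sparsity: float = 0.15,
    effect_scale: float = 2.0,
    block_sd: float = 0.5,
    n_per_cell: int = 15,
) -> SimConfig:
    """Default configuration emulating the study's screen layout.

    33 genes, six of them with two independent insertion alleles (39 lines
    total), a catalogue of assays spanning all five families, and a sparse
    gene x assay effect matrix: each entry is nonzero with probability
    ``sparsity`` with signed magnitudes of about ``effect_scale`` residual
    SDs, so most cells are null as in a real mutant screen.
    """
    genes = [f"GENE{i + 1:02d}" for i in range(n_genes)]
    allele_map: dict[str, str] = {}
    for i, g in enumerate(genes):
        allele_map[f"{g.lower()}-1"] = g
        if i < n_twin_allele_genes:
            allele_map[f"{g.lower()}-2"] = g

    assays = [
        AssayDesign("root_length", "endpoint_continuous", n_blocks=3),
        AssayDesign("flowering_time", "endpoint_continuous", n_blocks=3),
        AssayDesign("leakage_o3", "timecourse_continuous",
                    timepoints=(0.0, 2.0, 6.0, 24.0), n_blocks=2),
        AssayDesign("leakage_uv", "timecourse_continuous",
                    timepoints=(0.0, 6.0, 24.0), n_blocks=2),
        AssayDesign("pto_symptoms", "ordinal_score", n_blocks=2),
        AssayDesign("germination_nacl", "germination_curve",
                    timepoints=tuple(float(t) for t in range(0, 55, 5)), n_blocks=3),
        AssayDesign("ros_burst_flg22", "burst_total", noise_sd=0.5, n_blocks=2),
        AssayDesign("phi_po_mv", "endpoint_continuous", n_blocks=2),
    ]

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xEFFEC7,)))
    eff = rng.normal(0.0, effect_scale, size=(len(genes), len(assays)))
    mask = rng.random(eff.shape) < sparsity
    effect_matrix = pd.DataFrame(
        np.where(mask, eff, 0.0), index=genes, columns=[a.assay_id for a in assays]
    )
    return SimConfig(
        allele_map=allele_map,
        assays=assays,
        effect_matrix=effect_matrix,
        block_sd=block_sd,
        n_per_cell=n_per_cell,
        seed=seed,
    )
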