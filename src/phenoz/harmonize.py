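"""Bootstrap Z-score commensuration and signed FDR adjustment in Z-space.

The harmonization stage makes ~30 heterogeneous experiments comparable:

1. every mutant-vs-reference comparison is bootstrapped to a common sample
   size (n = 15 per condition cell) and the assay's adapter statistic is
   averaged over bootstrap replicates, giving one signed Z per
   (line, assay-endpoint) cell;
2. the Z values of each experiment are transformed to two-sided p-values,
   Benjamini-Hochberg adjusted, and transformed back through the normal
   quantile with the original sign, yielding adjusted Z scores;
3. cells are assigned significance tiers from the |adjusted Z| guideline
   cutpoints (1.67 / 2 / 2.6 for FDR 10% / 5% / 1%);
4. multiple insertion alleles of a gene are collapsed by averaging.

Because the Z -> p -> BH -> p -> Z chain is monotone, thresholding |adjusted
Z| at the normal quantile of q/2 is *exactly* BH rejection at FDR level q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import B_DEFAULT, N_BOOT_SIZE, TIER_CUTPOINTS, TIER_ORDER, Z_CAP
from .contrasts import (
    ContrastResult,
    _mann_whitney_z_arrays,
    _reml_fit,
    _two_sample_z_arrays,
    mann_whitney_z,
    two_sample_z,
)

__all__ = [
    "ZMatrix",
    "AdjustedZMatrix",
    "bootstrap_z",
    "bootstrap_pair_z",
    "z_to_p",
    "bh_adjust",
    "p_to_adjusted_z",
    "adjust_matrix",
    "average_alleles",
    "assign_tiers",
]


@dataclass
class ZMatrix:
    """Raw signed Z per line x assay-endpoint, with bootstrap provenance."""

    z: pd.DataFrame
    adapter: dict[str, str] = field(default_factory=dict)
    n_boot: int = N_BOOT_SIZE
    b: int = B_DEFAULT


@dataclass
class AdjustedZMatrix:
    """Sign-preserving BH-adjusted Z matrix with FDR tiers.

    ``mask`` is True where the cell was measured; ``tier`` holds one of
    ns / fdr10 / fdr5 / fdr1 (the missing cells hold the NA string handled
    by the I/O layer).
    """

    z_adj: pd.DataFrame
    p_adj: pd.DataFrame
    tier: pd.DataFrame
    mask: pd.DataFrame
    family_scope: str = "per_experiment"


# ---------------------------------------------------------------------------
# Z <-> p transforms
# ---------------------------------------------------------------------------

def z_to_p(z):
    """Two-sided standard-normal p, p = 2 (1 - Phi(|z|)). NaN passes through."""
    z = np.asarray(z, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return p if p.ndim else float(p)


def p_to_adjusted_z(p_adj, sign):
    """Back-transform adjusted p to a signed adjusted Z.

    z_adj = sign * Phi^-1(1 - p_adj / 2), clamped to [-Z_CAP, Z_CAP]; an
    adjusted p of exactly 1 maps to 0 and an underflowed p of 0 to Z_CAP.
    """
    p_adj = np.asarray(p_adj, dtype=float)
    sign = np.sign(np.asarray(sign, dtype=float))
    if np.nanmin(p_adj, initial=1.0) < 0 or np.nanmax(p_adj, initial=0.0) > 1:
        raise ValueError("adjusted p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        mag = stats.norm.isf(p_adj / 2.0)
    mag = np.clip(mag, 0.0, Z_CAP)
    out = np.where(p_adj >= 1.0, 0.0, sign * mag)
    out = np.where(np.isnan(p_adj), np.nan, out)
    return out if out.ndim else float(out)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, q_(i) = min_{j >= i} (m p_(j) / j) clipped at 1, mapped
    back to the input order.  NaNs are ignored (not counted in m) and
    returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out


# ---------------------------------------------------------------------------
# Bootstrap commensuration
# ---------------------------------------------------------------------------

_PAIR_STATS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "linear": _two_sample_z_arrays,
    "mann_whitney": _mann_whitney_z_arrays,
}


def bootstrap_pair_z(
    x: Sequence[float],
    y: Sequence[float],
    stat: str = "linear",
    n_boot: int = N_BOOT_SIZE,
    b: int = B_DEFAULT,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Bootstrap-commensurated Z for a plain two-group comparison.

    Each group is independently resampled with replacement to ``n_boot``
    observations, the adapter statistic is computed on every bootstrap pair,
    and the arithmetic mean of the ``b`` Z estimates is returned.  The x
    (mutant) cell is drawn before the y (reference) cell, so results are
    reproducible given the generator state.
    """
    if stat not in _PAIR_STATS:
        raise ValueError(f"unknown two-group statistic {stat!r}")
    rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return float("nan")
    ix = rng.integers(0, x.size, size=(b, n_boot))
    iy = rng.integers(0, y.size, size=(b, n_boot))
    zb = _PAIR_STATS[stat](x[ix], y[iy])
    return float(np.mean(zb))


def _bootstrap_pair_sorted(
    xv: np.ndarray,
    yv: np.ndarray,
    x_name: str,
    y_name: str,
    stat: str,
    n_boot: int,
    b: int,
    rng: np.random.Generator | int | None,
) -> float:
    """Two-group bootstrap drawing cells in sorted-name order.

    Reproduces :func:`bootstrap_z` exactly for simple two-group slices (one
    arm, one timepoint) at a fraction of the cost; used by the pipeline's
    matrix builder.
    """
    rng = np.random.default_rng(rng)
    if xv.size == 0 or yv.size == 0:
        return float("nan")
    if str(x_name) <= str(y_name):
        ix = rng.integers(0, xv.size, size=(b, n_boot))
        iy = rng.integers(0, yv.size, size=(b, n_boot))
    else:
        iy = rng.integers(0, yv.size, size=(b, n_boot))
        ix = rng.integers(0, xv.size, size=(b, n_boot))
    zb = _PAIR_STATS[stat](xv[ix], yv[iy])
    return float(np.mean(zb))


def bootstrap_z(
    table: pd.DataFrame,
    genotype: str,
    reference: str,
    adapter: str = "linear",
    n_boot: int = N_BOOT_SIZE,
    b: int = B_DEFAULT,
    rng: np.random.Generator | int | None = None,
    value_col: str = "value",
    timepoint: float | None = None,
) -> float:
    """Bootstrap-commensurated Z on a long-format table slice.

    Rows are grouped into condition cells (genotype x arm x timepoint); each
    cell is resampled with replacement to ``n_boot`` rows per replicate and
    the adapter Z is averaged over ``b`` replicates.  Cells are drawn in
    sorted key order so the generic path reproduces :func:`bootstrap_pair_z`
    exactly for simple two-group designs.  An empty genotype cell yields NaN
    (missing marker), never an exception.

    Adapters: ``linear``, ``mann_whitney`` (fast vectorized paths) and
    ``mixed`` (per-replicate mixed-model fit; block labels travel with the
    resampled rows).
    """
    if adapter not in ("linear", "mann_whitney", "mixed"):
        raise ValueError(f"unknown adapter {adapter!r}")
    rng = np.random.default_rng(rng)
    sl = table
    if timepoint is not None and "timepoint" in sl.columns:
        sl = sl[sl["timepoint"] == timepoint]
    sl = sl[sl["genotype"].isin([genotype, reference])]
    if (sl["genotype"] == genotype).sum() == 0 or (sl["genotype"] == reference).sum() == 0:
        return float("nan")

    cell_cols = [c for c in ("genotype", "arm", "timepoint") if c in sl.columns]
    key_df = sl[cell_cols].astype(object).where(sl[cell_cols].notna(), "")
    key_strings = key_df.astype(str).agg("\x1f".join, axis=1)
    keys = sorted(key_strings.unique())
    cell_rows = {k: sl.index[(key_strings == k).to_numpy()].to_numpy() for k in keys}
    draws = {k: rng.integers(0, cell_rows[k].size, size=(b, n_boot)) for k in keys}

    if adapter in _PAIR_STATS and len(keys) == 2:
        gkey = next(k for k in keys if k.split("\x1f")[0] == genotype)
        rkey = next(k for k in keys if k.split("\x1f")[0] == reference)
        vals = sl[value_col].to_numpy(float)
        pos = {idx: i for i, idx in enumerate(sl.index)}
        xv = vals[[pos[i] for i in cell_rows[gkey]]]
        yv = vals[[pos[i] for i in cell_rows[rkey]]]
        zb = _PAIR_STATS[adapter](xv[draws[gkey]], yv[draws[rkey]])
        return float(np.mean(zb))

    if adapter == "mixed":
        return _bootstrap_mixed(sl, genotype, cell_rows, draws, keys, value_col)

    zs = np.empty(b)
    for i in range(b):
        idx = np.concatenate([cell_rows[k][draws[k][i]] for k in keys])
        boot = sl.loc[idx]
        fn = two_sample_z if adapter == "linear" else mann_whitney_z
        res = fn(
            boot.loc[boot["genotype"] == genotype, value_col],
            boot.loc[boot["genotype"] == reference, value_col],
        )
        zs[i] = res.z
    return float(zs.mean())


def _bootstrap_mixed(sl, genotype, cell_rows, draws, keys, value_col):
    """Array fast path for the mixed adapter: per-replicate REML refits on
    resampled rows, block labels travelling with the rows."""
    pos = {idx: i for i, idx in enumerate(sl.index)}
    vals = sl[value_col].to_numpy(float)
    gind = (sl["genotype"] == genotype).to_numpy()
    bcodes = pd.Categorical(sl["block_id"]).codes if "block_id" in sl.columns \
        else np.zeros(len(sl), dtype=int)
    cell_pos = {k: np.array([pos[i] for i in rows]) for k, rows in cell_rows.items()}
    b = next(iter(draws.values())).shape[0]
    zs = np.empty(b)
    for i in range(b):
        take = np.concatenate([cell_pos[k][draws[k][i]] for k in keys])
        y, g, blk = vals[take], gind[take], bcodes[take]
        if np.unique(blk).size < 2 or g.all() or not g.any():
            res = two_sample_z(y[g], y[~g]) if (g.any() and (~g).any() and
                                                g.sum() >= 2 and (~g).sum() >= 2) \
                else None
            zs[i] = res.z if res is not None else 0.0
            continue
        est, se, _ = _reml_fit(y, g, blk)
        if se == 0.0:
            zs[i] = 0.0 if est == 0.0 else float(np.sign(est) * Z_CAP)
        else:
            zs[i] = float(np.clip(est / se, -Z_CAP, Z_CAP))
    return float(zs.mean())


# ---------------------------------------------------------------------------
# Matrix-level adjustment
# ---------------------------------------------------------------------------

def assign_tiers(z_adj: pd.DataFrame,
                 cutpoints: Mapping[str, float] = TIER_CUTPOINTS) -> pd.DataFrame:
    """Map |adjusted Z| to significance tiers (ns / fdr10 / fdr5 / fdr1)."""
    a = z_adj.abs().to_numpy()
    out = np.select(
        [a > cutpoints["fdr1"], a > cutpoints["fdr5"], a > cutpoints["fdr10"]],
        ["fdr1", "fdr5", "fdr10"],
        default="ns",
    ).astype(object)
    out = np.where(np.isnan(a), None, out)
    return pd.DataFrame(out, index=z_adj.index, columns=z_adj.columns)


def adjust_matrix(
    zm: ZMatrix | pd.DataFrame,
    family_scope: str = "per_experiment",
    cutpoints: Mapping[str, float] = TIER_CUTPOINTS,
) -> AdjustedZMatrix:
    """Sign-preserving BH adjustment of a raw Z matrix.

    ``family_scope`` = ``per_experiment`` applies BH within each
    assay-endpoint column (each experiment its own family, the default);
    ``global`` pools every measured cell into one family.  Missing cells are
    carried through untouched.
    """
    if family_scope not in ("per_experiment", "global"):
        raise ValueError(f"family_scope must be per_experiment or global, got {family_scope!r}")
    zdf = zm.z if isinstance(zm, ZMatrix) else zm
    z = zdf.to_numpy(dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[np.isnan(z)] = np.nan
    if family_scope == "global":
        p_adj = bh_adjust(p.ravel()).reshape(p.shape)
    else:
        p_adj = np.column_stack([bh_adjust(p[:, j]) for j in range(p.shape[1])]) \
            if p.shape[1] else p.copy()
    z_adj = p_to_adjusted_z(p_adj, np.sign(z))
    z_adj_df = pd.DataFrame(z_adj, index=zdf.index, columns=zdf.columns)
    p_adj_df = pd.DataFrame(p_adj, index=zdf.index, columns=zdf.columns)
    return AdjustedZMatrix(
        z_adj=z_adj_df,
        p_adj=p_adj_df,
        tier=assign_tiers(z_adj_df, cutpoints),
        mask=zdf.notna(),
        family_scope=family_scope,
    )


def average_alleles(
    matrix: pd.DataFrame,
    allele_map: Mapping[str, str],
) -> pd.DataFrame:
    """Collapse insertion alleles to genes by missing-aware averaging.

    ``allele_map`` maps every row (line) to its gene; per gene and column the
    arithmetic mean over the gene's alleles is taken ignoring missing cells,
    so a gene measured through a single allele inherits that allele's value.
    """
    missing = [r for r in matrix.index if r not in allele_map]
    if missing:
        raise ValueError(f"allele_map does not cover rows: {missing}")
    genes = pd.Index([allele_map[r] for r in matrix.index], name="gene")
    out = matrix.groupby(genes, sort=True).mean()
    return out
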