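"""Per-assay statistical adapters producing signed Z statistics.

Every assay in the screen is reduced to the same currency: a signed standard
normal statistic for each mutant-vs-reference comparison.  Adapters:

* :func:`z_linear_contrast` — ordinary two-sample mean contrast with pooled
  variance (endpoint assays without block structure).
* :func:`z_mann_whitney` — rank-sum statistic with midranks and
  tie-corrected variance, normal-approximated (ordinal 0-3 disease scores).
* :func:`z_mixed_timecourse` — genotype contrast at one timepoint from a
  random-intercept-per-experiment-block linear mixed model, fitted by
  profiling the block-variance ratio on the restricted likelihood.
* :func:`single_step_adjust` — max-|z| single-step familywise adjustment for
  within-experiment figure annotations.

All p-values come from the standard normal, never from t distributions: the
downstream bootstrap-commensuration stage assumes every adapter emits an
(approximately) N(0,1)-distributed statistic under the null.  |z| is clamped
to ``Z_CAP`` so that perfectly separated samples stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import Z_CAP

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastResult",
    "MixedModelSpec",
    "FamilyAdjustment",
    "two_sample_z",
    "z_linear_contrast",
    "mann_whitney_z",
    "z_mann_whitney",
    "z_mixed_timecourse",
    "single_step_adjust",
]


@dataclass
class ContrastResult:
    """A single genotype-vs-reference comparison reduced to a Z statistic.

    ``p_two_sided`` always equals ``2 * (1 - Phi(|z|))``; ``df_note`` records
    that the reference distribution is the normal approximation, and ``flag``
    marks degenerate inputs (zero pooled variance, all values tied).
    """

    genotype: str
    assay_id: str | None = None
    timepoint: float | None = None
    estimate: float = float("nan")
    se: float = float("nan")
    z: float = 0.0
    p_two_sided: float = 1.0
    df_note: str = "normal-approximated"
    flag: str | None = None


@dataclass
class MixedModelSpec:
    """Fixed/random structure of the time-course mixed model.

    Fixed effects: genotype, time and their interaction; random effect: an
    intercept per experiment replicate (block).  Each timepoint is analysed
    separately, so within one fit the fixed part reduces to the genotype
    contrast at that timepoint.
    """

    response: str = "value"
    genotype_col: str = "genotype"
    time_col: str = "timepoint"
    block_col: str = "block_id"


@dataclass
class FamilyAdjustment:
    """Single-step (max-|z|) familywise-adjusted comparisons."""

    contrasts: list[ContrastResult]
    correlation: np.ndarray
    p_adjusted: np.ndarray = field(default_factory=lambda: np.array([]))


def _cap(z: float | np.ndarray) -> float | np.ndarray:
    return np.clip(z, -Z_CAP, Z_CAP)


def _z_to_p(z: np.ndarray | float) -> np.ndarray | float:
    return 2.0 * stats.norm.sf(np.abs(z))


# ---------------------------------------------------------------------------
# Two-sample mean contrast
# ---------------------------------------------------------------------------

def two_sample_z(x: Sequence[float], y: Sequence[float]) -> ContrastResult:
    """Pooled-variance mean contrast of sample ``x`` against reference ``y``.

    z = (mean_x - mean_y) / sqrt(s_p^2 (1/n1 + 1/n2)) with the usual pooled
    variance; positive z means x larger than the reference.  Both samples
    need >= 2 observations.  If the pooled variance is exactly zero the
    statistic is undefined: z = 0 is returned with a ``degenerate`` flag when
    the means agree, and z = +/-Z_CAP when they are separated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(
            f"need >=2 observations per group, got {x.size} and {y.size}"
        )
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in contrast input")
    n1, n2 = x.size, y.size
    est = float(x.mean() - y.mean())
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    se = float(np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    if se == 0.0:
        if est == 0.0:
            return ContrastResult(genotype="", estimate=0.0, se=0.0, z=0.0,
                                  p_two_sided=1.0, flag="degenerate")
        z = float(np.sign(est) * Z_CAP)
        return ContrastResult(genotype="", estimate=est, se=0.0, z=z,
                              p_two_sided=float(_z_to_p(z)), flag="separated")
    z = float(_cap(est / se))
    return ContrastResult(genotype="", estimate=est, se=se, z=z,
                          p_two_sided=float(_z_to_p(z)))


def _two_sample_z_arrays(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized two-sample z over the last axis; leading axes broadcast."""
    n1, n2 = x.shape[-1], y.shape[-1]
    est = x.mean(axis=-1) - y.mean(axis=-1)
    sp2 = ((n1 - 1) * x.var(axis=-1, ddof=1) + (n2 - 1) * y.var(axis=-1, ddof=1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / np.where(se > 0, se, 1.0), np.sign(est) * Z_CAP)
    return np.asarray(_cap(z))


def z_linear_contrast(
    table: pd.DataFrame,
    genotype: str,
    reference: str,
    value_col: str = "value",
    genotype_col: str = "genotype",
) -> ContrastResult:
    """Mean contrast of ``genotype`` vs ``reference`` on a long-format slice."""
    x = table.loc[table[genotype_col] == genotype, value_col].to_numpy(float)
    y = table.loc[table[genotype_col] == reference, value_col].to_numpy(float)
    res = two_sample_z(x, y)
    res.genotype = genotype
    return res


# ---------------------------------------------------------------------------
# Mann-Whitney rank-sum statistic
# ---------------------------------------------------------------------------

def _tie_term(pooled_sorted: np.ndarray) -> np.ndarray:
    """sum over tie groups of (t^3 - t), vectorized over leading axes.

    Uses the per-element identity sum_groups t(t^2-1) = sum_elements (t^2-1)
    where t is the size of the element's tie group; the O(N^2) pairwise
    comparison is fine for bootstrap cell sizes (N <= ~60).
    """
    eq = pooled_sorted[..., :, None] == pooled_sorted[..., None, :]
    group_size = eq.sum(axis=-1)
    return (group_size.astype(float) ** 2 - 1.0).sum(axis=-1)


def mann_whitney_z(x: Sequence[float], y: Sequence[float]) -> ContrastResult:
    """Rank-sum comparison of ``x`` vs reference ``y``, normal-approximated.

    U is computed from midranks; the variance carries the usual tie
    correction and no continuity correction is applied, so z maps to the
    two-sided p exactly through the normal CDF.  Positive z means x is
    stochastically larger than y.  All values tied across both samples gives
    z = 0 with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    tie = float(_tie_term(np.sort(pooled)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    est = u1 - mu
    if var <= 0:
        return ContrastResult(genotype="", estimate=est, se=0.0, z=0.0,
                              p_two_sided=1.0, flag="all-tied")
    z = float(_cap(est / np.sqrt(var)))
    return ContrastResult(genotype="", estimate=est, se=float(np.sqrt(var)),
                          z=z, p_two_sided=float(_z_to_p(z)))


def _mann_whitney_z_arrays(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized Mann-Whitney z over the last axis."""
    n1, n2 = x.shape[-1], y.shape[-1]
    pooled = np.concatenate([x, y], axis=-1)
    ranks = stats.rankdata(pooled, axis=-1)
    u1 = ranks[..., :n1].sum(axis=-1) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    tie = _tie_term(np.sort(pooled, axis=-1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (u1 - mu) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    return np.asarray(_cap(z))


def z_mann_whitney(
    x: Sequence[float] | pd.DataFrame,
    y: Sequence[float] | None = None,
    genotype: str = "",
    reference: str = "",
    value_col: str = "value",
    genotype_col: str = "genotype",
) -> ContrastResult:
    """Mann-Whitney adapter; accepts two samples or a long-format slice."""
    if isinstance(x, pd.DataFrame):
        table = x
        xs = table.loc[table[genotype_col] == genotype, value_col].to_numpy(float)
        ys = table.loc[table[genotype_col] == reference, value_col].to_numpy(float)
        res = mann_whitney_z(xs, ys)
        res.genotype = genotype
        return res
    res = mann_whitney_z(x, y)
    res.genotype = genotype
    return res


# ---------------------------------------------------------------------------
# Random-intercept mixed model, REML by variance-ratio profiling
# ---------------------------------------------------------------------------

def _reml_fit(y: np.ndarray, x_ind: np.ndarray, blocks: np.ndarray):
    """Genotype contrast from y = mu + beta*g + block intercept + error.

    ``x_ind`` is the 0/1 genotype indicator, ``blocks`` integer block codes.
    The ratio lambda = sigma_block^2 / sigma_err^2 is profiled on a log grid
    (lambda = 0 included) maximizing the restricted likelihood; the contrast
    and its standard error are the GLS estimates at the chosen lambda.
    Deterministic, adequate for a single random intercept.
    """
    n = y.size
    X = np.column_stack([np.ones(n), x_ind.astype(float)])
    p = X.shape[1]
    uniq, codes = np.unique(blocks, return_inverse=True)
    # per-block sufficient statistics; V = I + lam * J within each block, so
    # V^-1 = I - lam/(1 + m lam) J and log|V| = sum log(1 + m lam)
    sizes = np.bincount(codes).astype(float)
    xtx = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)
    k = uniq.size
    sx = np.zeros((k, p))
    sy = np.zeros(k)
    np.add.at(sx, codes, X)
    np.add.at(sy, codes, y)

    def _crit(lam: float):
        w = lam / (1.0 + sizes * lam)  # shrinkage per block
        A = xtx - (sx * w[:, None]).T @ sx
        b_vec = xty - sx.T @ (w * sy)
        q = yty - float(w @ (sy * sy))
        beta = np.linalg.solve(A, b_vec)
        rss = q - float(beta @ (2.0 * b_vec - A @ beta))
        s2 = max(rss, 1e-300) / (n - p)
        logdet_v = float(np.log1p(sizes * lam).sum())
        _, logdet_a = np.linalg.slogdet(A)
        reml = -0.5 * ((n - p) * np.log(s2) + logdet_v + logdet_a)
        cov = s2 * np.linalg.inv(A)
        return reml, beta, cov

    grid = np.concatenate([[0.0], np.logspace(-6, 6, 121)])
    crits = [_crit(l)[0] for l in grid]
    i = int(np.argmax(crits))
    # one local refinement pass around the best grid point
    if 0 < i < len(grid) - 1 and grid[i] > 0:
        local = np.logspace(np.log10(grid[max(i - 1, 1)]), np.log10(grid[i + 1]), 41)
        crits_l = [_crit(l)[0] for l in local]
        j = int(np.argmax(crits_l))
        if crits_l[j] > crits[i]:
            best = local[j]
        else:
            best = grid[i]
    else:
        best = grid[i]
    _, beta, cov = _crit(best)
    return float(beta[1]), float(np.sqrt(cov[1, 1])), float(best)


def z_mixed_timecourse(
    table: pd.DataFrame,
    genotype: str,
    reference: str,
    timepoint: float | None = None,
    spec: MixedModelSpec | None = None,
    assay_id: str | None = None,
) -> ContrastResult:
    """Genotype-vs-reference contrast at one timepoint with a block random
    intercept.

    With a single experiment block the random effect is unidentifiable; the
    adapter degrades to the plain two-sample contrast and logs a warning.
    """
    spec = spec or MixedModelSpec()
    sl = table
    if timepoint is not None:
        sl = sl[sl[spec.time_col] == timepoint]
    sl = sl[sl[spec.genotype_col].isin([genotype, reference])]
    if (sl[spec.genotype_col] == reference).sum() == 0:
        raise ValueError(f"reference {reference!r} absent at timepoint {timepoint!r}")
    blocks = pd.Categorical(sl[spec.block_col]).codes
    if len(np.unique(blocks)) < 2:
        logger.warning(
            "single experiment block for %s at t=%s; falling back to plain contrast",
            genotype, timepoint,
        )
        res = z_linear_contrast(sl, genotype, reference, value_col=spec.response,
                                genotype_col=spec.genotype_col)
        res.timepoint = timepoint
        res.assay_id = assay_id
        return res
    y = sl[spec.response].to_numpy(float)
    g = (sl[spec.genotype_col] == genotype).to_numpy()
    est, se, _lam = _reml_fit(y, g, blocks)
    if se == 0.0:
        z = 0.0 if est == 0.0 else float(np.sign(est) * Z_CAP)
        flag = "degenerate" if est == 0.0 else "separated"
    else:
        z = float(_cap(est / se))
        flag = None
    return ContrastResult(genotype=genotype, assay_id=assay_id, timepoint=timepoint,
                          estimate=est, se=se, z=z, p_two_sided=float(_z_to_p(z)),
                          flag=flag)


# ---------------------------------------------------------------------------
# Single-step (max-|z|) familywise adjustment
# ---------------------------------------------------------------------------

def single_step_adjust(
    family: list[ContrastResult],
    correlation: np.ndarray | None = None,
    n_draws: int = 100_000,
    seed: int = 186283,
) -> FamilyAdjustment:
    """Single-step max-|z| adjustment across a family of contrasts.

    adjusted p_i = P(max_j |Z_j| >= |z_i|) under the joint normal with the
    given contrast correlation, estimated by Monte Carlo with a fixed,
    documented seed (default 186283).  Identity correlation is assumed when
    none is given.  Adjusted values are floored at the unadjusted p so the
    familywise guarantee p_adj >= p holds despite Monte-Carlo noise.
    """
    k = len(family)
    if k == 0:
        raise ValueError("empty contrast family")
    if correlation is None:
        correlation = np.eye(k)
    correlation = np.asarray(correlation, dtype=float)
    if correlation.shape != (k, k):
        raise ValueError(f"correlation must be {k}x{k}, got {correlation.shape}")
    w, v = np.linalg.eigh((correlation + correlation.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")
    z_obs = np.array([c.z for c in family])
    if k == 1:
        p_adj = np.array([family[0].p_two_sided])
    else:
        root = v * np.sqrt(np.clip(w, 0.0, None))
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((n_draws, k)) @ root.T
        maxabs = np.abs(draws).max(axis=1)
        p_adj = np.array([(maxabs >= abs(z)).mean() for z in z_obs])
        p_adj = np.maximum(p_adj, [c.p_two_sided for c in family])
    return FamilyAdjustment(contrasts=list(family), correlation=correlation,
                           p_adjusted=np.clip(p_adj, 0.0, 1.0))
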