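"""Hierarchical clustering of adjusted-Z matrices and dendrogram export.

Two recipes are provided, matching the integrated heatmaps of a mutant
screen: Ward linkage on Euclidean distances (the full phenotype heatmap) and
complete linkage on 1 - Pearson correlation (response-profile heatmaps).
Missing cells are neutral-imputed to 0 (no difference from the reference)
for the Euclidean recipe and handled by pairwise-complete correlations for
the Pearson recipe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "Dendrogram",
    "cluster_ward_euclidean",
    "cluster_complete_pearson",
    "export_dendrogram",
    "cut",
]


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form plus leaf labels."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: list[str]
    metric: str
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    m = np.asarray(matrix, dtype=float)
    return pd.DataFrame(m, index=[f"r{i}" for i in range(m.shape[0])])


def cluster_ward_euclidean(matrix) -> Dendrogram:
    """Ward-linkage clustering of rows on Euclidean distances.

    Missing cells are set to 0 — the neutral adjusted Z of "no difference
    from the reference" — before computing distances.
    """
    df = _as_frame(matrix)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    x = df.fillna(0.0).to_numpy(dtype=float)
    link = hierarchy.linkage(x, method="ward", metric="euclidean")
    return Dendrogram(link, [str(i) for i in df.index], "euclidean", "ward")


def cluster_complete_pearson(matrix, min_overlap: int = 3) -> Dendrogram:
    """Complete-linkage clustering of rows on 1 - Pearson correlation.

    Correlations use pairwise-complete columns; every pair of rows must
    share at least ``min_overlap`` measured columns, and every row must have
    nonzero variance over its measured cells.
    """
    df = _as_frame(matrix)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    var = df.var(axis=1, skipna=True)
    flat = var[(var == 0) | var.isna()]
    if len(flat):
        raise ValueError(f"zero-variance row(s): {list(flat.index)}")
    overlap = df.notna().astype(int) @ df.notna().astype(int).T
    bad = [(str(a), str(b)) for a in df.index for b in df.index
           if a < b and overlap.loc[a, b] < min_overlap]
    if bad:
        raise ValueError(f"row pairs with <{min_overlap} overlapping columns: {bad}")
    r = df.T.corr(min_periods=min_overlap).to_numpy(dtype=float)
    d = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    link = hierarchy.linkage(squareform(d, checks=False), method="complete")
    return Dendrogram(link, [str(i) for i in df.index], "1-pearson", "complete")


def cut(dendro: Dendrogram, k: int) -> dict[str, int]:
    """Flat clustering into ``k`` groups; returns label -> cluster id."""
    assignment = hierarchy.fcluster(dendro.linkage, t=k, criterion="maxclust")
    return dict(zip(dendro.labels, (int(a) for a in assignment)))


def _quote(name: str) -> str:
    if any(c in name for c in " \t()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def export_dendrogram(dendro: Dendrogram) -> str:
    """Serialize the merge tree as a Newick string.

    Branch lengths are half the difference of merge heights, so the
    path length between two leaves equals their cophenetic distance and a
    two-leaf tree of height h reads ``(A:h/2,B:h/2);``.  Leaf names needing
    it are single-quoted per Newick convention.
    """
    tree = hierarchy.to_tree(dendro.linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return _quote(dendro.labels[node.id])
        half = node.dist / 2.0
        parts = []
        for child in (node.left, node.right):
            length = half - (0.0 if child.is_leaf() else child.dist / 2.0)
            parts.append(f"{walk(child)}:{length:.10g}")
        return "(" + ",".join(parts) + ")"

    return walk(tree) + ";"
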