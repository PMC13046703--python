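"""Hierarchical clustering of per-origin mean chemical profiles.

Origins are compared through the shape of their 70-component mean profile:
the distance between two origins is 1 − r, where r is the Pearson correlation
of their mean vectors across components.  Agglomerative clustering (average
linkage by default) on that distance yields the origin dendrogram, exportable
as Newick or a JSON merge list.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .synthesis import ChemTable

__all__ = ["Dendrogram", "mean_profiles", "pearson_distance", "agglomerate", "to_newick"]

_LINKAGES = ("single", "complete", "average")


def mean_profiles(table: ChemTable, group_by: str = "region") -> pd.DataFrame:
    """Per-group component means: one row per group, one column per component."""
    labels = table.labels(group_by)
    order = list(dict.fromkeys(labels))
    rows = []
    for g in order:
        mask = labels == g
        if not mask.any():
            raise ValueError(f"group {g!r} is empty")
        rows.append(table.values[mask].mean(axis=0))
    return pd.DataFrame(rows, index=order, columns=table.component_names)


def pearson_distance(profiles: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Correlation distance d(i, j) = 1 − r(i, j) across components; d ∈ [0, 2]."""
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two profiles")
    if np.any(X.std(axis=1) == 0):
        raise ValueError("constant profile: Pearson correlation undefined")
    r = np.corrcoef(X)
    d = 1.0 - r
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass(frozen=True)
class Dendrogram:
    """Result of agglomerative merging.

    ``merges[i] = (left, right, height)`` creates internal node
    ``len(leaves) + i``; node ids below ``len(leaves)`` are leaves.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a dendrogram over k leaves needs exactly k-1 merges")

    @property
    def linkage_matrix(self) -> np.ndarray:
        """SciPy-format linkage matrix (for plotting / cutting)."""
        k = len(self.leaves)
        sizes: dict[int, int] = {i: 1 for i in range(k)}
        Z = np.zeros((k - 1, 4))
        for i, (a, b, h) in enumerate(self.merges):
            sizes[k + i] = sizes[a] + sizes[b]
            Z[i] = [a, b, h, sizes[k + i]]
        return Z

    def to_json(self) -> str:
        return json.dumps({"leaves": list(self.leaves),
                           "merges": [[a, b, h] for a, b, h in self.merges]})


def agglomerate(distances: np.ndarray, labels: list[str],
                linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering on a precomputed distance matrix.

    ``linkage`` is one of single / complete / average (UPGMA, the default for
    correlation distances).  Equal-distance merge ties follow SciPy's
    deterministic nearest-neighbour chaining, so output is reproducible.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) != D.shape[0]:
        raise ValueError("labels length must match matrix size")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if D.shape[0] == 1:
        raise ValueError("need at least two leaves")
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    merges = tuple((int(a), int(b), float(h)) for a, b, h, _ in Z)
    return Dendrogram(tuple(labels), merges)


def _escape(name: str) -> str:
    if re.search(r"[\s()\[\]:;,']", name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick serialisation with ultrametric branch lengths.

    A node merged at height h sits at depth h/2, so a child merged at height
    h_c hangs on a branch of length (h − h_c) / 2; leaves hang at h/2.
    """
    k = len(dendrogram.leaves)
    height = {i: 0.0 for i in range(k)}
    children: dict[int, tuple[int, int]] = {}
    for i, (a, b, h) in enumerate(dendrogram.merges):
        height[k + i] = h
        children[k + i] = (a, b)

    def render(node: int, parent_h: float) -> str:
        length = (parent_h - height[node]) / 2.0
        if node < k:
            return f"{_escape(dendrogram.leaves[node])}:{length:.10g}"
        a, b = children[node]
        return f"({render(a, height[node])},{render(b, height[node])}):{length:.10g}"

    root = k + len(dendrogram.merges) - 1
    a, b = children[root]
    h = height[root]
    return f"({render(a, h)},{render(b, h)});"
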