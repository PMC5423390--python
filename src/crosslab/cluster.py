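"""Hierarchical clustering of group profiles and gene-list concordance.

Column profiles (one per laboratory-condition group, each the median
log2 expression of the differentially expressed gene set) are clustered
agglomeratively with the uncentered Pearson correlation similarity
r_u = sum(x*y) / sqrt(sum(x^2) * sum(y^2)), distance 1 - r_u, and
complete linkage.  Concordance between differentially expressed gene
lists is intersection-over-union, reported as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import GeneList

__all__ = [
    "Dendrogram",
    "ConcordanceResult",
    "uncentered_pearson",
    "uncentered_distance_matrix",
    "hierarchical_cluster",
    "separation_check",
    "pairwise_concordance",
    "multiway_concordance",
]


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over labelled column profiles."""

    linkage: np.ndarray          # scipy linkage matrix, (n-1) x 4
    labels: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("complete-linkage merge heights must be "
                             "non-decreasing")

    def leaf_sets(self) -> list[frozenset[str]]:
        """Leaf-label set under each internal node, in merge order."""
        n = len(self.labels)
        sets: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for k, (a, b, _h, _c) in enumerate(self.linkage):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + k] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        """Serialise as a Newick string with branch lengths from heights."""
        n = len(self.labels)
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        newick: dict[int, str] = {
            i: _escape(self.labels[i]) for i in range(n)}
        for k, (a, b, h, _c) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node = n + k
            newick[node] = f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g})"
            height[node] = h
        return newick[n + len(self.linkage) - 1] + ";"


def _escape(label: str) -> str:
    return label.replace(" ", "_").replace("(", "_").replace(")", "_")


def uncentered_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Uncentered Pearson correlation: sum(xy)/sqrt(sum(x^2)*sum(y^2)).

    Cosine-style similarity without mean-centering; undefined for a
    zero-norm vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must share a length >= 2")
    nx = np.sqrt((x * x).sum())
    ny = np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        raise ValueError("uncentered Pearson undefined for a zero vector")
    return float((x * y).sum() / (nx * ny))


def uncentered_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """All-pairs 1 - r_u distances between columns of *profiles*."""
    x = profiles.to_numpy(dtype=float)
    norms = np.sqrt((x * x).sum(axis=0))
    if (norms == 0).any():
        bad = profiles.columns[norms == 0].tolist()
        raise ValueError(f"zero-norm profile(s): {bad}")
    r = (x.T @ x) / np.outer(norms, norms)
    d = 1.0 - np.clip(r, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against rounding
    return pd.DataFrame(d, index=profiles.columns, columns=profiles.columns)


def hierarchical_cluster(profiles: pd.DataFrame) -> Dendrogram:
    """Complete-linkage agglomeration of column profiles under 1 - r_u.

    ``profiles`` is genes x groups (median log2 of the DE gene set, one
    column per laboratory-condition group).  d(A, B) is the maximum
    pairwise distance between members, so merge heights are ultrametric.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 group profiles to cluster")
    if profiles.shape[0] < 1:
        raise ValueError("empty gene set")
    if profiles.columns.has_duplicates:
        raise ValueError("duplicate group labels")
    d = uncentered_distance_matrix(profiles)
    z = hierarchy.linkage(squareform(d.to_numpy(), checks=False),
                          method="complete")
    return Dendrogram(z, list(profiles.columns))


def separation_check(dendrogram: Dendrogram, set1: set[str], set2: set[str]
                     ) -> bool:
    """Do two label sets fall into disjoint pure subtrees?

    True iff the tree contains a subtree whose members-of-interest are
    exactly ``set1`` (no ``set2`` member) and another subtree likewise
    pure for ``set2``.  Labels outside both sets may fall anywhere.
    """
    labels = set(dendrogram.labels)
    unknown = (set(set1) | set(set2)) - labels
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    set1, set2 = frozenset(set1), frozenset(set2)
    candidates = [frozenset([l]) for l in dendrogram.labels]
    candidates += dendrogram.leaf_sets()
    ok1 = any(leaves & (set1 | set2) == set1 for leaves in candidates)
    ok2 = any(leaves & (set1 | set2) == set2 for leaves in candidates)
    return ok1 and ok2


def pairwise_concordance(a: GeneList, b: GeneList
                         ) -> tuple[int, int, float]:
    """Intersection size, union size, and IoU percentage of two lists."""
    inter = a.symbols & b.symbols
    union = a.symbols | b.symbols
    if not union:
        raise ValueError("concordance undefined for two empty lists")
    return len(inter), len(union), 100.0 * len(inter) / len(union)


@dataclass
class ConcordanceResult:
    """Pairwise and multiway overlap of differentially expressed gene lists."""

    names: list[str]
    pairwise: pd.DataFrame          # columns: list_a, list_b, n_intersection, n_union, pct
    intersection: GeneList
    union_size: int
    pct: float
    empty_inputs: list[str]


def multiway_concordance(lists: list[GeneList]) -> ConcordanceResult:
    """Concordance across >= 2 lists: all-pairs IoU plus the multiway
    intersection over the multiway union.

    Any empty input forces an empty intersection and is flagged in
    ``empty_inputs`` rather than raising.
    """
    if len(lists) < 2:
        raise ValueError("need at least 2 gene lists")
    names = [gl.name for gl in lists]
    if len(set(names)) != len(names):
        raise ValueError("gene list names must be distinct")
    empty = [gl.name for gl in lists if len(gl) == 0]
    rows = []
    for a, b in combinations(lists, 2):
        if len(a.symbols | b.symbols) == 0:
            n_i, n_u, pct = 0, 0, float("nan")
        else:
            n_i, n_u, pct = pairwise_concordance(a, b)
        rows.append({"list_a": a.name, "list_b": b.name,
                     "n_intersection": n_i, "n_union": n_u, "pct": pct})
    inter = frozenset.intersection(*[gl.symbols for gl in lists])
    union = frozenset.union(*[gl.symbols for gl in lists])
    if not union:
        raise ValueError("concordance undefined: all lists empty")
    return ConcordanceResult(
        names=names,
        pairwise=pd.DataFrame(rows),
        intersection=GeneList("multiway_intersection", inter,
                              "intersection of: " + ", ".join(names)),
        union_size=len(union),
        pct=100.0 * len(inter) / len(union),
        empty_inputs=empty,
    )
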