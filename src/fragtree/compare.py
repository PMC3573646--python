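"""Comparing fragmentation trees: Tanimoto similarity, clustering,
and composite-spectrum dot products.

A fragmentation tree is compared as a *set* of elemental formula paths
(EFPs): the Tanimoto coefficient divides the number of EFPs common to
two trees by the size of the union.  Collections of trees become binary
occurrence matrices (tree x EFP) which are clustered agglomeratively on
Euclidean distances.  A cosine ("dot product") comparison of composite
spectra is provided as the conventional baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hierarchy
from scipy.spatial.distance import pdist

from .spectra import Peak

__all__ = [
    "tanimoto",
    "occurrence_matrix",
    "Dendrogram",
    "cluster",
    "similarity_matrix",
    "dot_product",
    "characteristic_efps",
]


def tanimoto(a: Set[str], b: Set[str]) -> float:
    """|a n b| / (|a| + |b| - |a n b|); zero when both sets are empty."""
    inter = len(a & b)
    union = len(a) + len(b) - inter
    return inter / union if union else 0.0


def occurrence_matrix(trees: Sequence[Tuple[str, Set[str]]]) -> pd.DataFrame:
    """Binary tree-by-EFP presence matrix.

    Rows follow the input order of tree identifiers, columns are the
    lexicographically sorted union of the EFP sets.  Duplicate
    identifiers are an error; no column is all-zero by construction.
    """
    ids = [tid for tid, _ in trees]
    if len(set(ids)) != len(ids):
        raise ValueError("tree identifiers must be unique")
    columns = sorted(set().union(*(efps for _, efps in trees))) if trees else []
    data = [[1 if efp in efps else 0 for efp in columns] for _, efps in trees]
    return pd.DataFrame(data, index=ids, columns=columns, dtype=int)


@dataclass
class Dendrogram:
    """Agglomerative merge history over a collection of trees.

    ``linkage_matrix`` is in scipy's standard form; ``labels`` are the
    leaf labels in the (sorted) order used for clustering.
    """

    labels: List[str]
    linkage_matrix: np.ndarray
    method: str

    @property
    def merges(self) -> List[Tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix]

    @property
    def heights(self) -> List[float]:
        return [float(h) for _, _, h, _ in self.linkage_matrix]

    def cut(self, n_clusters: int) -> Dict[str, int]:
        """Labels -> flat cluster index, for a cut into n clusters."""
        flat = _hierarchy.fcluster(
            self.linkage_matrix, t=n_clusters, criterion="maxclust"
        )
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        tree = _hierarchy.to_tree(self.linkage_matrix)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            ld = node.dist - left.dist
            rd = node.dist - right.dist
            return f"({render(left)}:{ld:.6g},{render(right)}:{rd:.6g})"

        return render(tree) + ";"

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "method": self.method,
            "merges": [
                {"left": a, "right": b, "height": h} for a, b, h in self.merges
            ],
        }


def cluster(
    matrix: pd.DataFrame, linkage: str = "complete", metric: str = "euclidean"
) -> Dendrogram:
    """Bottom-up agglomerative clustering of occurrence vectors.

    Default linkage is complete; ``average`` (mean linkage) is offered
    as the alternative.  Rows are sorted lexicographically by label
    before clustering so that relabeling/permutation cannot change the
    merge topology (ties break by label order).
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least two trees")
    if linkage not in ("complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    ordered = matrix.sort_index()
    distances = pdist(ordered.to_numpy(dtype=float), metric=metric)
    z = _hierarchy.linkage(distances, method=linkage)
    return Dendrogram(labels=list(ordered.index), linkage_matrix=z, method=linkage)


def similarity_matrix(
    trees: Sequence[Tuple[str, Set[str]]], metric: str = "tanimoto"
) -> pd.DataFrame:
    """Symmetric pairwise Tanimoto matrix with unit diagonal."""
    if metric != "tanimoto":
        raise ValueError(f"unsupported metric {metric!r}")
    ids = [tid for tid, _ in trees]
    if len(set(ids)) != len(ids):
        raise ValueError("tree identifiers must be unique")
    n = len(trees)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = tanimoto(trees[i][1], trees[j][1])
            out[i, j] = out[j, i] = s
        if not trees[i][1]:
            out[i, i] = 0.0
    return pd.DataFrame(out, index=ids, columns=ids)


def dot_product(
    a: Sequence[Peak], b: Sequence[Peak], bin_tol_mz: float = 0.01
) -> float:
    """Cosine similarity of two composite spectra after m/z alignment.

    Peaks are aligned greedily: walking both spectra in m/z order, the
    nearest unmatched cross-spectrum peak within ``bin_tol_mz`` shares a
    vector dimension; unmatched peaks get dimensions of their own.
    Relative intensities are used, so the score is invariant to uniform
    intensity scaling.
    """
    if not a or not b:
        raise ValueError("dot product of an empty spectrum is undefined")

    def vector(peaks: Sequence[Peak]) -> List[Tuple[float, float]]:
        return sorted(
            (
                (p.mz, p.rel_intensity if p.rel_intensity is not None else p.intensity)
                for p in peaks
            ),
            key=lambda t: t[0],
        )

    va, vb = vector(a), vector(b)
    pairs: List[Tuple[float, float]] = []  # matched (ia, ib) intensities
    used_b: Set[int] = set()
    for mz, inten in va:
        best_j, best_d = None, bin_tol_mz
        for j, (mzb, _) in enumerate(vb):
            if j in used_b:
                continue
            d = abs(mzb - mz)
            if d <= best_d:
                best_j, best_d = j, d
        if best_j is None:
            pairs.append((inten, 0.0))
        else:
            used_b.add(best_j)
            pairs.append((inten, vb[best_j][1]))
    for j, (_, inten) in enumerate(vb):
        if j not in used_b:
            pairs.append((0.0, inten))
    xs = np.array([p[0] for p in pairs])
    ys = np.array([p[1] for p in pairs])
    denom = math.sqrt(float(xs @ xs)) * math.sqrt(float(ys @ ys))
    if denom == 0:
        return 0.0
    return float(xs @ ys) / denom


def characteristic_efps(
    a: Set[str], b: Set[str]
) -> Tuple[Set[str], Set[str], Set[str]]:
    """Partition two EFP sets into (only in a, only in b, shared)."""
    return a - b, b - a, a & b
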