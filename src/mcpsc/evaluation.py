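"""Cluster-quality evaluation of consensus scores.

Directed consensus scores are symmetrized into a distance matrix,
agglomerated by unweighted average linkage (UPGMA), cut to a fixed number
of clusters, and compared against ground-truth fold labels with the
F-measure: each cluster is mapped to its majority class, correct members
count as true positives, the rest of the cluster as false positives, and
mapped-class members outside the cluster as false negatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "FMeasureReport",
    "consensus_to_distance_matrix",
    "hclust_average",
    "cut_to_k",
    "f_measure",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal, non-negative pairwise distances."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        k = len(self.ids)
        if values.shape != (k, k):
            raise ValueError(f"distance matrix shape {values.shape} != ({k}, {k})")
        if not np.allclose(values, values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if values.size and values.min() < 0:
            raise ValueError("distances must be non-negative")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history: ids plus (left, right, height) merges.

    ``left`` and ``right`` are frozensets of member ids; K - 1 merges for K
    leaves, heights non-decreasing for the matrices produced here.
    """

    ids: tuple
    merges: tuple  # ((frozenset, frozenset, float), ...)

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        height: dict[frozenset, float] = {frozenset([i]): 0.0 for i in self.ids}
        text: dict[frozenset, str] = {frozenset([i]): str(i) for i in self.ids}
        node = None
        for left, right, h in self.merges:
            node = left | right
            bl_l = (h - height[left]) / 2.0
            bl_r = (h - height[right]) / 2.0
            text[node] = f"({text[left]}:{bl_l:.6f},{text[right]}:{bl_r:.6f})"
            height[node] = h
        if node is None:
            return f"({','.join(str(i) for i in self.ids)});"
        return text[node] + ";"


@dataclass(frozen=True)
class FMeasureReport:
    """Eq.-style precision/recall summary of a clustering vs true classes."""

    n_clusters: int
    cluster_to_class: tuple  # (cluster_label, mapped_class) pairs
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float


def consensus_to_distance_matrix(
    pairs: Sequence[tuple[str, str]], consensus: Sequence[float]
) -> DistanceMatrix:
    """Symmetrize directed consensus scores into a distance matrix.

    D[a, b] = mean(consensus(a -> b), consensus(b -> a)); the diagonal is
    forced to zero regardless of self-pair scores. Ids are ordered
    lexicographically. Every unordered off-diagonal pair must be covered in
    at least one direction.
    """
    if len(pairs) != len(consensus):
        raise ValueError("pairs and consensus must have equal length")
    score: dict[tuple[str, str], float] = {}
    ids_seen: dict[str, None] = {}
    for (q, d), v in zip(pairs, consensus):
        if (q, d) in score:
            raise ValueError(f"duplicate pair ({q}, {d})")
        score[(q, d)] = float(v)
        ids_seen.setdefault(q, None)
        ids_seen.setdefault(d, None)
    ids = tuple(sorted(ids_seen))
    k = len(ids)
    values = np.zeros((k, k))
    for ai in range(k):
        for bi in range(ai + 1, k):
            a, b = ids[ai], ids[bi]
            fwd = score.get((a, b))
            rev = score.get((b, a))
            if fwd is None and rev is None:
                raise ValueError(f"missing consensus for pair ({a}, {b})")
            vals = [v for v in (fwd, rev) if v is not None]
            values[ai, bi] = values[bi, ai] = float(np.mean(vals))
    return DistanceMatrix(ids=ids, values=values)


def hclust_average(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with unweighted average linkage (UPGMA).

    Repeatedly merges the closest pair of clusters; the distance between
    clusters is the mean over all cross-pair distances. Ties are broken by
    the lexicographically smallest (representative, representative) id
    pair, representatives being each cluster's smallest member id.
    """
    if dm.n < 2:
        raise ValueError("need at least 2 items to cluster")
    idx = {i: n for n, i in enumerate(dm.ids)}
    clusters: list[frozenset] = [frozenset([i]) for i in dm.ids]
    merges: list[tuple[frozenset, frozenset, float]] = []

    def linkage(c1: frozenset, c2: frozenset) -> float:
        rows = [idx[i] for i in c1]
        cols = [idx[j] for j in c2]
        return float(dm.values[np.ix_(rows, cols)].mean())

    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = linkage(clusters[a], clusters[b])
                ra, rb = min(clusters[a]), min(clusters[b])
                key = (d, min(ra, rb), max(ra, rb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (_, _, _), a, b = best
        left, right = clusters[a], clusters[b]
        if min(right) < min(left):
            left, right = right, left
        h = linkage(left, right)
        merges.append((left, right, h))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(left | right)
    return Dendrogram(ids=dm.ids, merges=tuple(merges))


def cut_to_k(dendrogram: Dendrogram, n_clusters: int) -> dict[str, int]:
    """Cut the tree to exactly ``n_clusters`` by undoing the last merges.

    Returns id -> cluster index; clusters are numbered by their smallest
    member id in lexicographic order.
    """
    k = len(dendrogram.ids)
    if not (1 <= n_clusters <= k):
        raise ValueError(f"n_clusters must be in [1, {k}], got {n_clusters}")
    clusters: list[frozenset] = [frozenset([i]) for i in dendrogram.ids]
    for left, right, _ in dendrogram.merges[: k - n_clusters]:
        clusters = [c for c in clusters if c != left and c != right]
        clusters.append(left | right)
    clusters.sort(key=min)
    assignment: dict[str, int] = {}
    for label, members in enumerate(clusters):
        for i in members:
            assignment[i] = label
    return assignment


def f_measure(
    assignments: Mapping[str, int],
    true_labels: Mapping[str, str],
    n_clusters: int | None = None,
) -> FMeasureReport:
    """Precision/recall/F of a flat clustering against true classes.

    Each cluster maps to its majority class (ties resolved to the class of
    the lexicographically smallest member id among the tied classes'
    members). Per cluster: TP = members of the mapped class, FP = other
    members, FN = mapped-class members assigned elsewhere; totals are
    summed over clusters.
    """
    missing = [i for i in assignments if i not in true_labels]
    if missing:
        raise ValueError(f"no true label for domain(s): {sorted(missing)[:5]}")
    clusters: dict[int, list[str]] = {}
    for i, c in assignments.items():
        clusters.setdefault(c, []).append(i)
    if n_clusters is None:
        n_clusters = len(clusters)
    class_sizes: dict[str, int] = {}
    for i in assignments:
        lbl = true_labels[i]
        class_sizes[lbl] = class_sizes.get(lbl, 0) + 1

    tp = fp = fn = 0
    mapping: list[tuple[int, str]] = []
    for c in sorted(clusters):
        members = sorted(clusters[c])
        counts: dict[str, int] = {}
        for i in members:
            counts[true_labels[i]] = counts.get(true_labels[i], 0) + 1
        top = max(counts.values())
        tied = {lbl for lbl, n in counts.items() if n == top}
        if len(tied) == 1:
            mapped = tied.pop()
        else:
            mapped = next(true_labels[i] for i in members if true_labels[i] in tied)
        mapping.append((c, mapped))
        correct = counts[mapped]
        tp += correct
        fp += len(members) - correct
        fn += class_sizes[mapped] - correct

    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return FMeasureReport(
        n_clusters=n_clusters,
        cluster_to_class=tuple(mapping),
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f_measure=f,
    )
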