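"""RSCU-profile clustering: squared Euclidean distances, between-groups
average linkage and newick export.

Species are compared by the squared Euclidean distance between their
59-dimensional RSCU vectors.  The hierarchy uses the between-groups
(unweighted average) linkage — the SPSS "intergroup linkage" procedure —
where the dissimilarity between two clusters is the mean of all original
pairwise dissimilarities across them.  Ties are broken deterministically by
lexicographic comparison of the clusters' sorted leaf-label tuples, so the
topology does not depend on input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    labels: list
    d: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class Dendrogram:
    """Merge history: scipy-style node ids (leaves 0..n-1, then internals)."""

    labels: list
    merges: list = field(default_factory=list)  # (node_a, node_b, height)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_scipy(self) -> np.ndarray:
        """Linkage matrix in scipy.cluster.hierarchy format."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((len(self.merges), 4))
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + k] = size
            Z[k] = [min(a, b), max(a, b), h, size]
        return Z

    def leaf_sets(self) -> dict[int, frozenset]:
        """Node id -> set of leaf labels under that node."""
        n = self.n_leaves
        sets = {i: frozenset([self.labels[i]]) for i in range(n)}
        for k, (a, b, _h) in enumerate(self.merges):
            sets[n + k] = sets[a] | sets[b]
        return sets

    def root_split(self) -> tuple[frozenset, frozenset]:
        """The two leaf-label sets joined by the final merge."""
        sets = self.leaf_sets()
        a, b, _ = self.merges[-1]
        return sets[a], sets[b]


def rscu_distance_matrix(profiles: pd.DataFrame) -> DistanceMatrix:
    """Squared Euclidean distances between species RSCU profiles (rows)."""
    if profiles.isna().any().any():
        warnings.warn("missing RSCU entries imputed as 0 for distances", stacklevel=2)
    X = profiles.fillna(0.0).to_numpy(dtype=float)
    sq = np.sum(X**2, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(profiles.index), d=d)


def average_linkage(dm: DistanceMatrix) -> Dendrogram:
    """Between-groups (unweighted average) agglomerative clustering.

    At each step the pair of clusters with the smallest mean inter-cluster
    dissimilarity (over the *original* matrix) merges; equal candidates are
    ordered by their sorted leaf-label tuples.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("clustering requires at least 2 leaves")
    d0 = np.asarray(dm.d, dtype=float)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    keys = {i: (str(dm.labels[i]),) for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1 :]:
                h = float(np.mean(d0[np.ix_(members[a], members[b])]))
                pair_key = tuple(sorted((keys[a], keys[b])))
                cand = (h, pair_key, a, b)
                if best is None or cand < best:
                    best = cand
        h, _, a, b = best
        merges.append((a, b, h))
        members[next_id] = members[a] + members[b]
        keys[next_id] = tuple(sorted(keys[a] + keys[b]))
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(labels=list(dm.labels), merges=merges)


def _escape_label(label: str) -> str:
    if any(ch in label for ch in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(dendrogram: Dendrogram) -> str:
    """Ultrametric-style newick: a node merged at height h sits at h/2 from
    the leaves, so branch lengths are differences of half-heights."""
    n = dendrogram.n_leaves
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, h) in enumerate(dendrogram.merges):
        node = n + k
        height[node] = h / 2.0
        children[node] = (a, b)
    # canonical child order: lexicographic by sorted leaf labels
    sets = dendrogram.leaf_sets()
    key = {node: tuple(sorted(str(x) for x in s)) for node, s in sets.items()}

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height[node]
        if node < n:
            return f"{_escape_label(str(dendrogram.labels[node]))}:{bl:.12g}"
        a, b = sorted(children[node], key=key.get)
        inner = ",".join(render(c, height[node]) for c in (a, b))
        return f"({inner}):{bl:.12g}"

    root = n + len(dendrogram.merges) - 1
    a, b = sorted(children[root], key=key.get)
    inner = ",".join(render(c, height[root]) for c in (a, b))
    return f"({inner});"
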