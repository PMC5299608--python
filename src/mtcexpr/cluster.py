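"""Unsupervised hierarchical clustering of tumour samples.

Samples (matrix columns) are clustered on Euclidean distances between their
log2 expression vectors with Ward's minimum-variance linkage, in the
squared-distance update convention (the variant R calls ``ward.D2`` and
scipy implements as ``method="ward"``).  Probes are not clustered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


@dataclass
class Dendrogram:
    """Agglomeration result over samples.

    ``linkage`` is the (n-1) x 4 scipy linkage matrix: each row merges two
    nodes at a height; leaves 0..n-1 map to ``labels`` in order.
    """

    linkage: np.ndarray
    labels: list[str]
    method: str = "ward"
    metric: str = "euclidean"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_samples(matrix: pd.DataFrame) -> Dendrogram:
    """Ward/Euclidean dendrogram over the samples of a filtered matrix."""
    if matrix.shape[1] < 3:
        raise ValueError("clustering needs >= 3 samples")
    X = matrix.to_numpy(dtype=float).T
    if not np.isfinite(X).all():
        raise ValueError("non-finite expression values")
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    return Dendrogram(linkage=Z, labels=list(matrix.columns))


def cut_tree(dend: Dendrogram, k: int) -> dict[str, int]:
    """Partition the samples into ``k`` clusters consistent with the merges.

    Cluster ids are arbitrary integers starting at 0.
    """
    if not 1 <= k <= dend.n_leaves:
        raise ValueError(f"k must be in [1, {dend.n_leaves}], got {k}")
    assignments = hierarchy.cut_tree(dend.linkage, n_clusters=k).ravel()
    return dict(zip(dend.labels, (int(c) for c in assignments)))


def _newick_escape(label: str) -> str:
    if any(ch in label for ch in " ();,:'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(dend: Dendrogram) -> str:
    """Newick string with branch lengths = parent height - child height."""
    tree = hierarchy.to_tree(dend.linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{_newick_escape(dend.labels[node.id])}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return render(tree, tree.dist) + ";"


def export_newick(dend: Dendrogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(dend) + "\n")
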