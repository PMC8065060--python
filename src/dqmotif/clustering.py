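"""Haplotype sequence clustering.

Unique DQ haplotype residue strings are compared pairwise with the Levenshtein
edit distance and agglomerated hierarchically under the Ward criterion
(ward.D2 convention: two clusters merge when the increase in within-cluster
sum of squared distances is smallest).  The tree can be rendered as Newick
for phylogenetic-style display of the motif landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

_SEPARATORS = "- \t"


class ClusteringError(ValueError):
    pass


def levenshtein(s1: str, s2: str) -> int:
    """Unit-cost edit distance (substitution/insertion/deletion) between two
    residue strings.  Separator characters ('-', whitespace) are stripped first
    so rendered motifs like 'DCAA-YSARD' compare on their nine residues."""
    for sep in _SEPARATORS:
        s1 = s1.replace(sep, "")
        s2 = s2.replace(sep, "")
    if s1 == s2:
        return 0
    return int(edlib.align(s1, s2, task="distance")["editDistance"])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with row/column labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ClusteringError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ClusteringError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ClusteringError("distance matrix diagonal is not zero")
        if np.any(self.d < 0):
            raise ClusteringError("negative distances")

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "DistanceMatrix":
        """Pairwise Levenshtein distances between labelled sequences.

        Labels are sorted lexicographically, making downstream clustering
        invariant to the input ordering.
        """
        labels = sorted(sequences)
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = levenshtein(sequences[labels[i]], sequences[labels[j]])
        return cls(labels, d)


@dataclass
class ClusterTree:
    """Agglomerative merge history (scipy linkage convention) plus leaf labels."""

    merges: np.ndarray  # (n-1, 4) linkage matrix
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.merges.shape[0] != n - 1:
            raise ClusteringError("tree must contain n-1 merges for n leaves")

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into k clusters."""
        assign = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assign)))

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def cluster(dm: DistanceMatrix, linkage: str = "ward_d2") -> ClusterTree:
    """Agglomerate a distance matrix under the ward.D2 criterion.

    scipy's 'ward' linkage on a precomputed condensed distance vector applies
    the Lance-Williams recurrence on (squared) distances, which is the ward.D2
    convention when the input is a plain distance matrix.
    """
    if linkage != "ward_d2":
        raise ClusteringError(f"unsupported linkage {linkage!r}")
    if len(dm.labels) < 2:
        raise ClusteringError("need at least two sequences to cluster")
    z = hierarchy.linkage(squareform(dm.d, checks=False), method="ward")
    return ClusterTree(z, list(dm.labels))


def _escape(label: str) -> str:
    for ch in "(),:;":
        label = label.replace(ch, "_")
    return label.replace(" ", "_")


def to_newick(tree: ClusterTree) -> str:
    """Render the merge history as a Newick string.

    Branch lengths are merge-height differences (leaves sit at height 0), so
    the root-to-leaf path length equals the root merge height.
    """
    root = hierarchy.to_tree(tree.merges)

    def render(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{_escape(tree.labels[node.id])}:{parent_height:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"


def cluster_sequences(sequences: dict[str, str], k: int | None = None):
    """Convenience wrapper: distances -> tree (-> optional k-cut assignment)."""
    dm = DistanceMatrix.from_sequences(sequences)
    tree = cluster(dm)
    if k is None:
        return tree
    return tree, tree.cut(k)
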