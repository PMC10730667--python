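"""Seeded generators of trees and distance matrices with known ground truth.

Used throughout the test suite: additive matrices from random (optionally
multifurcating) trees exercise consistency, star matrices exercise the
all-pairs-tied path, and Gaussian perturbation makes inputs tie-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import InputError
from .matrix_io import DistanceMatrix
from .tree_model import PhyloTree, TreeNode

__all__ = [
    "GeneratorSpec",
    "random_tree",
    "additive_matrix",
    "star_matrix",
    "perturb",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters for :func:`random_tree`.

    ``polytomy_prob`` is the probability that a coalescence event merges
    more than two lineages (polytomies are built directly, not by collapsing
    short edges, so ground truth contains no zero-length branches).
    """

    n_leaves: int
    polytomy_prob: float = 0.0
    length_dist: Callable[[np.random.Generator], float] | None = None
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise InputError("need at least 2 leaves")
        if not 0.0 <= self.polytomy_prob <= 1.0:
            raise InputError("polytomy_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")

    def draw_length(self, rng: np.random.Generator) -> float:
        if self.length_dist is not None:
            return float(self.length_dist(rng))
        return float(rng.uniform(0.5, 5.0))


def random_tree(spec: GeneratorSpec) -> PhyloTree:
    """Random labeled tree with ``spec.n_leaves`` leaves (T1, T2, ...).

    Built by repeated coalescence of random lineage subsets; with
    ``polytomy_prob == 0`` every internal node is strictly binary (the root,
    as the unrooted central node, has three children).  Fully reproducible
    from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lineages: list[TreeNode] = [
        TreeNode(name=f"T{i + 1}", branch_length=spec.draw_length(rng))
        for i in range(spec.n_leaves)
    ]
    if spec.n_leaves == 2:
        root = TreeNode(children=lineages)
        return PhyloTree(root)

    # Merge while > 3 lineages remain, never leaving exactly 2 behind, so
    # the final join has 3+ lineages and the unrooted tree has no fake root.
    while len(lineages) > 3:
        max_k = len(lineages) - 2  # leave >= 2 plus the merged one => >= 3
        if max_k >= 3 and rng.random() < spec.polytomy_prob:
            k = int(rng.integers(3, max_k + 1))
        else:
            k = 2
        idx = sorted(rng.choice(len(lineages), size=k, replace=False).tolist())
        merged = TreeNode(
            children=[lineages[i] for i in idx],
            branch_length=spec.draw_length(rng),
        )
        lineages = [l for i, l in enumerate(lineages) if i not in set(idx)]
        lineages.append(merged)
    root = TreeNode(children=lineages)
    for child in root.children:
        assert child.branch_length is not None
    return PhyloTree(root)


def additive_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Path-length distance matrix of a tree (labels in leaf traversal order)."""
    # Distance from root to every leaf, plus leaf set under every node,
    # allows D_ij = d_i + d_j - 2 * d_lca via per-node aggregation.
    leaves = tree.root.leaves()
    labels = tuple(n.name for n in leaves)
    index = {id(n): i for i, n in enumerate(leaves)}
    n = len(labels)
    D = np.zeros((n, n))

    def rec(node: TreeNode, depth: float) -> list[tuple[int, float]]:
        """Returns (leaf index, root-to-leaf distance) for the subtree and
        fills in cross-child distances at every internal node."""
        if node.is_leaf:
            return [(index[id(node)], depth)]
        below: list[list[tuple[int, float]]] = []
        for child in node.children:
            below.append(rec(child, depth + (child.branch_length or 0.0)))
        for a in range(len(below)):
            for b in range(a + 1, len(below)):
                for i, di in below[a]:
                    for j, dj in below[b]:
                        D[i, j] = D[j, i] = di + dj - 2.0 * depth
        return [x for sub in below for x in sub]

    rec(tree.root, 0.0)
    return DistanceMatrix(labels, D)


def star_matrix(
    lengths: Sequence[float], labels: Sequence[str] | None = None
) -> DistanceMatrix:
    """Additive matrix of a star tree: D_ij = l_i + l_j."""
    l = np.asarray(lengths, dtype=float)
    if l.size < 3:
        raise InputError("a star matrix needs at least 3 arms")
    if np.any(l <= 0):
        raise InputError("arm lengths must be positive")
    if labels is None:
        labels = tuple(f"T{i + 1}" for i in range(l.size))
    D = l[:, None] + l[None, :]
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(tuple(labels), D)


def perturb(dm: DistanceMatrix, noise_sd: float, seed: int | None = None) -> DistanceMatrix:
    """Add one Gaussian draw per unordered pair to both mirror entries.

    Negative results are clamped to a small positive floor so the output is
    still a valid distance matrix.  ``noise_sd == 0`` is the identity.
    """
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    if noise_sd == 0:
        return dm
    rng = np.random.default_rng(seed)
    D = dm.values.copy()
    n = len(dm)
    for i in range(n):
        for j in range(i + 1, n):
            v = D[i, j] + rng.normal(0.0, noise_sd)
            D[i, j] = D[j, i] = max(v, 1e-6)
    return DistanceMatrix(dm.labels, D)
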