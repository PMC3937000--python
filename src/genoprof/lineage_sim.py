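"""Cell-lineage tree geometry and somatic mutation accumulation.

The synthetic study models a woody plant as a trunk with branches attached
at known heights.  Cell lineages are treated as single files of cells of
fixed length *a* (the unit cell length), so a physical distance *B* along
the tree corresponds to ``g' = B / a`` cell generations.  Each generation a
genome acquires point substitutions at a constant per-base rate ``mu_c``;
leaf genomes therefore diverge in proportion to the generational separation
along the unique tree path between them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TreeSpec",
    "LineageTree",
    "LeafGenome",
    "build_lineage",
    "simulate_leaf_genomes",
    "pairwise_generations",
    "random_genome",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_SET = frozenset("ACGT")


@dataclass(frozen=True)
class TreeSpec:
    """Geometry and mutational parameters of one synthetic tree.

    Distances are in meters.  ``unit_cell_length_a`` converts physical edge
    lengths into cell-generation counts; ``mu_c`` is the constant per-base
    per-generation substitution rate.
    """

    trunk_height: float = 2.5
    branch_attach_heights: tuple[float, ...] = (0.5, 1.4, 2.3)
    leaves_per_branch: int = 3
    branch_length: float = 0.02
    unit_cell_length_a: float = 20e-6
    genome_length_L: int = 10_000
    mu_c: float = 5e-7
    seed: int = 0
    tree_name: str = "A"

    def __post_init__(self) -> None:
        if self.trunk_height <= 0:
            raise ValueError("trunk_height must be > 0")
        if self.branch_length <= 0:
            raise ValueError("branch_length must be > 0")
        if self.unit_cell_length_a <= 0:
            raise ValueError("unit_cell_length_a must be > 0")
        if self.genome_length_L <= 0:
            raise ValueError("genome_length_L must be > 0")
        if self.leaves_per_branch < 1:
            raise ValueError("leaves_per_branch must be >= 1")
        if self.mu_c < 0:
            raise ValueError("mu_c must be >= 0")
        if not self.branch_attach_heights:
            raise ValueError("need at least one branch attach height")
        heights = tuple(self.branch_attach_heights)
        if any(h < 0 or h > self.trunk_height for h in heights):
            raise ValueError("attach heights must lie within [0, trunk_height]")
        if any(b > a for a, b in zip(heights[1:], heights)):
            raise ValueError("attach heights must be nondecreasing (ground to top)")
        object.__setattr__(self, "branch_attach_heights", heights)


@dataclass(frozen=True)
class Edge:
    parent: str
    child: str
    physical_length: float
    generations: int


@dataclass
class LineageTree:
    """Rooted tree: root at the ground, internal trunk nodes at branch
    attach heights, one terminal edge per leaf.

    Leaf labels follow the ``<tree><branch>-<leaf>`` convention (``A1-2`` =
    leaf 2 of branch 1 of tree A, branches numbered ground to top).
    """

    root: str
    edges: list[Edge]
    leaf_branch: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._parent = {e.child: e for e in self.edges}
        if len(self._parent) != len(self.edges):
            raise ValueError("duplicate child node in edge list")
        self._children: dict[str, list[Edge]] = {}
        for e in self.edges:
            self._children.setdefault(e.parent, []).append(e)

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self.leaf_branch)

    def children(self, node: str) -> list[Edge]:
        return self._children.get(node, [])

    def _path_to_root(self, node: str) -> list[Edge]:
        if node != self.root and node not in self._parent:
            raise KeyError(f"unknown node label: {node!r}")
        path = []
        while node != self.root:
            e = self._parent[node]
            path.append(e)
            node = e.parent
        return path

    def path_generations(self, a: str, b: str) -> int:
        """Sum of edge generation counts along the unique a--b path."""
        pa = {e.child: i for i, e in enumerate(self._path_to_root(a))}
        total = 0
        node = b
        if b != self.root and b not in self._parent:
            raise KeyError(f"unknown node label: {b!r}")
        # climb from b until hitting a node on a's root path
        while node != self.root and node not in pa:
            e = self._parent[node]
            total += e.generations
            node = e.parent
        # then add a's edges down to the meeting point
        for e in self._path_to_root(a):
            if e.child == node:
                break
            total += e.generations
        return total


def _edge_generations(length: float, a: float) -> int:
    if a <= 0:
        raise ValueError("unit cell length must be > 0")
    if length < 0:
        raise ValueError("edge length must be >= 0")
    return math.ceil(length / a)


def build_lineage(spec: TreeSpec) -> LineageTree:
    """Deterministically build the lineage tree for a :class:`TreeSpec`.

    Edge generation counts are ``ceil(length / a)`` so that any positive
    physical distance costs at least one cell division.
    """
    a = spec.unit_cell_length_a
    edges: list[Edge] = []
    leaf_branch: dict[str, int] = {}
    prev_node, prev_h = "root", 0.0
    for i, h in enumerate(spec.branch_attach_heights, start=1):
        bp = f"bp{i}"
        seg = h - prev_h
        edges.append(Edge(prev_node, bp, seg, _edge_generations(seg, a)))
        for j in range(1, spec.leaves_per_branch + 1):
            label = f"{spec.tree_name}{i}-{j}"
            edges.append(
                Edge(bp, label, spec.branch_length,
                     _edge_generations(spec.branch_length, a))
            )
            leaf_branch[label] = i
        prev_node, prev_h = bp, h
    return LineageTree(root="root", edges=edges, leaf_branch=leaf_branch)


def pairwise_generations(tree: LineageTree) -> pd.DataFrame:
    """Symmetric matrix of path generation counts between all leaves."""
    labels = tree.leaf_labels
    n = len(labels)
    m = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            g = tree.path_generations(labels[i], labels[j])
            m[i, j] = m[j, i] = g
    return pd.DataFrame(m, index=labels, columns=labels)


@dataclass
class LeafGenome:
    label: str
    sequence: str
    mutations_from_root: int


def random_genome(length: int, seed: int, gc: float = 0.5) -> str:
    """Uniform-composition random genome (equal AT/GC split around ``gc``)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=p)
    return arr.tobytes().decode("ascii")


def _mutate(seq: np.ndarray, n_mut: int, rng: np.random.Generator) -> np.ndarray:
    """Apply ``n_mut`` substitutions at uniform positions, each to a
    uniformly chosen *different* base.  Back mutation can occur across
    events (true point process)."""
    out = seq.copy()
    if n_mut == 0:
        return out
    pos = rng.integers(0, seq.size, size=n_mut)
    for p in pos:
        cur = out[p]
        choices = _BASES[_BASES != cur]
        out[p] = rng.choice(choices)
    return out


def simulate_leaf_genomes(
    tree: LineageTree, root: str, mu_c: float, seed: int
) -> list[LeafGenome]:
    """Evolve the root genome down every lineage-tree edge.

    Per edge, the substitution count is Poisson with mean
    ``mu_c * L * generations`` (constant per-generation rate, repair term
    neglected); children inherit the mutated sequence.  Reproducible under
    ``seed``; substitutions only, so all genomes keep the root length.
    """
    if not root:
        raise ValueError("root sequence must be non-empty")
    if set(root.upper()) - _BASE_SET:
        raise ValueError("root sequence must be over the alphabet ACGT")
    if mu_c < 0:
        raise ValueError("mu_c must be >= 0")
    root = root.upper()
    L = len(root)
    total_g = max(
        (tree.path_generations(leaf, tree.root) for leaf in tree.leaf_labels),
        default=0,
    )
    if mu_c * L * total_g > L:
        warnings.warn(
            "expected mutation load exceeds genome length; Poisson "
            "substitution model is saturating", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    root_arr = np.frombuffer(root.encode("ascii"), dtype=np.uint8).copy()
    leaves: list[LeafGenome] = []

    def descend(node: str, seq: np.ndarray, n_from_root: int) -> None:
        kids = tree.children(node)
        if not kids:
            if node in tree.leaf_branch:
                leaves.append(
                    LeafGenome(node, seq.tobytes().decode("ascii"), n_from_root)
                )
            return
        for e in sorted(kids, key=lambda e: e.child):
            n_mut = int(rng.poisson(mu_c * L * e.generations))
            child_seq = _mutate(seq, n_mut, rng)
            descend(e.child, child_seq, n_from_root + n_mut)

    descend(tree.root, root_arr, 0)
    leaves.sort(key=lambda g: g.label)
    return leaves
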