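"""Ultrametric tree container used across delimitation and simulation.

Nodes are integer indexed: ``0 .. n_tips-1`` are tips, the rest internal.
Heights are times before present (tips at 0, root the oldest node).
Newick parsing/serialisation is delegated to :mod:`dendropy`.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

ULTRAMETRIC_TOL = 1e-9


class TreeValidationError(ValueError):
    pass


@dataclass
class UltrametricTree:
    parent: np.ndarray  # (n_nodes,) index of parent, -1 at root
    heights: np.ndarray  # (n_nodes,) time before present
    tip_labels: list[str]  # labels of nodes 0..n_tips-1

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.heights = np.asarray(self.heights, dtype=float)
        self._children: list[list[int]] | None = None
        self._tips_below: list[np.ndarray] | None = None

    # -- basic structure ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def root_height(self) -> float:
        return float(self.heights[self.root])

    @property
    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    def tips_below(self, node: int) -> np.ndarray:
        """Sorted tip indices in the subtree rooted at ``node``."""
        if self._tips_below is None:
            below: list[set[int]] = [set() for _ in range(self.n_nodes)]
            order = np.argsort(self.heights, kind="stable")  # tips first
            for i in order:
                if not self.children[i]:
                    below[i] = {int(i)}
                else:
                    s: set[int] = set()
                    for c in self.children[i]:
                        s |= below[c]
                    below[i] = s
            self._tips_below = [np.array(sorted(s), dtype=int) for s in below]
        return self._tips_below[node]

    def internal_heights(self) -> np.ndarray:
        """Heights of internal nodes, ascending (from present to root)."""
        internal = np.flatnonzero([len(c) > 0 for c in self.children])
        return np.sort(self.heights[internal])

    def validate(self) -> None:
        """Check ultrametricity (tips at height 0) and ordering of heights."""
        for i in range(self.n_tips):
            if abs(self.heights[i]) > ULTRAMETRIC_TOL:
                raise TreeValidationError(
                    f"tree is not ultrametric: tip {self.tip_labels[i]!r} at height {self.heights[i]:g}"
                )
        for i, p in enumerate(self.parent):
            if p >= 0 and self.heights[p] <= self.heights[i] - ULTRAMETRIC_TOL:
                raise TreeValidationError(f"parent height not above child at node {i}")

    def clusters_at(self, threshold: float) -> list[np.ndarray]:
        """Tip partition induced by a time threshold.

        A cluster is the tip set of each branch crossing the threshold
        (child end strictly below, parent end at/above).  A threshold at or
        above the root height yields the single whole-tree cluster.
        """
        if threshold >= self.root_height:
            return [np.arange(self.n_tips)]
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        clusters = []
        for i, p in enumerate(self.parent):
            if p >= 0 and self.heights[i] < threshold <= self.heights[p]:
                clusters.append(self.tips_below(i))
        return clusters

    # -- newick ------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "UltrametricTree":
        tree = tree.clone(depth=1)
        if len(tree.seed_node.child_nodes()) > 2:
            tree.resolve_polytomies()
        tree.calc_node_ages(ultrametricity_precision=False)
        leaves = [lf for lf in tree.leaf_node_iter()]
        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        index = {id(nd): i for i, nd in enumerate(leaves)}
        for j, nd in enumerate(internals):
            index[id(nd)] = len(leaves) + j
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=int)
        heights = np.zeros(n)
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            heights[i] = nd.age
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
        labels = [lf.taxon.label if lf.taxon else f"t{i}" for i, lf in enumerate(leaves)]
        # snap tip heights to zero: dendropy ages are relative to the lowest leaf
        heights[: len(leaves)] = np.where(
            np.abs(heights[: len(leaves)]) <= ULTRAMETRIC_TOL, 0.0, heights[: len(leaves)]
        )
        out = cls(parent, heights, labels)
        out.validate()
        return out

    @classmethod
    def from_newick(cls, source: str) -> "UltrametricTree":
        """Parse a newick string (not a path)."""
        tree = dendropy.Tree.get(data=source, schema="newick")
        return cls.from_dendropy(tree)

    @classmethod
    def read_newick(cls, path) -> list["UltrametricTree"]:
        """Read one or many trees from a newick file."""
        trees = dendropy.TreeList.get(path=str(path), schema="newick")
        return [cls.from_dendropy(t) for t in trees]

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            if not self.children[node]:
                return self.tip_labels[node]
            inner = ",".join(
                f"{fmt(c)}:{self.heights[node] - self.heights[c]:.12g}" for c in self.children[node]
            )
            return f"({inner})"

        return fmt(self.root) + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")
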