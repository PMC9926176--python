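"""Tree utilities: newick IO via dendropy plus an array-indexed view.

All downstream numerics (pruning likelihoods, stochastic mapping, forward
range simulation, DR) work on :class:`IndexedTree`, a flat array view of a
rooted tree with node ages in My before present (tips of an ultrametric tree
sit at age 0). dendropy remains the IO and manipulation layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "read_newick",
    "parse_newick",
    "to_newick",
    "prune_to_taxa",
    "total_branch_length",
    "IndexedTree",
    "lineages_at",
]


def parse_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def prune_to_taxa(tree: dendropy.Tree, names) -> dendropy.Tree:
    """Return a copy of the tree pruned to the given tip names."""
    keep = set(names)
    pruned = tree.clone(depth=1)
    taxa = [t for t in pruned.taxon_namespace if t.label in keep]
    if not taxa:
        raise ValueError("no requested taxa present on the tree")
    pruned.retain_taxa(taxa)
    return pruned


def total_branch_length(tree: dendropy.Tree) -> float:
    return float(sum(e.length for e in tree.preorder_edge_iter() if e.length))


@dataclass
class IndexedTree:
    """Flat arrays for a rooted (usually binary, ultrametric) tree.

    Node order is a fixed preorder traversal; ``postorder`` gives indices in
    child-before-parent order. Internal nodes get deterministic labels
    ``nd<k>`` (preorder rank) unless already labelled, so output files keyed
    by node label are reproducible.
    """

    parent: np.ndarray        # int, -1 at root
    children: list[list[int]]
    blen: np.ndarray          # float, branch length above each node (root: 0)
    age: np.ndarray           # float, My before present
    labels: list[str]
    is_tip: np.ndarray        # bool

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def root(self) -> int:
        return 0

    @property
    def root_age(self) -> float:
        return float(self.age[0])

    @property
    def postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return np.array(order[::-1], dtype=int)

    @property
    def preorder(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices()]

    def tip_index(self) -> dict[str, int]:
        return {self.labels[i]: int(i) for i in self.tip_indices()}

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        tips = self.age[self.is_tip]
        return bool(np.all(np.abs(tips) <= tol * max(1.0, self.root_age)))

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "IndexedTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        blen = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        labels: list[str] = [""] * n
        is_tip = np.zeros(n, dtype=bool)
        k_internal = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                blen[i] = float(nd.edge.length or 0.0)
            if nd.is_leaf():
                is_tip[i] = True
                labels[i] = nd.taxon.label if nd.taxon else (nd.label or f"tip{i}")
            else:
                labels[i] = nd.label or f"nd{k_internal}"
                k_internal += 1
        # depths then ages relative to the deepest tip
        depth = np.zeros(n)
        for i in range(1, n):
            depth[i] = depth[parent[i]] + blen[i]
        height = depth[is_tip].max()
        age = height - depth
        return cls(parent, children, blen, age, labels, is_tip)

    @classmethod
    def from_newick(cls, newick: str) -> "IndexedTree":
        return cls.from_dendropy(parse_newick(newick))

    def to_newick(self, label_internal: bool = True) -> str:
        def render(v: int) -> str:
            if self.is_tip[v]:
                core = self.labels[v]
            else:
                inner = ",".join(render(c) for c in self.children[v])
                core = f"({inner})" + (self.labels[v] if label_internal else "")
            if self.parent[v] == -1:
                return core
            return f"{core}:{self.blen[v]:.10g}"

        return render(0) + ";"

    def total_length(self) -> float:
        return float(self.blen.sum())


def lineages_at(tree: IndexedTree, t: float) -> int:
    """Number of branches alive at age ``t`` Ma (the LTT curve).

    A branch from parent age a_p down to child age a_c is alive on
    (a_c, a_p]. Ages at or above the root age count the single root lineage.
    """
    if t >= tree.root_age:
        return 1
    pa = tree.age[tree.parent[1:]]
    alive = int(np.sum((tree.age[1:] <= t) & (pa > t)))
    return max(alive, 1)
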