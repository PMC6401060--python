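"""Rooted, dated phylogenies as flat arrays, with Newick I/O via dendropy.

Node ages are in millions of years before present and increase into the
past; extant tips sit at age 0.  Trees must be binary; dated analyses
additionally require ultrametricity (all tips equidistant from the root)
within a relative tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["Phylogeny", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed input trees."""


@dataclass
class Phylogeny:
    """A rooted binary tree stored as parent/children/age arrays.

    Nodes are indexed ``0 .. 2n-2`` with tips first (``0 .. n-1``, in the
    order of ``tip_labels``); ``parent[root] == -1``.  ``postorder`` lists
    all node indices children-before-parents.
    """

    tip_labels: list[str]
    parent: np.ndarray
    children: list[tuple[int, ...]]
    age: np.ndarray
    ultrametric: bool = True

    ULTRAMETRIC_RTOL = 1e-6

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.intp)
        self.age = np.asarray(self.age, dtype=float)
        n = self.n_tips
        if n < 2:
            raise TreeError("a phylogeny needs at least two tips")
        if len(set(self.tip_labels)) != n:
            raise TreeError("tip labels must be unique")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError("tree must have exactly one root")
        self.root = int(roots[0])
        for i, ch in enumerate(self.children):
            if ch and len(ch) != 2:
                raise TreeError(
                    f"node {i} has {len(ch)} children; only binary trees are supported"
                )
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        self.postorder = np.array(order, dtype=np.intp)
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0 and not self.age[p] > self.age[v] - 1e-12:
                raise TreeError(f"node {v} is not younger than its parent")

    # -- basic properties ------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root_age(self) -> float:
        return float(self.age[self.root])

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    def branch_length(self, v: int) -> float:
        p = self.parent[v]
        return float(self.age[p] - self.age[v]) if p >= 0 else 0.0

    def internal_nodes(self) -> list[int]:
        return [int(v) for v in self.postorder if self.children[int(v)]]

    def clade_tips(self, v: int) -> frozenset[str]:
        """Tip labels descending from node ``v``."""
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if self.is_tip(u):
                out.append(self.tip_labels[u])
            else:
                stack.extend(self.children[u])
        return frozenset(out)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_dendropy(
        cls, tree: dendropy.Tree, require_ultrametric: bool = True
    ) -> "Phylogeny":
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        nodes = list(tree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        for nd in tips:
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("every tip must carry a label")
        internals = [nd for nd in nodes if not nd.is_leaf()]
        idx: dict[int, int] = {}
        for i, nd in enumerate(tips + internals):
            idx[id(nd)] = i
        n_nodes = len(nodes)
        parent = np.full(n_nodes, -1, dtype=np.intp)
        children: list[tuple[int, ...]] = [()] * n_nodes
        depth = np.zeros(n_nodes)
        for nd in nodes:
            i = idx[id(nd)]
            kids = nd.child_nodes()
            children[i] = tuple(idx[id(c)] for c in kids)
            if nd.parent_node is not None:
                parent[i] = idx[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeError("every branch must carry a length")
                depth[i] = depth[parent[i]] + nd.edge.length
        root_age = depth.max()
        age = root_age - depth
        labels = [nd.taxon.label for nd in tips]
        if require_ultrametric:
            tol = max(cls.ULTRAMETRIC_RTOL * max(root_age, 1.0), 1e-9)
            tip_ages = age[: len(tips)]
            worst = int(np.argmax(np.abs(tip_ages)))
            if abs(tip_ages[worst]) > tol:
                raise TreeError(
                    f"tree is not ultrametric: tip {labels[worst]!r} sits at age "
                    f"{tip_ages[worst]:.6g} My (tolerance {tol:.3g})"
                )
            age[: len(tips)] = 0.0
        return cls(
            tip_labels=labels,
            parent=parent,
            children=children,
            age=age,
            ultrametric=require_ultrametric,
        )

    @classmethod
    def from_newick(cls, newick: str, require_ultrametric: bool = True) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        return cls.from_dendropy(tree, require_ultrametric=require_ultrametric)

    # -- output ----------------------------------------------------------

    def to_newick(self, precision: int = 10) -> str:
        def render(v: int) -> str:
            if self.is_tip(v):
                body = self.tip_labels[v]
            else:
                body = "(" + ",".join(render(c) for c in self.children[v]) + ")"
            p = self.parent[v]
            if p < 0:
                return body
            return f"{body}:{self.branch_length(v):.{precision}f}"

        return render(self.root) + ";"

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick")
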