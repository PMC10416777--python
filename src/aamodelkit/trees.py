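"""Phylogenetic trees with branch lengths.

Trees are unrooted in interpretation but stored with an arbitrary root
(a trifurcation after unrooting a bifurcating root).  Branch lengths are
expected numbers of substitutions per site.  Newick reading goes through
dendropy (quoted labels, comments); writing is direct.
"""

from __future__ import annotations

import io
from typing import Iterator

import dendropy
import numpy as np


class Node:
    __slots__ = ("children", "parent", "length", "label")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label = label
        self.length = length  # length of the edge to the parent

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """An (arbitrarily rooted) phylogenetic tree with unique leaf labels."""

    def __init__(self, root: Node):
        self.root = root
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        if any(lbl is None for lbl in labels):
            raise ValueError("unlabeled leaf")

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def edges(self) -> list[Node]:
        """Every edge, identified by its child node."""
        return [n for n in self.postorder() if n.parent is not None]

    def tree_length(self) -> float:
        return float(sum(n.length for n in self.edges()))

    # -- structure ---------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.length)
            for ch in node.children:
                c.add(clone(ch))
            return c

        return PhyloTree(clone(self.root))

    def unroot(self) -> "PhyloTree":
        """Collapse a bifurcating root into a trifurcation (in place)."""
        while len(self.root.children) == 2 and not self.root.is_leaf:
            a, b = self.root.children
            keep, merge = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:  # two-leaf tree: nothing to collapse
                break
            # fold the root into `keep`: its edge length is absorbed
            merge.length += keep.length
            self.root.children = list(keep.children) + [merge]
            for ch in self.root.children:
                ch.parent = self.root
            self.root.label = keep.label
        return self

    def reroot_at_edge(self, child: Node, fraction: float = 0.5) -> "PhyloTree":
        """Return a copy rerooted on the edge above ``child`` (for testing
        pulley-principle invariance)."""
        tree = self.copy()
        # locate the corresponding node in the copy by traversal position
        orig = list(self.postorder())
        copied = list(tree.postorder())
        idx = orig.index(child)
        target = copied[idx]
        if target.parent is None:
            return tree
        new_root = Node()
        upper = target.parent
        upper.children.remove(target)
        t = target.length
        new_root.add(target)
        target.length = t * fraction
        # reverse the path from upper to the old root
        prev, prev_len = new_root, t * (1.0 - fraction)
        node = upper
        while node is not None:
            parent = node.parent
            length = node.length
            if parent is not None:
                parent.children.remove(node)
            node.parent = None
            node.children = list(node.children)
            prev.add(node)
            node.length = prev_len
            prev, prev_len = node, length
            node = parent
        # drop degree-2 nodes created at the old root
        _suppress_unifurcations(new_root)
        return PhyloTree(new_root)

    # -- bipartitions ------------------------------------------------------
    def bipartitions(self, include_trivial: bool = False) -> dict[frozenset, float]:
        """Map each bipartition to its branch length.

        A bipartition is keyed by the leaf-label set on the far side of the
        lexicographically smallest leaf (canonical orientation).  With a
        bifurcating root the two root edges describe the same split; their
        lengths are summed, matching the unrooted reading of the tree.
        """
        all_labels = frozenset(self.leaf_labels())
        ref = min(all_labels)
        n = len(all_labels)
        below: dict[Node, frozenset] = {}
        out: dict[frozenset, float] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.label])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            if node.parent is None:
                continue
            side = below[node]
            if ref in side:
                side = all_labels - side
            size = len(side)
            trivial = size in (0, 1, n - 1, n)
            if trivial and not include_trivial:
                continue
            if trivial and size in (0, n):
                continue  # root edge of a rooted-on-leaf representation
            out[side] = out.get(side, 0.0) + node.length
        return out

    def topology_id(self) -> frozenset:
        """Canonical unrooted-topology identifier (set of nontrivial splits)."""
        return frozenset(self.bipartitions().keys())

    # -- newick ------------------------------------------------------------
    def to_newick(self, precision: int = 12) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                lbl = node.label
                if any(c in lbl for c in "(),:;'[] \t"):
                    lbl = "'" + lbl.replace("'", "''") + "'"
                core = lbl
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.parent is not None:
                core += f":{node.length:.{precision}g}"
            return core

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
        return cls._from_dendropy(dt)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            text = fh.read()
        if not text.strip():
            raise ValueError(f"{path}: empty tree file")
        try:
            dt = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)
        except Exception as exc:
            raise ValueError(f"{path}: newick parse error: {exc}") from exc
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "PhyloTree":
        def convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon is not None else None
            node = Node(label, dnode.edge.length if dnode.edge.length is not None else 0.0)
            for ch in dnode.child_nodes():
                node.add(convert(ch))
            return node

        root = convert(dt.seed_node)
        root.length = 0.0
        return cls(root)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self):
        return f"PhyloTree(n_leaves={self.n_leaves}, length={self.tree_length():.4f})"


def _suppress_unifurcations(root: Node) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        for child in list(node.children):
            while len(child.children) == 1:
                gc = child.children[0]
                gc.length += child.length
                gc.parent = node
                node.children[node.children.index(child)] = gc
                child = gc
            stack.append(child)
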