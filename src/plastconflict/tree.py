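"""Leaf-labelled phylogenetic trees with branch lengths and edge support.

Trees are stored rooted for traversal but carry unrooted semantics: a tree
read from Newick is de-rooted to a basal trifurcation when possible, and all
comparisons (bipartitions, Robinson–Foulds) are on unrooted splits. Newick
parsing is delegated to dendropy; serialisation is a plain recursive walk.
Support values ride on internal nodes as Newick internal-node labels, the
convention used by most ML tree software.
"""

from __future__ import annotations

import math
from typing import Callable, Iterator, Optional

import dendropy
import numpy as np


class Node:
    __slots__ = ("children", "parent", "length", "label", "support")

    def __init__(
        self,
        label: Optional[str] = None,
        length: float = 0.0,
        support: Optional[float] = None,
    ) -> None:
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.length = length
        self.label = label
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self


class PhyloTree:
    """Unrooted leaf-labelled tree with non-negative branch lengths.

    ``support`` on an internal node refers to the edge above that node and
    lives in [0, 100] when present.
    """

    def __init__(self, root: Node) -> None:
        self.root = root
        self._check()

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate leaf label: {exc}") from exc
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(f"malformed Newick: {exc}") from exc

        def convert(dnode) -> Node:
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon is not None else dnode.label
                node = Node(label=label)
            else:
                support = None
                if dnode.label is not None and dnode.label != "":
                    try:
                        support = float(dnode.label)
                    except ValueError:
                        support = None
                node = Node(support=support)
            node.length = float(dnode.edge.length) if dnode.edge.length is not None else 0.0
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        root = convert(dt.seed_node)
        tree = cls(root)
        tree.deroot()
        return tree

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: Node, top: bool) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = ""
                if with_support and node.support is not None and not top:
                    label = f"{node.support:.10g}"
                body = f"({inner}){label}"
            if top:
                return body
            return f"{body}:{node.length:.10g}"

        return fmt(self.root, True) + ";"

    def write(self, path, with_support: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(with_support=with_support) + "\n")

    # ------------------------------------------------------------- structure

    def _check(self) -> None:
        labels = self.leaf_labels()
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf label(s): {sorted(dupes)}")
        for node in self.postorder():
            if not math.isfinite(node.length) or node.length < 0:
                raise ValueError("branch lengths must be finite and non-negative")
            if node.support is not None and not (0 <= node.support <= 100):
                raise ValueError("support values must lie in [0, 100]")

    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen:
                out.append(node)
            else:
                stack.append((node, True))
                for child in node.children:
                    stack.append((child, False))
        return out

    def preorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def copy(self) -> "PhyloTree":
        def dup(node: Node) -> Node:
            new = Node(label=node.label, length=node.length, support=node.support)
            for child in node.children:
                new.add(dup(child))
            return new

        return PhyloTree(dup(self.root))

    def deroot(self) -> "PhyloTree":
        """Collapse a degree-2 root into a basal trifurcation (in place)."""
        root = self.root
        while len(root.children) == 2 and self.n_leaves > 2:
            a, b = root.children
            keep, absorb = (a, b) if not b.is_leaf else (b, a) if not a.is_leaf else (a, b)
            if absorb.is_leaf:
                break
            # merge the two root edges onto the children of the absorbed node
            absorb.detach()
            keep.length += absorb.length
            for child in list(absorb.children):
                child.detach()
                root.add(child)
        return self

    def is_binary_unrooted(self) -> bool:
        allowed_root = {2, 3} if self.n_leaves <= 3 else {3}
        for node in self.postorder():
            if node is self.root:
                if len(node.children) not in allowed_root:
                    return False
            elif not node.is_leaf and len(node.children) != 2:
                return False
        return True

    # ----------------------------------------------------------- comparison

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial unrooted splits, each as the canonical leaf-label side.

        The canonical side is the one not containing the lexicographically
        smallest leaf label, so splits compare across trees with the same
        leaf set.
        """
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        below: dict[int, frozenset[str]] = {}
        splits = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                clade = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = clade
                if node is not self.root and 1 < len(clade) < len(all_leaves) - 1:
                    side = clade if ref not in clade else all_leaves - clade
                    splits.add(side)
        return frozenset(splits)

    def rf_distance(self, other: "PhyloTree") -> int:
        a, b = self.bipartitions(), other.bipartitions()
        return len(a ^ b)

    def same_topology(self, other: "PhyloTree") -> bool:
        return (
            set(self.leaf_labels()) == set(other.leaf_labels())
            and self.bipartitions() == other.bipartitions()
        )

    # ------------------------------------------------------------ distances

    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        """All-pairs path-length distances between leaves.

        Returns the sorted leaf labels and the corresponding symmetric
        matrix with zero diagonal.
        """
        leaves = sorted(self.leaves(), key=lambda n: n.label)
        labels = [n.label for n in leaves]
        n = len(leaves)
        depth: dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node is not self.root:
                depth[id(node)] = depth[id(node.parent)] + node.length

        def ancestors(node: Node) -> list[Node]:
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            return path

        anc = [ancestors(leaf) for leaf in leaves]
        anc_sets = [{id(x) for x in path} for path in anc]
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                lca = next(x for x in anc[i] if id(x) in anc_sets[j])
                d = depth[id(leaves[i])] + depth[id(leaves[j])] - 2 * depth[id(lca)]
                dist[i, j] = dist[j, i] = d
        return labels, dist

    def pruned_to(self, labels) -> "PhyloTree":
        """Restrict the tree to a subset of leaves, contracting unary nodes.

        Branch lengths along contracted paths are summed; supports on
        contracted edges are dropped.
        """
        keep = set(labels)
        have = set(self.leaf_labels())
        if keep - have:
            raise ValueError(f"labels not in tree: {sorted(keep - have)}")
        if len(keep) < 2:
            raise ValueError("need at least 2 leaves after pruning")
        tree = self.copy()
        for leaf in [n for n in tree.leaves() if n.label not in keep]:
            leaf.detach()
        changed = True
        while changed:
            changed = False
            for node in tree.postorder():
                if node.is_leaf and node.label is None:
                    # former internal node left childless
                    node.detach()
                    changed = True
                    break
                if not node.is_leaf and len(node.children) == 1 and node is not tree.root:
                    child = node.children[0]
                    child.detach()
                    child.length += node.length
                    parent = node.parent
                    node.detach()
                    parent.add(child)
                    changed = True
                    break
            if not changed and len(tree.root.children) == 1 and not tree.root.children[0].is_leaf:
                new_root = tree.root.children[0]
                new_root.detach()
                new_root.length = 0.0
                tree.root = new_root
                changed = True
        tree.deroot()
        return PhyloTree(tree.root)

    # ------------------------------------------------------ support editing

    def collapse_low_support(self, threshold: float = 10.0) -> "PhyloTree":
        """Contract internal edges with support below ``threshold`` (percent).

        Returns a new tree; leaf edges are never touched. Raises if any
        internal edge lacks a support value.
        """
        tree = self.copy()
        changed = True
        while changed:
            changed = False
            for node in tree.postorder():
                if node.is_leaf or node is tree.root:
                    continue
                if node.support is None:
                    raise ValueError("internal edge without support value")
                if node.support < threshold:
                    parent = node.parent
                    node.detach()
                    for child in list(node.children):
                        child.detach()
                        parent.add(child)
                    changed = True
                    break
        return tree

    # ------------------------------------------------------------------ NNI

    def internal_edges(self) -> list[Node]:
        """Child nodes of internal edges eligible for NNI (internal, non-root)."""
        return [
            n
            for n in self.postorder()
            if not n.is_leaf and n is not self.root and len(n.children) == 2
        ]

    def nni_neighbors(self) -> Iterator["PhyloTree"]:
        """Yield every tree one NNI move away (two per internal edge)."""
        n_edges = len(self.internal_edges())
        for edge_idx in range(n_edges):
            for which in (0, 1):
                yield self.apply_nni(edge_idx, which)

    def apply_nni(
        self, edge_idx: int, which: int, return_edge: bool = False
    ):
        """Return a copy with one NNI applied around internal edge ``edge_idx``.

        ``which`` selects which child of the lower node is exchanged with the
        first sibling subtree on the upper side of the edge. With
        ``return_edge`` the central node of the rearranged edge is returned
        alongside the tree.
        """
        tree = self.copy()
        v = tree.internal_edges()[edge_idx]
        p = v.parent
        sib = next(c for c in p.children if c is not v)
        moved = v.children[which]
        moved.detach()
        sib.detach()
        v.add(sib)
        p.add(moved)
        v.support = None
        if return_edge:
            return tree, v
        return tree


# ------------------------------------------------------------ construction


def random_topology(labels: list[str], rng: np.random.Generator) -> PhyloTree:
    """Uniform-ish random unrooted binary topology by sequential insertion.

    Branch lengths are set to zero; assign them afterwards.
    """
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves for an unrooted topology")
    labels = list(labels)
    order = rng.permutation(len(labels))
    root = Node()
    for i in order[:3]:
        root.add(Node(label=labels[i]))
    tree = PhyloTree(root)
    for i in order[3:]:
        # pick a random edge (any non-root node) and bisect it
        candidates = [n for n in tree.postorder() if n is not tree.root]
        target = candidates[rng.integers(len(candidates))]
        parent = target.parent
        target.detach()
        mid = Node()
        mid.add(target)
        mid.add(Node(label=labels[i]))
        parent.add(mid)
    return tree


def assign_branch_lengths(
    tree: PhyloTree, draw: Callable[[], float]
) -> PhyloTree:
    """Assign every edge a length drawn from ``draw`` (in place)."""
    for node in tree.postorder():
        if node is not tree.root:
            node.length = float(draw())
    return tree
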