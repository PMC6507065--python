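"""Rooted species trees with a single marked foreground branch.

The scan tests one branch of the tree at a time ("foreground"); the mark is
carried in Newick text as the ``#1`` suffix on the node subtending the
branch, the de-facto dialect of branch-site analysis inputs. Internally a
tree is flattened to parent/child index arrays in post-order, which is the
layout the pruning likelihood consumes directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

__all__ = ["LabeledTree", "TreeFormatError", "read_newick_labeled", "write_newick_labeled"]


class TreeFormatError(ValueError):
    """Raised for malformed Newick input or an illegal foreground marking."""


@dataclass
class _Node:
    index: int
    label: str | None
    parent: int | None
    length: float | None
    children: list[int] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class LabeledTree:
    """A rooted tree whose nodes are stored in post-order (root last).

    ``foreground`` is the index of the node whose subtending edge is the
    foreground branch, or ``None`` when no branch is marked. Branch lengths
    are expected substitutions per codon; ``None`` means "to be estimated".
    """

    nodes: list[_Node]
    foreground: int | None = None

    # -- structure queries ------------------------------------------------
    @property
    def root(self) -> _Node:
        return self.nodes[-1]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes if n.is_leaf)

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.nodes if n.is_leaf]

    def postorder(self) -> list[_Node]:
        return self.nodes

    def find(self, label: str) -> _Node:
        """Return the node (leaf or named internal clade) with this label."""
        for n in self.nodes:
            if n.label == label:
                return n
        raise KeyError(f"no node labelled {label!r}")

    def leaves_under(self, index: int) -> set[str]:
        out: set[str] = set()
        stack = [index]
        while stack:
            n = self.nodes[stack.pop()]
            if n.is_leaf:
                out.add(n.label)
            else:
                stack.extend(n.children)
        return out

    # -- foreground handling ----------------------------------------------
    def with_foreground(self, label: str) -> "LabeledTree":
        """Copy of the tree with the edge above the named node marked."""
        t = self.copy()
        node = t.find(label)
        if node.parent is None:
            raise TreeFormatError("cannot mark the root edge as foreground")
        t.foreground = node.index
        return t

    def without_foreground(self) -> "LabeledTree":
        t = self.copy()
        t.foreground = None
        return t

    def copy(self) -> "LabeledTree":
        nodes = [
            _Node(n.index, n.label, n.parent, n.length, list(n.children))
            for n in self.nodes
        ]
        return LabeledTree(nodes, self.foreground)

    def scaled(self, factor: float) -> "LabeledTree":
        t = self.copy()
        for n in t.nodes:
            if n.length is not None:
                n.length *= factor
        return t

    def unrooted_view(self) -> "LabeledTree":
        """Collapse a binary root: its two subtending edges are one branch.

        Under a reversible substitution process the two edges meeting at a
        binary root are identifiable only through their sum, so likelihood
        computation and simulation operate on the unrooted tree. The merged
        branch keeps a foreground mark carried by either half. Trees whose
        root is already multifurcating (or 2-taxon trees, where there is
        nothing to merge into) are returned unchanged.
        """
        root = self.root
        if len(root.children) != 2:
            return self.copy()
        a, b = (self.nodes[c] for c in root.children)
        keep = a if a.children else b  # becomes the new root
        move = b if keep is a else a
        if not keep.children:
            return self.copy()  # 2-taxon tree

        merged_len = None
        if keep.length is not None or move.length is not None:
            merged_len = (keep.length or 0.0) + (move.length or 0.0)
        fg_on_merged = self.foreground in (a.index, b.index)

        nodes: list[_Node] = []
        fg_new: list[int | None] = [None]
        _remap: dict[int, int] = {}

        def build(old: _Node) -> int:
            for c in old.children:
                build(self.nodes[c])
            idx = len(nodes)
            nodes.append(_Node(idx, old.label, None, old.length,
                               [_remap[c] for c in old.children]))
            _remap[old.index] = idx
            if self.foreground == old.index:
                fg_new[0] = idx
            return idx

        # children of the new root: keep's children, then the merged branch
        for c in keep.children:
            build(self.nodes[c])
        move_idx = build(move)
        nodes[move_idx].length = merged_len
        if fg_on_merged:
            fg_new[0] = move_idx
        root_idx = len(nodes)
        nodes.append(_Node(root_idx, keep.label, None, None,
                           [_remap[c] for c in keep.children] + [move_idx]))
        for n in nodes:
            for c in n.children:
                nodes[c].parent = n.index
        return LabeledTree(nodes, fg_new[0])

    def newick(self) -> str:
        return write_newick_labeled(self)


def _strip_mark(label: str | None) -> tuple[str | None, bool]:
    if label is not None and label.endswith("#1"):
        stripped = label[:-2] or None
        return stripped, True
    return label, False


def read_newick_labeled(text: str) -> LabeledTree:
    """Parse Newick text, honouring at most one ``#1`` foreground mark.

    The mark may sit on a leaf (``A#1``) or on an internal node
    (``(A,B)#1``); it designates the edge subtending that node. Branch
    lengths are optional. Two or more marks, or malformed Newick, raise
    :class:`TreeFormatError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeFormatError(f"malformed Newick: {exc}") from exc

    nodes: list[_Node] = []
    index_of: dict[int, int] = {}
    marks: list[int] = []
    for dnode in dtree.postorder_node_iter():
        raw = dnode.taxon.label if dnode.taxon is not None else dnode.label
        label, marked = _strip_mark(raw)
        idx = len(nodes)
        index_of[id(dnode)] = idx
        nodes.append(_Node(idx, label, None, dnode.edge.length))
        if marked:
            marks.append(idx)
    for dnode in dtree.postorder_node_iter():
        idx = index_of[id(dnode)]
        if dnode.parent_node is not None:
            nodes[idx].parent = index_of[id(dnode.parent_node)]
            nodes[nodes[idx].parent].children.append(idx)

    labels = [n.label for n in nodes if n.is_leaf]
    if len(set(labels)) != len(labels):
        raise TreeFormatError("duplicate leaf labels")
    if len(marks) > 1:
        raise TreeFormatError(f"{len(marks)} foreground '#1' marks found; at most one allowed")
    return LabeledTree(nodes, marks[0] if marks else None)


def write_newick_labeled(tree: LabeledTree) -> str:
    """Render the tree as Newick, re-attaching the ``#1`` mark if present."""
    buf = io.StringIO()

    def emit(idx: int) -> None:
        node = tree.nodes[idx]
        if node.children:
            buf.write("(")
            for i, c in enumerate(node.children):
                if i:
                    buf.write(",")
                emit(c)
            buf.write(")")
        if node.label is not None:
            buf.write(node.label)
        if tree.foreground == idx:
            buf.write("#1")
        if node.length is not None:
            buf.write(f":{node.length:.10g}")

    emit(tree.root.index)
    buf.write(";")
    return buf.getvalue()
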