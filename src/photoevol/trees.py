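"""Rooted phylogeny container and Newick input/output.

The tree is the coordinate system every inferred substitution event maps
onto: events are anchored to the branch above a (child) node.  Parsing is
delegated to dendropy; internally a minimal node structure is kept so the
likelihood machinery can index it directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import dendropy


class TreeError(ValueError):
    """Raised for malformed Newick, duplicate labels or bad branch lengths."""


@dataclass(eq=False)  # identity comparison/hash: nodes are places in one tree
class TreeNode:
    name: str
    length: Optional[float] = None  # None only at the root
    parent: Optional["TreeNode"] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node


class PhyloTree:
    """A rooted tree with branch lengths in substitutions/site.

    Node names are unique across the whole tree; unnamed internal nodes
    are assigned ``N<i>`` labels at construction.  An optional outgroup
    clade may be tagged (by its subtending node) so event extraction can
    exclude it.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.outgroup_node: Optional[TreeNode] = None
        self._finalize()

    def _finalize(self) -> None:
        counter = 0
        seen: set[str] = set()
        for node in self.postorder():
            if not node.name:
                while f"N{counter}" in seen:
                    counter += 1
                node.name = f"N{counter}"
                counter += 1
            if node.name in seen:
                raise TreeError(f"duplicate node label {node.name!r}")
            seen.add(node.name)
            if node.is_root:
                continue
            if node.length is None:
                raise TreeError(f"missing branch length above {node.name!r}")
            if not (node.length >= 0) or node.length != node.length:
                raise TreeError(f"bad branch length {node.length!r} above {node.name!r}")

    # -- traversal ----------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def node(self, name: str) -> TreeNode:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- outgroup -----------------------------------------------------
    def tag_outgroup(self, labels: set[str] | str) -> None:
        """Tag the smallest clade containing ``labels`` as the outgroup."""
        if isinstance(labels, str):
            labels = {labels}
        self.outgroup_node = self.mrca(labels)

    def mrca(self, labels: set[str]) -> TreeNode:
        want = set(labels)
        below: dict[TreeNode, set[str]] = {}
        best: Optional[TreeNode] = None
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.name}
            else:
                below[node] = set().union(*(below[c] for c in node.children))
            if want <= below[node] and best is None:
                best = node
        if best is None:
            missing = want - below[self.root]
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        return best

    def descendant_leaves(self, node: TreeNode) -> set[str]:
        out = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.name)
            stack.extend(n.children)
        return out

    def in_clade(self, node: TreeNode, clade_root: TreeNode) -> bool:
        while node is not None:
            if node is clade_root:
                return True
            node = node.parent
        return False

    # -- serialization ------------------------------------------------
    def newick(self, include_internal_names: bool = True, precision: int = 10) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = node.name if include_internal_names else ""
                body = f"({inner}){label}"
            if node.is_root:
                return body
            return f"{body}:{node.length:.{precision}g}"

        return fmt(self.root) + ";"

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        tree = PhyloTree.__new__(PhyloTree)
        tree.root = clone(self.root)
        tree.outgroup_node = None
        if self.outgroup_node is not None:
            tree.outgroup_node = tree.node(self.outgroup_node.name)
        return tree


def _from_dendropy(dtree: dendropy.Tree, default_length: Optional[float]) -> PhyloTree:
    def convert(dnode, is_root: bool) -> TreeNode:
        name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
        length = dnode.edge.length
        if length is None and not is_root:
            if default_length is None:
                raise TreeError(f"missing branch length above {name or 'an internal node'}")
            length = default_length
        node = TreeNode(name, None if is_root else float(length))
        for child in dnode.child_nodes():
            node.add_child(convert(child, False))
        return node

    return PhyloTree(convert(dtree.seed_node, True))


def read_newick(
    path: str | Path, default_length: Optional[float] = None
) -> PhyloTree:
    """Read a rooted Newick tree from a file path or literal string.

    Missing branch lengths are rejected unless ``default_length`` is
    given.  Duplicate leaf labels raise :class:`TreeError`.
    """
    text = Path(path).read_text() if Path(str(path)).exists() else str(path)
    return parse_newick(text, default_length=default_length)


def parse_newick(text: str, default_length: Optional[float] = None) -> PhyloTree:
    if text.count("(") != text.count(")"):
        raise TreeError("unbalanced parentheses in Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeError(f"Newick parse failure: {exc}") from exc
    labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate leaf labels: {dup}")
    return _from_dendropy(dtree, default_length)


def write_newick(tree: PhyloTree, path: str | Path, **kwargs) -> None:
    Path(path).write_text(tree.newick(**kwargs) + "\n")
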