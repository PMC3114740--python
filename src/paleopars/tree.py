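"""Rooted phylogenetic trees.

A deliberately small tree class tuned for the parsimony dynamic programmes and
rearrangement enumeration used throughout the package.  Newick serialization is
delegated to dendropy; trees are rooted as written and polytomies are preserved.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy

__all__ = ["Node", "PhyloTree", "TreeError"]


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("label", "children", "parent", "age")

    def __init__(self, label: Optional[str] = None, age: Optional[float] = None):
        self.label = label
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.age = age

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, {len(self.children)} children)"


class PhyloTree:
    """A rooted tree with tips, optional polytomies, and optional node ages."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=False
            )
        except Exception as exc:  # dendropy raises various parse errors
            raise TreeError(f"newick parse error: {exc}") from exc

        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(label=label)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        tree = cls(convert(dtree.seed_node))
        labels = tree.tip_labels()
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate tip labels in newick")
        return tree

    def to_newick(self, include_ages: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                core = _quote(node.label or "")
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if include_ages and node.age is not None and node.parent is not None:
                core += f":{node.parent.age - node.age:g}"
            return core

        return fmt(self.root) + ";"

    # --------------------------------------------------------- traversal
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen or node.is_tip:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def find_tip(self, label: str) -> Node:
        for node in self.tips():
            if node.label == label:
                return node
        raise TreeError(f"tip {label!r} not in tree")

    # ------------------------------------------------------------- basics
    def copy(self) -> "PhyloTree":
        def dup(node: Node) -> Node:
            new = Node(label=node.label, age=node.age)
            for child in node.children:
                new.add_child(dup(child))
            return new

        return PhyloTree(dup(self.root))

    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    def mrca(self, labels: Iterable[str]) -> Node:
        want = set(labels)
        best = None
        for node in self.postorder():
            below = self.tipset(node)
            if want <= below and (best is None or len(below) < len(self.tipset(best))):
                best = node
        if best is None:
            raise TreeError("labels not all present in tree")
        return best

    def tipset(self, node: Node) -> frozenset[str]:
        if node.is_tip:
            return frozenset([node.label])
        out: set[str] = set()
        for child in node.children:
            out |= self.tipset(child)
        return frozenset(out)

    # ---------------------------------------------------------- topology
    def clades(self) -> set[frozenset[str]]:
        """Tip sets of all internal nodes except the root (rooted clades)."""
        out: set[frozenset[str]] = set()
        sets: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                sets[id(node)] = frozenset([node.label])
            else:
                s = frozenset().union(*(sets[id(c)] for c in node.children))
                sets[id(node)] = s
                if node.parent is not None:
                    out.add(s)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted splits, each canonicalized to the side that
        excludes the lexicographically smallest tip label."""
        all_tips = frozenset(self.tip_labels())
        ref = min(all_tips)
        out: set[frozenset[str]] = set()
        for clade in self.clades():
            side = clade if ref not in clade else all_tips - clade
            if 2 <= len(side) <= len(all_tips) - 2:
                out.add(side)
        return out

    def has_clade(self, tipset: frozenset[str]) -> bool:
        return frozenset(tipset) in self.clades() or frozenset(tipset) == frozenset(
            self.tip_labels()
        )

    def restrict(self, keep: Iterable[str]) -> "PhyloTree":
        """Restriction to a tip subset, suppressing degree-2 internal nodes."""
        keep = set(keep)

        def prune(node: Node) -> Optional[Node]:
            if node.is_tip:
                if node.label in keep:
                    return Node(label=node.label, age=node.age)
                return None
            kids = [k for k in (prune(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            new = Node(label=node.label, age=node.age)
            for k in kids:
                new.add_child(k)
            return new

        root = prune(self.root)
        if root is None:
            raise TreeError("restriction removed every tip")
        return PhyloTree(root)

    def reroot_at_tip_edge(self, label: str) -> "PhyloTree":
        """Return a copy rerooted so `label` hangs off a degree-2 root.

        Used to orient trees at an outgroup for ACCTRAN/DELTRAN.
        """
        return _reroot_at_tip(self, label)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return (
            set(self.tip_labels()) == set(other.tip_labels())
            and self.clades() == other.clades()
        )

    def __hash__(self):
        return hash((frozenset(self.tip_labels()), frozenset(self.clades())))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.to_newick()})"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]{},;:'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def same_unrooted_topology(a: PhyloTree, b: PhyloTree) -> bool:
    return set(a.tip_labels()) == set(b.tip_labels()) and a.bipartitions() == b.bipartitions()


def _reroot_at_tip(tree: PhyloTree, label: str) -> PhyloTree:
    """Reroot (unrooted semantics) on the edge leading to tip `label`."""
    work = tree.copy()
    tip = work.find_tip(label)
    if tip.parent is None:
        raise TreeError("cannot reroot at a lone root tip")
    adj: dict[int, list[Node]] = {}
    nodes: dict[int, Node] = {}
    for node in work.postorder():
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        if node.parent is not None:
            adj[id(node)].append(node.parent)
            adj.setdefault(id(node.parent), []).append(node)

    newroot = Node()
    newroot.add_child(Node(label=label))

    def build(node: Node, came_from: Node, parent_new: Node) -> None:
        neighbours = [n for n in adj[id(node)] if n is not came_from]
        if not neighbours:  # a tip
            parent_new.add_child(Node(label=node.label))
            return
        new = parent_new.add_child(Node())
        for nb in neighbours:
            build(nb, node, new)

    build(tip.parent, tip, newroot)
    return _suppress_unifurcations(PhyloTree(newroot))


def _suppress_unifurcations(tree: PhyloTree) -> PhyloTree:
    def fix(node: Node) -> Node:
        node.children = [fix(c) for c in node.children]
        for c in node.children:
            c.parent = node
        if len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            child.parent = node.parent
            return child
        return node

    root = fix(tree.root)
    while len(root.children) == 1 and not root.children[0].is_tip:
        root = root.children[0]
        root.parent = None
    return PhyloTree(root)
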