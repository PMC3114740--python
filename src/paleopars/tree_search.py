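"""Minimum-score tree search under equal, scaled, or implied weighting.

Searches use random-addition-sequence starting trees improved by
subtree-pruning-regrafting (SPR, which subsumes NNI) and tree-bisection-
reconnection (TBR), accepting strict improvements, optionally under a backbone
constraint on a taxon subset with the remaining ("floating") taxa free to
attach anywhere.  An exhaustive enumerator over all unrooted topologies serves
as the exact oracle on small instances.

Trees are handled in an unrooted convention: a trifurcating root node, so every
non-root node corresponds to exactly one unrooted edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Optional, Union

import numpy as np

from .matrix_io import CharacterMatrix, MatrixError
from .parsimony import LENGTH_TOL, PackedMatrix, WeightScheme, scaling_weights
from .tree import Node, PhyloTree, TreeError

__all__ = [
    "BackboneConstraint",
    "SearchResult",
    "Objective",
    "satisfies_constraint",
    "heuristic_search",
    "exhaustive_search",
    "strict_consensus",
    "majority_consensus",
    "n_unrooted_topologies",
]

MAX_EXHAUSTIVE_TAXA = 9


@dataclass
class BackboneConstraint:
    """A resolved tree on a taxon subset; `floating` taxa may attach anywhere."""

    backbone: PhyloTree
    floating: frozenset = frozenset()

    def __post_init__(self):
        self.floating = frozenset(self.floating)
        overlap = set(self.backbone.tip_labels()) & self.floating
        if overlap:
            raise MatrixError(f"taxa both in backbone and floating: {sorted(overlap)}")


@dataclass
class SearchResult:
    best_score: float
    best_trees: list[PhyloTree]
    replicates_hitting_best: int
    seed: int


class Objective:
    """Scores trees: weighted parsimony length or the implied-weighting fit."""

    def __init__(
        self,
        matrix: CharacterMatrix,
        weights: Optional[WeightScheme] = None,
    ):
        self.matrix = matrix
        self.weights = weights or WeightScheme(mode="equal")
        self.packed = PackedMatrix(matrix)
        if self.weights.mode == "implied":
            scale = scaling_weights(matrix).weights_for(matrix)
            self._scale = scale
            self._mins = self.packed.min_lengths
        elif self.weights.mode == "scaled" and self.weights.per_char_weights is None:
            self._w = scaling_weights(matrix).weights_for(matrix)
        else:
            self._w = self.weights.weights_for(matrix)

    def score(self, tree: PhyloTree) -> float:
        raw = self.packed.per_char_lengths(tree)
        if self.weights.mode == "implied":
            h = (raw - self._mins) * self._scale
            return float(np.sum(h / (h + self.weights.k)))
        return float(raw @ self._w)

    __call__ = score


# ------------------------------------------------------------- constraints


def _splits_conflict(a: frozenset, b: frozenset, universe: frozenset) -> bool:
    ac, bc = universe - a, universe - b
    return all((a & b, a & bc, ac & b, ac & bc))


def compatible_with_backbone(tree: PhyloTree, backbone: PhyloTree) -> bool:
    """True iff the tree restricted to the common tip set does not contradict
    any backbone bipartition (the backbone may be less resolved)."""
    common = set(tree.tip_labels()) & set(backbone.tip_labels())
    if len(common) < 4:
        return True
    rt = tree.restrict(common)
    rb = backbone.restrict(common) if set(backbone.tip_labels()) != common else backbone
    universe = frozenset(common)
    tree_splits = rt.bipartitions()
    for split in rb.bipartitions():
        if split in tree_splits:
            continue
        if any(_splits_conflict(split, ts, universe) for ts in tree_splits):
            return False
    return True


def satisfies_constraint(tree: PhyloTree, constraint: BackboneConstraint) -> bool:
    missing = set(constraint.backbone.tip_labels()) - set(tree.tip_labels())
    if missing:
        raise MatrixError(f"backbone tips not in tree: {sorted(missing)}")
    return compatible_with_backbone(tree, constraint.backbone)


def has_split(tree: PhyloTree, tipset: Iterable[str]) -> bool:
    """Is the tip set monophyletic in the unrooted sense (a split of the tree)?"""
    tipset = frozenset(tipset)
    universe = frozenset(tree.tip_labels())
    if not tipset <= universe:
        raise MatrixError("tip set not contained in tree")
    if len(tipset) < 2 or len(universe - tipset) < 2:
        return True  # trivial splits are present in every unrooted tree
    ref = min(universe)
    side = tipset if ref not in tipset else universe - tipset
    return side in tree.bipartitions()


# --------------------------------------------------------------- surgery


def _copy_with_map(tree: PhyloTree) -> tuple[PhyloTree, dict[int, Node]]:
    mapping: dict[int, Node] = {}

    def dup(node: Node) -> Node:
        new = Node(label=node.label, age=node.age)
        mapping[id(node)] = new
        for child in node.children:
            new.add_child(dup(child))
        return new

    return PhyloTree(dup(tree.root)), mapping


def _detach(tree: PhyloTree, node: Node) -> Node:
    """Remove the subtree rooted at `node`; suppress the resulting degree-2
    node; returns the detached subtree root (parentless)."""
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    if parent is tree.root:
        if len(parent.children) == 1 and not parent.children[0].is_tip:
            # splice the lone internal child into the root
            child = parent.children[0]
            parent.children = child.children
            for c in parent.children:
                c.parent = parent
    elif len(parent.children) == 1:
        only = parent.children[0]
        gp = parent.parent
        gp.children[gp.children.index(parent)] = only
        only.parent = gp
    return node


def _regraft(tree: PhyloTree, subtree: Node, edge_node: Node) -> None:
    """Attach `subtree` on the edge above `edge_node`."""
    parent = edge_node.parent
    joint = Node()
    parent.children[parent.children.index(edge_node)] = joint
    joint.parent = parent
    joint.add_child(edge_node)
    joint.add_child(subtree)


def _edge_nodes(tree: PhyloTree) -> list[Node]:
    return [n for n in tree.postorder() if n.parent is not None]


def _subtree_nodes(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def spr_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    """All subtree-prune-regraft neighbours (deterministic order)."""
    edges = _edge_nodes(tree)
    for i in range(len(edges)):
        work, mapping = _copy_with_map(tree)
        prune = mapping[id(edges[i])]
        forbidden = {id(prune.parent)} | {id(n) for n in _subtree_nodes(prune)}
        sub = _detach(work, prune)
        rest_edges = _edge_nodes(work)
        if not rest_edges:
            continue
        for u in rest_edges:
            if id(u) in forbidden:
                continue
            w2, m2 = _copy_with_map(work)
            _regraft(w2, _copy_node(sub), m2[id(u)])
            yield w2


def _copy_node(node: Node) -> Node:
    new = Node(label=node.label, age=node.age)
    for child in node.children:
        new.add_child(_copy_node(child))
    return new


def _reroot_node(subtree: Node, target: Node) -> Node:
    """Reroot a detached subtree so the attachment lies on the edge above
    `target`; returns a degree-2 root."""
    adj: dict[int, list[Node]] = {}
    for n in _subtree_nodes(subtree):
        adj.setdefault(id(n), [])
        for c in n.children:
            adj[id(n)].append(c)
            adj.setdefault(id(c), []).append(n)

    newroot = Node()

    def build(node: Node, came_from: Optional[Node], parent_new: Node) -> None:
        neighbours = [x for x in adj[id(node)] if x is not came_from]
        if not neighbours:
            parent_new.add_child(Node(label=node.label))
            return
        new = parent_new.add_child(Node())
        for nb in neighbours:
            build(nb, node, new)

    build(target, target.parent, newroot)
    build(target.parent, target, newroot)
    # collapse single-child buds left by tips
    def squeeze(n: Node) -> Node:
        n.children = [squeeze(c) for c in n.children]
        for c in n.children:
            c.parent = n
        if len(n.children) == 1 and n.label is None:
            child = n.children[0]
            child.parent = n.parent
            return child
        return n

    return squeeze(newroot)


def tbr_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    """Tree-bisection-reconnection neighbours: SPR moves plus all reattachment
    points within the pruned subtree."""
    yield from spr_neighbors(tree)
    edges = _edge_nodes(tree)
    for i, enode in enumerate(edges):
        if len(enode.children) < 2:
            continue  # pruning a tip: rerooting is vacuous, covered by SPR
        work, mapping = _copy_with_map(tree)
        prune = mapping[id(edges[i])]
        forbidden = {id(prune.parent)} | {id(n) for n in _subtree_nodes(prune)}
        sub = _detach(work, prune)
        rest_edges = [u for u in _edge_nodes(work) if id(u) not in forbidden]
        inner_edges = [n for n in _subtree_nodes(sub) if n.parent is not None]
        for target in inner_edges:
            if target.parent is sub and len(sub.children) == 2:
                continue  # same attachment as SPR
            croot, ctarget = _copy_node_with(sub, target)
            resub = _reroot_node(croot, ctarget)
            for u in rest_edges:
                w2, m2 = _copy_with_map(work)
                _regraft(w2, _copy_node(resub), m2[id(u)])
                yield w2


def _copy_node_with(node: Node, target: Node) -> tuple[Node, Node]:
    """Copy a subtree, returning (copy_root, copy_of_target)."""
    found = [None]

    def dup(n: Node) -> Node:
        new = Node(label=n.label, age=n.age)
        if n is target:
            found[0] = new
        for child in n.children:
            new.add_child(dup(child))
        return new

    root = dup(node)
    return root, found[0]


# ----------------------------------------------------------- enumeration


def n_unrooted_topologies(n_taxa: int) -> int:
    out = 1
    for k in range(3, n_taxa + 1):
        out *= 2 * k - 5
    return max(out, 1)


def enumerate_topologies(taxa: list[str]) -> Iterator[PhyloTree]:
    """All unrooted binary topologies, as trees with a trifurcating root."""
    taxa = list(taxa)
    if len(taxa) < 3:
        root = Node()
        for t in taxa:
            root.add_child(Node(label=t))
        yield PhyloTree(root)
        return

    def base() -> PhyloTree:
        root = Node()
        for t in taxa[:3]:
            root.add_child(Node(label=t))
        return PhyloTree(root)

    def expand(tree: PhyloTree, idx: int) -> Iterator[PhyloTree]:
        if idx == len(taxa):
            yield tree
            return
        for enode in list(_edge_nodes(tree)):
            work, mapping = _copy_with_map(tree)
            _regraft(work, Node(label=taxa[idx]), mapping[id(enode)])
            yield from expand(work, idx + 1)

    yield from expand(base(), 3)


# ---------------------------------------------------------------- search


def _topo_key(tree: PhyloTree) -> frozenset:
    return frozenset(tree.bipartitions())


def _bitkey(tree: PhyloTree, bits: dict[str, int], fullmask: int) -> frozenset:
    """Cheap canonical topology key: non-trivial splits as integer bitmasks,
    each on the side excluding taxon bit 0."""
    masks: dict[int, int] = {}
    out = []
    for node in tree.postorder():
        if node.is_tip:
            masks[id(node)] = bits[node.label]
        else:
            v = 0
            for c in node.children:
                v |= masks.pop(id(c))
            masks[id(node)] = v
            if node.parent is not None:
                side = v if not (v & 1) else fullmask ^ v
                if side.bit_count() >= 2 and (fullmask ^ side).bit_count() >= 2:
                    out.append(side)
    return frozenset(out)


class _CachedScore:
    """Memoizes tree scores by unrooted topology within one search."""

    def __init__(self, score_fn, taxa: list[str]):
        self._fn = score_fn
        self.bits = {t: 1 << i for i, t in enumerate(sorted(taxa))}
        self.fullmask = (1 << len(taxa)) - 1
        self.cache: dict[frozenset, float] = {}

    def key(self, tree: PhyloTree) -> frozenset:
        return _bitkey(tree, self.bits, self.fullmask)

    def __call__(self, tree: PhyloTree) -> float:
        key = self.key(tree)
        hit = self.cache.get(key)
        if hit is None:
            hit = self._fn(tree)
            self.cache[key] = hit
        return hit


def _make_validator(
    constraint: Optional[BackboneConstraint],
    tree_filter: Optional[Callable[[PhyloTree], bool]],
) -> Callable[[PhyloTree], bool]:
    def valid(tree: PhyloTree) -> bool:
        if constraint is not None and not compatible_with_backbone(
            tree, constraint.backbone
        ):
            return False
        if tree_filter is not None and not tree_filter(tree):
            return False
        return True

    return valid


def _random_addition_tree(
    taxa: list[str],
    objective: Objective,
    constraint: Optional[BackboneConstraint],
    rng: np.random.Generator,
) -> PhyloTree:
    order = [taxa[i] for i in rng.permutation(len(taxa))]
    root = Node()
    for t in order[:3]:
        root.add_child(Node(label=t))
    tree = PhyloTree(root)
    backbone = constraint.backbone if constraint is not None else None
    for label in order[3:]:
        candidates = []
        for enode in _edge_nodes(tree):
            work, mapping = _copy_with_map(tree)
            _regraft(work, Node(label=label), mapping[id(enode)])
            if backbone is not None and not compatible_with_backbone(work, backbone):
                continue
            candidates.append((objective.score(work), work))
        if not candidates:
            raise TreeError(
                "no constraint-satisfying insertion position during stepwise addition"
            )
        best = min(c[0] for c in candidates)
        ties = [w for s, w in candidates if s <= best + LENGTH_TOL]
        tree = ties[int(rng.integers(len(ties)))]
    return tree


def _hill_climb(
    tree: PhyloTree,
    score_fn: Callable[[PhyloTree], float],
    valid: Callable[[PhyloTree], bool],
) -> tuple[PhyloTree, float]:
    cur, cur_score = tree, score_fn(tree)
    while True:
        improved = False
        for gen in (spr_neighbors, tbr_neighbors):
            for nb in gen(cur):
                if not valid(nb):
                    continue
                s = score_fn(nb)
                if s < cur_score - LENGTH_TOL:
                    cur, cur_score = nb, s
                    improved = True
                    break
            if improved:
                break
        if not improved:
            return cur, cur_score


def _plateau(
    tree: PhyloTree,
    score: float,
    score_fn: Callable[[PhyloTree], float],
    valid: Callable[[PhyloTree], bool],
    cap: int,
    key_fn: Callable[[PhyloTree], frozenset] = _topo_key,
) -> dict[frozenset, PhyloTree]:
    found = {key_fn(tree): tree}
    queue = [tree]
    while queue and len(found) < cap:
        t = queue.pop()
        for nb in spr_neighbors(t):
            key = key_fn(nb)
            if key in found or not valid(nb):
                continue
            if abs(score_fn(nb) - score) <= LENGTH_TOL:
                found[key] = nb
                queue.append(nb)
    return found


def _resolve_objective(matrix, objective) -> Objective:
    if isinstance(objective, Objective):
        return objective
    if objective is None:
        return Objective(matrix, WeightScheme(mode="equal"))
    if isinstance(objective, WeightScheme):
        return Objective(matrix, objective)
    raise MatrixError(f"cannot interpret objective {objective!r}")


def heuristic_search(
    matrix: CharacterMatrix,
    objective: Union[Objective, WeightScheme, None] = None,
    constraint: Optional[BackboneConstraint] = None,
    n_replicates: int = 10,
    seed: int = 0,
    tree_filter: Optional[Callable[[PhyloTree], bool]] = None,
    max_trees: int = 10_000,
    plateau_cap: int = 100,
    taxa: Optional[list[str]] = None,
) -> SearchResult:
    """Random-addition + SPR/TBR hill-climbing search; deterministic per seed."""
    if n_replicates < 1:
        raise MatrixError("n_replicates must be >= 1")
    obj = _resolve_objective(matrix, objective)
    taxa = list(taxa) if taxa is not None else list(matrix.taxa)
    valid = _make_validator(constraint, tree_filter)
    rng = np.random.default_rng(seed)
    scorer = _CachedScore(obj.score, taxa)

    best_score = np.inf
    best: dict[frozenset, PhyloTree] = {}
    hits = 0
    for _ in range(n_replicates):
        start = _random_addition_tree(taxa, obj, constraint, rng)
        if not valid(start):
            start = _repair(start, scorer, valid)
            if start is None:
                continue
        local, local_score = _hill_climb(start, scorer, valid)
        if local_score < best_score - LENGTH_TOL:
            best_score = local_score
            best = {}
            hits = 0
        if local_score <= best_score + LENGTH_TOL:
            hits += 1
            for key, t in _plateau(
                local, local_score, scorer, valid, plateau_cap, scorer.key
            ).items():
                if len(best) >= max_trees:
                    break
                best.setdefault(key, t)
    if not best:
        raise TreeError("no constraint-satisfying tree constructible")
    return SearchResult(
        best_score=float(best_score),
        best_trees=list(best.values()),
        replicates_hitting_best=hits,
        seed=seed,
    )


def _repair(
    tree: PhyloTree,
    score_fn: Callable[[PhyloTree], float],
    valid: Callable[[PhyloTree], bool],
) -> Optional[PhyloTree]:
    """Cheapest valid SPR/TBR neighbour of an invalid starting tree."""
    best = None
    best_score = np.inf
    for nb in tbr_neighbors(tree):
        if valid(nb):
            s = score_fn(nb)
            if s < best_score:
                best, best_score = nb, s
    return best


def exhaustive_search(
    matrix: CharacterMatrix,
    objective: Union[Objective, WeightScheme, None] = None,
    constraint: Optional[BackboneConstraint] = None,
    tree_filter: Optional[Callable[[PhyloTree], bool]] = None,
    taxa: Optional[list[str]] = None,
) -> SearchResult:
    """Exact global optimum by enumeration of all unrooted topologies."""
    obj = _resolve_objective(matrix, objective)
    taxa = list(taxa) if taxa is not None else list(matrix.taxa)
    if len(taxa) > MAX_EXHAUSTIVE_TAXA:
        raise MatrixError(
            f"{len(taxa)} taxa exceed the exhaustive-search bound "
            f"({MAX_EXHAUSTIVE_TAXA})"
        )
    valid = _make_validator(constraint, tree_filter)
    best_score = np.inf
    best: dict[frozenset, PhyloTree] = {}
    for tree in enumerate_topologies(taxa):
        if not valid(tree):
            continue
        s = obj.score(tree)
        if s < best_score - LENGTH_TOL:
            best_score = s
            best = {_topo_key(tree): tree}
        elif s <= best_score + LENGTH_TOL:
            best.setdefault(_topo_key(tree), tree)
    if not best:
        raise TreeError("no constraint-satisfying tree exists")
    return SearchResult(
        best_score=float(best_score),
        best_trees=list(best.values()),
        replicates_hitting_best=1,
        seed=0,
    )


# --------------------------------------------------------------- consensus


def _rooted_clades_at(tree: PhyloTree, ref: str) -> set[frozenset]:
    return tree.reroot_at_tip_edge(ref).clades()


def _tree_from_clades(tips: list[str], clades: set[frozenset]) -> PhyloTree:
    items: dict[frozenset, Node] = {
        frozenset([t]): Node(label=t) for t in tips
    }
    for clade in sorted(clades, key=len):
        if len(clade) < 2 or len(clade) >= len(tips):
            continue
        node = Node()
        for key in [k for k in items if k <= clade]:
            node.add_child(items.pop(key))
        items[clade] = node
    root = Node()
    for node in items.values():
        root.add_child(node)
    return PhyloTree(root)


def _check_same_tips(trees: list[PhyloTree]) -> list[str]:
    tipsets = {frozenset(t.tip_labels()) for t in trees}
    if len(tipsets) != 1:
        raise MatrixError("consensus requires identical tip sets")
    return sorted(tipsets.pop())


def strict_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the clades present in every input tree."""
    tips = _check_same_tips(trees)
    ref = tips[0]
    clade_sets = [_rooted_clades_at(t, ref) for t in trees]
    common = set.intersection(*clade_sets)
    return _tree_from_clades(tips, common)


def majority_consensus(trees: list[PhyloTree], threshold: float = 0.5) -> PhyloTree:
    """Tree of clades occurring in more than `threshold` of the input trees."""
    if threshold < 0.5:
        raise MatrixError("majority threshold below 0.5 can yield incompatible clades")
    tips = _check_same_tips(trees)
    ref = tips[0]
    counts: dict[frozenset, int] = {}
    for t in trees:
        for clade in _rooted_clades_at(t, ref):
            counts[clade] = counts.get(clade, 0) + 1
    keep = {c for c, n in counts.items() if n / len(trees) > threshold}
    return _tree_from_clades(tips, keep)
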