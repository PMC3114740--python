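"""Bremer branch support and double-decay branch support with floating fossils.

Bremer support (BS) for a clade is the extra weighted tree length needed before
the clade is lost: the score of the shortest tree in which the clade is *not*
monophyletic, minus the optimal score.  Double-decay branch support (ddBS)
measures the same quantity for a relationship among extant taxa only, with all
extinct taxa free to attach anywhere ("floating"), so the cost reflects
contrasting relationships among living lineages irrespective of fossil
placements.  ddBS >= BS for the corresponding extant clade because breaking the
relationship among extant taxa forces the full clade to break as well.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Optional, Union

from .matrix_io import CharacterMatrix, MatrixError
from .parsimony import WeightScheme
from .tree import PhyloTree
from .tree_search import (
    BackboneConstraint,
    MAX_EXHAUSTIVE_TAXA,
    Objective,
    exhaustive_search,
    has_split,
    heuristic_search,
)

__all__ = [
    "SupportResult",
    "bremer_support",
    "double_decay_support",
    "crown_exclusion_ddbs",
    "format_bs",
    "format_ddbs",
]


@dataclass
class SupportResult:
    clade: frozenset
    bs: Optional[float] = None
    ddbs: Optional[float] = None
    suboptimal_tree: Optional[PhyloTree] = None


def format_bs(value: float) -> float:
    """Paper convention: BS rounded *up* to the nearest tenth of a step."""
    return math.ceil(value * 10 - 1e-9) / 10


def format_ddbs(value: float) -> float:
    """Paper convention: ddBS rounded *up* to the nearest whole step."""
    return float(math.ceil(value - 1e-9))


def _search(matrix, objective, constraint, tree_filter, n_replicates, seed, method):
    if method == "exhaustive" or (
        method == "auto" and matrix.n_taxa <= MAX_EXHAUSTIVE_TAXA
    ):
        return exhaustive_search(
            matrix, objective, constraint=constraint, tree_filter=tree_filter
        )
    return heuristic_search(
        matrix,
        objective,
        constraint=constraint,
        tree_filter=tree_filter,
        n_replicates=n_replicates,
        seed=seed,
    )


def bremer_support(
    matrix: CharacterMatrix,
    weights: Union[WeightScheme, Objective, None],
    best_score: float,
    clade,
    n_replicates: int = 10,
    seed: int = 0,
    method: str = "auto",
) -> SupportResult:
    """Converse-constraint search: shortest tree lacking the clade.

    `best_score` is the optimal score of the unconstrained analysis; the seed
    is offset by a hash of the clade so different clades draw independent
    addition sequences while remaining reproducible.
    """
    clade = frozenset(clade)
    universe = set(matrix.taxa)
    if not 2 <= len(clade) < len(universe):
        raise MatrixError("clade must be a proper subset with at least 2 tips")
    if len(universe - clade) < 2:
        raise MatrixError(
            "clade is the complement of a single tip: unbreakable in the "
            "unrooted sense"
        )
    clade_seed = (seed + zlib.crc32(",".join(sorted(clade)).encode())) % (2**31)
    res = _search(
        matrix,
        weights,
        None,
        lambda t: not has_split(t, clade),
        n_replicates,
        clade_seed,
        method,
    )
    return SupportResult(
        clade=clade,
        bs=res.best_score - best_score,
        suboptimal_tree=res.best_trees[0],
    )


def _collapse_clade(tree: PhyloTree, clade: frozenset) -> PhyloTree:
    """Copy of `tree` with the split subtending `clade` collapsed.

    Rerooted at a tip outside the clade first so the split corresponds to a
    unique edge (a root-adjacent clade's split otherwise survives through the
    complement edge)."""
    outside = sorted(set(tree.tip_labels()) - clade)
    if not outside:
        raise MatrixError("clade spans the whole tree")
    work = tree.reroot_at_tip_edge(outside[0])
    for node in work.postorder():
        if node.parent is not None and work.tipset(node) == clade:
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx : idx + 1] = node.children
            for c in node.children:
                c.parent = parent
            return work
    raise MatrixError("clade not present in backbone tree")


def _extant_split_absent(tree: PhyloTree, clade: frozenset, extant: frozenset) -> bool:
    """True when the extant-restricted tree lacks the clade as a split.

    Fossil members of a clade never count toward the monophyly predicate.
    """
    restricted = tree.restrict(extant & set(tree.tip_labels()))
    return not has_split(restricted, clade)


def double_decay_support(
    matrix: CharacterMatrix,
    weights: Union[WeightScheme, Objective, None],
    extant_backbone: PhyloTree,
    target_clade,
    fossils,
    n_replicates: int = 10,
    seed: int = 0,
    method: str = "auto",
    best_score: Optional[float] = None,
) -> SupportResult:
    """ddBS: cost of contrasting relationships among extant taxa with all
    extinct taxa floating.

    The backbone (with the tested node collapsed) is enforced for the other
    extant relationships; the search looks for the shortest tree whose
    extant-restricted topology lacks the target clade.
    """
    target_clade = frozenset(target_clade)
    extant = frozenset(extant_backbone.tip_labels())
    if not target_clade <= extant:
        raise MatrixError("target clade must consist of extant (backbone) taxa")
    fossils = frozenset(fossils)
    if best_score is None:
        base = _search(matrix, weights, None, None, n_replicates, seed, method)
        best_score = base.best_score
    if len(target_clade) >= 2 and len(extant - target_clade) >= 2 and has_split(
        extant_backbone, target_clade
    ):
        reduced = _collapse_clade(extant_backbone, target_clade)
    else:
        # the backbone does not enforce the tested grouping: nothing to collapse
        reduced = extant_backbone
    constraint = BackboneConstraint(reduced, fossils)
    clade_seed = (seed + zlib.crc32(",".join(sorted(target_clade)).encode())) % (2**31)
    res = _search(
        matrix,
        weights,
        constraint,
        lambda t: _extant_split_absent(t, target_clade, extant),
        n_replicates,
        clade_seed,
        method,
    )
    return SupportResult(
        clade=target_clade,
        ddbs=res.best_score - best_score,
        suboptimal_tree=res.best_trees[0],
    )


def _fossil_in_crown(tree: PhyloTree, crown: frozenset, focal: str, extant: frozenset) -> bool:
    """Is the focal fossil inside the clade spanned by the crown's extant
    members?  Evaluated on the tree restricted to extant taxa + the fossil,
    rooted at an extant taxon outside the crown."""
    keep = (extant & set(tree.tip_labels())) | {focal}
    restricted = tree.restrict(keep)
    outside = sorted(extant - crown)
    if not outside:
        raise MatrixError("crown clade must exclude at least one extant taxon")
    rooted = restricted.reroot_at_tip_edge(outside[0])
    return focal in rooted.tipset(rooted.mrca(crown))


def crown_exclusion_ddbs(
    matrix: CharacterMatrix,
    weights: Union[WeightScheme, Objective, None],
    extant_backbone: PhyloTree,
    crown_clade,
    focal_fossil: str,
    other_fossils,
    n_replicates: int = 10,
    seed: int = 0,
    method: str = "auto",
    best_score: Optional[float] = None,
) -> SupportResult:
    """Step cost of forcing one fossil inside a crown clade.

    The extant backbone is enforced, the focal fossil is constrained to attach
    inside the clade spanned by the crown's extant members, and all other
    fossils float.  The returned value is the score difference against the
    optimum under the backbone alone.
    """
    crown_clade = frozenset(crown_clade)
    other_fossils = frozenset(other_fossils)
    if focal_fossil in other_fossils:
        raise MatrixError("focal fossil cannot also be in the floating set")
    extant = frozenset(extant_backbone.tip_labels())
    floating = other_fossils | {focal_fossil}
    constraint = BackboneConstraint(extant_backbone, floating)
    if best_score is None:
        base = _search(matrix, weights, constraint, None, n_replicates, seed, method)
        best_score = base.best_score
    res = _search(
        matrix,
        weights,
        constraint,
        lambda t: _fossil_in_crown(t, crown_clade, focal_fossil, extant),
        n_replicates,
        (seed + 1) % (2**31),
        method,
    )
    return SupportResult(
        clade=crown_clade,
        ddbs=res.best_score - best_score,
        suboptimal_tree=res.best_trees[0],
    )
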