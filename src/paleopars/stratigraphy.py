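"""Stratigraphic congruence: ghost lineages, MIG, MSM*, GER, and significance.

A rooted tree plus first-appearance datums (FADs) implies ghost lineages: the
span between a node's age (the oldest FAD among its descendants) and each
child's age.  Their sum is the minimum implied gap (MIG).  MSM* = G_min / MIG
behaves like a consistency index of a stratigraphic character whose states are
the distinct FADs with irreversible age-difference costs; GER =
(G_max - MIG) / (G_max - G_min) behaves like its retention index.  Significance
follows the permutation scheme of shuffling FADs across tips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .matrix_io import AgeTable, CharacterSpec, MatrixError
from .tree import Node, PhyloTree

__all__ = [
    "StratFit",
    "StratCharacter",
    "node_min_ages",
    "mig",
    "ger",
    "msm_star",
    "strat_permutation_test",
    "stratigraphic_character",
    "stratfit",
]

_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"


@dataclass
class StratFit:
    mig: float
    g_min: float
    g_max: float
    msm_star: float
    ger: Optional[float]
    p_value: Optional[float]
    per_branch_ghost: dict[str, float] = field(default_factory=dict)


@dataclass
class StratCharacter:
    """Time as an irreversible character: one state per distinct FAD."""

    spec: CharacterSpec  # kind="irreversible", states ordered old -> young
    state_ages: tuple[float, ...]
    tip_states: dict[str, str]


def _fads(tree: PhyloTree, ages: AgeTable) -> dict[str, float]:
    out = {}
    for label in tree.tip_labels():
        if label not in ages:
            raise MatrixError(f"tip {label!r} has no age entry")
        out[label] = ages.fad(label)
    return out


def node_min_ages(tree: PhyloTree, ages: AgeTable) -> dict[int, float]:
    """Minimum node ages consistent with the record: each internal node takes
    the oldest FAD among its tip descendants.  Keyed by id(node)."""
    fad = _fads(tree, ages)
    out: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_tip:
            out[id(node)] = fad[node.label]
        else:
            out[id(node)] = max(out[id(c)] for c in node.children)
    return out


def _branch_ghosts(tree: PhyloTree, ages: AgeTable) -> dict[Node, float]:
    node_age = node_min_ages(tree, ages)
    out: dict[Node, float] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        out[node] = node_age[id(node.parent)] - node_age[id(node)]
    return out


def mig(tree: PhyloTree, ages: AgeTable) -> float:
    """Minimum implied gap: the summed ghost-lineage duration (Ma)."""
    return float(sum(_branch_ghosts(tree, ages).values()))


def _bounds(tree: PhyloTree, ages: AgeTable) -> tuple[float, float]:
    fads = list(_fads(tree, ages).values())
    oldest = max(fads)
    g_min = oldest - min(fads)
    g_max = float(sum(oldest - f for f in fads))
    return g_min, g_max


def ger(tree: PhyloTree, ages: AgeTable) -> float:
    """Gap excess ratio: (G_max - MIG) / (G_max - G_min), in [0, 1]."""
    g_min, g_max = _bounds(tree, ages)
    if g_max == g_min:
        raise MatrixError("GER undefined: all first appearances are equal")
    return float((g_max - mig(tree, ages)) / (g_max - g_min))


def msm_star(tree: PhyloTree, ages: AgeTable) -> float:
    """Modified Manhattan stratigraphic measure: G_min / MIG, in (0, 1]."""
    g_min, _ = _bounds(tree, ages)
    m = mig(tree, ages)
    if m == 0:
        if g_min == 0:
            return 1.0
        raise MatrixError("MIG = 0 with a positive FAD range is impossible")
    return float(g_min / m)


def strat_permutation_test(
    tree: PhyloTree, ages: AgeTable, n_perm: int = 999, seed: int = 0
) -> float:
    """Permutation significance of stratigraphic fit.

    FADs are shuffled across tips (ties preserved); p = (1 + #{permuted
    MSM* >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise MatrixError("n_perm must be >= 1")
    fad = _fads(tree, ages)
    labels = sorted(fad)
    values = np.array([fad[l] for l in labels])
    observed = msm_star(tree, ages)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = values[rng.permutation(len(values))]
        table = AgeTable()
        for label, f in zip(labels, perm):
            table.add(label, float(f), None, extant=(f == 0))
        if msm_star(tree, table) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def stratigraphic_character(ages: AgeTable) -> StratCharacter:
    """Irreversible multistate character with one state per distinct FAD.

    cost(older -> younger) = age difference; reversals (younger -> older) are
    infinite.  The Sankoff length of this character on a tree equals the
    tree's MIG.
    """
    distinct = sorted({ages.fad(t) for t in ages.taxa()}, reverse=True)
    if len(distinct) < 2:
        raise MatrixError("need at least two distinct FADs")
    if len(distinct) > len(_SYMBOLS):
        raise MatrixError("more distinct FADs than available state symbols")
    symbols = tuple(_SYMBOLS[i] for i in range(len(distinct)))
    k = len(distinct)
    cost = np.full((k, k), np.inf)
    np.fill_diagonal(cost, 0.0)
    for i in range(k):
        for j in range(k):
            if distinct[i] > distinct[j]:
                cost[i, j] = distinct[i] - distinct[j]
    spec = CharacterSpec(
        char_id=0, kind="irreversible", state_space=symbols, cost=cost
    )
    by_age = {a: symbols[i] for i, a in enumerate(distinct)}
    tip_states = {t: by_age[ages.fad(t)] for t in ages.taxa()}
    return StratCharacter(spec=spec, state_ages=tuple(distinct), tip_states=tip_states)


def stratfit(
    tree: PhyloTree,
    ages: AgeTable,
    n_perm: int = 999,
    seed: int = 0,
) -> StratFit:
    """All stratigraphic-fit statistics for one tree."""
    g_min, g_max = _bounds(tree, ages)
    m = mig(tree, ages)
    ghosts = {
        (node.label or f"node[{','.join(sorted(tree.tipset(node)))}]"): dur
        for node, dur in _branch_ghosts(tree, ages).items()
    }
    return StratFit(
        mig=m,
        g_min=g_min,
        g_max=g_max,
        msm_star=msm_star(tree, ages),
        ger=ger(tree, ages) if g_max > g_min else None,
        p_value=strat_permutation_test(tree, ages, n_perm=n_perm, seed=seed)
        if n_perm
        else None,
        per_branch_ghost=ghosts,
    )
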