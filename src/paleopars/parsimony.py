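"""Weighted parsimony scoring.

Characters are scored by a generalized Sankoff dynamic programme over state
sets: unit costs for unordered characters (Fitch), rank distances for ordered
characters, and arbitrary (possibly asymmetric, possibly infinite) cost tables
for irreversible characters such as the stratigraphic character.  Missing and
polymorphic cells enter the DP as their state sets with zero internal cost.

A matrix is compiled once (`PackedMatrix`) and then scored on many candidate
trees; columns sharing a cost structure are batched into numpy arrays so a
single tree evaluation costs a few vectorized operations per node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .matrix_io import CharacterMatrix, CharacterSpec, MatrixError
from .tree import PhyloTree

__all__ = [
    "WeightScheme",
    "LengthReport",
    "PackedMatrix",
    "character_length",
    "min_length",
    "scaling_weights",
    "tree_length",
    "implied_weight_score",
]

LENGTH_TOL = 1e-6  # trees within this many weighted steps count as equal


@dataclass
class WeightScheme:
    """How characters are weighted: equal, between-character scaled, or implied."""

    mode: str = "equal"  # {"equal", "scaled", "implied"}
    k: float = 3.0
    per_char_weights: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.mode not in ("equal", "scaled", "implied"):
            raise MatrixError(f"unknown weighting mode {self.mode!r}")
        if self.mode == "implied" and not self.k > 0:
            raise MatrixError("implied weighting requires k > 0")
        if self.per_char_weights is not None:
            w = np.asarray(self.per_char_weights, dtype=float)
            if np.any(~np.isfinite(w)) or np.any(w <= 0):
                raise MatrixError("per-character weights must be finite and positive")
            self.per_char_weights = w

    def weights_for(self, matrix: CharacterMatrix) -> np.ndarray:
        if self.per_char_weights is not None:
            if len(self.per_char_weights) != matrix.n_char:
                raise MatrixError("weight vector length != number of characters")
            return self.per_char_weights
        return np.ones(matrix.n_char)


@dataclass
class LengthReport:
    per_char_length: np.ndarray  # weighted steps per character
    total: float
    per_char_h: np.ndarray  # extra steps beyond minimum (unweighted units)


# ------------------------------------------------------------------ packing


class PackedMatrix:
    """A character matrix compiled for repeated tree scoring."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.taxa = list(matrix.taxa)
        self.n_char = matrix.n_char
        self.min_lengths = np.array(
            [min_length(matrix.column(j), matrix.specs[j]) for j in range(matrix.n_char)]
        )
        # batch characters: all unordered columns share one padded unit-cost
        # group, all ordered columns one padded rank-distance group (padding
        # states are unreachable at tips and never cheaper internally), and
        # each distinct irreversible cost table its own group
        groups: dict[tuple, list[int]] = {}
        for j, spec in enumerate(matrix.specs):
            if spec.kind == "unordered":
                key = ("unordered",)
            elif spec.kind == "ordered":
                key = ("ordered",)
            else:
                key = ("irreversible", spec.n_states, spec.cost_matrix().tobytes())
            groups.setdefault(key, []).append(j)
        self.groups = []
        taxon_index = {t: i for i, t in enumerate(self.taxa)}
        for key, char_idx in groups.items():
            kind = key[0]
            n_states = max(matrix.specs[j].n_states for j in char_idx)
            if kind == "unordered":
                cost = 1.0 - np.eye(n_states)
            elif kind == "ordered":
                idx = np.arange(n_states, dtype=float)
                cost = np.abs(idx[:, None] - idx[None, :])
            else:
                cost = matrix.specs[char_idx[0]].cost_matrix()
            m = len(char_idx)
            # tip cost arrays: (n_taxa, m, S); 0 where symbol allowed else inf
            tipcost = np.full((len(self.taxa), m, n_states), np.inf)
            for col, j in enumerate(char_idx):
                spec = matrix.specs[j]
                for t, label in enumerate(self.taxa):
                    cell = matrix.cells[t][j]
                    for sym in cell:
                        tipcost[t, col, spec.symbol_index(sym)] = 0.0
            self.groups.append(
                {
                    "chars": np.array(char_idx),
                    "cost": cost,
                    "unit": kind == "unordered",
                    "tipcost": tipcost,
                }
            )
        self._taxon_index = taxon_index

    # ---------------------------------------------------------------- score
    def per_char_lengths(self, tree: PhyloTree) -> np.ndarray:
        """Unweighted minimum steps per character on `tree` (Sankoff DP)."""
        idx = self._taxon_index
        out = np.empty(self.n_char)
        for g in self.groups:
            cost = g["cost"]
            tipcost = g["tipcost"]
            unit = g["unit"]
            node_cost: dict[int, np.ndarray] = {}
            root_cost = None
            for node in tree.postorder():
                if node.is_tip:
                    try:
                        node_cost[id(node)] = tipcost[idx[node.label]]
                    except KeyError:
                        raise MatrixError(
                            f"tree tip {node.label!r} has no row in the matrix"
                        ) from None
                else:
                    total = None
                    for child in node.children:
                        cc = node_cost.pop(id(child))
                        if unit:
                            contrib = np.minimum(cc, cc.min(axis=1, keepdims=True) + 1.0)
                        else:
                            # min over child state t of cc[:, t] + cost[s, t]
                            contrib = (cc[:, None, :] + cost[None, :, :]).min(axis=2)
                        total = contrib if total is None else total + contrib
                    node_cost[id(node)] = total
                    root_cost = total
            out[g["chars"]] = root_cost.min(axis=1)
        return out

    def lengths(self, tree: PhyloTree, weights: np.ndarray) -> float:
        return float(self.per_char_lengths(tree) @ weights)


# --------------------------------------------------------------- operations


def _column_matrix(
    column: Mapping[str, frozenset[str]], spec: CharacterSpec
) -> CharacterMatrix:
    taxa = list(column)
    spec1 = CharacterSpec(0, spec.kind, spec.state_space, spec.weight, spec.cost)
    cells = [[frozenset(column[t])] for t in taxa]
    return CharacterMatrix(taxa=taxa, cells=cells, specs=[spec1])


def character_length(
    tree: PhyloTree, column: Mapping[str, frozenset[str]], spec: CharacterSpec
) -> float:
    """Minimum total cost of the character on the tree over all internal-state
    assignments (unit costs unordered, |i-j| ordered, cost table irreversible)."""
    if tree.n_tips() < 2:
        raise MatrixError("character_length needs a tree with at least 2 tips")
    packed = PackedMatrix(_column_matrix(column, spec))
    return float(packed.per_char_lengths(tree)[0])


def min_length(column: Mapping[str, frozenset[str]], spec: CharacterSpec) -> float:
    """Minimum possible steps of the character over all trees.

    Unordered: one less than the number of distinct fixed observed states;
    ordered: the range of fixed observed states in order units.  Cells carrying
    the full state set (missing data) are ignored, as are polymorphisms, so the
    value is a lower bound that PAUP*/TNT also report.
    """
    if not column:
        raise MatrixError("empty column")
    fixed = {next(iter(cell)) for cell in column.values() if len(cell) == 1}
    if len(fixed) <= 1:
        return 0.0
    if spec.kind == "unordered":
        return float(len(fixed) - 1)
    ranks = sorted(spec.symbol_index(s) for s in fixed)
    if spec.kind == "ordered":
        return float(ranks[-1] - ranks[0])
    # irreversible: every observed state except the root's needs one cheapest
    # incoming transition; exempting the costliest-to-reach state as the root
    # gives a tight bound (exact when costs telescope, as for the
    # stratigraphic character with all states observed)
    cost = spec.cost_matrix()
    minin = []
    for r in ranks:
        incoming = [cost[q, r] for q in range(spec.n_states) if q != r]
        minin.append(min(incoming) if incoming else np.inf)
    minin = sorted(minin)  # exempt the costliest-to-reach (possibly inf) state
    return float(sum(minin[:-1]))


def scaling_weights(matrix: CharacterMatrix) -> WeightScheme:
    """Between-character scaling: down-weight ordered multistate characters by
    the inverse of their observed state range so each has minimum length one,
    the same as a binary character.  Unordered characters keep weight 1."""
    w = np.ones(matrix.n_char)
    for j, spec in enumerate(matrix.specs):
        if spec.kind == "ordered":
            s = min_length(matrix.column(j), spec)
            if s > 0:
                w[j] = 1.0 / s
    return WeightScheme(mode="scaled", per_char_weights=w)


def tree_length(
    tree: PhyloTree, matrix: CharacterMatrix, weights: WeightScheme
) -> LengthReport:
    missing = set(tree.tip_labels()) - set(matrix.taxa)
    if missing:
        raise MatrixError(f"tree tips without matrix rows: {sorted(missing)}")
    packed = PackedMatrix(matrix.subset_taxa(
        [t for t in matrix.taxa if t in set(tree.tip_labels())]
    ))
    raw = packed.per_char_lengths(tree)
    w = weights.weights_for(matrix)
    per_char = raw * w
    return LengthReport(
        per_char_length=per_char,
        total=float(per_char.sum()),
        per_char_h=raw - packed.min_lengths,
    )


def implied_weight_score(tree: PhyloTree, matrix: CharacterMatrix, k: float = 3.0) -> float:
    """Concave implied-weighting objective sum_c h_c / (h_c + k).

    Homoplasy h is measured on between-character scaled steps so ordered
    multistate characters contribute in binary-equivalent units.
    """
    if not k > 0:
        raise MatrixError("implied weighting requires k > 0")
    scheme = scaling_weights(matrix)
    report = tree_length(tree, matrix, scheme)
    w = scheme.weights_for(matrix)
    h = report.per_char_h * w
    return float(np.sum(h / (h + k)))
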