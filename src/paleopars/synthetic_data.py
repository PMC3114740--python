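"""Synthetic trees, character matrices, fossil-style missingness, and ages.

The generator emulates the structure of a combined ("total-evidence")
supermatrix: a birth-death tree over extant and extinct lineages, a modest
morphology block scored for every taxon (mixing unordered and ordered
characters), a large molecular-style block missing for all fossil taxa, and
first/last-appearance ages consistent with the true tree.  Defaults mirror
that shape at desk scale: 12 extant + 8 fossil taxa, 60 morphological and 400
molecular columns.

Everything is bit-reproducible from the seed in `SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .matrix_io import AgeTable, CharacterMatrix, CharacterSpec, MatrixError
from .tree import Node, PhyloTree

__all__ = [
    "SimConfig",
    "sim_tree",
    "sim_tree_duration",
    "sim_matrix",
    "apply_fossil_missingness",
    "sim_ages",
    "simulate_dataset",
]

MAX_RETRIES = 4000


@dataclass
class SimConfig:
    n_extant: int = 12
    n_fossil: int = 8
    birth: float = 1.0  # lineage births per My
    death: float = 0.4  # lineage deaths per My
    n_morph: int = 60
    n_mol: int = 400
    ordered_fraction: float = 0.2  # of morphology characters
    max_states: int = 4
    change_rate: float = 1.0  # expected changes per character per tree
    morph_missing_fraction: float = 0.25  # extra missing morphology in fossils
    preservation_rate: float = 1.0  # 1 = FAD equals the true tip age
    min_edge_ratio: float = 0.6  # minimum internal edge as a fraction of the
    # mean edge length; trees with shorter internal edges are resampled so
    # every split of the true tree is in principle resolvable
    seed: int = 0

    def __post_init__(self):
        if self.birth <= 0 or self.death < 0:
            raise MatrixError("birth rate must be positive, death nonnegative")
        if self.n_extant < 2:
            raise MatrixError("need at least two extant taxa")
        if min(self.n_fossil, self.n_morph, self.n_mol) < 0:
            raise MatrixError("counts must be nonnegative")
        if not 0 <= self.ordered_fraction <= 1:
            raise MatrixError("ordered_fraction must lie in [0, 1]")
        if self.seed is None:
            raise MatrixError("a seed is mandatory")


# ----------------------------------------------------------------- trees


def _gillespie(
    birth: float,
    death: float,
    rng: np.random.Generator,
    stop_extant: Optional[int] = None,
    stop_time: Optional[float] = None,
):
    """Forward birth-death simulation from a single lineage.

    Returns (root, tips) where each tip carries (birth_time, death_time or
    None); times run forward from 0.  Stops when `stop_extant` lineages are
    simultaneously alive or at `stop_time`.
    """
    root = Node()
    alive: list[tuple[Node, float]] = [(root, 0.0)]
    dead: list[tuple[Node, float, float]] = []
    t = 0.0
    while alive:
        if stop_extant is not None and len(alive) >= stop_extant:
            # the present falls inside the window during which stop_extant
            # lineages are alive (avoids zero-length terminal branches)
            t += rng.exponential(1.0 / ((birth + death) * len(alive)))
            break
        total_rate = (birth + death) * len(alive)
        t_next = t + rng.exponential(1.0 / total_rate)
        if stop_time is not None and t_next >= stop_time:
            t = stop_time
            break
        t = t_next
        i = int(rng.integers(len(alive)))
        node, t0 = alive.pop(i)
        if rng.random() < birth / (birth + death):
            left, right = Node(), Node()
            node.add_child(left)
            node.add_child(right)
            node.age = t  # forward time of the split, converted later
            alive.append((left, t))
            alive.append((right, t))
        else:
            dead.append((node, t0, t))
    return root, alive, dead, t


def sim_tree_duration(
    birth: float, death: float, duration: float, rng: np.random.Generator
):
    """Birth-death tree run for a fixed duration; returns the number of
    lineages alive at the end (0 if the clade went extinct)."""
    _, alive, _, _ = _gillespie(birth, death, rng, stop_time=duration)
    return len(alive)


def sim_tree(config: SimConfig) -> tuple[PhyloTree, dict[str, float]]:
    """Birth-death tree with `n_extant` living tips and `n_fossil` extinct
    tips; returns (tree, true tip ages in Ma before present).

    Node.age holds the true age (Ma before present) for every node.
    """
    rng = np.random.default_rng(config.seed)
    fallback = None  # best-conditioned draw if the edge floor is never met
    fallback_ratio = -1.0
    for _ in range(MAX_RETRIES):
        root, alive, dead, t_end = _gillespie(
            config.birth, config.death, rng, stop_extant=config.n_extant
        )
        if len(alive) < config.n_extant or len(dead) < config.n_fossil:
            continue
        # choose fossils among extinct lineages
        order = rng.permutation(len(dead))
        chosen = [dead[i] for i in order[: config.n_fossil]]
        dropped = {id(node) for j, (node, _, _) in enumerate(dead) if j not in set(order[: config.n_fossil])}

        tip_ages: dict[str, float] = {}
        for i, (node, _) in enumerate(alive):
            node.label = f"t{i+1}"
            node.age = 0.0
            tip_ages[node.label] = 0.0
        for i, (node, _, t_death) in enumerate(chosen):
            node.label = f"f{i+1}"
            node.age = t_end - t_death
            tip_ages[node.label] = node.age

        # convert internal forward times to ages before present
        for node in PhyloTree(root).postorder():
            if node.children and node.age is not None:
                node.age = t_end - node.age

        tree = _prune_unlabeled(PhyloTree(root))
        if tree is None or tree.n_tips() != config.n_extant + config.n_fossil:
            continue
        if config.min_edge_ratio > 0:
            blens = _branch_lengths(tree)
            mean_edge = sum(blens.values()) / len(blens)
            internal = [
                blens[id(n)]
                for n in tree.postorder()
                if n.parent is not None and not n.is_tip
            ]
            ratio = min(internal) / mean_edge if internal else np.inf
            if ratio < config.min_edge_ratio:
                if ratio > fallback_ratio:
                    fallback, fallback_ratio = (tree, tip_ages), ratio
                continue
        return tree, tip_ages
    if fallback is not None:
        # the floor is unattainable at this size within the retry budget:
        # return the best-conditioned tree seen
        return fallback
    raise MatrixError(
        "could not simulate a tree with the requested tip counts; "
        "try different birth/death rates"
    )


def _prune_unlabeled(tree: PhyloTree) -> Optional[PhyloTree]:
    """Drop extinct lineages not sampled as fossils; suppress unary nodes."""

    def prune(node: Node) -> Optional[Node]:
        if node.is_tip:
            return node if node.label is not None else None
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        new = Node(label=node.label, age=node.age)
        for k in kids:
            new.add_child(k)
        return new

    root = prune(tree.root)
    if root is None or root.is_tip:
        return None
    return PhyloTree(root)


# ----------------------------------------------------------------- matrix


def _branch_lengths(tree: PhyloTree) -> dict[int, float]:
    out = {}
    for node in tree.postorder():
        if node.parent is not None:
            out[id(node)] = max(node.parent.age - node.age, 0.0)
    return out


def sim_matrix(
    tree: PhyloTree, config: SimConfig
) -> tuple[CharacterMatrix, np.ndarray]:
    """Characters evolved by a continuous-time Markov chain on the true tree.

    Unordered characters jump uniformly among the other states; ordered
    characters step to a neighbouring state (reflecting at the ends).  The
    per-character rate is set so the expected number of changes on the whole
    tree equals `change_rate`.  Returns (matrix, true change counts).
    """
    rng = np.random.default_rng(config.seed + 1)
    blens = _branch_lengths(tree)
    total_len = sum(blens.values())
    if total_len <= 0:
        raise MatrixError("tree has no positive branch lengths")
    rate = config.change_rate / total_len

    n_char = config.n_morph + config.n_mol
    kinds = []
    for j in range(config.n_morph):
        kinds.append("ordered" if rng.random() < config.ordered_fraction else "unordered")
    kinds += ["unordered"] * config.n_mol

    n_states = [
        int(rng.integers(2, config.max_states + 1)) if j < config.n_morph else 4
        for j in range(n_char)
    ]

    taxa = sorted(tree.tip_labels())
    tindex = {t: i for i, t in enumerate(taxa)}
    cells = [[None] * n_char for _ in taxa]
    changes = np.zeros(n_char)
    specs = []
    for j in range(n_char):
        k = n_states[j]
        space = tuple(str(s) for s in range(k))
        specs.append(CharacterSpec(j, kinds[j], space))
        state_at: dict[int, int] = {id(tree.root): int(rng.integers(k))}
        for node in tree.preorder():
            if node.parent is None:
                continue
            s = state_at[id(node.parent)]
            n_events = rng.poisson(rate * blens[id(node)])
            for _ in range(n_events):
                if k == 1:
                    break
                if kinds[j] == "ordered":
                    if s == 0:
                        s = 1
                    elif s == k - 1:
                        s = k - 2
                    else:
                        s = s + 1 if rng.random() < 0.5 else s - 1
                else:
                    step = int(rng.integers(k - 1))
                    s = step if step < s else step + 1
                changes[j] += 1
            state_at[id(node)] = s
            if node.is_tip:
                cells[tindex[node.label]][j] = frozenset({str(s)})
    matrix = CharacterMatrix(taxa=taxa, cells=cells, specs=specs)
    return matrix, changes


def apply_fossil_missingness(
    matrix: CharacterMatrix,
    fossil_taxa,
    molecular_columns,
    morph_missing_fraction: float = 0.0,
    seed: int = 0,
) -> CharacterMatrix:
    """Blank all molecular cells of fossils (coded '?') and, optionally, a
    random fraction of their morphology cells."""
    fossil_taxa = set(fossil_taxa)
    molecular_columns = sorted(set(molecular_columns))
    unknown = fossil_taxa - set(matrix.taxa)
    if unknown:
        raise MatrixError(f"fossil taxa not in matrix: {sorted(unknown)}")
    bad = [j for j in molecular_columns if not 0 <= j < matrix.n_char]
    if bad:
        raise MatrixError(f"molecular column indices out of range: {bad}")
    if not 0 <= morph_missing_fraction <= 1:
        raise MatrixError("morph_missing_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mol = set(molecular_columns)
    full = [frozenset(spec.state_space) for spec in matrix.specs]
    cells = [list(row) for row in matrix.cells]
    morph_cols = [j for j in range(matrix.n_char) if j not in mol]
    for i, taxon in enumerate(matrix.taxa):
        if taxon not in fossil_taxa:
            continue
        for j in molecular_columns:
            cells[i][j] = full[j]
        if morph_missing_fraction > 0 and morph_cols:
            n_blank = int(round(morph_missing_fraction * len(morph_cols)))
            blank = rng.choice(len(morph_cols), size=n_blank, replace=False)
            for b in blank:
                j = morph_cols[int(b)]
                cells[i][j] = full[j]
    return CharacterMatrix(taxa=list(matrix.taxa), cells=cells, specs=list(matrix.specs))


# ------------------------------------------------------------------- ages


def sim_ages(
    tree: PhyloTree, preservation_rate: float = 1.0, seed: int = 0
) -> AgeTable:
    """First/last appearances consistent with the true tree.

    A fossil tip's FAD falls between its true (extinction) age and its origin
    (parent node age): perfect preservation (rate 1) puts the FAD at the true
    tip age; lower rates push it up to a uniform fraction of the lineage
    duration earlier.  Extant tips are pinned to the present.  LAD trails the
    FAD by a small uniform offset, never older than the FAD.
    """
    if not 0 < preservation_rate <= 1:
        raise MatrixError("preservation_rate must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    table = AgeTable()
    for node in tree.tips():
        if node.age is None:
            raise MatrixError(f"tip {node.label!r} lacks a true age")
        if node.age == 0:
            table.add(node.label, 0.0, 0.0, extant=True)
            continue
        duration = max((node.parent.age or 0.0) - node.age, 0.0)
        offset = rng.uniform(0.0, (1.0 - preservation_rate) * duration)
        fad = node.age + offset
        lad = max(node.age, fad - rng.uniform(0.0, 0.5))
        table.add(node.label, fad, lad, extant=False)
    return table


# --------------------------------------------------------------- datasets


def simulate_dataset(config: SimConfig):
    """One full synthetic study: true tree, supermatrix with fossil
    missingness, and an age table.

    Returns (tree, matrix, ages, fossil labels).
    """
    tree, tip_ages = sim_tree(config)
    matrix, _ = sim_matrix(tree, config)
    fossils = [t for t, a in tip_ages.items() if a > 0]
    mol_cols = range(config.n_morph, config.n_morph + config.n_mol)
    matrix = apply_fossil_missingness(
        matrix,
        fossils,
        mol_cols,
        morph_missing_fraction=config.morph_missing_fraction,
        seed=config.seed + 2,
    )
    ages = sim_ages(tree, preservation_rate=config.preservation_rate, seed=config.seed + 3)
    return tree, matrix, ages, fossils
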