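"""Ancestral-state reconstruction and homology/analogy classification.

All most-parsimonious reconstructions (MPRs) of a character are enumerated by
backtracking through the Sankoff dynamic programme; ACCTRAN and DELTRAN pick a
single MPR by resolving each ambiguity toward early (root-ward) or late
(tip-ward) placement of changes.  A state shared by two tips is *homologous*
when it labels the whole path between them through their most recent common
ancestor, *analogous* when it does not; aggregating over MPRs gives the
H / A / ambiguous calls used to scrutinize putative synapomorphies (e.g. the
skeletal states shared by river dolphins).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .matrix_io import CharacterSpec, MatrixError
from .tree import Node, PhyloTree

__all__ = [
    "Reconstruction",
    "HomologyCall",
    "enumerate_mprs",
    "acctran",
    "deltran",
    "count_origins",
    "classify_pair_homology",
    "map_binary_trait",
    "state_changes",
]


@dataclass
class Reconstruction:
    assignment: dict[int, str]  # id(node) -> state symbol
    length: float
    flavor: str  # {"mpr", "acctran", "deltran"}

    def state_of(self, node: Node) -> str:
        return self.assignment[id(node)]


@dataclass
class HomologyCall:
    pair: tuple[str, str]
    character: int
    call: str  # {"H", "A", "ambiguous"}


class MPRCapExceeded(RuntimeError):
    def __init__(self, count_bound: int):
        super().__init__(
            f"number of most-parsimonious reconstructions exceeds cap "
            f"({count_bound})"
        )
        self.count_bound = count_bound


# --------------------------------------------------------------------- DP


def _down_pass(
    tree: PhyloTree, column: Mapping[str, frozenset[str]], spec: CharacterSpec
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Sankoff costs S(v, s) for every node; returns (per-node arrays, cost)."""
    cost = spec.cost_matrix()
    k = spec.n_states
    S: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            if node.label not in column:
                raise MatrixError(f"tip {node.label!r} missing from column")
            arr = np.full(k, np.inf)
            for sym in column[node.label]:
                arr[spec.symbol_index(sym)] = 0.0
            S[id(node)] = arr
        else:
            total = np.zeros(k)
            for child in node.children:
                # min over child state t of S(child, t) + cost(s -> t)
                total += (S[id(child)][None, :] + cost).min(axis=1)
            S[id(node)] = total
    return S, S[id(tree.root)]


def _child_options(
    S: dict[int, np.ndarray], cost: np.ndarray, child: Node, parent_state: int
) -> np.ndarray:
    opts = S[id(child)] + cost[parent_state, :]
    best = opts.min()
    return np.flatnonzero(np.abs(opts - best) < 1e-9)


def enumerate_mprs(
    tree: PhyloTree,
    column: Mapping[str, frozenset[str]],
    spec: CharacterSpec,
    cap: int = 10_000,
) -> list[Reconstruction]:
    """Every minimum-cost internal-state assignment (Sankoff backtracking)."""
    if cap < 1:
        raise MatrixError("cap must be >= 1")
    S, root_cost = _down_pass(tree, column, spec)
    best = root_cost.min()
    cost = spec.cost_matrix()
    symbols = spec.state_space

    nodes_pre = list(tree.preorder())
    results: list[dict[int, str]] = []

    def assign(i: int, states: dict[int, int]) -> None:
        if len(results) > cap:
            return
        if i == len(nodes_pre):
            results.append({nid: symbols[s] for nid, s in states.items()})
            return
        node = nodes_pre[i]
        if node.parent is None:
            options = np.flatnonzero(np.abs(root_cost - best) < 1e-9)
        else:
            options = _child_options(S, cost, node, states[id(node.parent)])
        for s in options:
            states[id(node)] = int(s)
            assign(i + 1, states)
            if len(results) > cap:
                return
        del states[id(node)]

    assign(0, {})
    if len(results) > cap:
        raise MPRCapExceeded(cap)
    return [
        Reconstruction(assignment=a, length=float(best), flavor="mpr")
        for a in results
    ]


def _directed_mpr(
    tree: PhyloTree,
    column: Mapping[str, frozenset[str]],
    spec: CharacterSpec,
    delay: bool,
) -> Reconstruction:
    """Greedy preorder MPR selection: keep the parent's state when possible
    (DELTRAN, delaying changes toward the tips) or change as early as possible
    (ACCTRAN).  Ties beyond that rule break toward the lowest state index."""
    S, root_cost = _down_pass(tree, column, spec)
    cost = spec.cost_matrix()
    symbols = spec.state_space
    assignment: dict[int, int] = {}
    best = root_cost.min()
    for node in tree.preorder():
        if node.parent is None:
            options = np.flatnonzero(np.abs(root_cost - best) < 1e-9)
            assignment[id(node)] = int(options[0])
            continue
        parent_state = assignment[id(node.parent)]
        options = _child_options(S, cost, node, parent_state)
        if delay:
            pick = parent_state if parent_state in options else int(options[0])
        else:
            differing = [s for s in options if s != parent_state]
            pick = int(differing[0]) if differing else int(options[0])
        assignment[id(node)] = pick
    return Reconstruction(
        assignment={nid: symbols[s] for nid, s in assignment.items()},
        length=float(best),
        flavor="deltran" if delay else "acctran",
    )


def acctran(
    tree: PhyloTree, column: Mapping[str, frozenset[str]], spec: CharacterSpec
) -> Reconstruction:
    """Accelerated transformation: changes placed as close to the root as the
    MPR set allows (reversals over convergences)."""
    return _directed_mpr(tree, column, spec, delay=False)


def deltran(
    tree: PhyloTree, column: Mapping[str, frozenset[str]], spec: CharacterSpec
) -> Reconstruction:
    """Delayed transformation: changes pushed toward apical branches
    (convergences over reversals)."""
    return _directed_mpr(tree, column, spec, delay=True)


def state_changes(
    tree: PhyloTree, reconstruction: Reconstruction
) -> list[tuple[Node, str, str]]:
    """Branches carrying a change: (child node, parent state, child state)."""
    out = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        a = reconstruction.assignment[id(node.parent)]
        b = reconstruction.assignment[id(node)]
        if a != b:
            out.append((node, a, b))
    return out


def count_origins(
    tree: PhyloTree,
    column: Mapping[str, frozenset[str]],
    spec: CharacterSpec,
    state: str,
    flavor: str = "deltran",
) -> int:
    """Number of branches on which the reconstruction transitions into `state`."""
    if state not in spec.state_space:
        raise MatrixError(f"state {state!r} not in the character's state space")
    if flavor == "acctran":
        rec = acctran(tree, column, spec)
    elif flavor == "deltran":
        rec = deltran(tree, column, spec)
    else:
        raise MatrixError("flavor must be 'acctran' or 'deltran'")
    return sum(1 for _, _, to in state_changes(tree, rec) if to == state)


def _path_nodes(tree: PhyloTree, tip_x: Node, tip_y: Node) -> list[Node]:
    def ancestors(n: Node) -> list[Node]:
        out = [n]
        while n.parent is not None:
            n = n.parent
            out.append(n)
        return out

    ax = ancestors(tip_x)
    ay = set(id(n) for n in ancestors(tip_y))
    mrca = next(n for n in ax if id(n) in ay)
    path = []
    n = tip_x
    while n is not mrca:
        path.append(n)
        n = n.parent
    path.append(mrca)
    tail = []
    n = tip_y
    while n is not mrca:
        tail.append(n)
        n = n.parent
    path.extend(reversed(tail))
    return path


def classify_pair_homology(
    tree: PhyloTree,
    column: Mapping[str, frozenset[str]],
    spec: CharacterSpec,
    tip_x: str,
    tip_y: str,
    cap: int = 10_000,
    char_id: Optional[int] = None,
) -> HomologyCall:
    """Is a state shared by two tips homologous (H: continuous along the path
    between them in every MPR), analogous (A: interrupted in every MPR), or
    ambiguous (mixed across MPRs)?

    Two tips share a state when their observed sets intersect on a state that
    is fixed in at least one of them.
    """
    obs_x, obs_y = column[tip_x], column[tip_y]
    shared = {
        s
        for s in obs_x & obs_y
        if len(obs_x) == 1 or len(obs_y) == 1
    }
    if not shared:
        raise MatrixError(f"tips {tip_x!r} and {tip_y!r} share no fixed state")
    nx, ny = tree.find_tip(tip_x), tree.find_tip(tip_y)
    path = _path_nodes(tree, nx, ny)
    try:
        mprs = enumerate_mprs(tree, column, spec, cap=cap)
    except MPRCapExceeded:
        return HomologyCall(
            pair=(tip_x, tip_y), character=char_id or spec.char_id, call="ambiguous"
        )
    verdicts = []
    for rec in mprs:
        homologous = any(
            all(rec.assignment[id(n)] == s for n in path) for s in shared
        )
        verdicts.append(homologous)
    if all(verdicts):
        call = "H"
    elif not any(verdicts):
        call = "A"
    else:
        call = "ambiguous"
    return HomologyCall(
        pair=(tip_x, tip_y), character=char_id or spec.char_id, call=call
    )


def map_binary_trait(
    tree: PhyloTree, trait: Mapping[str, int], flavor: str = "deltran"
) -> tuple[Reconstruction, list[tuple[Node, str, str]]]:
    """Optimize a binary tip trait (e.g. marine=0 / riverine=1) onto the tree;
    returns the reconstruction and the branches carrying each transition."""
    missing = set(tree.tip_labels()) - set(trait)
    if missing:
        raise MatrixError(f"tips without trait scores: {sorted(missing)}")
    spec = CharacterSpec(0, "unordered", ("0", "1"))
    column = {t: frozenset({str(int(trait[t]))}) for t in tree.tip_labels()}
    if flavor == "acctran":
        rec = acctran(tree, column, spec)
    elif flavor == "deltran":
        rec = deltran(tree, column, spec)
    else:
        raise MatrixError("flavor must be 'acctran' or 'deltran'")
    return rec, state_changes(tree, rec)
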