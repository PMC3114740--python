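import itertools

import numpy as np
import pytest

from paleopars.matrix_io import CharacterMatrix, CharacterSpec
from paleopars.tree import PhyloTree


@pytest.fixture
def quartet():
    return PhyloTree.from_newick("((A,B),(C,D));")


@pytest.fixture
def five_taxon():
    return PhyloTree.from_newick("((A,(B,C)),(D,E));")


def random_matrix(taxa, n_char, rng, n_states=2, ordered_fraction=0.0,
                  polymorphic_fraction=0.0):
    """Uniform random state-set matrix for oracle tests."""
    space = tuple(str(i) for i in range(n_states))
    cells, specs = [], []
    for j in range(n_char):
        kind = "ordered" if rng.random() < ordered_fraction else "unordered"
        specs.append(CharacterSpec(j, kind, space))
    for _ in taxa:
        row = []
        for j in range(n_char):
            if rng.random() < polymorphic_fraction:
                k = int(rng.integers(2, n_states + 1))
                row.append(frozenset(
                    str(s) for s in rng.choice(n_states, size=k, replace=False)
                ))
            else:
                row.append(frozenset({str(int(rng.integers(n_states)))}))
        cells.append(row)
    return CharacterMatrix(taxa=list(taxa), cells=cells, specs=specs)


def brute_force_character_length(tree, column, spec):
    """Exhaustive minimum over every internal-node and tip state assignment."""
    cost = spec.cost_matrix()
    internals = [n for n in tree.postorder() if not n.is_tip]
    tips = tree.tips()
    tip_choices = [
        [spec.symbol_index(s) for s in sorted(column[n.label])] for n in tips
    ]
    best = np.inf
    for internal_states in itertools.product(
        range(spec.n_states), repeat=len(internals)
    ):
        amap = {id(n): s for n, s in zip(internals, internal_states)}
        for tip_states in itertools.product(*tip_choices):
            amap.update({id(n): s for n, s in zip(tips, tip_states)})
            total = 0.0
            for node in tree.postorder():
                if node.parent is not None:
                    total += cost[amap[id(node.parent)], amap[id(node)]]
            best = min(best, total)
    return best


def random_topology(labels, rng):
    """Uniform-ish random unrooted topology by random stepwise addition."""
    from paleopars.tree import Node
    from paleopars.tree_search import _copy_with_map, _edge_nodes, _regraft

    order = [labels[i] for i in rng.permutation(len(labels))]
    root = Node()
    for t in order[:3]:
        root.add_child(Node(label=t))
    tree = PhyloTree(root)
    for label in order[3:]:
        edges = _edge_nodes(tree)
        pick = edges[int(rng.integers(len(edges)))]
        work, mapping = _copy_with_map(tree)
        _regraft(work, Node(label=label), mapping[id(pick)])
        tree = work
    return tree
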