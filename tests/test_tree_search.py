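"""Tree search: constraints, heuristic vs exhaustive optima, consensus."""

import numpy as np
import pytest

from paleopars.matrix_io import CharacterMatrix, CharacterSpec, MatrixError
from paleopars.parsimony import WeightScheme
from paleopars.tree import PhyloTree, same_unrooted_topology
from paleopars.tree_search import (
    BackboneConstraint,
    Objective,
    exhaustive_search,
    heuristic_search,
    majority_consensus,
    n_unrooted_topologies,
    enumerate_topologies,
    satisfies_constraint,
    strict_consensus,
)

from conftest import random_matrix


class TestConstraints:
    def test_identity_backbone_satisfied(self):
        t = PhyloTree.from_newick("((A,B),(C,D));")
        c = BackboneConstraint(PhyloTree.from_newick("((A,B),(C,D));"))
        assert satisfies_constraint(t, c)

    def test_conflicting_resolution_rejected(self):
        t = PhyloTree.from_newick("((A,C),(B,D));")
        c = BackboneConstraint(PhyloTree.from_newick("((A,B),C,D);"))
        assert not satisfies_constraint(t, c)

    def test_floating_taxon_removed_before_check(self):
        t = PhyloTree.from_newick("(((A,F1),B),(C,D));")
        c = BackboneConstraint(
            PhyloTree.from_newick("((A,B),(C,D));"), frozenset({"F1"})
        )
        assert satisfies_constraint(t, c)

    def test_less_resolved_tree_is_compatible(self):
        # polytomy in the candidate does not contradict the backbone
        t = PhyloTree.from_newick("(A,B,C,(D,E));")
        c = BackboneConstraint(PhyloTree.from_newick("((A,B,C),(D,E));"))
        assert satisfies_constraint(t, c)

    def test_overlap_between_backbone_and_floating_rejected(self):
        with pytest.raises(MatrixError):
            BackboneConstraint(
                PhyloTree.from_newick("((A,B),(C,D));"), frozenset({"A"})
            )


class TestEnumeration:
    def test_topology_counts(self):
        assert n_unrooted_topologies(5) == 15
        assert n_unrooted_topologies(7) == 945
        assert sum(1 for _ in enumerate_topologies(list("ABCDE"))) == 15

    def test_three_taxa_single_topology(self):
        m = random_matrix(list("ABC"), 4, np.random.default_rng(0))
        res = exhaustive_search(m)
        assert len(res.best_trees) == 1

    def test_two_synapomorphies_resolve_five_taxa(self):
        # two binary characters with A,B derived: unique optimum has (A,B)
        cells = {
            "A": ["1", "1", "0"],
            "B": ["1", "1", "0"],
            "C": ["0", "0", "1"],
            "D": ["0", "0", "0"],
            "E": ["0", "0", "0"],
        }
        m = CharacterMatrix(
            taxa=list("ABCDE"),
            cells=[[frozenset({s}) for s in cells[t]] for t in "ABCDE"],
            specs=[CharacterSpec(j, "unordered", ("0", "1")) for j in range(3)],
        )
        res = exhaustive_search(m)
        from paleopars.tree_search import has_split
        assert all(has_split(t, {"A", "B"}) for t in res.best_trees)

    def test_too_many_taxa_rejected(self):
        m = random_matrix([f"t{i}" for i in range(10)], 3, np.random.default_rng(0))
        with pytest.raises(MatrixError):
            exhaustive_search(m)


class TestHeuristicSearch:
    def test_all_invariant_characters_make_every_topology_optimal(self):
        taxa = list("ABCDE")
        m = CharacterMatrix(
            taxa=taxa,
            cells=[[frozenset({"0"})] * 2 for _ in taxa],
            specs=[CharacterSpec(j, "unordered", ("0", "1")) for j in range(2)],
        )
        res = heuristic_search(m, n_replicates=2, seed=0, plateau_cap=30)
        assert res.best_score == 0.0
        assert len(res.best_trees) == 15  # every 5-taxon topology ties

    def test_congruent_matrix_recovers_generating_topology(self):
        truth = PhyloTree.from_newick("((A,(B,C)),(D,(E,F)));")
        # one clean binary synapomorphy per internal edge
        splits = [{"B", "C"}, {"A", "B", "C"}, {"E", "F"}, {"D", "E", "F"}]
        taxa = list("ABCDEF")
        cells = [
            [frozenset({"1"}) if t in s else frozenset({"0"}) for s in splits]
            for t in taxa
        ]
        m = CharacterMatrix(
            taxa=taxa,
            cells=cells,
            specs=[CharacterSpec(j, "unordered", ("0", "1")) for j in range(4)],
        )
        res = heuristic_search(m, n_replicates=2, seed=1)
        assert res.best_score == len(splits)  # each split character one step
        assert any(same_unrooted_topology(t, truth) for t in res.best_trees)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(7)]
        m = random_matrix(taxa, 12, rng, n_states=3, ordered_fraction=0.25)
        ex = exhaustive_search(m)
        he = heuristic_search(m, n_replicates=3, seed=seed)
        assert he.best_score == pytest.approx(ex.best_score)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        m = random_matrix([f"t{i}" for i in range(8)], 15, rng)
        a = heuristic_search(m, n_replicates=3, seed=11)
        b = heuristic_search(m, n_replicates=3, seed=11)
        assert a.best_score == b.best_score
        assert {frozenset(t.bipartitions()) for t in a.best_trees} == {
            frozenset(t.bipartitions()) for t in b.best_trees
        }

    def test_constrained_results_satisfy_constraint(self):
        rng = np.random.default_rng(2)
        taxa = [f"t{i}" for i in range(8)]
        m = random_matrix(taxa, 15, rng)
        backbone = PhyloTree.from_newick("((t0,t1),(t2,t3));")
        c = BackboneConstraint(backbone, frozenset(taxa[4:]))
        res = heuristic_search(m, constraint=c, n_replicates=2, seed=2)
        assert all(satisfies_constraint(t, c) for t in res.best_trees)

    def test_constraint_never_improves_score(self):
        rng = np.random.default_rng(3)
        taxa = [f"t{i}" for i in range(7)]
        m = random_matrix(taxa, 14, rng)
        free = exhaustive_search(m)
        backbone = PhyloTree.from_newick("((t0,t1),(t2,t3));")
        constrained = exhaustive_search(
            m, constraint=BackboneConstraint(backbone, frozenset(taxa[4:]))
        )
        assert constrained.best_score >= free.best_score - 1e-9


class TestConsensus:
    def test_identical_trees(self):
        t = PhyloTree.from_newick("((A,B),(C,(D,E)));")
        cons = strict_consensus([t, t.copy()])
        assert cons.bipartitions() == t.bipartitions()

    def test_conflict_collapses_to_polytomy(self):
        t1 = PhyloTree.from_newick("((A,B),C,(D,E));")
        t2 = PhyloTree.from_newick("((A,C),B,(D,E));")
        cons = strict_consensus([t1, t2])
        assert cons.bipartitions() == {frozenset({"D", "E"})}

    def test_consensus_of_optima_differs_only_at_unstable_nodes(self):
        # two trees differing in one subtree placement: consensus keeps the rest
        t1 = PhyloTree.from_newick("(((A,F),B),(C,(D,E)));")
        t2 = PhyloTree.from_newick("((A,B),(C,((D,F),E)));")
        cons = strict_consensus([t1, t2])
        shared = t1.bipartitions() & t2.bipartitions()
        assert cons.bipartitions() == shared

    def test_majority_keeps_clades_above_threshold(self):
        t1 = PhyloTree.from_newick("((A,B),(C,(D,E)));")
        t2 = PhyloTree.from_newick("((A,B),(D,(C,E)));")
        t3 = PhyloTree.from_newick("((A,B),(E,(C,D)));")
        cons = majority_consensus([t1, t2, t3], threshold=0.5)
        from paleopars.tree_search import has_split
        assert has_split(cons, {"A", "B"})
        # clades in only one tree each are dropped
        assert not has_split(cons, {"C", "D"})

    def test_tip_set_mismatch_rejected(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D));")
        t2 = PhyloTree.from_newick("((A,B),(C,E));")
        with pytest.raises(MatrixError):
            strict_consensus([t1, t2])
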