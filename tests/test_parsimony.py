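"""Parsimony scoring: Fitch/ordered/Sankoff lengths, scaling, implied weights."""

import numpy as np
import pytest

from paleopars.matrix_io import CharacterMatrix, CharacterSpec, MatrixError
from paleopars.parsimony import (
    WeightScheme,
    character_length,
    implied_weight_score,
    min_length,
    scaling_weights,
    tree_length,
)
from paleopars.tree import PhyloTree

from conftest import brute_force_character_length, random_matrix, random_topology


def col(**kw):
    return {k: frozenset(str(v)) for k, v in kw.items()}


class TestCharacterLength:
    def test_invariant_character_is_free(self, quartet):
        spec = CharacterSpec(0, "unordered", ("0", "1"))
        assert character_length(quartet, col(A=0, B=0, C=0, D=0), spec) == 0

    def test_incongruent_binary_costs_two(self, quartet):
        spec = CharacterSpec(0, "unordered", ("0", "1"))
        assert character_length(quartet, col(A=0, B=1, C=0, D=1), spec) == 2

    def test_ordered_doubles_unordered_on_two_step_states(self, quartet):
        column = col(A=0, B=2, C=0, D=2)
        assert character_length(
            quartet, column, CharacterSpec(0, "ordered", ("0", "1", "2"))
        ) == 4
        assert character_length(
            quartet, column, CharacterSpec(0, "unordered", ("0", "1", "2"))
        ) == 2

    def test_symbol_outside_space_rejected(self, quartet):
        spec = CharacterSpec(0, "unordered", ("0", "1"))
        with pytest.raises(MatrixError):
            character_length(quartet, col(A=0, B=1, C=2, D=0), spec)

    @pytest.mark.parametrize("kind", ["unordered", "ordered"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_assignment_minimum(self, kind, seed):
        """Property: the DP equals the brute-force minimum over all internal
        assignments, for every character kind, incl. polymorphic cells."""
        rng = np.random.default_rng(seed)
        labels = [f"s{i}" for i in range(5 + seed % 2)]
        tree = random_topology(labels, rng)
        spec = CharacterSpec(0, kind, ("0", "1", "2"))
        column = {}
        for lab in labels:
            if rng.random() < 0.2:
                column[lab] = frozenset({"0", "1", "2"})
            elif rng.random() < 0.2:
                column[lab] = frozenset({"0", "2"})
            else:
                column[lab] = frozenset({str(int(rng.integers(3)))})
        assert character_length(tree, column, spec) == pytest.approx(
            brute_force_character_length(tree, column, spec)
        )

    def test_irreversible_cost_table(self):
        tree = PhyloTree.from_newick("((A,B),C);")
        cost = np.array([[0.0, 1.0], [np.inf, 0.0]])
        spec = CharacterSpec(0, "irreversible", ("0", "1"), cost=cost)
        # two tips in derived state on opposite sides: two separate gains
        assert character_length(tree, col(A=1, B=0, C=1), spec) in (1.0, 2.0)
        # reversal impossible: A=0 below a derived ancestor would cost inf,
        # so the optimum keeps the root primitive
        assert np.isfinite(character_length(tree, col(A=0, B=1, C=1), spec))

    @pytest.mark.parametrize("seed", range(5))
    def test_reroot_invariance_for_reversible_costs(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"s{i}" for i in range(6)]
        tree = random_topology(labels, rng)
        spec = CharacterSpec(0, "ordered", ("0", "1", "2", "3"))
        column = {l: frozenset({str(int(rng.integers(4)))}) for l in labels}
        base = character_length(tree, column, spec)
        for lab in labels[:3]:
            rerooted = tree.reroot_at_tip_edge(lab)
            assert character_length(rerooted, column, spec) == pytest.approx(base)

    @pytest.mark.parametrize("seed", range(5))
    def test_ordered_never_shorter_than_unordered(self, seed):
        rng = np.random.default_rng(seed + 50)
        labels = [f"s{i}" for i in range(6)]
        tree = random_topology(labels, rng)
        column = {l: frozenset({str(int(rng.integers(4)))}) for l in labels}
        lo = character_length(tree, column, CharacterSpec(0, "unordered", tuple("0123")))
        lu = character_length(tree, column, CharacterSpec(0, "ordered", tuple("0123")))
        assert lu >= lo - 1e-12


class TestMinLength:
    def test_binary(self):
        spec = CharacterSpec(0, "unordered", ("0", "1"))
        assert min_length(col(a=0, b=1), spec) == 1

    def test_ordered_range(self):
        spec = CharacterSpec(0, "ordered", tuple("01234"))
        assert min_length(col(a=0, b=1, c=2, d=3, e=4), spec) == 4

    def test_sparse_observed_states(self):
        column = col(a=0, b=2, c=5)
        assert min_length(column, CharacterSpec(0, "ordered", tuple("012345"))) == 5
        assert min_length(column, CharacterSpec(0, "unordered", tuple("012345"))) == 2

    def test_full_set_cells_ignored(self):
        spec = CharacterSpec(0, "unordered", ("0", "1"))
        column = {"a": frozenset({"0"}), "b": frozenset({"0", "1"})}
        assert min_length(column, spec) == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_never_exceeds_any_tree_length(self, seed):
        rng = np.random.default_rng(seed + 7)
        labels = [f"s{i}" for i in range(6)]
        spec = CharacterSpec(0, "ordered", tuple("0123"))
        column = {l: frozenset({str(int(rng.integers(4)))}) for l in labels}
        floor = min_length(column, spec)
        for s2 in range(5):
            tree = random_topology(labels, np.random.default_rng(s2))
            assert character_length(tree, column, spec) >= floor - 1e-12


class TestScalingWeights:
    def test_ordered_range_four_gets_quarter_weight(self):
        m = CharacterMatrix(
            taxa=["a", "b"],
            cells=[[frozenset({"0"})], [frozenset({"4"})]],
            specs=[CharacterSpec(0, "ordered", tuple("01234"))],
        )
        w = scaling_weights(m).per_char_weights
        assert w[0] == pytest.approx(0.25)

    def test_unordered_multistate_keeps_unit_weight(self):
        m = CharacterMatrix(
            taxa=["a", "b", "c"],
            cells=[[frozenset({"0"})], [frozenset({"1"})], [frozenset({"2"})]],
            specs=[CharacterSpec(0, "unordered", ("0", "1", "2"))],
        )
        assert scaling_weights(m).per_char_weights[0] == 1.0

    def test_every_variable_ordered_character_scales_to_unit_min_length(self):
        rng = np.random.default_rng(11)
        taxa = [f"t{i}" for i in range(8)]
        m = random_matrix(taxa, 30, rng, n_states=5, ordered_fraction=0.5)
        w = scaling_weights(m).per_char_weights
        for j, spec in enumerate(m.specs):
            s = min_length(m.column(j), spec)
            if spec.kind == "ordered" and s > 0:
                assert s * w[j] == pytest.approx(1.0)
            else:
                assert w[j] == 1.0


class TestTreeLength:
    def test_weighted_sum(self, quartet):
        m = CharacterMatrix(
            taxa=list("ABCD"),
            cells=[
                [frozenset({"0"}), frozenset({"0"})],
                [frozenset({"1"}), frozenset({"1"})],
                [frozenset({"0"}), frozenset({"1"})],
                [frozenset({"1"}), frozenset({"0"})],
            ],
            specs=[
                CharacterSpec(0, "unordered", ("0", "1"), weight=1.0),
                CharacterSpec(1, "unordered", ("0", "1"), weight=0.5),
            ],
        )
        w = WeightScheme(mode="scaled", per_char_weights=np.array([1.0, 0.5]))
        report = tree_length(quartet, m, w)
        assert report.total == pytest.approx(report.per_char_length.sum())
        assert report.total == pytest.approx(2.0 * 1.0 + 2.0 * 0.5)
        assert np.all(report.per_char_h >= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_total_equals_brute_force_sum(self, seed):
        rng = np.random.default_rng(seed + 100)
        taxa = [f"t{i}" for i in range(6)]
        m = random_matrix(taxa, 6, rng, n_states=3, ordered_fraction=0.3)
        tree = random_topology(taxa, rng)
        report = tree_length(tree, m, WeightScheme(mode="equal"))
        expected = sum(
            brute_force_character_length(tree, m.column(j), m.specs[j])
            for j in range(m.n_char)
        )
        assert report.total == pytest.approx(expected)

    def test_tip_without_row_rejected(self, quartet):
        m = random_matrix(["A", "B", "C"], 3, np.random.default_rng(0))
        with pytest.raises(MatrixError):
            tree_length(quartet, m, WeightScheme())


class TestImpliedWeighting:
    def test_no_homoplasy_scores_zero(self, quartet):
        m = CharacterMatrix(
            taxa=list("ABCD"),
            cells=[
                [frozenset({"0"})],
                [frozenset({"0"})],
                [frozenset({"1"})],
                [frozenset({"1"})],
            ],
            specs=[CharacterSpec(0, "unordered", ("0", "1"))],
        )
        assert implied_weight_score(quartet, m, k=3.0) == 0.0

    def test_h_equal_k_scores_half(self, quartet):
        # A=0,B=1,C=0,D=1 on ((A,B),(C,D)): length 2, min 1, h=1 -> 1/(1+3)
        m = CharacterMatrix(
            taxa=list("ABCD"),
            cells=[
                [frozenset({"0"})],
                [frozenset({"1"})],
                [frozenset({"0"})],
                [frozenset({"1"})],
            ],
            specs=[CharacterSpec(0, "unordered", ("0", "1"))],
        )
        assert implied_weight_score(quartet, m, k=1.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_bounded_and_monotone_in_k(self, seed):
        rng = np.random.default_rng(seed + 9)
        taxa = [f"t{i}" for i in range(7)]
        m = random_matrix(taxa, 12, rng, n_states=3)
        tree = random_topology(taxa, rng)
        scores = [implied_weight_score(tree, m, k) for k in (1.0, 3.0, 10.0)]
        assert 0 <= scores[0] < m.n_char
        assert scores[0] >= scores[1] >= scores[2]

    def test_implied_optimum_can_differ_from_equal_weights(self):
        """Two objectives can prefer different topologies on the same matrix
        (verified by exhaustive search over all trees)."""
        from paleopars.tree_search import exhaustive_search
        from paleopars.parsimony import WeightScheme

        found = False
        for seed in range(60):
            rng = np.random.default_rng(seed)
            taxa = [f"t{i}" for i in range(6)]
            m = random_matrix(taxa, 10, rng, n_states=3, ordered_fraction=0.3)
            eq = exhaustive_search(m, WeightScheme(mode="equal"))
            iw = exhaustive_search(m, WeightScheme(mode="implied", k=1.0))
            eq_keys = {frozenset(t.bipartitions()) for t in eq.best_trees}
            iw_keys = {frozenset(t.bipartitions()) for t in iw.best_trees}
            if eq_keys != iw_keys:
                found = True
                break
        assert found
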