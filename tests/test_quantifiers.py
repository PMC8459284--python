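"""Structure indexing, the substructure order, and quantifier constructions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quantevo import (
    Quantifier,
    all_structures,
    count_quantitative,
    degeneracy,
    index_of_structure,
    is_monotone,
    is_quantitative,
    is_substructure,
    make_quantifier,
    named_quantifier,
    structure_from_index,
)

from oracles import brute_is_monotone, brute_is_quantitative


T, F = True, False


class TestStructureIndexing:
    @pytest.mark.parametrize(
        "i, n, expected",
        [
            (7, 3, [T, T, T]),  # the last structure is all-True
            (0, 3, [F, F, F]),
            (5, 3, [T, F, T]),
        ],
    )
    def test_lexicographic_convention(self, i, n, expected):
        assert structure_from_index(i, n).tolist() == expected

    @pytest.mark.parametrize("i, n", [(-1, 3), (8, 3), (1024, 10)])
    def test_out_of_range_rejected(self, i, n):
        with pytest.raises(ValueError):
            structure_from_index(i, n)

    @pytest.mark.parametrize("n", [1, 3, 6])
    def test_round_trip_bijection(self, n):
        for i in range(2**n):
            assert index_of_structure(structure_from_index(i, n)) == i

    def test_all_structures_rows_match_indexing(self):
        structs = all_structures(5)
        for i in (0, 7, 19, 31):
            assert np.array_equal(structs[i], structure_from_index(i, 5))


class TestSubstructureOrder:
    def test_worked_example(self):
        assert is_substructure([F, T, T, F, F], [F, T, T, T, T])
        assert not is_substructure([F, T, T, T, T], [F, T, T, F, F])

    def test_reflexive_and_counterexample(self):
        assert is_substructure([T, F, T], [T, F, T])
        assert not is_substructure([T, F, F], [F, T, T])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            is_substructure([T, F], [T, F, T])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 63), st.integers(0, 63), st.integers(0, 63))
    def test_partial_order(self, i, j, k):
        a, b, c = (structure_from_index(x, 6) for x in (i, j, k))
        assert is_substructure(a, a)
        if is_substructure(a, b) and is_substructure(b, a):
            assert np.array_equal(a, b)
        if is_substructure(a, b) and is_substructure(b, c):
            assert is_substructure(a, c)


class TestQuantifierConstruction:
    def test_all_quantifier_table(self):
        q = make_quantifier(lambda m: bool(m.all()), 3)
        assert q.to_bitstring() == "00000001"
        assert q == named_quantifier("all", 3)

    def test_constant_true(self):
        q = make_quantifier(lambda m: True, 2)
        assert q.table.all() and q.n == 2

    def test_count_threshold_matches_brute_force(self):
        q = make_quantifier(lambda m: m.sum() >= 2, 3)
        expected = [structure_from_index(i, 3).sum() >= 2 for i in range(8)]
        assert q.table.tolist() == expected
        assert q.table.sum() == 4

    def test_bitstring_round_trip(self):
        q = named_quantifier("between", 4, 1, 2)
        assert Quantifier.from_bitstring(q.to_bitstring()) == q

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            Quantifier(np.array([True, False, True]))  # not a power of two


class TestNamedQuantifiers:
    def test_some(self):
        assert named_quantifier("some", 2).to_bitstring() == "0111"

    def test_ultrafilter_tracks_single_bit(self):
        q = named_quantifier("ultrafilter", 3, 2)
        structs = all_structures(3)
        assert np.array_equal(q.table, structs[:, 2])

    def test_between_cardinality(self):
        # C(10,2)+C(10,3)+C(10,4) = 45+120+210
        assert named_quantifier("between", 10, 2, 4).table.sum() == 375

    @pytest.mark.parametrize(
        "name, args",
        [("ultrafilter", (3,)), ("between", (4, 2)), ("conj_ultrafilter", (1, 1)), ("at_most", (9,))],
    )
    def test_out_of_range_parameters_rejected(self, name, args):
        with pytest.raises(ValueError):
            named_quantifier(name, 3, *args)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            named_quantifier("most", 3)


class TestDegeneracy:
    def test_constant_is_fully_degenerate(self):
        assert degeneracy(named_quantifier("const", 4, True)) == 1.0

    def test_all_at_n3(self):
        assert degeneracy(named_quantifier("all", 3)) == 0.875

    def test_between_3_5_at_n10(self):
        # C(10,3)+C(10,4)+C(10,5) = 582 True entries of 1024
        assert degeneracy(named_quantifier("between", 10, 3, 5)) == pytest.approx(582 / 1024)


class TestMonotoneAndQuantitative:
    def test_known_quantifiers(self):
        assert is_monotone(named_quantifier("at_least", 10, 4), "up")
        assert not is_monotone(named_quantifier("at_least", 10, 4), "down")
        ev = named_quantifier("even", 10)
        assert not is_monotone(ev, "up") and not is_monotone(ev, "down")
        const = named_quantifier("const", 5, False)
        assert is_monotone(const, "up") and is_monotone(const, "down")

    def test_quantity_predicate(self):
        assert is_quantitative(named_quantifier("between", 10, 2, 4))
        assert not is_quantitative(named_quantifier("ultrafilter", 4, 1))
        assert is_quantitative(named_quantifier("const", 4, True))

    @pytest.mark.parametrize("n", [3, 4])
    def test_agreement_with_pairwise_oracle(self, n):
        rng = np.random.default_rng(42)
        tables = [rng.random(2**n) < 0.5 for _ in range(25)]
        tables += [named_quantifier(nm, n).table for nm in ("some", "all", "even")]
        for t in tables:
            q = Quantifier(t)
            for d in ("up", "down"):
                assert is_monotone(q, d) == brute_is_monotone(t.tolist(), n, d)
            assert is_quantitative(q) == brute_is_quantitative(t.tolist(), n)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.permutations(list(range(4))))
    def test_quantitative_invariant_under_bit_permutation(self, seed, perm):
        rng = np.random.default_rng(seed)
        table_on_counts = rng.random(5) < 0.5
        counts = all_structures(4).sum(axis=1)
        q = Quantifier(table_on_counts[counts])
        assert is_quantitative(q)
        permuted_structs = all_structures(4)[:, perm]
        new_index = permuted_structs @ (2 ** np.arange(3, -1, -1))
        assert np.array_equal(q.table[new_index], q.table)


class TestCountQuantitative:
    @pytest.mark.parametrize("n, expected", [(1, (4, 4)), (2, (8, 6)), (10, (2048, 22))])
    def test_known_counts(self, n, expected):
        assert count_quantitative(n) == expected

    def test_ratio_at_n10(self):
        total, mono = count_quantitative(10)
        assert round(100 * mono / total, 2) == 1.07

    def test_matches_exhaustive_enumeration_at_n3(self):
        n = 3
        total = monotone = 0
        for code in range(2 ** (2**n)):
            table = [(code >> i) & 1 for i in range(2**n)]
            if brute_is_quantitative(table, n):
                total += 1
                if brute_is_monotone(table, n, "up") or brute_is_monotone(table, n, "down"):
                    monotone += 1
        assert (total, monotone) == count_quantitative(n)
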