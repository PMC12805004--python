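"""Symmetry engine: connectivity, invariance, enumeration, parity verdicts."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import catsym as cs
from catsym.symmetry import (
    CategorySystem,
    ParityInstabilityError,
    _compositions,
)
from conftest import brute_force_connected_partitions, brute_force_set_partitions


class TestIsConnected:
    def test_endpoints_only_block_is_disconnected_on_interval(self):
        s = cs.make_structure("linear", 6)
        assert not cs.is_connected({0, 5}, s.space)

    def test_singletons_always_connected(self, canonical_structures):
        for s in canonical_structures.values():
            assert all(cs.is_connected({i}, s.space) for i in range(s.n))

    def test_wraparound_arc_connected_on_cycle(self):
        s = cs.make_structure("bisected_circular", 8)
        assert cs.is_connected({7, 0, 1}, s.space)
        assert not cs.is_connected({7, 1}, s.space)

    def test_feature_space_connectivity_vacuous(self):
        s = cs.make_structure("binary_feature", 2)
        assert cs.is_connected({0, 3}, s.space)

    def test_empty_block_rejected(self):
        s = cs.make_structure("linear", 4)
        with pytest.raises(ValueError):
            cs.is_connected(set(), s.space)


class TestIsSymmetric:
    def test_mirror_split_capturing_centre_is_not_symmetric(self):
        s = cs.make_structure("bisected_linear", 5)
        system = CategorySystem((0, 0, 0, 1, 1))  # centre in left block
        assert not cs.is_symmetric(system, s.group)

    def test_palindromic_three_block_system_is_symmetric(self):
        s = cs.make_structure("bisected_linear", 5)
        system = CategorySystem((0, 1, 1, 1, 2))  # (1, 3, 1)
        assert cs.is_symmetric(system, s.group)

    def test_one_block_system_symmetric_on_every_structure(
        self, canonical_structures
    ):
        for s in canonical_structures.values():
            assert cs.is_symmetric(CategorySystem((0,) * s.n), s.group)

    def test_degree_mismatch_rejected(self):
        s = cs.make_structure("linear", 4)
        with pytest.raises(ValueError, match="points"):
            cs.is_symmetric(CategorySystem((0, 0, 1)), s.group)

    def test_hole_set_must_be_invariant(self):
        s = cs.make_structure("linear", 4)
        symmetric_holes = CategorySystem((None, 0, 0, None))
        asymmetric_holes = CategorySystem((None, 0, 0, 1))
        assert cs.is_symmetric(symmetric_holes, s.group)
        assert not cs.is_symmetric(asymmetric_holes, s.group)


class TestInducedBlockPermutation:
    def test_rotation_pairs_opposite_arcs_of_seasons_system(self):
        s = cs.make_structure("bisected_circular", 8)
        seasons = CategorySystem((0, 0, 1, 1, 2, 2, 3, 3))
        rotation = next(
            t for t in s.group.generators if t.label == "rotation-half"
        )
        perm = cs.induced_block_permutation(seasons, rotation)
        assert perm == {0: 2, 1: 3, 2: 0, 3: 1}
        assert all(perm[perm[b]] == b and perm[b] != b for b in perm)

    def test_asymmetric_split_fails(self):
        s = cs.make_structure("linear", 4)
        reversal = s.group.generators[0]
        assert cs.induced_block_permutation(
            CategorySystem((0, 0, 0, 1)), reversal
        ) is None

    def test_symmetric_split_swaps_outer_blocks(self):
        s = cs.make_structure("linear", 4)
        reversal = s.group.generators[0]
        perm = cs.induced_block_permutation(
            CategorySystem((0, 1, 1, 2)), reversal
        )
        assert perm == {0: 2, 1: 1, 2: 0}

    def test_equivalent_to_pairwise_relation_check(self, canonical_structures):
        """The two symmetry routes agree on every connected partition."""
        for s in canonical_structures.values():
            for system in cs.enumerate_connected_partitions(s):
                oracle = all(
                    cs.induced_block_permutation(system, t) is not None
                    for t in s.group
                )
                assert cs.is_symmetric(system, s.group) == oracle


class TestEnumeration:
    @pytest.mark.parametrize(
        "kind, size, expected",
        [
            ("linear", 4, 8),          # compositions of 4
            ("bisected_circular", 4, 12),  # 1 + C(4,2)+C(4,3)+C(4,4)
            ("binary_feature", 2, 15),  # Bell number of a 4-set
        ],
    )
    def test_partition_counts(self, kind, size, expected):
        s = cs.make_structure(kind, size)
        assert len(cs.enumerate_connected_partitions(s)) == expected

    @pytest.mark.parametrize(
        "kind, size",
        [
            ("linear", 4), ("linear", 6),
            ("bisected_linear", 5),
            ("bisected_circular", 4), ("bisected_circular", 6),
            ("binary_feature", 2),
        ],
    )
    def test_matches_brute_force_oracle(self, kind, size):
        s = cs.make_structure(kind, size)
        ours = {p.assignment for p in cs.enumerate_connected_partitions(s)}
        oracle = set(brute_force_connected_partitions(s))
        assert ours == oracle

    @pytest.mark.parametrize("n", [2, 4, 6, 8])
    def test_linear_count_closed_form(self, n):
        s = cs.make_structure("linear", n)
        assert len(cs.enumerate_connected_partitions(s)) == 2 ** (n - 1)

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_cycle_count_closed_form(self, n):
        s = cs.make_structure("bisected_circular", n)
        assert len(cs.enumerate_connected_partitions(s)) == 2 ** n - n

    def test_max_size_truncates(self):
        s = cs.make_structure("linear", 6)
        systems = cs.enumerate_connected_partitions(s, max_size=2)
        assert all(p.size <= 2 for p in systems)
        assert len(systems) == 1 + 5  # trivial + 5 single cuts

    def test_no_duplicates_under_relabelling(self, canonical_structures):
        for s in canonical_structures.values():
            systems = cs.enumerate_connected_partitions(s)
            assert len(systems) == len({p.assignment for p in systems})


class TestSymmetricSystems:
    def test_linear4_sizes(self):
        s = cs.make_structure("linear", 4)
        assert [p.size for p in cs.enumerate_symmetric_systems(s)] == [1, 2, 3, 4]

    def test_bisected_linear5_sizes_all_odd(self):
        s = cs.make_structure("bisected_linear", 5)
        assert [p.size for p in cs.enumerate_symmetric_systems(s)] == [1, 3, 3, 5]

    def test_feature2_never_three_categories(self):
        s = cs.make_structure("binary_feature", 2)
        systems = cs.enumerate_symmetric_systems(s)
        assert [p.size for p in systems] == [1, 2, 2, 2, 4]
        two_systems = {p.assignment for p in systems if p.size == 2}
        # older/younger, male/female, and the diagonal pairing
        assert two_systems == {(0, 0, 1, 1), (0, 1, 0, 1), (0, 1, 1, 0)}

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_linear_systems_are_palindromic_compositions(self, n):
        """Independent palindrome oracle for the linear structure."""
        s = cs.make_structure("linear", n)
        ours = {p.assignment for p in cs.enumerate_symmetric_systems(s)}
        palindromes = set()
        for comp in _compositions(n, n):
            if comp == comp[::-1]:
                labels = []
                for lab, length in enumerate(comp):
                    labels.extend([lab] * length)
                palindromes.add(CategorySystem(tuple(labels)).assignment)
        assert ours == palindromes

    @pytest.mark.parametrize("n", [4, 8, 12])
    def test_half_turn_acts_freely_on_nontrivial_circular_blocks(self, n):
        """The mechanism of the even-parity theorem: rotation induces a
        fixed-point-free involution on blocks."""
        s = cs.make_structure("bisected_circular", n)
        rotation = next(
            t for t in s.group.generators if t.label == "rotation-half"
        )
        for system in cs.enumerate_symmetric_systems(s):
            if system.is_trivial:
                continue
            perm = cs.induced_block_permutation(system, rotation)
            assert perm is not None
            assert all(perm[b] != b for b in perm)
            assert all(perm[perm[b]] == b for b in perm)


class TestClassifyParity:
    @pytest.mark.parametrize(
        "kind, resolutions, verdict",
        [
            ("linear", (4, 6, 8), "both"),
            ("bisected_linear", (3, 5, 7, 9), "odd"),
            ("bisected_circular", (4, 8, 12), "even"),
            ("binary_feature", (1, 2, 3), "even"),
        ],
    )
    def test_canonical_verdicts(self, kind, resolutions, verdict):
        v = cs.classify_parity(kind, resolutions)
        assert v.verdict == verdict
        assert v.trivial_excluded
        for parity, witness in v.witnesses.items():
            assert witness.size % 2 == (0 if parity == "even" else 1)
            assert not witness.is_trivial

    def test_requires_at_least_two_resolutions(self):
        with pytest.raises(ValueError, match="resolutions"):
            cs.classify_parity("linear", (6,))

    def test_verdict_json_round_trips(self):
        import json

        v = cs.classify_parity("bisected_linear", (5, 7))
        doc = json.loads(json.dumps(v.to_dict()))
        assert doc["verdict"] == "odd"
        assert doc["parities_attested"] == ["odd"]


class TestCategorySystem:
    def test_canonical_relabelling(self):
        assert CategorySystem((5, 5, 2, 2)).assignment == (0, 0, 1, 1)
        assert CategorySystem((1, 0, 0, 1)) == CategorySystem((0, 1, 1, 0))

    def test_from_blocks_round_trip(self):
        system = CategorySystem.from_blocks([{0, 1}, {2}], 3)
        assert system.blocks == (frozenset({0, 1}), frozenset({2}))
        assert system.size == 2

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            CategorySystem.from_blocks([{0, 1}, {1, 2}], 3)

    def test_holes_do_not_count_toward_size(self):
        system = CategorySystem((None, 0, 0, None))
        assert system.size == 1
        assert system.holes == {0, 3}
        assert not system.is_trivial

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 4), min_size=1, max_size=8))
    def test_size_equals_block_count(self, labels):
        system = CategorySystem(tuple(labels))
        assert system.size == len(system.blocks)
        assert set().union(*system.blocks) == set(range(len(labels)))
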