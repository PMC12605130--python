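"""Complex construction, incidence/connectivity matrices, q-components."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import oracle_component_counts, oracle_q_components, random_simplex_list
from qcomplex import SimplicialComplex, build_complex, complex_from_adjacency

simplex_lists = st.lists(
    st.lists(st.integers(0, 9), min_size=1, max_size=5),
    min_size=1,
    max_size=8,
)


class TestBuild:
    def test_worked_example_shape(self, k2):
        assert (k2.m, k2.n_vertices, k2.d_max) == (2, 4, 2)

    def test_within_simplex_duplicates_removed(self):
        K = build_complex([[1, 1, 2]])
        assert K.m == 1
        assert K.simplices[0] == frozenset({0, 1})
        assert K.d_max == 1

    def test_duplicate_simplices_retained_by_default(self):
        K = build_complex([[0], [0]])
        assert K.m == 2
        assert all(len(s) - 1 == 0 for s in K.simplices)

    def test_duplicate_simplices_collapsed_on_request(self):
        K = build_complex([[0, 1], [1, 0], [2]], keep_duplicates=False)
        assert K.m == 2

    def test_labels_indexed_in_first_appearance_order(self):
        K = build_complex([["b", "a"], ["c", "a"]])
        assert K.vertex_labels == ["b", "a", "c"]

    def test_empty_record_names_position(self):
        with pytest.raises(ValueError, match="position 1"):
            build_complex([[1], []])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_complex([])


class TestFromAdjacency:
    def test_triangle_single_maximal_clique(self, triangle_adj):
        K = complex_from_adjacency(triangle_adj)
        assert K.m == 1
        assert K.simplices[0] == frozenset({0, 1, 2})

    def test_path_yields_edge_simplices(self, path4_adj):
        K = complex_from_adjacency(path4_adj)
        assert [set(s) for s in K.simplices] == [{0, 1}, {1, 2}, {2, 3}]

    def test_isolated_vertices_become_zero_simplices(self):
        K = complex_from_adjacency(np.zeros((3, 3)))
        assert K.m == 3
        assert K.d_max == 0

    def test_self_loops_ignored(self, triangle_adj):
        K = complex_from_adjacency(triangle_adj + np.eye(3))
        assert K.m == 1

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0, 1, 0], [1, 0, 0]]),  # non-square
            np.array([[0, 1], [0, 0]]),  # asymmetric
            np.array([[0, -1], [-1, 0]]),  # negative
        ],
        ids=["non-square", "asymmetric", "negative"],
    )
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(ValueError):
            complex_from_adjacency(bad)


class TestMatrices:
    def test_incidence_worked_example(self, k2):
        assert np.array_equal(
            k2.incidence_matrix(), [[1, 1, 1, 0], [0, 1, 1, 1]]
        )

    def test_incidence_single_simplex(self):
        K = build_complex([[1, 2, 3]])
        assert np.array_equal(K.incidence_matrix(), [[1, 1, 1]])

    def test_incidence_reference_complex(self, ref):
        lam = ref.incidence_matrix()
        assert lam.shape == (4, 7)
        assert np.array_equal(lam.sum(axis=1), [4, 4, 3, 2])

    def test_connectivity_worked_example(self, k2):
        assert np.array_equal(k2.connectivity_matrix(), [[2, 1], [1, 2]])

    def test_connectivity_reference_complex(self, ref):
        pi = ref.connectivity_matrix()
        assert pi[0, 0] == 3
        assert pi[0, 1] == 2
        assert pi[0, 2] == 0  # single shared vertex

    def test_disjoint_pair_off_diagonal(self):
        K = build_complex([[0, 1], [2, 3]])
        assert K.connectivity_matrix()[0, 1] == -1

    def test_q_nearness(self, k2):
        assert k2.q_nearness(0, 1) == 1
        assert k2.q_nearness(0, 0) == 2
        with pytest.raises(IndexError):
            k2.q_nearness(0, 5)


class TestComponents:
    @pytest.mark.parametrize("q,count", [(0, 1), (1, 1), (2, 2)])
    def test_worked_example_counts(self, k2, q, count):
        assert k2.q_connected_components(q) == count

    def test_worked_example_labelings(self, k2):
        assert k2.q_connected_components_labeled(2) == [{0}, {1}]
        assert k2.q_connected_components_labeled(1) == [{0, 1}]

    def test_reference_complex_chain(self, ref):
        comps = ref.q_connected_components_labeled(1)
        assert {0, 1, 2} in comps
        assert len(comps) == 2

    @pytest.mark.parametrize("q", [-1, 3])
    def test_out_of_range_level_rejected(self, k2, q):
        with pytest.raises(ValueError):
            k2.q_connected_components(q)

    def test_low_dimension_simplices_excluded(self):
        K = build_complex([[0, 1, 2], [0]])
        labeled = K.q_connected_components_labeled(1)
        assert labeled == [{0}]


class TestProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(simplex_lists)
    def test_connectivity_symmetry_and_diagonal(self, records):
        K = SimplicialComplex(records)
        pi = K.connectivity_matrix()
        assert np.array_equal(pi, pi.T)
        assert np.array_equal(np.diag(pi), [len(s) - 1 for s in K.simplices])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(simplex_lists)
    def test_refinement_across_levels(self, records):
        """Every (q+1)-component lies inside exactly one q-component."""
        K = SimplicialComplex(records)
        for q in range(K.d_max):
            coarse = K.q_connected_components_labeled(q)
            for fine in K.q_connected_components_labeled(q + 1):
                assert sum(fine <= c for c in coarse) == 1

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(simplex_lists)
    def test_eligible_count_non_increasing(self, records):
        K = SimplicialComplex(records)
        sizes = [
            sum(len(c) for c in K.q_connected_components_labeled(q))
            for q in range(K.d_max + 1)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_determinism(self):
        records = [[0, 1, 2], [1, 2, 3], [3, 4], [5]]
        a, b = SimplicialComplex(records), SimplicialComplex(records)
        assert np.array_equal(a.connectivity_matrix(), b.connectivity_matrix())
        for q in range(a.d_max + 1):
            assert a.q_connected_components_labeled(q) == b.q_connected_components_labeled(q)

    def test_matches_bfs_oracle_on_random_complexes(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            records = random_simplex_list(rng)
            K = SimplicialComplex(records)
            assert [
                K.q_connected_components(q) for q in range(K.d_max + 1)
            ] == oracle_component_counts([set(r) for r in records])
            for q in range(K.d_max + 1):
                assert K.q_connected_components_labeled(q) == oracle_q_components(
                    [set(r) for r in records], q
                )
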