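from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ishc.sync_clustering import (
    epsilon_neighborhood,
    find_closures,
    hierarchical_search,
    shc_cluster,
    sync_step,
)


def brute_force_closures(coords: np.ndarray, eps: float, active=None) -> list[set]:
    """Exhaustive-subset enumeration of the closure definition.

    S is a closure iff for every x in S the closed eps-neighborhood of x
    (restricted to active objects) equals S exactly.
    """
    n = coords.shape[0]
    act = sorted(range(n)) if active is None else sorted(active)
    nbhd = {
        i: (epsilon_neighborhood(coords, i, eps) & set(act)) | {i}
        for i in act
    }
    out = []
    for size in range(1, len(act) + 1):
        for subset in combinations(act, size):
            S = set(subset)
            if all(nbhd[x] == S for x in S):
                out.append(S)
    return out


def canon(sets):
    return sorted(tuple(sorted(s)) for s in sets)


class TestEpsilonNeighborhood:
    def test_single_object_empty(self):
        assert epsilon_neighborhood(np.zeros((1, 3)), 0, 1.0) == set()

    def test_boundary_inclusive(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert epsilon_neighborhood(coords, 0, 1.0) == {1}

    def test_membership_symmetric(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(size=(10, 3))
        for i in range(10):
            for j in epsilon_neighborhood(coords, i, 0.5):
                assert i in epsilon_neighborhood(coords, j, 0.5)

    def test_nonpositive_eps_rejected(self):
        with pytest.raises(ValueError):
            epsilon_neighborhood(np.zeros((2, 3)), 0, 0.0)


class TestFindClosures:
    def test_tight_quadruple_is_one_closure(self):
        coords = np.vstack([np.random.default_rng(1).normal(0, 0.05, (4, 3)), [[5, 5, 5]]])
        closures = find_closures(coords, eps=0.5, active={0, 1, 2, 3})
        assert canon(closures) == [(0, 1, 2, 3)]

    def test_isolated_object_is_singleton_closure(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        assert canon(find_closures(coords, eps=1.0)) == [(0,), (1,)]

    def test_chain_at_spacing_eps_has_no_closure(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        assert find_closures(coords, eps=1.0) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 9)
        coords = rng.uniform(0, 1, size=(n, 3))
        eps = rng.uniform(0.1, 0.8)
        assert canon(find_closures(coords, eps)) == canon(brute_force_closures(coords, eps))

    def test_respects_active_restriction(self):
        # 0 and 2 are each within eps of 1 but not of each other; dropping 1
        # from the active set turns them into singleton closures.
        coords = np.array([[0.0, 0, 0], [0.9, 0, 0], [1.8, 0, 0]])
        assert canon(find_closures(coords, 1.0, active={0, 2})) == [(0,), (2,)]


class TestSyncStep:
    def test_isolated_object_fixed(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        assert np.array_equal(sync_step(coords, 1.0), coords)

    def test_coincident_pair_fixed(self):
        coords = np.array([[0.3, 0.3, 0.3], [0.3, 0.3, 0.3]])
        assert np.array_equal(sync_step(coords, 1.0), coords)

    def test_two_point_update_values(self):
        # closed neighborhoods have 2 members, so each point moves by sin(d)/2
        coords = np.array([[0.0, 0, 0], [0.5, 0, 0]])
        out = sync_step(coords, 1.0)
        assert out[0, 0] == pytest.approx(np.sin(0.5) / 2)
        assert out[1, 0] == pytest.approx(0.5 - np.sin(0.5) / 2)

    def test_pair_separation_contracts_below_tolerance(self):
        coords = np.array([[0.0, 0, 0], [0.5, 0, 0]])
        sep = 0.5
        for _ in range(50):
            coords = sync_step(coords, 1.0)
            new_sep = abs(coords[1, 0] - coords[0, 0])
            assert new_sep <= sep
            sep = new_sep
        assert sep < 1e-6

    def test_closure_diameter_non_increasing(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            coords = rng.uniform(0, 0.3, size=(6, 3))  # diameter < 1, all mutual
            diam = np.max([np.linalg.norm(a - b) for a in coords for b in coords])
            for _ in range(50):
                coords = sync_step(coords, eps=2.0)
                new_diam = np.max([np.linalg.norm(a - b) for a in coords for b in coords])
                assert new_diam <= diam + 1e-12
                diam = new_diam


class TestShcCluster:
    def test_everything_within_eps_is_one_cluster(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 0.1, size=(6, 3))
        clu = shc_cluster(coords, eps=1.0)
        assert clu.n_clusters == 1 and clu.n_sync_steps == 0

    def test_everything_far_apart_is_singletons(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        clu = shc_cluster(coords, eps=1.0)
        assert clu.n_clusters == 3 and clu.n_sync_steps == 0

    def test_two_blobs_resolved_exactly(self, two_blob_coords):
        clu = shc_cluster(two_blob_coords, eps=0.2)
        assert canon(clu.clusters) == [(0, 1, 2, 3, 4), (5, 6, 7, 8, 9)]

    def test_output_is_partition(self):
        rng = np.random.default_rng(4)
        for seed in range(10):
            coords = np.random.default_rng(seed).uniform(size=(12, 3))
            clu = shc_cluster(coords, eps=float(rng.uniform(0.05, 1.0)))
            clu.validate_partition(12)  # raises on overlap/miss

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(size=(10, 3))
        perm = rng.permutation(10)
        clu = shc_cluster(coords, eps=0.3)
        clu_p = shc_cluster(coords[perm], eps=0.3)
        # mapping: object i in original appears at position perm^-1[i]
        inv = np.argsort(perm)
        remapped = [{int(inv[i]) for i in c} for c in clu.clusters]
        assert canon(remapped) == canon(clu_p.clusters)

    def test_deterministic(self):
        coords = np.random.default_rng(8).uniform(size=(15, 3))
        a = shc_cluster(coords, eps=0.25)
        b = shc_cluster(coords, eps=0.25)
        assert canon(a.clusters) == canon(b.clusters)

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            shc_cluster(np.zeros((3, 3)), eps=-1.0)
        with pytest.raises(ValueError):
            shc_cluster(np.zeros((3, 3)), eps=1.0, max_steps=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.floats(min_value=0.05, max_value=1.5))
    def test_partition_property_random_points(self, seed, eps):
        coords = np.random.default_rng(seed).uniform(size=(9, 3))
        shc_cluster(coords, eps=eps, max_steps=60).validate_partition(9)


class TestHierarchicalSearch:
    def test_single_level_returns_initial_radius(self, two_blob_coords):
        from ishc.sync_clustering import knn_distances

        eps0 = float(np.mean(knn_distances(two_blob_coords, 3)))
        eps, clu = hierarchical_search(two_blob_coords, lambda c: 0.0, max_levels=1)
        assert eps == pytest.approx(eps0)

    def test_constant_objective_ties_break_small(self, two_blob_coords):
        eps1, _ = hierarchical_search(two_blob_coords, lambda c: 1.0, max_levels=1)
        eps5, _ = hierarchical_search(two_blob_coords, lambda c: 1.0, max_levels=5)
        assert eps5 == pytest.approx(eps1)

    def test_recovers_two_blobs_with_matching_objective(self, two_blob_coords):
        # reward exactly the 2-cluster solution
        eps, clu = hierarchical_search(
            two_blob_coords, lambda c: -abs(c.n_clusters - 2), max_levels=20
        )
        assert clu.n_clusters == 2

    def test_needs_five_objects(self):
        with pytest.raises(ValueError):
            hierarchical_search(np.zeros((4, 3)), lambda c: 0.0)
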