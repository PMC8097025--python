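"""Density, standardized degree, hub classification, modular densities."""

import warnings

import numpy as np
import pytest

from scndev.errors import InvalidConfigError, InvalidInputError
from scndev.graph_metrics import (
    global_density,
    identify_hubs,
    modular_density,
    standardized_degree,
)


def _adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


def _brute_force_counts(adj, modules):
    """Oracle: count every edge once and classify by the module pair."""
    within = {}
    between = {}
    n = adj.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if not adj[i, j]:
                continue
            a, b = sorted((modules[i], modules[j]))
            if a == b:
                within[a] = within.get(a, 0) + 1
            else:
                between[(a, b)] = between.get((a, b), 0) + 1
    return within, between


class TestGlobalDensity:
    def test_complete_graph(self):
        a = 1 - np.eye(5, dtype=int)
        assert global_density(a) == 1.0

    def test_empty_graph(self):
        assert global_density(np.zeros((4, 4), dtype=int)) == 0.0

    def test_five_nodes_four_edges(self):
        a = _adj_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        assert global_density(a) == pytest.approx(0.4)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            global_density(np.zeros((1, 1), dtype=int))
        with pytest.raises(InvalidInputError):
            global_density(np.array([[0, 2], [2, 0]]))


class TestStandardizedDegree:
    def test_star_graph(self):
        a = _adj_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        z = standardized_degree(a)
        np.testing.assert_allclose(z, [1.5, -0.5, -0.5, -0.5])

    def test_regular_graph_all_zero(self):
        a = _adj_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        with pytest.warns(UserWarning, match="constant degree"):
            z = standardized_degree(a)
        np.testing.assert_allclose(z, 0.0)

    def test_mean_zero_and_unit_sd(self):
        rng = np.random.default_rng(0)
        a = (rng.random((12, 12)) < 0.3).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        z = standardized_degree(a)
        assert abs(z.mean()) < 1e-8
        assert abs(z.std(ddof=1) - 1) < 1e-8

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        a = (rng.random((10, 10)) < 0.4).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        perm = rng.permutation(10)
        z = standardized_degree(a)
        z_perm = standardized_degree(a[np.ix_(perm, perm)])
        np.testing.assert_allclose(z_perm, z[perm])


class TestHubs:
    def test_two_bins_above_threshold_is_hub(self):
        z = np.zeros((8, 3))
        z[2, 0] = 1.2  # region 0: bins 2 and 6 above 1
        z[6, 0] = 1.3
        z[4, 1] = 2.5  # region 1: only one bin
        hubs = identify_hubs(z)
        assert hubs.is_hub.tolist() == [True, False, False]

    def test_strict_inequality_at_threshold(self):
        z = np.full((5, 1), 1.0)  # exactly 1 everywhere: never a hub
        assert not identify_hubs(z).is_hub[0]

    def test_min_bins_exceeding_bins_rejected(self):
        with pytest.raises(InvalidConfigError):
            identify_hubs(np.zeros((1, 3)), min_bins=2)


class TestModularDensity:
    def test_complete_graph_all_normalized_one(self):
        a = 1 - np.eye(6, dtype=int)
        md = modular_density(a, [1, 1, 1, 2, 2, 2])
        assert all(v == pytest.approx(1.0) for v in md.intra.values())
        assert all(v == pytest.approx(1.0) for v in md.inter.values())

    def test_worked_example_two_modules(self):
        # modules A={0,1,2}, B={3,4,5}; all 3 edges within A, none in B,
        # 2 between -> raw intra (1.0, 0.0), raw inter 2/9, global 5/15
        a = _adj_from_edges(6, [(0, 1), (0, 2), (1, 2), (0, 3), (1, 4)])
        raw = modular_density(a, [1, 1, 1, 2, 2, 2], normalize=False)
        assert raw.intra[1] == pytest.approx(1.0)
        assert raw.intra[2] == pytest.approx(0.0)
        assert raw.inter[(1, 2)] == pytest.approx(2 / 9)
        norm = modular_density(a, [1, 1, 1, 2, 2, 2], normalize=True)
        assert norm.intra[1] == pytest.approx(3.0)
        assert norm.inter[(1, 2)] == pytest.approx(2 / 9 / (5 / 15))

    def test_module_without_internal_edges(self):
        a = _adj_from_edges(4, [(0, 2), (1, 3)])
        md = modular_density(a, [1, 1, 2, 2], normalize=False)
        assert md.intra[1] == 0.0

    def test_zero_global_density_flags_nan(self):
        a = np.zeros((4, 4), dtype=int)
        md = modular_density(a, [1, 1, 2, 2], normalize=True)
        assert np.isnan(md.intra[1])

    def test_singleton_module_intra_nan(self):
        a = _adj_from_edges(3, [(0, 1)])
        md = modular_density(a, [1, 1, 2], normalize=False)
        assert np.isnan(md.intra[2])

    def test_edge_count_conservation_random_instances(self):
        # sum of within- and between-module edge counts equals total edges
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = rng.integers(6, 16)
            a = (rng.random((n, n)) < rng.uniform(0.1, 0.7)).astype(int)
            a = np.triu(a, 1)
            a = a + a.T
            modules = rng.integers(1, 4, n)
            within, between = _brute_force_counts(a, modules)
            raw = modular_density(a, modules, normalize=False)
            total = a.sum() // 2
            # reconstruct counts from densities
            recon = 0.0
            for m, v in raw.intra.items():
                n_m = int((modules == m).sum())
                if n_m >= 2:
                    recon += v * n_m * (n_m - 1) / 2
            for (x, y), v in raw.inter.items():
                recon += v * (modules == x).sum() * (modules == y).sum()
            assert recon == pytest.approx(total)
            # and the oracle counts agree edge for edge
            for m, c in within.items():
                n_m = int((modules == m).sum())
                assert raw.intra[m] * n_m * (n_m - 1) / 2 == pytest.approx(c)
            for pair, c in between.items():
                nx_, ny_ = (modules == pair[0]).sum(), (modules == pair[1]).sum()
                assert raw.inter[pair] * nx_ * ny_ == pytest.approx(c)

    def test_densities_bounded_before_normalization(self):
        rng = np.random.default_rng(4)
        a = (rng.random((10, 10)) < 0.5).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        raw = modular_density(a, rng.integers(1, 4, 10), normalize=False)
        vals = [v for v in list(raw.intra.values()) + list(raw.inter.values())
                if np.isfinite(v)]
        assert all(0.0 <= v <= 1.0 for v in vals)
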