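import itertools
import warnings

import numpy as np
import pytest

from conftest import graph_from, random_graph
from hyperbrain.graphs import (characteristic_path_length,
                               clustering_coefficient, collapse_bands,
                               collapse_bands_and_regions, collapse_regions,
                               null_models, small_worldness, strengths)
from hyperbrain.signals import MONTAGE_21


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_binary_cc(a: np.ndarray) -> np.ndarray:
    """Neighbor-pair enumeration, undirected binary."""
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        closed = sum(1 for x, y in itertools.combinations(nbrs, 2)
                     if a[x, y] > 0)
        c[i] = closed / (k * (k - 1) / 2)
    return c


def oracle_weighted_cc(w: np.ndarray) -> np.ndarray:
    """Cube-root triangle intensity over all neighbor pairs, undirected."""
    n = w.shape[0]
    wh = w / w.max() if w.max() > 0 else w
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = sum((wh[i, x] * wh[i, y] * wh[x, y]) ** (1 / 3)
                    for x, y in itertools.combinations(nbrs, 2)
                    if w[x, y] > 0)
        c[i] = total / (k * (k - 1) / 2)
    return c


def oracle_directed_cc(w: np.ndarray) -> np.ndarray:
    """Ordered-triple enumeration of directed weighted triangles."""
    n = w.shape[0]
    a = (w > 0).astype(int)
    wh = np.cbrt(w / w.max()) if w.max() > 0 else w
    c = np.zeros(n)
    for i in range(n):
        t = 0.0
        for j in range(n):
            for h in range(n):
                if len({i, j, h}) < 3:
                    continue
                t += ((wh[i, j] + wh[j, i]) * (wh[i, h] + wh[h, i])
                      * (wh[j, h] + wh[h, j]))
        t /= 2.0
        k_tot = a[i].sum() + a[:, i].sum()
        k_bi = (a[i] * a[:, i]).sum()
        denom = k_tot * (k_tot - 1) - 2 * k_bi
        c[i] = t / denom if denom > 0 else 0.0
    return c


def oracle_floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths; lengths has inf for missing edges."""
    n = lengths.shape[0]
    d = lengths.copy()
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_cpl(g, weighted=False) -> float:
    if weighted:
        with np.errstate(divide="ignore"):
            lengths = np.where(g.weights > 0, 1.0 / g.weights, np.inf)
    else:
        lengths = np.where(g.adjacency > 0, 1.0, np.inf)
    if not g.directed:
        lengths = np.minimum(lengths, lengths.T)
    d = oracle_floyd_warshall(lengths)
    off = ~np.eye(d.shape[0], dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    return float(vals[finite].mean()) if finite.any() else float("nan")


# ---------------------------------------------------------------------------
# strengths
# ---------------------------------------------------------------------------

class TestStrengths:
    def test_directed_toy(self):
        w = np.zeros((3, 3))
        w[0, 1], w[1, 2] = 0.5, 0.2
        ns = strengths(graph_from(w, directed=True))
        np.testing.assert_allclose(ns.out_strength, [0.5, 0.2, 0.0])
        np.testing.assert_allclose(ns.in_strength, [0.0, 0.5, 0.2])

    def test_empty_graph_zeros(self):
        ns = strengths(graph_from(np.zeros((4, 4))))
        assert ns.total.sum() == 0.0

    def test_intra_plus_inter_is_total(self, rng):
        g = random_graph(8, 0.4, rng, directed=True, weighted=True)
        g.brains = ["A"] * 4 + ["B"] * 4
        ns = strengths(g)
        np.testing.assert_allclose(ns.intra + ns.inter, ns.total, atol=1e-12)

    def test_inter_only_counts_between_brain_edges(self):
        w = np.zeros((4, 4))
        w[0, 1] = 0.3  # intra A
        w[0, 2] = 0.7  # inter
        g = graph_from(w, directed=True, brains=["A", "A", "B", "B"])
        ns = strengths(g)
        assert ns.inter[0] == pytest.approx(0.7)
        assert ns.intra[0] == pytest.approx(0.3)


# ---------------------------------------------------------------------------
# clustering and path length vs oracles
# ---------------------------------------------------------------------------

class TestClustering:
    def test_complete_graph(self):
        w = 1.0 - np.eye(4)
        _, cc = clustering_coefficient(graph_from(w), "binary")
        assert cc == pytest.approx(1.0)

    def test_star_graph(self):
        w = np.zeros((4, 4))
        w[0, 1:] = 1.0
        w[1:, 0] = 1.0
        _, cc = clustering_coefficient(graph_from(w), "binary")
        assert cc == 0.0

    def test_oracle_battery(self, rng):
        # 100 random graphs of <= 8 nodes across all three modes
        for trial in range(100):
            n = int(rng.integers(3, 9))
            mode = ("binary", "weighted", "directed")[trial % 3]
            directed = mode == "directed"
            g = random_graph(n, 0.5, rng, directed=directed,
                             weighted=mode != "binary")
            c, _ = clustering_coefficient(g, mode)
            if mode == "binary":
                expected = oracle_binary_cc(g.adjacency)
            elif mode == "weighted":
                expected = oracle_weighted_cc(g.weights)
            else:
                expected = oracle_directed_cc(g.weights)
            np.testing.assert_allclose(c, expected, atol=1e-12)

    def test_too_few_nodes_errors(self):
        with pytest.raises(ValueError):
            clustering_coefficient(graph_from(np.zeros((2, 2))), "binary")


class TestPathLength:
    def test_complete_graph(self):
        w = 1.0 - np.eye(4)
        assert characteristic_path_length(graph_from(w)) == pytest.approx(1.0)

    def test_cycle_graph(self):
        w = np.zeros((4, 4))
        for i in range(4):
            w[i, (i + 1) % 4] = w[(i + 1) % 4, i] = 1.0
        assert characteristic_path_length(graph_from(w)) == pytest.approx(4 / 3)

    def test_oracle_battery(self, rng):
        for trial in range(100):
            n = int(rng.integers(3, 9))
            directed = trial % 2 == 0
            weighted = trial % 3 == 0
            g = random_graph(n, 0.5, rng, directed=directed,
                             weighted=weighted)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cpl = characteristic_path_length(g, weighted=weighted)
            expected = oracle_cpl(g, weighted=weighted)
            if np.isnan(expected):
                assert np.isnan(cpl)
            else:
                np.testing.assert_allclose(cpl, expected, atol=1e-12)

    def test_adding_edge_never_increases_binary_cpl(self, rng):
        for _ in range(20):
            g = random_graph(7, 0.6, rng)
            base_d = _reachable_distances(g)
            zeros = np.argwhere((g.weights == 0) &
                                ~np.eye(7, dtype=bool))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            w2 = g.weights.copy()
            w2[i, j] = w2[j, i] = 1.0
            d2 = _reachable_distances(graph_from(w2))
            # pairwise: distances only shrink on the common reachable set
            assert (d2 <= base_d + 1e-12).all()

    def test_directed_differs_from_symmetrized(self):
        # directed 3-cycle: CPL 1.5 directed, 1.0 symmetrized
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 2] = w[2, 0] = 1.0
        directed = graph_from(w, directed=True)
        undirected = graph_from(np.maximum(w, w.T))
        assert characteristic_path_length(directed) == pytest.approx(1.5)
        assert characteristic_path_length(undirected) == pytest.approx(1.0)


def _reachable_distances(g):
    from scipy.sparse.csgraph import shortest_path

    d = shortest_path(g.adjacency, directed=False, unweighted=True)
    d[~np.isfinite(d)] = 1e9  # adding edges can only reduce
    return d


# ---------------------------------------------------------------------------
# null models and small-worldness
# ---------------------------------------------------------------------------

def ring_lattice(n: int, k: int) -> np.ndarray:
    w = np.zeros((n, n))
    for i in range(n):
        for off in range(1, k // 2 + 1):
            j = (i + off) % n
            w[i, j] = w[j, i] = 1.0
    return w


class TestNullModels:
    def test_degree_sequence_preserved(self, rng):
        g = random_graph(12, 0.4, rng)
        for h in null_models(g, "random", n=5, seed=3):
            np.testing.assert_array_equal(h.adjacency.sum(1),
                                          g.adjacency.sum(1))

    def test_directed_in_out_preserved(self, rng):
        g = random_graph(12, 0.3, rng, directed=True)
        for h in null_models(g, "random", n=5, seed=3):
            np.testing.assert_array_equal(h.adjacency.sum(0),
                                          g.adjacency.sum(0))
            np.testing.assert_array_equal(h.adjacency.sum(1),
                                          g.adjacency.sum(1))

    def test_lattice_null_of_ring_lattice_cc(self):
        g = graph_from(ring_lattice(100, 6))
        _, cc_orig = clustering_coefficient(g, "binary")
        nulls = null_models(g, "lattice", n=3, seed=5)
        cc_null = np.mean([clustering_coefficient(h, "binary")[1]
                           for h in nulls])
        assert abs(cc_null - cc_orig) / cc_orig < 0.05

    def test_random_null_shortens_ring_lattice_paths(self):
        g = graph_from(ring_lattice(100, 6))
        cpl_orig = characteristic_path_length(g)
        nulls = null_models(g, "random", n=20, seed=7)
        shorter = sum(characteristic_path_length(h) < cpl_orig
                      for h in nulls)
        assert shorter >= 19

    def test_seed_determinism(self, rng):
        g = random_graph(10, 0.4, rng)
        a = null_models(g, "random", n=3, seed=11)
        b = null_models(g, "random", n=3, seed=11)
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga.weights, gb.weights)

    def test_edgeless_graph_errors(self):
        with pytest.raises(ValueError):
            null_models(graph_from(np.zeros((4, 4))), "random")

    def test_unknown_kind_errors(self, rng):
        with pytest.raises(ValueError):
            null_models(random_graph(5, 0.5, rng), "torus")


@pytest.mark.slow
class TestSmallWorldness:
    def test_watts_strogatz_sigma_above_one(self):
        import networkx as nx

        ws = nx.watts_strogatz_graph(42, 8, 0.1, seed=7)
        g = graph_from(nx.to_numpy_array(ws))
        sw = small_worldness(g, n_null=20, seed=3)
        assert sw.sigma > 1.0

    def test_ring_lattice_omega_negative(self):
        g = graph_from(ring_lattice(60, 6))
        sw = small_worldness(g, n_null=10, seed=3)
        assert sw.omega < 0.0

    def test_random_graph_sigma_near_one_omega_positive(self, rng):
        import networkx as nx

        sigmas, omegas = [], []
        for seed in range(5):
            gnm = nx.gnm_random_graph(40, 160, seed=seed)
            g = graph_from(nx.to_numpy_array(gnm))
            sw = small_worldness(g, n_null=10, seed=seed)
            sigmas.append(sw.sigma)
            omegas.append(sw.omega)
        assert abs(np.mean(sigmas) - 1.0) < 0.15
        assert np.mean(omegas) > 0.0


# ---------------------------------------------------------------------------
# band / region collapsing
# ---------------------------------------------------------------------------

class TestCollapsing:
    FOIS = (2., 3., 4., 5., 6., 7., 8., 9., 10., 11., 12., 14., 16., 18.,
            20., 24., 28.)

    def test_delta_band_mean(self):
        values = np.arange(17.0)
        bands = collapse_bands(values, self.FOIS)
        assert bands["delta"] == pytest.approx(0.5)  # FOIs 2, 3 -> idx 0, 1

    def test_constant_metric(self):
        values = np.full(17, 3.3)
        bands = collapse_bands(values, self.FOIS)
        for v in bands.values():
            assert v == pytest.approx(3.3)

    def test_all_17_fois_covered(self):
        values = np.ones(17)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no orphan warning expected
            bands = collapse_bands(values, self.FOIS)
        assert set(bands) == {"delta", "theta", "alpha", "beta1", "beta2"}

    def test_orphan_foi_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            collapse_bands(np.ones(2), (13.0, 2.0))

    def test_regions_cover_21_electrodes(self):
        values = np.arange(21.0)
        regions = collapse_regions(values, list(MONTAGE_21))
        assert set(regions) == {"frontal", "central", "parieto-occipital"}
        # every electrode contributes to exactly one region mean
        frontal = [i for i, c in enumerate(MONTAGE_21)
                   if c.startswith(("Fp", "F"))]
        assert regions["frontal"] == pytest.approx(np.mean(frontal))

    def test_brain_prefixes_pooled(self):
        values = np.arange(42.0)
        channels = [f"{b}:{c}" for b in "AB" for c in MONTAGE_21]
        regions = collapse_regions(values, channels)
        assert set(regions) == {"frontal", "central", "parieto-occipital"}

    def test_band_region_table(self):
        values = np.ones((17, 21))
        frame = collapse_bands_and_regions(values, self.FOIS,
                                           list(MONTAGE_21))
        assert frame.shape == (5, 3)
        assert (frame.to_numpy() == 1.0).all()
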