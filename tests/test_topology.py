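import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from msp.topology import (
    GraphView,
    betweenness,
    betweenness_summary,
    characteristic_path_length,
    clustering_coefficient,
    degree_distributions,
    er_null,
    global_efficiency,
    local_efficiency,
    shortest_paths,
    small_world,
    topology_record,
)


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and separate from the package)
# ---------------------------------------------------------------------------

def floyd_warshall_oracle(w):
    """All-pairs shortest directed distances with lengths 1/W."""
    n = w.shape[0]
    d = [[math.inf] * n for _ in range(n)]
    for i in range(n):
        d[i][i] = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[j][i] = 1.0 / w[i, j]  # edge j -> i
    for k in range(n):
        for a in range(n):
            for b in range(n):
                if d[a][k] + d[k][b] < d[a][b]:
                    d[a][b] = d[a][k] + d[k][b]
    return np.array(d)


def fagiolo_oracle(w):
    """Literal triple loop over the weighted directed clustering formula."""
    n = w.shape[0]
    if w.max() == 0:
        return np.zeros(n)
    w_hat = np.cbrt(w / w.max())
    a = (w > 0).astype(int)
    out = np.zeros(n)
    for i in range(n):
        triangles = 0.0
        for j in range(n):
            for h in range(n):
                triangles += (
                    (w_hat[j, i] + w_hat[i, j])
                    * (w_hat[h, i] + w_hat[i, h])
                    * (w_hat[h, j] + w_hat[j, h])
                ) / 2.0
        d_tot = sum(a[j, i] + a[i, j] for j in range(n))
        d_bi = sum(a[j, i] * a[i, j] for j in range(n))
        denom = d_tot * (d_tot - 1) - 2 * d_bi
        out[i] = triangles / denom if denom > 0 else 0.0
    return out


def betweenness_oracle(w):
    """Exact-arithmetic enumeration of all simple shortest paths.

    Edge lengths 1/W are kept as Fractions, so equal-length alternatives
    are identified without any floating tolerance.
    """
    n = w.shape[0]
    adj = {
        j: [(i, Fraction(1, int(w[i, j]))) for i in range(n) if w[i, j] > 0 and i != j]
        for j in range(n)
    }
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            best = None
            paths = []
            stack = [(s, Fraction(0), [s])]
            while stack:
                node, dist, path = stack.pop()
                if node == t:
                    if best is None or dist < best:
                        best, paths = dist, [path]
                    elif dist == best:
                        paths.append(path)
                    continue
                for nxt, length in adj[node]:
                    if nxt not in path:
                        stack.append((nxt, dist + length, path + [nxt]))
            if best is None:
                continue
            sigma = len(paths)
            for i in range(n):
                if i in (s, t):
                    continue
                through = sum(1 for p in paths if i in p)
                bc[i] += through / sigma
    return bc


def efficiency_oracles(w):
    """Direct loops over the local/global efficiency definitions."""
    n = w.shape[0]
    d = floyd_warshall_oracle(w)
    glob = np.zeros(n)
    for i in range(n):
        glob[i] = sum(1.0 / d[i][j] for j in range(n) if j != i and d[i][j] < math.inf)
        glob[i] /= max(n - 1, 1)
    loc = np.zeros(n)
    a = (w > 0) | (w.T > 0)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j] and j != i]
        k = len(nbrs)
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        d_sub = floyd_warshall_oracle(sub)
        total = sum(
            1.0 / d_sub[x][y]
            for x in range(k)
            for y in range(k)
            if x != y and d_sub[x][y] < math.inf
        )
        loc[i] = total / (k * (k - 1))
    return loc, glob


def random_digraph(rng, n, max_w=3, density=0.4):
    w = rng.integers(1, max_w + 1, size=(n, n)) * (rng.random((n, n)) < density)
    np.fill_diagonal(w, 0)
    return w.astype(np.int64)


def all_small_digraphs(n, weights=(0, 1, 2)):
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    for combo in itertools.product(weights, repeat=len(pairs)):
        w = np.zeros((n, n), dtype=np.int64)
        for (i, j), c in zip(pairs, combo):
            w[i, j] = c
        yield w


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestShortestPaths:
    def test_inverse_multiplicity_length(self):
        w = np.zeros((2, 2), dtype=int)
        w[1, 0] = 2  # edge 0 -> 1, length 1/2
        d = shortest_paths(GraphView(w))
        assert d[0, 1] == 0.5
        assert d[1, 0] == math.inf
        assert d[0, 0] == 0.0

    def test_chain_additivity(self):
        w = np.zeros((3, 3), dtype=int)
        w[1, 0] = 1
        w[2, 1] = 1
        d = shortest_paths(GraphView(w))
        assert d[0, 2] == 2.0


class TestCharacteristicPathLength:
    def test_complete_unit_graph(self):
        w = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
        length, frac = characteristic_path_length(GraphView(w))
        assert length == 1.0 and frac == 0.0

    def test_three_cycle(self):
        w = np.zeros((3, 3), dtype=int)
        w[1, 0] = w[2, 1] = w[0, 2] = 1
        length, frac = characteristic_path_length(GraphView(w))
        assert length == pytest.approx(1.5)  # distances 1 and 2 from each node
        assert frac == 0.0

    def test_edgeless_graph_undefined(self):
        length, frac = characteristic_path_length(GraphView(np.zeros((3, 3), int)))
        assert math.isnan(length) and frac == 1.0

    def test_region_restricted(self):
        w = np.zeros((3, 3), dtype=int)
        w[1, 0] = 4
        length, frac = characteristic_path_length(GraphView(w), [0], [1])
        assert length == 0.25

    def test_exhaustive_three_node_oracle(self):
        for w in all_small_digraphs(3):
            d = floyd_warshall_oracle(w)
            finite = []
            for i in range(3):
                for j in range(3):
                    if i != j and d[i][j] < math.inf:
                        finite.append(d[i][j])
            length, frac = characteristic_path_length(GraphView(w))
            if not finite:
                assert math.isnan(length)
            else:
                assert length == pytest.approx(np.mean(finite))
                assert frac == pytest.approx(1 - len(finite) / 6)

    @pytest.mark.parametrize("n", [4, 5, 8])
    def test_random_digraphs_match_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(40):
            w = random_digraph(rng, n)
            d = shortest_paths(GraphView(w))
            assert np.allclose(d, floyd_warshall_oracle(w))


class TestClustering:
    def test_bidirectional_binary_triangle(self):
        w = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        c, per_node = clustering_coefficient(GraphView(w))
        assert per_node == pytest.approx([1.0, 1.0, 1.0])
        assert c == pytest.approx(1.0)

    def test_edgeless(self):
        c, per_node = clustering_coefficient(GraphView(np.zeros((4, 4), int)))
        assert c == 0.0 and not per_node.any()

    def test_low_degree_nodes_contribute_zero(self):
        w = np.zeros((3, 3), dtype=int)
        w[1, 0] = 1  # nodes 0 and 1 have a single neighbor, node 2 none
        _, per_node = clustering_coefficient(GraphView(w))
        assert not per_node.any()

    def test_random_weighted_digraphs_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            w = random_digraph(rng, 6)
            _, per_node = clustering_coefficient(GraphView(w))
            assert np.allclose(per_node, fagiolo_oracle(w))

    def test_subset_mean(self):
        w = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        c, _ = clustering_coefficient(GraphView(w), subset=[0])
        assert c == pytest.approx(1.0)


class TestBetweenness:
    def test_two_hop_path(self):
        w = np.zeros((3, 3), dtype=int)
        w[1, 0] = 1
        w[2, 1] = 1
        bc = betweenness(GraphView(w))
        assert bc == pytest.approx([0.0, 1.0, 0.0])

    def test_isolated_node(self):
        w = np.zeros((4, 4), dtype=int)
        w[1, 0] = w[2, 1] = 1
        assert betweenness(GraphView(w))[3] == 0.0

    def test_equal_length_paths_share_weight(self):
        # two parallel 2-hop routes of identical length 1: each carries 1/2
        w = np.zeros((4, 4), dtype=int)
        w[1, 0] = w[3, 1] = 2  # 0 -> 1 -> 3, length 1/2 + 1/2
        w[2, 0] = w[3, 2] = 2  # 0 -> 2 -> 3
        bc = betweenness(GraphView(w))
        assert bc[1] == pytest.approx(0.5)
        assert bc[2] == pytest.approx(0.5)

    def test_tie_detection_across_float_noise(self):
        # 1/3 + 1/6 and 1/2 differ by one ulp in floating arithmetic but
        # are a genuine tie; both routes must carry half the dependency.
        w = np.zeros((4, 4), dtype=int)
        w[1, 0] = 3
        w[3, 1] = 6  # route via 1: 1/3 + 1/6
        w[3, 0] = 2  # direct: 1/2
        bc = betweenness(GraphView(w))
        assert bc[1] == pytest.approx(0.5)

    def test_exhaustive_three_node_oracle(self):
        for w in all_small_digraphs(3):
            assert np.allclose(betweenness(GraphView(w)), betweenness_oracle(w))

    @pytest.mark.parametrize("n,trials", [(4, 40), (5, 25)])
    def test_random_digraphs_match_exact_oracle(self, n, trials):
        rng = np.random.default_rng(n * 100)
        for _ in range(trials):
            w = random_digraph(rng, n)
            assert np.allclose(betweenness(GraphView(w)), betweenness_oracle(w))

    def test_matches_networkx_on_unit_weights(self):
        """Cross-check against the independent networkx implementation on
        binary graphs (integral lengths: no tie-tolerance subtleties)."""
        rng = np.random.default_rng(99)
        for _ in range(20):
            w = random_digraph(rng, 8, max_w=1, density=0.3)
            g = nx.from_numpy_array(w.T, create_using=nx.DiGraph)
            expected = nx.betweenness_centrality(g, normalized=False, weight="weight")
            bc = betweenness(GraphView(w))
            assert np.allclose(bc, [expected[i] for i in range(8)])

    def test_summary_regions(self):
        w = np.zeros((3, 3), dtype=int)
        w[1, 0] = w[2, 1] = 1
        s = betweenness_summary(GraphView(w, lpz=np.array([True, False, False])))
        assert s["bc_global"] == pytest.approx(1.0)
        assert s["bc_lpz_mean"] == 0.0
        assert s["bc_intact_mean"] == pytest.approx(0.5)


class TestEfficiency:
    def test_triangle_local_efficiency(self):
        w = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        e, per_node = local_efficiency(GraphView(w))
        assert per_node == pytest.approx([1.0, 1.0, 1.0])

    def test_star_center_zero(self):
        w = np.zeros((4, 4), dtype=int)
        for leaf in (1, 2, 3):
            w[leaf, 0] = 1
            w[0, leaf] = 1
        _, per_node = local_efficiency(GraphView(w))
        assert per_node[0] == 0.0  # leaves are mutually unconnected

    def test_single_neighbor_zero(self):
        w = np.zeros((2, 2), dtype=int)
        w[1, 0] = 1
        e, per_node = local_efficiency(GraphView(w))
        assert not per_node.any()

    def test_global_efficiency_pair(self):
        w = np.zeros((2, 2), dtype=int)
        w[1, 0] = w[0, 1] = 1
        e, _ = global_efficiency(GraphView(w))
        assert e == 1.0

    def test_disconnected_pairs_add_zero(self):
        w = np.zeros((3, 3), dtype=int)
        w[1, 0] = 1  # only 0 -> 1
        e, per_node = global_efficiency(GraphView(w))
        assert per_node[0] == pytest.approx(0.5)  # reaches 1 of 2 others
        assert per_node[1] == 0.0

    def test_single_node(self):
        e, per_node = global_efficiency(GraphView(np.zeros((1, 1), int)))
        assert e == 0.0

    def test_random_digraphs_match_oracles(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            w = random_digraph(rng, 6)
            loc_o, glob_o = efficiency_oracles(w)
            _, loc = local_efficiency(GraphView(w))
            _, glob = global_efficiency(GraphView(w))
            assert np.allclose(loc, loc_o)
            assert np.allclose(glob, glob_o)


class TestErNullAndSmallWorld:
    def test_synapse_count_conserved(self):
        rng = np.random.default_rng(0)
        # conservation is structural: every draw places all synapses
        null = er_null(10, 57, replicates=3, rng=rng)
        assert null["c_rand"] >= 0.0

    def test_zero_synapses(self):
        null = er_null(5, 0, replicates=2, rng=np.random.default_rng(0))
        assert null["c_rand"] == 0.0
        assert math.isnan(null["l_rand"])

    def test_small_world_arithmetic(self):
        gamma, lam, s = small_world(0.4, 2.0, 0.2, 2.0)
        assert gamma == pytest.approx(2.0)
        assert lam == pytest.approx(1.0)
        assert s == pytest.approx(2.0)

    def test_small_world_undefined_flags(self):
        gamma, lam, s = small_world(0.4, 2.0, 0.0, 2.0)
        assert math.isnan(gamma) and math.isnan(s)

    def test_multiplicity_conservation_in_null(self):
        # construct one replicate by hand through the same sampling rule
        rng = np.random.default_rng(1)
        n, m = 8, 33
        counts = rng.multinomial(m, np.full(n * (n - 1), 1.0 / (n * (n - 1))))
        assert counts.sum() == m


class TestDegreeDistributions:
    def test_edgeless_all_mass_at_zero(self):
        view = GraphView(np.zeros((5, 5), int))
        hists = degree_distributions(view, bins=4)
        counts, edges = hists["in_all"]
        assert counts[0] == 5 and counts[1:].sum() == 0

    def test_multiplicity_weighted_degrees(self):
        w = np.zeros((3, 3), dtype=int)
        w[2, 1] = 3
        in_deg = w.sum(axis=1)
        out_deg = w.sum(axis=0)
        assert out_deg[1] == 3 and in_deg[2] == 3
        assert in_deg.sum() == out_deg.sum() == w.sum()

    def test_regions_share_bin_edges(self):
        rng = np.random.default_rng(2)
        w = random_digraph(rng, 10)
        lpz = np.zeros(10, bool)
        lpz[:4] = True
        hists = degree_distributions(GraphView(w, lpz=lpz), bins=6)
        assert np.array_equal(hists["in_lpz"][1], hists["out_intact"][1])
        assert hists["in_lpz"][0].sum() == 4
        assert hists["in_intact"][0].sum() == 6


class TestScaleInvariance:
    def test_uniform_weight_scaling_preserves_bc_and_clustering(self):
        rng = np.random.default_rng(21)
        w = random_digraph(rng, 8)
        bc1 = betweenness(GraphView(w))
        bc3 = betweenness(GraphView(3 * w))
        assert np.allclose(bc1, bc3)  # same shortest-path structure
        c1 = clustering_coefficient(GraphView(w))[1]
        c3 = clustering_coefficient(GraphView(3 * w))[1]
        assert np.allclose(c1, c3)  # weights are max-normalized


class TestTopologyRecord:
    def test_battery_keys_and_consistency(self):
        rng = np.random.default_rng(3)
        w = random_digraph(rng, 12, density=0.5)
        lpz = np.zeros(12, bool)
        lpz[:5] = True
        rec = topology_record(GraphView(w, lpz=lpz), np.random.default_rng(0), er_replicates=4)
        for key in ("l", "c", "gamma", "lambda", "s", "bc_global",
                    "e_glob", "e_loc", "l_intact_to_lpz", "c_lpz"):
            assert key in rec
        assert rec["s"] == pytest.approx(rec["gamma"] / rec["lambda"])
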