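"""Weighted directed graph measures on the excitatory connectome.

All measures operate on the excitatory-to-excitatory multiplicity matrix
``W`` (``W[i, j]`` synapses from j to i) with edge *length* defined as the
inverse multiplicity 1/W: strong connections are short.  Small-worldness
is normalized against Erdos-Renyi null graphs with the same number of
nodes and synapses (synapses placed uniformly over ordered non-self pairs,
multiplicities preserved).

Betweenness centrality uses Brandes' algorithm for weighted directed
graphs with equal-length path multiplicities detected at a relative
tolerance of 1e-12 (lengths are ratios of small integers, so ties are
genuine and would be missed by exact float comparison).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

#: relative tolerance for detecting equal-length shortest paths
TIE_RTOL = 1e-12


@dataclass
class GraphView:
    """Excitatory subgraph with optional LPZ/intact node partition."""

    w: np.ndarray  # (n, n) non-negative int, W[i, j] = multiplicity j -> i
    lpz: np.ndarray | None = None  # bool mask over nodes

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ValueError("W must be square")
        if np.any(self.w < 0):
            raise ValueError("multiplicities must be non-negative")
        if self.lpz is not None:
            self.lpz = np.asarray(self.lpz, dtype=bool)
            if self.lpz.shape != (self.n,):
                raise ValueError("lpz mask must match the node count")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def intact(self) -> np.ndarray:
        if self.lpz is None:
            raise ValueError("no LPZ partition set")
        return ~self.lpz

    def lengths(self) -> csr_matrix:
        """Sparse matrix of edge lengths 1/W in (target, source) layout."""
        w = self.w
        rows, cols = np.nonzero(w)
        return csr_matrix(
            (1.0 / w[rows, cols], (rows, cols)), shape=w.shape, dtype=float
        )


def shortest_paths(view: GraphView, sources: np.ndarray | None = None) -> np.ndarray:
    """Directed shortest-path distances d[j, i] from source j to target i.

    Dijkstra over edge lengths 1/W; unreachable pairs are +inf and the
    diagonal is 0.  ``sources`` restricts the rows (default: all nodes).
    """
    # lengths() stores entry (i, j) = length of edge j -> i, so paths that
    # *follow* edge direction traverse the transpose.
    graph = view.lengths().T.tocsr()
    indices = None if sources is None else np.asarray(sources)
    return _dijkstra(graph, directed=True, indices=indices)


def characteristic_path_length(
    view: GraphView,
    from_set: np.ndarray | None = None,
    to_set: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mean finite shortest-path distance over ordered (from, to) pairs.

    Returns ``(L, unreachable_fraction)``; pairs with i == j are excluded,
    unreachable pairs are excluded from the mean but reported as a
    fraction.  If every pair is unreachable, L is nan (undefined flag).
    """
    n = view.n
    from_idx = np.arange(n) if from_set is None else np.asarray(from_set)
    to_idx = np.arange(n) if to_set is None else np.asarray(to_set)
    if from_idx.size == 0 or to_idx.size == 0:
        raise ValueError("node sets must be non-empty")
    d = shortest_paths(view, sources=from_idx)[:, to_idx]
    same = from_idx[:, None] == to_idx[None, :]
    vals = d[~same]
    if vals.size == 0:
        return math.nan, 0.0
    finite = np.isfinite(vals)
    frac_unreachable = float(1.0 - finite.mean())
    if not finite.any():
        return math.nan, 1.0
    return float(vals[finite].mean()), frac_unreachable


def clustering_coefficient(
    view: GraphView, subset: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Weighted directed clustering after Fagiolo.

    Weights are normalized by the maximum weight and cube-rooted; the
    per-node coefficient is the ratio of the weighted directed triangle
    intensity around the node to the number of possible directed triangles
    ``d_tot (d_tot - 1) - 2 d_reciprocal``.  Nodes with fewer than two
    neighbors contribute 0.  Returns (mean over subset, per-node values);
    note the subset restricts the averaging only — triangles always use
    the full graph.
    """
    w = view.w.astype(float)
    n = view.n
    per_node = np.zeros(n)
    if w.max() > 0:
        a = (w > 0).astype(float)
        w_hat = np.cbrt(w / w.max())
        s = w_hat + w_hat.T
        numer = np.einsum("ij,jk,ki->i", s, s, s) / 2.0
        d_tot = (a + a.T).sum(axis=1)
        d_recip = (a * a.T).sum(axis=1)
        denom = d_tot * (d_tot - 1.0) - 2.0 * d_recip
        valid = denom > 0
        per_node[valid] = numer[valid] / denom[valid]
    idx = np.arange(n) if subset is None else np.asarray(subset)
    return float(per_node[idx].mean()), per_node


def er_null(
    n_nodes: int,
    n_synapses: int,
    replicates: int,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Clustering and path length of Erdos-Renyi multiplicity null graphs.

    Places ``n_synapses`` indistinguishable synapses uniformly over the
    ordered non-self pairs (multiplicities allowed) and evaluates C and L
    per replicate.  Returns means and standard deviations; ``l_rand`` is
    nan if L was undefined in every replicate.
    """
    if n_synapses < 0:
        raise ValueError("n_synapses must be non-negative")
    cs, ls = [], []
    n_pairs = n_nodes * (n_nodes - 1)
    off_diag = ~np.eye(n_nodes, dtype=bool)
    for _ in range(replicates):
        w = np.zeros((n_nodes, n_nodes), dtype=np.int64)
        if n_synapses > 0:
            counts = rng.multinomial(n_synapses, np.full(n_pairs, 1.0 / n_pairs))
            w[off_diag] = counts
        g = GraphView(w)
        c, _ = clustering_coefficient(g)
        length, _ = characteristic_path_length(g)
        cs.append(c)
        ls.append(length)
    ls_arr = np.asarray(ls)
    finite = np.isfinite(ls_arr)
    return {
        "c_rand": float(np.mean(cs)),
        "c_rand_sd": float(np.std(cs)),
        "l_rand": float(ls_arr[finite].mean()) if finite.any() else math.nan,
        "l_rand_sd": float(ls_arr[finite].std()) if finite.any() else math.nan,
    }


def small_world(
    c: float, length: float, c_rand: float, l_rand: float
) -> tuple[float, float, float]:
    """Normalized clustering gamma, path length lambda, small-worldness S.

    ``S = gamma / lambda = (C / C_rand) / (L / L_rand)``; any zero or
    undefined denominator yields nan flags rather than an exception.
    """
    gamma = c / c_rand if c_rand and np.isfinite(c_rand) else math.nan
    lam = length / l_rand if l_rand and np.isfinite(l_rand) else math.nan
    s = gamma / lam if lam and np.isfinite(lam) and np.isfinite(gamma) else math.nan
    return gamma, lam, s


def betweenness(view: GraphView) -> np.ndarray:
    """Per-node betweenness centrality, Brandes' algorithm.

    Directed shortest paths over lengths 1/W; endpoints are excluded, no
    normalization — the value of node i is the sum over ordered pairs
    (k, l), k != i != l, of the fraction of shortest k -> l paths through
    i.  Equal-length alternatives are counted as multiplicities using a
    relative tie tolerance (:data:`TIE_RTOL`).
    """
    n = view.n
    w = view.w
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    src, dst = np.nonzero(w.T)  # follow edge direction j -> i
    for j, i in zip(src.tolist(), dst.tolist()):
        adj[j].append((i, 1.0 / w[i, j]))

    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        preds: list[list[int]] = [[] for _ in range(n)]
        dist[s] = 0.0
        sigma[s] = 1.0
        visited = np.zeros(n, dtype=bool)
        order: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            d_v, v = heapq.heappop(heap)
            if visited[v]:
                continue
            visited[v] = True
            order.append(v)
            d_v = dist[v]
            for t, length in adj[v]:
                if visited[t]:
                    continue
                d_new = d_v + length
                if not np.isfinite(dist[t]):
                    dist[t] = d_new
                    sigma[t] = sigma[v]
                    preds[t] = [v]
                    heapq.heappush(heap, (d_new, t))
                    continue
                tol = TIE_RTOL * max(abs(d_new), abs(dist[t]))
                if d_new < dist[t] - tol:
                    dist[t] = d_new
                    sigma[t] = sigma[v]
                    preds[t] = [v]
                    heapq.heappush(heap, (d_new, t))
                elif abs(d_new - dist[t]) <= tol:
                    sigma[t] += sigma[v]
                    preds[t].append(v)
        delta = np.zeros(n)
        for v in reversed(order):
            for p in preds[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    return bc


def betweenness_summary(view: GraphView) -> dict[str, float]:
    """Global sum and (if partitioned) per-region means of betweenness."""
    bc = betweenness(view)
    out = {"bc_global": float(bc.sum())}
    if view.lpz is not None:
        out["bc_lpz_mean"] = float(bc[view.lpz].mean()) if view.lpz.any() else math.nan
        out["bc_intact_mean"] = (
            float(bc[view.intact].mean()) if view.intact.any() else math.nan
        )
    return out


def local_efficiency(view: GraphView) -> tuple[float, np.ndarray]:
    """Mean inverse distance among each node's neighbors, node excluded.

    Neighbors of i are nodes connected to i in either direction; distances
    are shortest paths (lengths 1/W) on the subgraph induced by the
    neighbors with i removed, so routes through i itself never count.
    Nodes with fewer than two neighbors score 0.  Returns (mean, per-node).
    """
    w = view.w
    n = view.n
    a = (w > 0) | (w.T > 0)
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            continue
        sub = GraphView(w[np.ix_(nbrs, nbrs)])
        d = shortest_paths(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        np.fill_diagonal(inv, 0.0)
        per_node[i] = inv.sum() / (k * (k - 1))
    return float(per_node.mean()), per_node


def global_efficiency(
    view: GraphView, subset: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean inverse shortest-path distance, 1/inf counted as zero.

    Per-node efficiency is the mean of 1/d(i -> j) over all other nodes j
    of the full graph; the reported scalar averages per-node efficiencies
    over ``subset`` (default: all nodes).  Disconnected pairs add zero, so
    the measure is defined for arbitrary graphs.  Returns
    (mean over subset, per-node values).
    """
    n = view.n
    if n < 2:
        return 0.0, np.zeros(n)
    d = shortest_paths(view)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    per_node = inv.sum(axis=1) / (n - 1)
    idx = np.arange(n) if subset is None else np.asarray(subset)
    return float(per_node[idx].mean()), per_node


def degree_distributions(
    view: GraphView,
    bins: int | np.ndarray = 20,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Multiplicity-weighted in/out-degree histograms per region.

    In-degree of i is the total multiplicity of its afferents (row sum),
    out-degree the total multiplicity of its efferents (column sum).  All
    histograms share bin edges so regions and time points are comparable.
    Returns ``{key: (counts, edges)}`` with keys like ``'in_lpz'``; when no
    partition is set the keys are ``'in_all'``/``'out_all'``.
    """
    in_deg = view.w.sum(axis=1)
    out_deg = view.w.sum(axis=0)
    both = np.concatenate([in_deg, out_deg])
    edges = np.histogram_bin_edges(both, bins=bins, range=(0, max(both.max(), 1)))
    regions: dict[str, np.ndarray]
    if view.lpz is None:
        regions = {"all": np.arange(view.n)}
    else:
        regions = {"lpz": np.flatnonzero(view.lpz), "intact": np.flatnonzero(view.intact)}
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, idx in regions.items():
        out[f"in_{name}"] = (np.histogram(in_deg[idx], bins=edges)[0], edges)
        out[f"out_{name}"] = (np.histogram(out_deg[idx], bins=edges)[0], edges)
    return out


def topology_record(
    view: GraphView,
    rng: np.random.Generator,
    er_replicates: int = 10,
) -> dict[str, float]:
    """The full measurement battery for one connectome snapshot.

    Whole-network L, C, gamma, lambda, S (Erdos-Renyi normalized),
    betweenness (global sum and region means), efficiencies, and — when an
    LPZ partition is present — region-restricted path lengths and region
    means of clustering and efficiency.
    """
    out: dict[str, float] = {}
    length, frac = characteristic_path_length(view)
    c, c_nodes = clustering_coefficient(view)
    out["l"] = length
    out["l_unreachable_frac"] = frac
    out["c"] = c
    null = er_null(view.n, int(view.w.sum()), er_replicates, rng)
    out.update(null)
    gamma, lam, s = small_world(c, length, null["c_rand"], null["l_rand"])
    out["gamma"], out["lambda"], out["s"] = gamma, lam, s
    out.update(betweenness_summary(view))
    e_glob, eg_nodes = global_efficiency(view)
    e_loc, el_nodes = local_efficiency(view)
    out["e_glob"] = e_glob
    out["e_loc"] = e_loc
    if view.lpz is not None and view.lpz.any() and view.intact.any():
        lpz = np.flatnonzero(view.lpz)
        intact = np.flatnonzero(view.intact)
        out["l_intact_to_lpz"], out["l_intact_to_lpz_unreachable"] = (
            characteristic_path_length(view, intact, lpz)
        )
        out["l_lpz_to_intact"], out["l_lpz_to_intact_unreachable"] = (
            characteristic_path_length(view, lpz, intact)
        )
        out["c_lpz"] = float(c_nodes[view.lpz].mean())
        out["c_intact"] = float(c_nodes[view.intact].mean())
        out["e_glob_lpz"] = float(eg_nodes[view.lpz].mean())
        out["e_glob_intact"] = float(eg_nodes[view.intact].mean())
        out["e_loc_lpz"] = float(el_nodes[view.lpz].mean())
        out["e_loc_intact"] = float(el_nodes[view.intact].mean())
    return out
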