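"""Graph statistics for hyper-brain networks.

Strengths with intra/inter-brain decomposition, clustering coefficient
(binary / weighted / directed variants), characteristic path length,
degree-preserving random and lattice null models, and the small-world
coefficients sigma and omega.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .signals import FREQUENCY_BANDS, REGION_MAP
from .thresholding import HyperBrainGraph

__all__ = [
    "NodeStrengths",
    "SmallWorldStats",
    "strengths",
    "clustering_coefficient",
    "characteristic_path_length",
    "null_models",
    "small_worldness",
    "collapse_bands",
    "collapse_regions",
    "collapse_bands_and_regions",
]


@dataclass
class NodeStrengths:
    """Per-node strength sums, split into within- and between-brain parts.

    Every array has shape ``(n_nodes,)``; the decomposition satisfies
    ``intra + inter == total`` exactly, component-wise.
    """

    in_strength: np.ndarray
    out_strength: np.ndarray
    total: np.ndarray
    intra: np.ndarray
    inter: np.ndarray
    channels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": self.channels,
            "in_strength": self.in_strength,
            "out_strength": self.out_strength,
            "total": self.total,
            "intra": self.intra,
            "inter": self.inter,
        })


@dataclass
class SmallWorldStats:
    cc: float
    cpl: float
    cc_rand: float
    cpl_rand: float
    cc_latt: float
    cpl_latt: float

    @property
    def gamma(self) -> float:
        return self.cc / self.cc_rand

    @property
    def lam(self) -> float:
        return self.cpl / self.cpl_rand

    @property
    def sigma(self) -> float:
        return self.gamma / self.lam

    @property
    def omega(self) -> float:
        value = self.cpl_rand / self.cpl - self.cc / self.cc_latt
        if not (-1.0 <= value <= 1.0):
            warnings.warn(f"omega {value:.3f} outside [-1, 1]; clamped",
                          stacklevel=2)
            value = float(np.clip(value, -1.0, 1.0))
        return value


def strengths(g: HyperBrainGraph) -> NodeStrengths:
    """In-, out- and total strengths per node, with the intra-brain part
    computed on the within-brain blocks and inter = total - intra."""
    w = g.weights
    out_s = w.sum(axis=1)
    in_s = w.sum(axis=0)
    total = in_s + out_s
    intra_w = np.where(g.intra_mask(), w, 0.0)
    intra = intra_w.sum(axis=1) + intra_w.sum(axis=0)
    return NodeStrengths(in_strength=in_s, out_strength=out_s, total=total,
                         intra=intra, inter=total - intra,
                         channels=list(g.channels))


def _normalized_weights(w: np.ndarray) -> np.ndarray:
    mx = w.max()
    return w / mx if mx > 0 else w


def clustering_coefficient(
    g: HyperBrainGraph, mode: str = "binary"
) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean.

    ``binary``   - fraction of closed neighbor pairs, 2t_i / (k_i (k_i-1)).
    ``weighted`` - geometric-mean triangle intensity on weights normalized
                   by the maximum weight (undirected).
    ``directed`` - directed triangle variant counting all triangle
                   orientations, t_i = ((W^ + W^T)^(1/3) cubed)_ii / 2 with
                   denominator k_tot (k_tot - 1) - 2 k_bidirectional.

    Nodes whose denominator vanishes (degree < 2) get C_i = 0.
    """
    if g.n_nodes < 3:
        raise ValueError("clustering requires at least 3 nodes")
    a = g.adjacency
    if mode == "binary":
        a_sym = np.maximum(a, a.T) if g.directed else a
        k = a_sym.sum(axis=1)
        t = np.diagonal(a_sym @ a_sym @ a_sym) / 2.0
        denom = k * (k - 1) / 2.0
    elif mode == "weighted":
        w = _normalized_weights(g.weights)
        w_sym = np.maximum(w, w.T) if g.directed else w
        cw = np.cbrt(w_sym)
        k = (w_sym > 0).sum(axis=1)
        t = np.diagonal(cw @ cw @ cw) / 2.0
        denom = k * (k - 1) / 2.0
    elif mode == "directed":
        w = _normalized_weights(g.weights)
        cw = np.cbrt(w)
        s = cw + cw.T
        t = np.diagonal(s @ s @ s) / 2.0
        k_tot = (a.sum(axis=1) + a.sum(axis=0))
        k_bidir = np.diagonal(a @ a)
        denom = k_tot * (k_tot - 1) - 2.0 * k_bidir
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, t / denom, 0.0)
    return c, float(c.mean())


def characteristic_path_length(
    g: HyperBrainGraph,
    weighted: bool = False,
    unreachable: str = "exclude",
) -> float:
    """Mean shortest-path length over ordered reachable node pairs.

    Weighted paths use length = 1/weight.  ``unreachable`` is either
    ``"exclude"`` (drop those pairs from the mean, default) or
    ``"harmonic"`` (return the harmonic-mean distance, i.e. the inverse
    of global efficiency, where unreachable pairs contribute 0).
    """
    if g.n_nodes < 2:
        warnings.warn("CPL undefined for graphs with < 2 nodes", stacklevel=2)
        return float("nan")
    if weighted:
        with np.errstate(divide="ignore"):
            lengths = np.where(g.weights > 0, 1.0 / g.weights, 0.0)
        dist = shortest_path(lengths, method="D", directed=g.directed)
    else:
        dist = shortest_path(g.adjacency, method="D", directed=g.directed,
                             unweighted=True)
    off = ~np.eye(g.n_nodes, dtype=bool)
    d = dist[off]
    if unreachable == "harmonic":
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        eff = inv.mean()
        return float(1.0 / eff) if eff > 0 else float("inf")
    finite = np.isfinite(d)
    if not finite.any():
        warnings.warn("no reachable pairs; CPL undefined", stacklevel=2)
        return float("nan")
    n_unreachable = int((~finite).sum())
    if n_unreachable:
        warnings.warn(f"{n_unreachable} unreachable ordered pairs excluded "
                      "from CPL", stacklevel=2)
    return float(d[finite].mean())


def _edge_list(g: HyperBrainGraph) -> list[tuple[int, int]]:
    rows, cols = np.nonzero(g.weights)
    if g.directed:
        return [(int(i), int(j)) for i, j in zip(rows, cols)]
    return [(int(i), int(j)) for i, j in zip(rows, cols) if i < j]


def _graph_from_edges(g: HyperBrainGraph,
                      edges: list[tuple[int, int]],
                      edge_weights: list[float]) -> HyperBrainGraph:
    w = np.zeros_like(g.weights)
    for (i, j), wt in zip(edges, edge_weights):
        w[i, j] = wt
        if not g.directed:
            w[j, i] = wt
    return HyperBrainGraph(weights=w, directed=g.directed,
                           channels=list(g.channels),
                           brains=None if g.brains is None else list(g.brains),
                           measure=g.measure, foi=g.foi, threshold=g.threshold)


def _rewire(edges: list[tuple[int, int]], weights: list[float],
            directed: bool, rng: np.random.Generator,
            n_attempts: int,
            cost: np.ndarray | None = None) -> tuple[list, list]:
    """Degree-preserving double-edge swaps.

    When ``cost`` is given (node-distance matrix), a swap is accepted
    only if it does not increase the summed edge cost (greedy
    latticization); otherwise every feasible swap is accepted.
    """
    edges = list(edges)
    weights = list(weights)
    present = set(edges)
    if not directed:
        present |= {(j, i) for i, j in edges}
    n_edges = len(edges)
    if n_edges < 2:
        warnings.warn("too few edges to rewire; returning copies",
                      stacklevel=3)
        return edges, weights
    stall = 0
    stall_limit = 50 * n_edges if cost is not None else n_attempts + 1
    for _ in range(n_attempts):
        if stall >= stall_limit:
            break
        stall += 1
        e1, e2 = rng.integers(0, n_edges, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if not directed and rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if len({a, b, c, d}) < 4:
            continue
        new1, new2 = (a, d), (c, b)
        if new1 in present or new2 in present:
            continue
        if not directed and ((d, a) in present or (b, c) in present):
            continue
        if cost is not None:
            old = cost[a, b] + cost[c, d]
            new = cost[a, d] + cost[c, b]
            if new > old:
                continue
            if new < old:
                stall = 0
        for old_e in (edges[e1], edges[e2]):
            present.discard(old_e)
            if not directed:
                present.discard((old_e[1], old_e[0]))
        edges[e1], edges[e2] = new1, new2
        present.add(new1)
        present.add(new2)
        if not directed:
            present.add((new1[1], new1[0]))
            present.add((new2[1], new2[0]))
    return edges, weights


def null_models(
    g: HyperBrainGraph,
    kind: str = "random",
    n: int = 20,
    seed: int = 0,
    swap_factor: int = 10,
    lattice_factor: int = 1000,
) -> list[HyperBrainGraph]:
    """Generate ``n`` degree-sequence-preserving null graphs.

    ``random``  - Maslov-Sneppen double-edge swaps (about
    ``swap_factor * n_edges`` accepted-or-attempted swaps).
    ``lattice`` - the same randomization followed by greedy swaps that
    only ever reduce the total node-index distance of the edges, pushing
    them toward the main diagonal.

    Edge weights travel with the swapped edges, so the binary degree
    sequence is preserved exactly; strength sequences are not.
    """
    if kind not in ("random", "lattice"):
        raise ValueError(f"unknown null kind {kind!r}")
    edges = _edge_list(g)
    if not edges:
        raise ValueError("cannot build null models for an edgeless graph")
    base_weights = [float(g.weights[i, j]) for i, j in edges]
    idx = np.arange(g.n_nodes)
    cost = np.abs(idx[:, None] - idx[None, :]).astype(float)
    out = []
    master = np.random.default_rng(seed)
    for _ in range(n):
        rng = np.random.default_rng(master.integers(0, 2 ** 63))
        e, w = _rewire(edges, base_weights, g.directed, rng,
                       n_attempts=swap_factor * len(edges))
        if kind == "lattice":
            e, w = _rewire(e, w, g.directed, rng,
                           n_attempts=lattice_factor * len(edges), cost=cost)
        out.append(_graph_from_edges(g, e, w))
    return out


def small_worldness(
    g: HyperBrainGraph,
    n_null: int = 20,
    seed: int = 0,
    weighted: bool = False,
) -> SmallWorldStats:
    """Small-world coefficients against random and lattice nulls.

    sigma = (CC/CC_rand) / (CPL/CPL_rand); omega = CPL_rand/CPL - CC/CC_latt.
    CC and CPL default to the binary variants (directed-aware); the null
    means are taken over ``n_null`` seeded realizations of each kind.
    """
    cc_mode = "weighted" if weighted else "binary"
    if g.directed:
        cc_mode = "directed" if weighted else "binary"
    _, cc = clustering_coefficient(g, mode=cc_mode)
    cpl = characteristic_path_length(g, weighted=weighted)
    rand = null_models(g, "random", n=n_null, seed=seed)
    latt = null_models(g, "lattice", n=n_null, seed=seed + 1)
    cc_rand = float(np.mean([clustering_coefficient(h, cc_mode)[1] for h in rand]))
    cpl_rand = float(np.mean([characteristic_path_length(h, weighted=weighted)
                              for h in rand]))
    cc_latt = float(np.mean([clustering_coefficient(h, cc_mode)[1] for h in latt]))
    cpl_latt = float(np.mean([characteristic_path_length(h, weighted=weighted)
                              for h in latt]))
    if cc_rand == 0 or cc_latt == 0:
        raise ValueError(
            "degenerate null models (zero clustering); the graph is too "
            f"sparse for small-world statistics (edges={g.n_edges})"
        )
    return SmallWorldStats(cc=cc, cpl=cpl, cc_rand=cc_rand, cpl_rand=cpl_rand,
                           cc_latt=cc_latt, cpl_latt=cpl_latt)


def collapse_bands(values: np.ndarray, fois: tuple[float, ...],
                   bands: dict[str, tuple[float, float]] | None = None,
                   ) -> dict[str, np.ndarray]:
    """Mean of per-FOI values over each frequency band.

    ``values`` has the FOI axis first; FOIs falling outside every band
    are excluded with a warning.
    """
    bands = bands or dict(FREQUENCY_BANDS)
    values = np.asarray(values)
    out: dict[str, np.ndarray] = {}
    assigned = np.zeros(len(fois), dtype=bool)
    for name, (lo, hi) in bands.items():
        mask = np.array([lo <= f <= hi for f in fois])
        assigned |= mask
        if mask.any():
            out[name] = values[mask].mean(axis=0)
    orphans = [f for f, a in zip(fois, assigned) if not a]
    if orphans:
        warnings.warn(f"FOIs outside all bands excluded: {orphans}",
                      stacklevel=2)
    return out


def collapse_regions(values: np.ndarray, channels: list[str],
                     regions: dict[str, str] | None = None,
                     ) -> dict[str, np.ndarray]:
    """Mean of per-channel values over each scalp region.

    Channel labels may carry a brain prefix (``"A:Fz"``); the prefix is
    stripped before the region lookup and the means pool both brains.
    """
    regions = regions or dict(REGION_MAP)
    values = np.asarray(values)
    bare = [c.split(":", 1)[-1] for c in channels]
    out: dict[str, np.ndarray] = {}
    for region in sorted(set(regions.values())):
        mask = np.array([regions.get(b) == region for b in bare])
        if mask.any():
            out[region] = values[mask].mean(axis=0)
    return out


def collapse_bands_and_regions(
    values: np.ndarray,
    fois: tuple[float, ...],
    channels: list[str],
    bands: dict[str, tuple[float, float]] | None = None,
    regions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Band x region summary of a ``(n_fois, n_channels)`` metric table."""
    per_band = collapse_bands(values, fois, bands)
    rows = {}
    for band, vec in per_band.items():
        rows[band] = collapse_regions(vec, channels, regions)
    return pd.DataFrame(rows).T  # bands as rows, regions as columns
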