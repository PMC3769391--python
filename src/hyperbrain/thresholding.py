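"""Surrogate-based significance thresholds and graph sparsification.

Surrogate data are produced by shuffling samples within each epoch and
channel, processed through the identical spectral/coupling chain, and
pooled per measure and FOI.  The threshold is the bootstrap mean of the
pooled surrogate values plus the one-sided (1 - alpha) confidence
half-width of the bootstrap-mean distribution; only coupling values
strictly larger than the threshold become edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coupling import (DIRECTED_MEASURES, MEASURES, CouplingMatrices,
                       connectivity_matrices)
from .signals import EpochedSignals
from .spectral import WaveletParams
from .synthetic import shuffle_surrogate

__all__ = ["SurrogateEnsemble", "ThresholdSet", "HyperBrainGraph",
           "surrogate_distribution", "estimate_threshold", "apply_threshold"]


@dataclass
class SurrogateEnsemble:
    """Pooled surrogate coupling values, per measure and FOI.

    ``values[measure]`` has shape ``(n_fois, n_pooled)`` where the pool
    runs over all ordered off-diagonal pairs and all epochs.
    """

    values: dict[str, np.ndarray]
    fois: tuple[float, ...]
    n_surrogate_epochs: int
    seed: int


@dataclass
class ThresholdSet:
    """One threshold per measure and FOI."""

    thresholds: dict[str, np.ndarray]  # measure -> (n_fois,)
    fois: tuple[float, ...]
    alpha: float = 0.0001
    n_bootstrap: int = 1000
    seed: int = 0
    method: str = "ci_of_mean"  # or "percentile"

    def get(self, measure: str, foi: float) -> float:
        return float(self.thresholds[measure][self.fois.index(foi)])


@dataclass
class HyperBrainGraph:
    """Thresholded hyper-brain graph (weighted + binarized adjacency).

    ``weights[i, j]`` is the retained coupling value for the edge
    ``i -> j`` (directed measures) or the undirected edge {i, j}
    (symmetric weights).  No self-loops.
    """

    weights: np.ndarray
    directed: bool
    channels: list[str]
    brains: list[str] | None = None
    measure: str = ""
    foi: float = 0.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be a square matrix")
        np.fill_diagonal(self.weights, 0.0)
        if not self.directed and not np.allclose(self.weights, self.weights.T):
            raise ValueError("undirected graph requires symmetric weights")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        """Binarized adjacency (weights > 0)."""
        return (self.weights > 0).astype(float)

    @property
    def n_edges(self) -> int:
        a = self.adjacency
        return int(a.sum()) if self.directed else int(a.sum()) // 2

    def intra_mask(self) -> np.ndarray:
        if self.brains is None:
            mask = np.ones_like(self.weights, dtype=bool)
        else:
            b = np.asarray(self.brains)
            mask = b[:, None] == b[None, :]
        np.fill_diagonal(mask, False)
        return mask

    def to_networkx(self):
        """Export as a networkx (Di)Graph with node metadata."""
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        for i, name in enumerate(self.channels):
            attrs = {"label": name}
            if self.brains is not None:
                attrs["brain"] = self.brains[i]
            g.add_node(i, **attrs)
        rows, cols = np.nonzero(self.weights)
        for i, j in zip(rows, cols):
            if not self.directed and i > j:
                continue
            g.add_edge(int(i), int(j), weight=float(self.weights[i, j]))
        return g


def surrogate_distribution(
    epochs: EpochedSignals,
    params: WaveletParams | None = None,
    seed: int = 0,
    measures: tuple[str, ...] = MEASURES,
) -> SurrogateEnsemble:
    """Shuffle the data and run the identical coupling chain, pooling the
    resulting values per measure and FOI across all pairs and epochs."""
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    surrogate = shuffle_surrogate(epochs, seed=seed)
    mats = connectivity_matrices(surrogate, params=params, measures=measures)
    n = mats.n_nodes
    off = ~np.eye(n, dtype=bool)
    pooled: dict[str, np.ndarray] = {}
    for m in measures:
        v = mats.values[m]  # (n_epochs, n_fois, N, N)
        pooled[m] = np.moveaxis(v[:, :, off], 0, 1).reshape(len(mats.fois), -1)
    return SurrogateEnsemble(values=pooled, fois=mats.fois,
                             n_surrogate_epochs=epochs.n_epochs, seed=seed)


def estimate_threshold(
    ens: SurrogateEnsemble,
    n_bootstrap: int = 1000,
    alpha: float = 0.0001,
    seed: int = 0,
    method: str = "ci_of_mean",
) -> ThresholdSet:
    """Bootstrap the surrogate pool into a per-measure/FOI threshold.

    ``ci_of_mean`` (default): draw ``n_bootstrap`` resamples of the pool,
    take each resample's mean, and set threshold = mean of the bootstrap
    means + the one-sided (1 - alpha) half-width of their distribution.
    ``percentile``: the (1 - alpha) quantile of the raw pooled values.
    """
    if method not in ("ci_of_mean", "percentile"):
        raise ValueError(f"unknown method {method!r}")
    if not ens.values:
        raise ValueError("empty surrogate ensemble")
    rng = np.random.default_rng(seed)
    thresholds: dict[str, np.ndarray] = {}
    for measure, pool in ens.values.items():
        if pool.size == 0:
            raise ValueError("empty surrogate ensemble")
        n_fois, n_vals = pool.shape
        out = np.empty(n_fois)
        for k in range(n_fois):
            if method == "percentile":
                out[k] = np.quantile(pool[k], 1.0 - alpha)
                continue
            draws = rng.integers(0, n_vals, size=(n_bootstrap, n_vals))
            bmeans = pool[k][draws].mean(axis=1)
            center = bmeans.mean()
            half_width = np.quantile(bmeans, 1.0 - alpha) - center
            out[k] = center + half_width
        thresholds[measure] = out
    return ThresholdSet(thresholds=thresholds, fois=ens.fois, alpha=alpha,
                        n_bootstrap=n_bootstrap, seed=seed, method=method)


def apply_threshold(
    matrices: CouplingMatrices,
    thresholds: ThresholdSet,
    measure: str,
    foi: float,
) -> HyperBrainGraph:
    """Sparsify one measure/FOI slice of the (epoch-averaged) coupling
    matrices into a hyper-brain graph, keeping entries strictly above the
    threshold."""
    if measure not in matrices.values:
        raise KeyError(f"measure {measure!r} not present in matrices")
    if measure not in thresholds.thresholds:
        raise KeyError(f"measure {measure!r} not present in thresholds")
    if foi not in matrices.fois:
        raise KeyError(f"FOI {foi} not present in matrices")
    if foi not in thresholds.fois:
        raise KeyError(f"FOI {foi} not present in thresholds")
    mats = matrices.mean_over_epochs()
    w = mats.values[measure][mats.fois.index(foi)].copy()
    thr = thresholds.get(measure, foi)
    w[w <= thr] = 0.0
    np.fill_diagonal(w, 0.0)
    directed = measure in DIRECTED_MEASURES
    if not directed:
        w = 0.5 * (w + w.T)  # guard against float asymmetry
    if w.sum() == 0:
        warnings.warn(
            f"threshold {thr:.4g} removed every edge for {measure}@{foi} Hz",
            stacklevel=2,
        )
    return HyperBrainGraph(weights=w, directed=directed,
                           channels=list(mats.channels),
                           brains=None if mats.brains is None
                           else list(mats.brains),
                           measure=measure, foi=foi, threshold=thr)
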