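import numpy as np
import pytest

from hyperbrain.spectral import PhaseDifferenceSeries
from hyperbrain.thresholding import HyperBrainGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_delta_series(delta: np.ndarray, foi: float = 10.0,
                      interval: float = 0.02) -> PhaseDifferenceSeries:
    """Wrap a raw angle array (n_pairs, n_epochs, n_times) into a
    single-FOI PhaseDifferenceSeries with every time point valid."""
    delta = np.asarray(delta, dtype=float)
    if delta.ndim == 1:
        delta = delta[None, None, :]
    if delta.ndim == 3:
        delta = delta[:, :, None, :]
    n_pairs = delta.shape[0]
    valid = np.ones((1, delta.shape[-1]), dtype=bool)
    return PhaseDifferenceSeries(
        delta_phi=delta, pairs=[(2 * i, 2 * i + 1) for i in range(n_pairs)],
        fois=(foi,), interval=interval, valid=valid,
        channels=[f"c{i}" for i in range(2 * n_pairs)])


def graph_from(w: np.ndarray, directed: bool = False,
               brains: list[str] | None = None) -> HyperBrainGraph:
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    return HyperBrainGraph(weights=w, directed=directed,
                           channels=[f"n{i}" for i in range(n)],
                           brains=brains)


def random_graph(n: int, density: float, rng: np.random.Generator,
                 directed: bool = False, weighted: bool = False
                 ) -> HyperBrainGraph:
    """Random test graph; weights in (0, 1] when weighted."""
    a = (rng.random((n, n)) < density).astype(float)
    np.fill_diagonal(a, 0.0)
    if not directed:
        a = np.triu(a, 1)
        a = a + a.T
    if weighted:
        w = rng.uniform(0.1, 1.0, size=(n, n))
        if not directed:
            w = np.triu(w, 1)
            w = w + w.T
        a = a * w
    return graph_from(a, directed=directed)
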