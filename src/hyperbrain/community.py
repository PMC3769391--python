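"""Modularity optimization, node roles, and hyper-brain modules.

The quality function is the weighted Newman modularity for undirected
graphs and the Leicht-Newman in/out-degree form for directed graphs.
Optimization is a seeded multi-restart greedy scheme: local node moving
from a random initial assignment until convergence, followed by greedy
community merging, keeping the best of all restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .thresholding import HyperBrainGraph

__all__ = [
    "Partition",
    "NodeRoleTable",
    "modularity",
    "optimize_partition",
    "within_module_degree",
    "participation_coefficient",
    "classify_roles",
    "hyper_brain_modules",
    "role_census",
    "ROLE_NAMES",
]

ROLE_NAMES = {
    "R1": "non-hub ultra-peripheral",
    "R2": "non-hub peripheral",
    "R3": "non-hub connector",
    "R4": "non-hub kinless",
    "R5": "hub ultra-peripheral",
    "R6": "hub peripheral",
    "R7": "hub connector",
    "R8": "hub kinless",
}

HUB_Z = 1.4
P_CUTS = (0.05, 0.5, 0.8)


@dataclass
class Partition:
    """Module assignment with its modularity value."""

    labels: np.ndarray  # module id per node, contiguous ints from 0
    modularity: float
    variant: str  # "weighted" or "directed"
    seed: int = 0
    restarts: int = 1

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def members(self, module: int) -> np.ndarray:
        return np.nonzero(self.labels == module)[0]


@dataclass
class NodeRoleTable:
    z: np.ndarray
    p: np.ndarray
    roles: list[str]
    channels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": self.channels, "Z": self.z,
                             "P": self.p, "role": self.roles})


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel modules by order of first appearance (lowest ids first)."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _quality_matrix(g: HyperBrainGraph, variant: str) -> tuple[np.ndarray, float]:
    """Modularity matrix B and normalizer so that
    M = sum_{ij in same module} B_ij / norm."""
    if variant == "weighted":
        w = g.weights if not g.directed else 0.5 * (g.weights + g.weights.T)
        two_m = w.sum()
        if two_m == 0:
            raise ValueError("graph has no edges")
        s = w.sum(axis=1)
        b = w - np.outer(s, s) / two_m
        return b, two_m
    if variant == "directed":
        a = g.adjacency
        m = a.sum()
        if m == 0:
            raise ValueError("graph has no edges")
        k_in = a.sum(axis=0)
        k_out = a.sum(axis=1)
        b = a - np.outer(k_out, k_in) / m
        return b, m
    raise ValueError(f"unknown modularity variant {variant!r}")


def modularity(g: HyperBrainGraph, labels: np.ndarray,
               variant: str | None = None) -> float:
    """Evaluate the modularity of a given module assignment."""
    if variant is None:
        variant = "directed" if g.directed else "weighted"
    b, norm = _quality_matrix(g, variant)
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return float(b[same].sum() / norm)


def _local_moving(bs: np.ndarray, labels: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Greedy node moving on the symmetrized quality matrix until stable."""
    n = bs.shape[0]
    labels = labels.copy()
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            current = labels[i]
            # gain of i joining community c: 2 * sum_{j in c, j != i} bs[i, j]
            # (+ bs[i, i], constant across choices -> ignore)
            row = bs[i].copy()
            row[i] = 0.0
            gains = np.bincount(labels, weights=row,
                                minlength=labels.max() + 2)
            best = int(np.argmax(gains))
            # moving to an empty (new) community has gain 0
            new_id = int(labels.max()) + 1
            if gains[best] < 0.0:
                best = new_id
            if best != current and gains[best] > gains[current] + 1e-15:
                labels[i] = best
                labels = _canonical(labels)
                improved = True
    return _canonical(labels)


def _merge_communities(bs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Greedily merge community pairs while modularity increases."""
    labels = _canonical(labels)
    while True:
        k = labels.max() + 1
        if k < 2:
            break
        member = [labels == c for c in range(k)]
        block = np.array([[bs[np.ix_(mi, mj)].sum() for mj in member]
                          for mi in member])
        gain = block + block.T
        np.fill_diagonal(gain, -np.inf)
        i, j = np.unravel_index(np.argmax(gain), gain.shape)
        if gain[i, j] <= 1e-15:
            break
        labels[labels == max(i, j)] = min(i, j)
        labels = _canonical(labels)
    return labels


def optimize_partition(g: HyperBrainGraph, variant: str | None = None,
                       restarts: int = 20, seed: int = 0) -> Partition:
    """Maximize modularity by seeded multi-restart greedy optimization."""
    if variant is None:
        variant = "directed" if g.directed else "weighted"
    b, norm = _quality_matrix(g, variant)
    bs = 0.5 * (b + b.T)  # symmetrized; same total quality over modules
    n = g.n_nodes
    master = np.random.default_rng(seed)
    best_labels: np.ndarray | None = None
    best_m = -np.inf
    for r in range(max(1, restarts)):
        rng = np.random.default_rng(master.integers(0, 2 ** 63))
        if r % 2 == 0:
            labels = np.arange(n)  # Louvain-style singleton start
        else:
            k = int(rng.integers(2, n + 1))
            labels = _canonical(rng.integers(0, k, size=n))
        labels = _local_moving(bs, labels, rng)
        labels = _merge_communities(bs, labels)
        labels = _local_moving(bs, labels, rng)
        m = modularity(g, labels, variant)
        if m > best_m + 1e-15:
            best_m = m
            best_labels = labels
    assert best_labels is not None
    return Partition(labels=best_labels, modularity=best_m, variant=variant,
                     seed=seed, restarts=restarts)


def _module_degrees(g: HyperBrainGraph, labels: np.ndarray) -> np.ndarray:
    """k[i, c] = number of binary links between node i and module c.

    For directed graphs both incoming and outgoing links are counted.
    """
    a = g.adjacency
    if g.directed:
        a = a + a.T  # counts reciprocal links twice, once per direction
    k = np.zeros((g.n_nodes, labels.max() + 1))
    for c in range(labels.max() + 1):
        k[:, c] = a[:, labels == c].sum(axis=1)
    return k


def within_module_degree(g: HyperBrainGraph,
                         partition: Partition) -> np.ndarray:
    """Z-score of each node's within-module degree, per module.

    Uses the population standard deviation; modules where every node has
    the same within-module degree get Z = 0 throughout.
    """
    labels = partition.labels
    if labels.shape[0] != g.n_nodes:
        raise ValueError("partition does not cover all nodes")
    k = _module_degrees(g, labels)
    k_own = k[np.arange(g.n_nodes), labels]
    z = np.zeros(g.n_nodes)
    for c in range(labels.max() + 1):
        members = labels == c
        vals = k_own[members]
        sd = vals.std()  # population sd
        if sd > 0:
            z[members] = (vals - vals.mean()) / sd
    return z


def participation_coefficient(g: HyperBrainGraph,
                              partition: Partition) -> np.ndarray:
    """P_i = 1 - sum_c (k_i(c) / k_i)^2; isolated nodes get P = 0."""
    labels = partition.labels
    if labels.shape[0] != g.n_nodes:
        raise ValueError("partition does not cover all nodes")
    k = _module_degrees(g, labels)
    k_tot = k.sum(axis=1)
    p = np.zeros(g.n_nodes)
    nonzero = k_tot > 0
    ratios = k[nonzero] / k_tot[nonzero, None]
    p[nonzero] = 1.0 - (ratios ** 2).sum(axis=1)
    return p


def classify_roles(z: np.ndarray, p: np.ndarray,
                   channels: list[str] | None = None) -> NodeRoleTable:
    """Assign each node one of the eight Z-P roles.

    Hubs are Z >= 1.4; the P boundaries are half-open with the upper edge
    included: P <= 0.05, 0.05 < P <= 0.5, 0.5 < P <= 0.8, P > 0.8.
    """
    z = np.asarray(z, dtype=float)
    p = np.asarray(p, dtype=float)
    if channels is None:
        channels = [f"n{i}" for i in range(z.size)]
    roles = []
    for zi, pi in zip(z, p):
        if pi <= P_CUTS[0]:
            band = 1
        elif pi <= P_CUTS[1]:
            band = 2
        elif pi <= P_CUTS[2]:
            band = 3
        else:
            band = 4
        roles.append(f"R{band + 4}" if zi >= HUB_Z else f"R{band}")
    return NodeRoleTable(z=z, p=p, roles=roles, channels=list(channels))


def node_roles(g: HyperBrainGraph, partition: Partition) -> NodeRoleTable:
    """Convenience: Z, P and role labels for one graph + partition."""
    z = within_module_degree(g, partition)
    p = participation_coefficient(g, partition)
    return classify_roles(z, p, channels=list(g.channels))


def hyper_brain_modules(partition: Partition,
                        brains: list[str]) -> list[dict]:
    """Modules whose members span both brains, with their member indices."""
    if len(brains) != partition.labels.shape[0]:
        raise ValueError("brain metadata does not cover all nodes")
    brains_arr = np.asarray(brains)
    out = []
    for c in range(partition.n_modules):
        members = partition.members(c)
        present = set(brains_arr[members])
        if len(present) > 1:
            out.append({"module": int(c), "members": members.tolist(),
                        "brains": sorted(present)})
    return out


def role_census(tables: list[NodeRoleTable]) -> pd.Series:
    """Pooled percentage of nodes per role across a list of role tables."""
    if not tables:
        raise ValueError("need at least one role table")
    counts = {f"R{i}": 0 for i in range(1, 9)}
    total = 0
    for table in tables:
        for role in table.roles:
            counts[role] += 1
            total += 1
    return pd.Series({r: 100.0 * c / total for r, c in counts.items()})
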