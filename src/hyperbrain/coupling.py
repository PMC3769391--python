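"""Single-trial phase-coupling indices.

Five indices are computed per ordered channel pair, epoch, and FOI from
the wrapped phase-difference series:

* ``PSI`` - mean resultant length of the phase-difference angles across
  the epoch (phase stability at any angle).
* ``PCI`` / ``NCI`` - fraction of points whose phase difference lies in
  ``[0, +pi/4)`` / ``(-pi/4, 0)`` after run-length cleaning; a positive
  code means the first channel of the pair leads.
* ``ACI`` = PCI + NCI - in-phase synchronization within +-pi/4 (symmetric).
* ``ICI`` = PCI * (1 - NCI/2) - directed index in [0, 1]; equals 1 when
  every point is locked positive and 0 when every locked point is
  negative (the factor ``1 - NCI/2`` then approaches 0.5 while PCI
  vanishes).

Cleaning recodes to 0 every maximal run of consecutive same-sign nonzero
codes whose duration is shorter than one oscillation period ``1/f``,
suppressing accidental synchronization.  Cleaning affects only the coded
indices, not the PSI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import EpochedSignals
from .spectral import (PhaseDifferenceSeries, PhaseTensor, WaveletParams,
                       morlet_phase, phase_difference)

__all__ = [
    "MEASURES",
    "DIRECTED_MEASURES",
    "CodedSeries",
    "CouplingResult",
    "CouplingMatrices",
    "psi",
    "code_phase_difference",
    "clean_codes",
    "coupling_indices",
    "connectivity_matrices",
    "ici_from_counts",
]

MEASURES: tuple[str, ...] = ("psi", "pci", "nci", "aci", "ici")
DIRECTED_MEASURES: frozenset[str] = frozenset({"pci", "nci", "ici"})

#: Derivation note for the directed index: ICI = PCI * (1 - NCI/2).  The
#: intermediate factor (1 - NCI/2) equals 1 when no point is locked
#: negative and approaches 0.5 when all locked points are negative, in
#: which case multiplication with the vanishing PCI drives ICI to 0.
ICI_DERIVATION = "ici = pci * (1 - nci / 2)"


@dataclass
class CodedSeries:
    """{-1, 0, +1} coding of a phase-difference series.

    ``codes`` has the same shape as the source ``delta_phi``
    (pair x epoch x FOI x time).
    """

    codes: np.ndarray
    pairs: list[tuple[int, int]]
    fois: tuple[float, ...]
    interval: float
    valid: np.ndarray
    cleaned: bool = False


@dataclass
class CouplingResult:
    """Per-pair, per-epoch, per-FOI values of the five indices.

    Every array has shape ``(n_pairs, n_epochs, n_fois)``; ``k`` is the
    per-FOI count of valid (non-edge) coefficient times used as the
    normalizer.
    """

    psi: np.ndarray
    pci: np.ndarray
    nci: np.ndarray
    aci: np.ndarray
    ici: np.ndarray
    k: np.ndarray  # (n_fois,)
    pairs: list[tuple[int, int]]
    fois: tuple[float, ...]
    derivation: str = ICI_DERIVATION

    def get(self, measure: str) -> np.ndarray:
        if measure not in MEASURES:
            raise KeyError(f"unknown measure {measure!r}")
        return getattr(self, measure)


@dataclass
class CouplingMatrices:
    """Node-by-node coupling values for the hyper-brain node set.

    ``values[measure]`` has shape ``(n_epochs, n_fois, N, N)`` (or
    ``(n_fois, N, N)`` after epoch averaging); the diagonal is zero.
    """

    values: dict[str, np.ndarray]
    fois: tuple[float, ...]
    channels: list[str]
    brains: list[str] | None
    per_epoch: bool = True

    @property
    def n_nodes(self) -> int:
        return len(self.channels)

    def intra_mask(self) -> np.ndarray:
        """Boolean (N, N) mask of within-brain off-diagonal entries."""
        if self.brains is None:
            mask = np.ones((self.n_nodes, self.n_nodes), dtype=bool)
        else:
            b = np.asarray(self.brains)
            mask = b[:, None] == b[None, :]
        np.fill_diagonal(mask, False)
        return mask

    def inter_mask(self) -> np.ndarray:
        """Boolean (N, N) mask of between-brain entries."""
        if self.brains is None:
            return np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        b = np.asarray(self.brains)
        return b[:, None] != b[None, :]

    def mean_over_epochs(self) -> "CouplingMatrices":
        if not self.per_epoch:
            return self
        return CouplingMatrices(
            values={m: v.mean(axis=0) for m, v in self.values.items()},
            fois=self.fois, channels=list(self.channels),
            brains=None if self.brains is None else list(self.brains),
            per_epoch=False,
        )


def psi(delta_phi: PhaseDifferenceSeries) -> np.ndarray:
    """Mean resultant length of phase-difference angles across valid times.

    Returns an array of shape ``(n_pairs, n_epochs, n_fois)`` in [0, 1].
    """
    valid = delta_phi.valid  # (n_fois, n_times)
    k = valid.sum(axis=1)  # per FOI
    if np.any(k < 2):
        raise ValueError("fewer than 2 valid coefficient times for some FOI")
    vectors = np.exp(1j * delta_phi.delta_phi) * valid[None, None, :, :]
    return np.abs(vectors.sum(axis=-1)) / k[None, None, :]


def code_phase_difference(delta_phi: PhaseDifferenceSeries) -> CodedSeries:
    """Code each wrapped phase difference into {-1, 0, +1}.

    +1 for ``0 <= dphi < +pi/4`` (first channel leads), -1 for
    ``-pi/4 < dphi < 0``, 0 otherwise (non-synchronization).  The outer
    boundaries ``+-pi/4`` code 0; exactly 0 codes +1.
    """
    d = delta_phi.delta_phi
    codes = np.zeros(d.shape, dtype=np.int8)
    codes[(d >= 0.0) & (d < np.pi / 4.0)] = 1
    codes[(d > -np.pi / 4.0) & (d < 0.0)] = -1
    return CodedSeries(codes=codes, pairs=list(delta_phi.pairs),
                       fois=delta_phi.fois, interval=delta_phi.interval,
                       valid=delta_phi.valid, cleaned=False)


def _clean_runs(flat: np.ndarray, min_len: int) -> np.ndarray:
    """Zero out same-value nonzero runs shorter than ``min_len`` samples.

    ``flat`` is ``(n_series, n_times)`` with values in {-1, 0, +1}.
    Fully vectorized run-length pass.
    """
    if min_len <= 1:
        return flat
    n_series, n_times = flat.shape
    if n_times == 0:
        return flat
    change = np.ones((n_series, n_times), dtype=bool)
    change[:, 1:] = flat[:, 1:] != flat[:, :-1]
    run_id = np.cumsum(change.ravel()) - 1  # global, strictly increasing
    lengths = np.bincount(run_id)
    elem_len = lengths[run_id].reshape(n_series, n_times)
    out = flat.copy()
    out[(out != 0) & (elem_len < min_len)] = 0
    return out


def clean_codes(codes: CodedSeries) -> CodedSeries:
    """Discard locked runs shorter than one period of the FOI's oscillation.

    A maximal run of ``n`` consecutive identical nonzero codes at FOI
    ``f`` survives iff ``n * interval >= 1 / f``.
    """
    if codes.cleaned:
        return codes
    out = codes.codes.copy()
    n_fois = len(codes.fois)
    for k, foi in enumerate(codes.fois):
        min_len = int(np.ceil((1.0 / foi) / codes.interval - 1e-12))
        series = out[..., k, :]
        flat = series.reshape(-1, series.shape[-1])
        series[...] = _clean_runs(flat, min_len).reshape(series.shape)
    return CodedSeries(codes=out, pairs=list(codes.pairs), fois=codes.fois,
                       interval=codes.interval, valid=codes.valid,
                       cleaned=True)


def ici_from_counts(pci: np.ndarray, nci: np.ndarray) -> np.ndarray:
    """Directed integrative index from the positive/negative fractions."""
    return pci * (1.0 - nci / 2.0)


def coupling_indices(codes: CodedSeries,
                     psi_values: np.ndarray | None = None) -> CouplingResult:
    """Count the cleaned codes into PCI/NCI/ACI/ICI (and attach PSI).

    The normalizer ``k`` is the number of valid coefficient times per
    FOI, independent of how many points survived cleaning.
    """
    if not codes.cleaned:
        codes = clean_codes(codes)
    valid = codes.valid  # (n_fois, n_times)
    k = valid.sum(axis=1)
    if np.any(k == 0):
        raise ValueError("zero valid coefficient times for some FOI")
    masked = codes.codes * valid[None, None, :, :]
    pos = (masked == 1).sum(axis=-1) / k[None, None, :]
    neg = (masked == -1).sum(axis=-1) / k[None, None, :]
    if psi_values is None:
        psi_values = np.zeros_like(pos)
    return CouplingResult(psi=psi_values, pci=pos, nci=neg, aci=pos + neg,
                          ici=ici_from_counts(pos, neg), k=k,
                          pairs=list(codes.pairs), fois=codes.fois)


def pairwise_coupling(phases: PhaseTensor,
                      pairs: list[tuple[int, int]]) -> CouplingResult:
    """Full chain (difference -> PSI -> coding -> cleaning -> counting)
    for an explicit list of ordered pairs."""
    delta = phase_difference(phases, pairs)
    psi_vals = psi(delta)
    coded = clean_codes(code_phase_difference(delta))
    return coupling_indices(coded, psi_values=psi_vals)


def connectivity_matrices(
    epochs: EpochedSignals,
    params: WaveletParams | None = None,
    measures: tuple[str, ...] = MEASURES,
    average_epochs: bool = False,
) -> CouplingMatrices:
    """Compute hyper-brain coupling matrices for all ordered node pairs.

    Only unordered pairs are evaluated explicitly; the reverse direction
    follows from the exact mirror identities ``pci(m,n) = nci(n,m)`` and
    the symmetry of PSI/ACI.
    """
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise KeyError(f"unknown measures {sorted(unknown)}")
    params = params or WaveletParams()
    phases = morlet_phase(epochs, params)
    n = epochs.n_channels
    upper = [(i, j) for i in range(n) for j in range(i + 1, n)]
    result = pairwise_coupling(phases, upper)

    n_epochs, n_fois = epochs.n_epochs, len(params.fois)
    mats = {m: np.zeros((n_epochs, n_fois, n, n)) for m in measures}
    iu, ju = np.array([p[0] for p in upper]), np.array([p[1] for p in upper])
    for m in measures:
        forward = result.get(m)  # (n_pairs, n_epochs, n_fois)
        if m == "pci":
            backward = result.nci
        elif m == "nci":
            backward = result.pci
        elif m == "ici":
            backward = ici_from_counts(result.nci, result.pci)
        else:  # psi, aci are symmetric
            backward = forward
        mats[m][:, :, iu, ju] = np.moveaxis(forward, 0, -1)
        mats[m][:, :, ju, iu] = np.moveaxis(backward, 0, -1)
    out = CouplingMatrices(values=mats, fois=params.fois,
                           channels=list(epochs.channels),
                           brains=None if epochs.brains is None
                           else list(epochs.brains),
                           per_epoch=True)
    return out.mean_over_epochs() if average_epochs else out
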