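"""Complex Morlet wavelet phase extraction and pairwise phase differences.

The transform is evaluated only at the frequencies of interest (FOIs)
that feed the coupling measures, on a decimated time grid (every ``step``
samples).  Coefficients within half the kernel support of an epoch edge
are flagged invalid and excluded from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import EpochedSignals, wrap_phase

__all__ = ["DEFAULT_FOIS", "WaveletParams", "PhaseTensor",
           "PhaseDifferenceSeries", "morlet_phase", "phase_difference"]

#: The 17 analysis frequencies (Hz).
DEFAULT_FOIS: tuple[float, ...] = (
    2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 14, 16, 18, 20, 24, 28,
)


@dataclass
class WaveletParams:
    """Morlet transform parameters.

    ``cycles`` sets the Gaussian envelope width sigma = cycles / (2*pi*f),
    giving a frequency-proportional bandwidth.  ``step`` is the number of
    raw samples between evaluated coefficients (5 at 250 Hz -> 20 ms).
    """

    fois: tuple[float, ...] = DEFAULT_FOIS
    cycles: float = 7.0
    step: int = 5

    def __post_init__(self) -> None:
        self.fois = tuple(float(f) for f in self.fois)
        if any(f <= 0 for f in self.fois):
            raise ValueError("FOIs must be strictly positive")
        if any(b <= a for a, b in zip(self.fois, self.fois[1:])):
            raise ValueError("FOIs must be strictly increasing")
        if self.cycles <= 0:
            raise ValueError("cycles must be positive")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    def sigma_t(self, foi: float) -> float:
        """Envelope standard deviation in seconds at one FOI."""
        return self.cycles / (2.0 * np.pi * foi)

    def edge_margin(self, foi: float) -> float:
        """Seconds near each epoch edge whose coefficients are flagged."""
        return self.cycles / (2.0 * foi)


@dataclass
class PhaseTensor:
    """Instantaneous phase per channel, epoch, FOI, and coefficient time.

    ``phase`` has shape ``(n_channels, n_epochs, n_fois, n_times)`` with
    values in ``(-pi, pi]``.  ``valid`` is ``(n_fois, n_times)``; invalid
    entries fall inside the per-FOI edge margin.
    """

    phase: np.ndarray
    fois: tuple[float, ...]
    interval: float  # seconds between coefficient times
    times: np.ndarray  # seconds from epoch start, (n_times,)
    valid: np.ndarray  # bool, (n_fois, n_times)
    channels: list[str]
    brains: list[str] | None = None

    @property
    def n_channels(self) -> int:
        return self.phase.shape[0]

    def index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not found") from None


@dataclass
class PhaseDifferenceSeries:
    """Wrapped pairwise phase differences, ``(n_pairs, n_epochs, n_fois, n_times)``.

    ``pairs`` are ordered ``(m, n)`` channel-index tuples;
    ``delta_phi = wrap(phi_m - phi_n)`` in ``(-pi, pi]``.
    """

    delta_phi: np.ndarray
    pairs: list[tuple[int, int]]
    fois: tuple[float, ...]
    interval: float
    valid: np.ndarray
    channels: list[str] = field(default_factory=list)


def _morlet_kernel(foi: float, sfreq: float, cycles: float) -> np.ndarray:
    """Analytic Morlet kernel exp(i*2*pi*f*t) * Gaussian(sigma_t)."""
    sigma_t = cycles / (2.0 * np.pi * foi)
    half = int(np.ceil(4.0 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    kernel = np.exp(2j * np.pi * foi * t) * np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    # L1-ish normalisation; irrelevant for the phase but keeps magnitudes sane
    return kernel / np.abs(kernel).sum()


def morlet_phase(epochs: EpochedSignals,
                 params: WaveletParams | None = None) -> PhaseTensor:
    """Convolve every channel/epoch with the analytic Morlet kernel at each
    FOI and return the coefficient phases on the decimated time grid."""
    params = params or WaveletParams()
    nyq = epochs.sfreq / 2.0
    bad = [f for f in params.fois if f >= nyq]
    if bad:
        raise ValueError(f"FOIs at or above Nyquist ({nyq} Hz): {bad}")
    duration = epochs.epoch_duration
    too_low = [f for f in params.fois if params.cycles / f > duration]
    if too_low:
        raise ValueError(
            f"epoch ({duration} s) too short for {params.cycles} cycles at "
            f"FOIs {too_low}"
        )

    idx = np.arange(0, epochs.n_samples, params.step)
    times = idx / epochs.sfreq
    n_fois = len(params.fois)
    phase = np.empty(
        (epochs.n_channels, epochs.n_epochs, n_fois, idx.size), dtype=float
    )
    valid = np.empty((n_fois, idx.size), dtype=bool)
    for k, foi in enumerate(params.fois):
        kernel = _morlet_kernel(foi, epochs.sfreq, params.cycles)
        coef = sps.fftconvolve(epochs.data, kernel[None, None, :],
                               mode="same", axes=2)
        phase[:, :, k, :] = np.angle(coef[:, :, idx])
        margin = params.edge_margin(foi)
        valid[k] = (times >= margin) & (times <= duration - margin)
    return PhaseTensor(phase=phase, fois=params.fois,
                       interval=params.step / epochs.sfreq, times=times,
                       valid=valid, channels=list(epochs.channels),
                       brains=None if epochs.brains is None
                       else list(epochs.brains))


def phase_difference(
    phases: PhaseTensor,
    pairs: list[tuple[int, int] | tuple[str, str]],
) -> PhaseDifferenceSeries:
    """Wrapped phase difference ``phi_m - phi_n`` for each ordered pair."""
    resolved: list[tuple[int, int]] = []
    for m, n in pairs:
        mi = phases.index(m) if isinstance(m, str) else int(m)
        ni = phases.index(n) if isinstance(n, str) else int(n)
        for i in (mi, ni):
            if not (0 <= i < phases.n_channels):
                raise KeyError(f"channel index {i} out of range")
        resolved.append((mi, ni))
    m_idx = np.array([p[0] for p in resolved])
    n_idx = np.array([p[1] for p in resolved])
    delta = wrap_phase(phases.phase[m_idx] - phases.phase[n_idx])
    return PhaseDifferenceSeries(delta_phi=delta, pairs=resolved,
                                 fois=phases.fois, interval=phases.interval,
                                 valid=phases.valid,
                                 channels=list(phases.channels))
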