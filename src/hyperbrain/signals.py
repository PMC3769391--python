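"""Core data containers shared across the pipeline.

All multi-channel data are stored channels-first.  Epoched data use the
shape ``(n_channels, n_epochs, n_samples)`` so that per-epoch operations
broadcast naturally along the trailing axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RawRecording",
    "EpochedSignals",
    "MontageSpec",
    "MONTAGE_21",
    "REGION_MAP",
    "FREQUENCY_BANDS",
    "wrap_phase",
]

#: The 21-electrode montage (10-20 system) used for all graph analyses.
MONTAGE_21: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
)

#: Anterior-posterior grouping of the 21 electrodes into three regions.
REGION_MAP: Mapping[str, str] = {
    "Fp1": "frontal", "Fpz": "frontal", "Fp2": "frontal",
    "F7": "frontal", "F3": "frontal", "Fz": "frontal",
    "F4": "frontal", "F8": "frontal",
    "T7": "central", "C3": "central", "Cz": "central",
    "C4": "central", "T8": "central",
    "P7": "parieto-occipital", "P3": "parieto-occipital",
    "Pz": "parieto-occipital", "P4": "parieto-occipital",
    "P8": "parieto-occipital", "O1": "parieto-occipital",
    "Oz": "parieto-occipital", "O2": "parieto-occipital",
}

#: Frequency bands (Hz, inclusive bounds) used when collapsing FOI-level
#: results for reporting.
FREQUENCY_BANDS: Mapping[str, tuple[float, float]] = {
    "delta": (2.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta1": (14.0, 20.0),
    "beta2": (24.0, 28.0),
}


def wrap_phase(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into the half-open interval ``(-pi, pi]``."""
    return np.pi - np.mod(np.pi - np.asarray(x), 2.0 * np.pi)


@dataclass
class RawRecording:
    """Continuous multi-channel recording.

    Parameters
    ----------
    data
        Amplitude matrix, shape ``(n_channels, n_samples)``.
    sfreq
        Sampling rate in Hz.
    channels
        Unique channel labels, one per row of ``data``.  Dual-subject
        recordings prefix labels with the brain id, e.g. ``"A:Fz"``.
    eog_channels
        Labels of EOG channels (excluded from EEG-wide transforms).
    reference
        Label of the online reference, if known.
    """

    data: np.ndarray
    sfreq: float
    channels: list[str]
    eog_channels: list[str] = field(default_factory=list)
    reference: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not found") from None

    def copy(self) -> "RawRecording":
        return replace(self, data=self.data.copy(), channels=list(self.channels),
                       eog_channels=list(self.eog_channels))


@dataclass
class EpochedSignals:
    """Epoched multi-channel data, shape ``(n_channels, n_epochs, n_samples)``.

    ``brains`` assigns each channel to one member of the dyad (``"A"`` or
    ``"B"``); it may be ``None`` for single-subject data.
    """

    data: np.ndarray
    sfreq: float
    channels: list[str]
    brains: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (channels x epochs x samples)")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("label count does not match channel count")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.brains is not None and len(self.brains) != self.data.shape[0]:
            raise ValueError("brain membership count does not match channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_duration(self) -> float:
        return self.n_samples / self.sfreq

    def index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not found") from None

    def copy(self) -> "EpochedSignals":
        return EpochedSignals(
            data=self.data.copy(), sfreq=self.sfreq,
            channels=list(self.channels),
            brains=None if self.brains is None else list(self.brains),
        )


@dataclass
class MontageSpec:
    """An ordered electrode montage with a label-to-region map."""

    labels: Sequence[str] = MONTAGE_21
    regions: Mapping[str, str] = field(default_factory=lambda: dict(REGION_MAP))

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        missing = [lab for lab in self.labels if lab not in self.regions]
        if missing:
            raise ValueError(f"labels without a region: {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)
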