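"""Synthetic coupled-oscillator generators.

Provides (i) two-channel oscillator pairs with a controlled phase
relation, used to validate the coupling measures, (ii) full two-brain
multichannel datasets with selected coupled channel pairs, and (iii) the
within-epoch shuffling surrogate used for significance thresholding.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import MONTAGE_21, EpochedSignals

__all__ = [
    "OscillatorPairSpec",
    "CouplingEntry",
    "HyperBrainSpec",
    "generate_oscillator_pair",
    "generate_hyper_brain_dataset",
    "shuffle_surrogate",
]

UNIFORM = "uniform"  #: per-epoch phase shift drawn uniformly from (-pi, pi]


@dataclass
class OscillatorPairSpec:
    """Two noisy oscillators at one frequency with a controlled phase lag.

    ``phase_shift`` is either a fixed value in radians or the string
    ``"uniform"``, in which case one shift per epoch is drawn uniformly
    from ``(-pi, +pi]``.  Channel B lags channel A by
    ``phase_shift + 2*pi*frequency*lag``.
    """

    frequency: float
    duration: float = 3.0
    sampling_rate: float = 250.0
    phase_shift: float | str = 0.0
    lag: float = 0.0
    noise_sd: float = 0.5
    n_epochs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if isinstance(self.phase_shift, str) and self.phase_shift != UNIFORM:
            raise ValueError(f"unknown phase_shift mode {self.phase_shift!r}")


def _draw_shifts(spec: OscillatorPairSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.phase_shift, str):
        # uniform over (-pi, +pi]
        return np.pi - rng.uniform(0.0, 2.0 * np.pi, size=spec.n_epochs)
    return np.full(spec.n_epochs, float(spec.phase_shift))


def generate_oscillator_pair(spec: OscillatorPairSpec) -> EpochedSignals:
    """Generate an epoched two-channel oscillator pair.

    Channel A is ``cos(2*pi*f*t + phi0)`` with a random per-epoch base
    phase ``phi0``; channel B is the same oscillation delayed so that the
    instantaneous phase of A leads B by ``phase_shift + 2*pi*f*lag``.
    Independent Gaussian noise (sd ``noise_sd``) is added to each channel.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration * spec.sampling_rate))
    t = np.arange(n_samples) / spec.sampling_rate

    shifts = _draw_shifts(spec, rng)
    base = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_epochs)
    total_lag = shifts + 2.0 * np.pi * spec.frequency * spec.lag

    omega_t = 2.0 * np.pi * spec.frequency * t  # (n_samples,)
    phase_a = base[:, None] + omega_t[None, :]
    phase_b = phase_a - total_lag[:, None]
    sig_a = np.cos(phase_a)
    sig_b = np.cos(phase_b)
    data = np.stack([sig_a, sig_b])  # (2, n_epochs, n_samples)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    return EpochedSignals(data=data, sfreq=spec.sampling_rate,
                          channels=["A", "B"], brains=["A", "B"])


@dataclass
class CouplingEntry:
    """One imposed coupling: target carries a lagged copy of the source
    oscillation scaled by ``strength``."""

    source: str
    target: str
    frequency: float
    lag: float = 0.0
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("coupling frequency must be positive")


@dataclass
class HyperBrainSpec:
    """Two synthetic 'brains' of background-noise channels with selected
    oscillator couplings between named channels.

    Channel labels follow the ``"A:Fz"`` / ``"B:Fz"`` convention; the
    per-brain montage defaults to the 21-electrode set.
    """

    channels_per_brain: int = 21
    labels: tuple[str, ...] | None = None
    couplings: list[CouplingEntry] = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channels_per_brain < 1:
            raise ValueError("channels_per_brain must be >= 1")
        if self.labels is None:
            if self.channels_per_brain <= len(MONTAGE_21):
                self.labels = MONTAGE_21[: self.channels_per_brain]
            else:
                self.labels = tuple(
                    f"Ch{i + 1}" for i in range(self.channels_per_brain)
                )
        self.labels = tuple(self.labels)
        if len(self.labels) != self.channels_per_brain:
            raise ValueError("label count must equal channels_per_brain")

    def channel_names(self) -> list[str]:
        return [f"{brain}:{lab}" for brain in ("A", "B") for lab in self.labels]


def generate_hyper_brain_dataset(
    spec: HyperBrainSpec, epoch_length: float = 10.0, n_epochs: int = 1
) -> EpochedSignals:
    """Generate a dyadic multichannel dataset from a :class:`HyperBrainSpec`.

    Every channel is independent Gaussian noise; for each coupling entry
    an oscillation (unit amplitude, random per-epoch base phase) is added
    to the source channel and its lagged, ``strength``-scaled copy to the
    target channel.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(spec.seed)
    names = spec.channel_names()
    index = {name: i for i, name in enumerate(names)}
    for entry in spec.couplings:
        for label in (entry.source, entry.target):
            if label not in index:
                raise KeyError(f"coupling references unknown channel {label!r}")

    sfreq = 250.0
    n_samples = int(round(epoch_length * sfreq))
    t = np.arange(n_samples) / sfreq
    data = rng.normal(0.0, spec.noise_sd, size=(len(names), n_epochs, n_samples))

    for entry in spec.couplings:
        base = rng.uniform(0.0, 2.0 * np.pi, size=n_epochs)
        phase_src = base[:, None] + 2.0 * np.pi * entry.frequency * t[None, :]
        phase_tgt = phase_src - 2.0 * np.pi * entry.frequency * entry.lag
        data[index[entry.source]] += np.cos(phase_src)
        data[index[entry.target]] += entry.strength * np.cos(phase_tgt)

    brains = [name.split(":", 1)[0] for name in names]
    return EpochedSignals(data=data, sfreq=sfreq, channels=names, brains=brains)


def shuffle_surrogate(signals: EpochedSignals, seed: int) -> EpochedSignals:
    """Permute each channel's samples independently within every epoch.

    Destroys all temporal structure while preserving the per-epoch
    amplitude histogram exactly.
    """
    if signals.n_samples == 0:
        raise ValueError("cannot shuffle empty signals")
    rng = np.random.default_rng(seed)
    out = signals.copy()
    n_ch, n_ep, n_s = out.data.shape
    # one independent permutation per (channel, epoch)
    perm = np.argsort(rng.random((n_ch, n_ep, n_s)), axis=-1)
    out.data = np.take_along_axis(out.data, perm, axis=-1)
    return out
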