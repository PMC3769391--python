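"""Readers and writers for recordings, matrices, graphs and tables.

The first-class container is a delimited text format: a TSV with one
header row of channel labels and one row per sample, accompanied by a
JSON sidecar (``<path>.json``) holding the sampling rate and channel
metadata.  BrainVision and EDF are supported when the optional readers
(`mne` / `pyedflib`) are installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coupling import CouplingMatrices
from .signals import EpochedSignals, RawRecording
from .thresholding import HyperBrainGraph, ThresholdSet

__all__ = [
    "read_raw",
    "write_delimited",
    "read_delimited",
    "write_epochs_npz",
    "read_epochs_npz",
    "write_matrices",
    "write_thresholds",
    "read_thresholds",
    "write_graphml",
]


def write_delimited(raw: RawRecording, path: str | Path) -> Path:
    """Write a recording as TSV (header = labels, rows = samples) plus a
    JSON metadata sidecar."""
    path = Path(path)
    frame = pd.DataFrame(raw.data.T, columns=raw.channels)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "sampling_rate": raw.sfreq,
        "channels": raw.channels,
        "eog_channels": raw.eog_channels,
        "reference": raw.reference,
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_delimited(path: str | Path) -> RawRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    sfreq = float(meta.get("sampling_rate", 250.0))
    return RawRecording(
        data=frame.to_numpy().T,
        sfreq=sfreq,
        channels=list(frame.columns),
        eog_channels=list(meta.get("eog_channels", [])),
        reference=meta.get("reference"),
    )


def _read_brainvision(path: Path) -> RawRecording:
    try:
        import mne  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading BrainVision files requires the optional dependency "
            "'mne'; install it or convert to the delimited format"
        ) from exc
    rec = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    return RawRecording(data=rec.get_data(), sfreq=rec.info["sfreq"],
                        channels=list(rec.ch_names))


def _read_edf(path: Path) -> RawRecording:
    try:
        import pyedflib  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF files requires the optional dependency 'pyedflib'; "
            "install it or convert to the delimited format"
        ) from exc
    with pyedflib.EdfReader(str(path)) as f:
        labels = f.getSignalLabels()
        sfreq = f.getSampleFrequency(0)
        data = np.stack([f.readSignal(i) for i in range(f.signals_in_file)])
    return RawRecording(data=data, sfreq=float(sfreq), channels=list(labels))


def read_raw(path: str | Path, fmt: str = "delimited") -> RawRecording:
    """Load a recording.  ``fmt`` is one of ``delimited``, ``brainvision``,
    ``edf``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "delimited":
        return read_delimited(path)
    if fmt == "brainvision":
        return _read_brainvision(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {fmt!r}")


def merge_recordings(a: RawRecording, b: RawRecording) -> RawRecording:
    """Merge two single-subject recordings into one dyadic recording with
    ``A:`` / ``B:`` channel prefixes."""
    if a.sfreq != b.sfreq:
        raise ValueError("recordings have different sampling rates")
    n = min(a.n_samples, b.n_samples)
    channels = [f"A:{c}" for c in a.channels] + [f"B:{c}" for c in b.channels]
    eog = [f"A:{c}" for c in a.eog_channels] + [f"B:{c}" for c in b.eog_channels]
    return RawRecording(data=np.vstack([a.data[:, :n], b.data[:, :n]]),
                        sfreq=a.sfreq, channels=channels, eog_channels=eog)


def write_epochs_npz(epochs: EpochedSignals, path: str | Path) -> Path:
    """Binary container for epoched data (runtime scratch use)."""
    path = Path(path)
    np.savez_compressed(
        path, data=epochs.data, sfreq=epochs.sfreq,
        channels=np.array(epochs.channels),
        brains=np.array(epochs.brains if epochs.brains is not None else []),
    )
    return path


def read_epochs_npz(path: str | Path) -> EpochedSignals:
    with np.load(path, allow_pickle=False) as z:
        brains = [str(b) for b in z["brains"]] or None
        return EpochedSignals(data=z["data"], sfreq=float(z["sfreq"]),
                              channels=[str(c) for c in z["channels"]],
                              brains=brains)


def write_matrices(mats: CouplingMatrices, out_dir: str | Path) -> list[Path]:
    """One TSV per measure x FOI (epoch-averaged) plus a node-metadata
    sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    averaged = mats.mean_over_epochs()
    written = []
    for measure, stack in averaged.values.items():
        for k, foi in enumerate(averaged.fois):
            frame = pd.DataFrame(stack[k], index=averaged.channels,
                                 columns=averaged.channels)
            path = out_dir / f"{measure}_{foi:g}Hz.tsv"
            frame.to_csv(path, sep="\t", float_format="%.10g")
            written.append(path)
    nodes = pd.DataFrame({
        "channel": averaged.channels,
        "brain": averaged.brains if averaged.brains is not None
        else [""] * len(averaged.channels),
    })
    nodes_path = out_dir / "nodes.tsv"
    nodes.to_csv(nodes_path, sep="\t", index=False)
    written.append(nodes_path)
    return written


def write_thresholds(ts: ThresholdSet, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for measure, vals in ts.thresholds.items():
        for foi, val in zip(ts.fois, vals):
            rows.append({"measure": measure, "foi": foi, "threshold": val,
                         "alpha": ts.alpha, "n_bootstrap": ts.n_bootstrap,
                         "seed": ts.seed, "method": ts.method})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")
    return path


def read_thresholds(path: str | Path) -> ThresholdSet:
    frame = pd.read_csv(path, sep="\t")
    fois = tuple(sorted(frame["foi"].unique()))
    thresholds = {}
    for measure, grp in frame.groupby("measure"):
        grp = grp.set_index("foi").loc[list(fois)]
        thresholds[measure] = grp["threshold"].to_numpy()
    first = frame.iloc[0]
    return ThresholdSet(thresholds=thresholds, fois=fois,
                        alpha=float(first["alpha"]),
                        n_bootstrap=int(first["n_bootstrap"]),
                        seed=int(first["seed"]), method=str(first["method"]))


def write_graphml(g: HyperBrainGraph, path: str | Path) -> Path:
    """GraphML export with label/brain node attributes."""
    import networkx as nx

    path = Path(path)
    nx.write_graphml(g.to_networkx(), path)
    return path
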