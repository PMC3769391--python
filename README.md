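# hyperbrain

Single-trial phase-coupling measures and hyper-brain network analysis for
dual-EEG (hyperscanning) data.

The package computes five instantaneous phase-synchronization indices
between all electrode pairs within and between two brains, thresholds the
resulting connectivity matrices against shuffled surrogate data, and
characterizes the surviving "hyper-brain" graphs with standard
graph-theoretic statistics (strengths, clustering, path length,
small-worldness, modularity, and node roles).

## Measures

Given the wrapped instantaneous phase difference between two channels
(complex Morlet wavelet, evaluated every 5 samples at 250 Hz = 20 ms
resolution) per frequency of interest:

| Measure | Definition | Symmetry |
|---|---|---|
| PSI | mean resultant length of the phase-difference angles across the epoch | symmetric |
| PCI | fraction of points with phase difference in `[0, +pi/4)` after cleaning | directed |
| NCI | fraction of points in `(-pi/4, 0)` after cleaning | directed |
| ACI | PCI + NCI | symmetric |
| ICI | `PCI * (1 - NCI/2)` | directed |

The cleaning step zeroes every run of same-sign locked points shorter
than one oscillation period (1/f), suppressing accidental
synchronization. ICI equals 1 when every point is locked positive (first
channel leading) and 0 when every locked point is negative.

Graph construction: per measure and frequency, values are compared
against a surrogate threshold (within-epoch shuffling, 1,000 bootstrap
resamples, p < 0.0001 by default); only strictly supra-threshold values
become edges. PSI/ACI graphs are undirected, PCI/NCI/ICI graphs directed.

## CLI

```bash
# synthetic two-channel oscillator pair
hyperbrain simulate --frequency 10 --phase-shift uniform --n-epochs 100 --out pair.tsv

# preprocessing chain: re-reference, band-pass, EOG regression,
# resample to 250 Hz, 10-s epochs, artifact rejection, montage
hyperbrain preprocess rec.tsv --mastoids M1 M2 --eog EOG --out epochs.npz

# coupling matrices, thresholds, graphs, communities
hyperbrain couple epochs.npz --foi 6 --measure ici --out-dir mats/
hyperbrain threshold epochs.npz --foi 6 --alpha 0.0001 --out thresholds.tsv
hyperbrain graph epochs.npz --thresholds thresholds.tsv --measure ici --foi 6 --out-dir graphs/
hyperbrain community epochs.npz --thresholds thresholds.tsv --measure ici --foi 6 --out-dir comm/

# or the whole pipeline from a YAML config
hyperbrain run config.yaml --out-dir results/
```

A minimal config:

```yaml
input:
  format: synthetic          # or delimited / brainvision / edf with `path:`
  synthetic:
    channels_per_brain: 21
    n_epochs: 4
    couplings:
      - {source: "A:Fz", target: "B:Fz", frequency: 6.0, lag: 0.02}
seed: 1
wavelet: {fois: [6.0, 10.0], step: 5}
measures: [ici, aci, psi]
threshold: {alpha: 0.0001, n_bootstrap: 1000, seed: 2}
community: {restarts: 20, seed: 3}
```

## Layout

| Module | Contents |
|---|---|
| `hyperbrain.signals` | data containers, montage, bands, regions |
| `hyperbrain.synthetic` | oscillator-pair / two-brain generators, shuffling surrogate |
| `hyperbrain.preprocess` | re-referencing, band-pass, EOG regression, epoching, artifact rejection, montage |
| `hyperbrain.spectral` | Morlet phase, wrapped pairwise phase differences |
| `hyperbrain.coupling` | PSI / PCI / NCI / ACI / ICI, coding + cleaning, connectivity matrices |
| `hyperbrain.thresholding` | surrogate ensembles, bootstrap thresholds, graph sparsification |
| `hyperbrain.graphs` | strengths, CC, CPL, null models, sigma/omega, band/region collapsing |
| `hyperbrain.community` | modularity optimization, Z/P, role taxonomy R1-R8, hyper-brain modules |
| `hyperbrain.io` / `hyperbrain.cli` / `hyperbrain.pipeline` | formats, CLI, pipeline driver |
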