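# metastab

Metastability analysis of pulse-perturbed (TMS-style) EEG, together with a
delayed-Kuramoto connectome model ("digital twin") that reproduces the
observed dynamics mechanistically, and a synthetic-data generator that makes
the whole pipeline testable offline.

Two complementary metastability measures are implemented end to end:

1. **Kuramoto order parameter (KOP) route** — band-limited Hilbert phase per
   channel, the order parameter `r(t)` over a channel set, and its
   population standard deviation in a sliding window (50 ms default) as the
   metastability index, with baseline-percent normalization and
   epoch/subject averaging.
2. **Microstate-complexity route** — microstate templates from GFP peaks of
   alpha-filtered resting data via atomise-and-agglomerate hierarchical
   clustering (TAAHC), Krzanowski–Lai selection of the state count,
   polarity-invariant backfitting, transition-probability matrices, and the
   windowed Lempel–Ziv (LZ76) complexity of the label sequence.

Pre/post-pulse window means (250 ms) are compared per subject with exact
one-tailed Wilcoxon signed-rank tests (full null distribution for n ≤ 25,
continuity-corrected normal approximation above), with Shapiro–Wilk
normality annotation and an optional Holm-corrected column.

The digital twin is a 90-node delayed Kuramoto network
(`dθᵢ/dt = ωᵢ + (K/N) Σⱼ c_ij sin(θⱼ(t−τ_ij) − θᵢ) + d·ζ(t)`) with
node-strength-based intrinsic frequencies, conduction delays
`τ_ij = d_ij / velocity`, Euler integration over a ring-buffer history, a
low-coherence-triggered pulse that resets phases to π/2 (instantly within a
radius of the site, with conduction delay elsewhere), a similar-frequency
subgroup readout, and a maximum-frequency sweep over {5, 15, 25, 35} Hz with
seed averaging.

## Layout

```
src/metastab/
  containers.py   EpochedEEG / ContinuousEEG / Connectome
  config.py       bands, windows, thresholds (YAML-loadable)
  io/             BrainVision, EDF, HDF5 container, trace tables
  epoching.py     event-locked epoch extraction
  synth.py        synthetic cohorts + connectomes with planted effects
  phase.py        band-pass, Hilbert phase, KOP, sliding metastability
  grouping.py     evoked-potential GFP-peak tertile channel groups
  microstates.py  GFP peaks, TAAHC, Krzanowski-Lai, backfit, transitions
  lzc.py          LZ76 complexity, sliding/tiled windowed complexity
  stats.py        pre/post tables, exact Wilcoxon battery
  twin.py         delayed Kuramoto network + pulse-reset experiment
  pipeline.py     cohort-level orchestration
  cli.py          click CLI
```

## CLI

`metastab` exposes subcommands that chain the stages; every stochastic stage
takes `--seed` and writes it into its JSON sidecar:

```bash
metastab make-synthetic --kind connectome --seed 42 --out-dir conn/
metastab make-synthetic --kind tms --spec cohort.yaml --seed 1 --out-dir data/
metastab epoch --input rec.vhdr --out epochs.h5
metastab analyze-kop --input data/tms_sub00.h5 --out-dir traces/
metastab group-channels --input data/tms_sub00.h5 --out groups.json
metastab analyze-microstates --rest rest.h5 --tms data/tms_sub00.h5 --out-dir ms/
metastab stats --traces traces/ --pulse-ms 500 --out stats.csv
metastab simulate-twin --seeds 10 --config twin.yaml --out-dir twin/
```

Input formats: BrainVision (`.vhdr/.vmrk/.eeg`), EDF, and the package's own
lossless HDF5 container (`.h5`); outputs are CSV/TSV traces with JSON
sidecars.

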