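# tebc

Analysis toolkit for hippocampal LFP/EMG oscillation dynamics during trace
eyeblink conditioning (TEBC), together with a fully parameterized synthetic
session generator so every stage of the pipeline can be validated against
known ground truth without any recorded data.

The pipeline covers:

- **Synthetic data** (`tebc.synthetic`) — multi-rat, multi-session two-channel
  (hippocampal fissure/hilus) LFP epochs plus a concurrent EMG channel:
  1/f background noise, CS-locked evoked broadband transients,
  condition-dependent induced oscillations, low-frequency-phase-modulated
  high-frequency activity, lagged inter-site coupling, blink bursts following
  a programmable learning curve, and artifact trials. Bit-identical under a
  fixed seed; every injected component is listed in a ground-truth manifest.
- **Behavior** (`tebc.behavior`) — conditioned-response detection from
  rectified/smoothed EMG (baseline mean + 3 SD threshold in the last 200 ms
  of the trace period), hit rates, reaction times, and across-session
  learning summaries (Pearson trend + repeated-measures ANOVA).
- **Preprocessing** (`tebc.preprocess`) — 1,500 µV artifact-trial rejection,
  stimulus-artifact alpha-blend interpolation (0.45) around CS onset/offset,
  Laplacian (CSD) re-referencing, and a zero-lag FIR filter bank (3–480 Hz,
  log-spaced; 0.6·f/1.4·f stop edges at ≥60 dB) followed by Hilbert
  transformation into analytic phase/amplitude time series.
- **Spectral maps** (`tebc.spectral`) — trial-averaged amplitude TFRs with
  baseline correction and intertrial coherence (phase-locking factor).
- **Connectivity** (`tebc.connectivity`) — interareal PLV with 100-fold
  trial-shuffle normalization, n:m phase–amplitude coupling (ratios 2–9,
  four laminar pairs, three post-stimulus windows + pre-stimulus
  counterparts), and differential phase transfer entropy (dTE) from binned
  phase histograms.
- **Statistics** (`tebc.stats`) — trial-count equalization, 20,000-draw
  sign-flip Monte Carlo nulls, Benjamini–Hochberg FDR, cluster-based
  permutation over temporal adjacency (1,000 surrogates), two-way
  repeated-measures ANOVA on ROIs, PAC group tests, and trial-shuffle dTE
  significance tests. All Monte Carlo p-values use the +1-corrected
  estimator and reproduce bit-identically under a fixed seed.
- **Pipeline** (`tebc.pipeline`) — orchestrates simulate → behavior →
  preprocess → spectral/connectivity → stats into the CR vs no-CR
  (retrieval) and highest vs lowest %HR (consolidation) contrasts, with a
  deterministic CSV/JSON report bundle and provenance manifest.

## CLI

```bash
# generate a synthetic experiment (HDF5 + ground-truth sidecars)
tebc simulate --config sim.yaml --seed 1 --out exp.h5

# score EMG into a trial table
tebc behavior --data exp.h5 --out trials.csv

# clean + decompose into analytic narrow-band signals
tebc preprocess --data exp.h5 --out tfr.h5 --f-min 3 --f-max 100 --n-bands 20

# full analysis (report bundle: CSV tables + manifest.json)
tebc run --config run.yaml --seed 1 --out results/

# individual stages
tebc spectral --out results/      # amplitude/ITC contrasts only
tebc connectivity --out results/ --ratios 2,3,4,5,6,7,8,9 --shuffles 100
tebc stats --out results/ --contrast cr
```

Config files are YAML mirrors of `tebc.synthetic.SimConfig` and
`tebc.pipeline.RunConfig`.

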