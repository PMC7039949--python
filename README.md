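# eabrkit

Analysis pipeline for cochlear-implant pulse-shape efficiency studies
based on electrically evoked auditory brainstem responses (eABR).

The package covers the full chain from stimulus definition to threshold
modelling:

- **`eabrkit.stimulus`** — charge-balanced biphasic pulses (rectangular
  and three linearly ramped variants), hardware-style 25 uA ramp
  quantization, pulse trains, and charge-per-phase bookkeeping.
- **`eabrkit.synthdata`** — synthetic eABR sweep generation with known
  ground truth: polarity-antisymmetric stimulus artifact (with an
  exponential tail for long interphase gaps), waves II–IV following
  linear/saturating growth in charge, level-dependent latencies, white
  noise, and the four delay-shifted recordings (0/5/10/15 us) used for
  interleaved up-sampling.  All randomness derives from one seed via
  per-(condition, delay, sweep) counter-style substreams.
- **`eabrkit.preprocess`** — baseline correction and epoch averaging,
  interleaved-delay up-sampling to 4x the native 48,828 Hz rate,
  linear-interpolation onset-artifact removal, exponential-trend removal
  for long-gap stimuli, zero-phase 4th-order Butterworth bandpass
  (100–3000 Hz), and alternating-polarity averaging.
- **`eabrkit.quantify`** — wave peak/trough metrics, the 0.1 uV
  threshold criterion, dB conversions (20·log10), and the
  3-dB-above-threshold level selection.
- **`eabrkit.growthfit`** — linear and bounded "broken-stick" growth
  fits with F-test model selection, and strength-duration regressions in
  dB per doubling of phase duration (charge and current bases).
- **`eabrkit.filtermodel`** — the lowpass-filter threshold-prediction
  model: a biquad realization of a magnitude target (flat to 110 Hz,
  −6 dB/oct to 4 kHz, −3 dB/oct above), sliding 10 ms Hanning-window RMS
  over one stimulus period, inverse-max-RMS relative thresholds, and
  calibration against a measured reference.
- **`eabrkit.io` / `eabrkit.config` / `eabrkit.pipeline` /
  `eabrkit.cli`** — HDF5 trace container with a JSON manifest, YAML
  study configuration, and the composable pipeline.

## CLI

A study is one YAML file (see `eabrkit.config.StudyConfig` for the
schema; every field has a default, so `{seed: 1}` is a valid study).

```sh
eabrkit run -c study.yaml -o outdir/          # whole pipeline
# or stage by stage (composes to identical tables):
eabrkit simulate   -c study.yaml -o sweeps.h5
eabrkit preprocess -c study.yaml -i sweeps.h5 -o evoked.h5
eabrkit quantify   -c study.yaml -i evoked.h5 -o levels.csv
eabrkit fit        -c study.yaml -i levels.csv -o fitdir/
eabrkit model      -c study.yaml -o predictions.csv --reference-current-ua 350
```

Outputs are tidy CSV tables (per-level wave metrics, thresholds per
shape × polarity plus polarity means, growth fits, 3-dB-above-threshold
latencies, strength-duration slopes, and filter-model predictions), each
stamped with the config hash and seed.

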