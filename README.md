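# pulsedecomp

Pulse decomposition analysis of peripheral arterial pressure waveforms.

The peripheral arterial pulse is modelled as a superposition of a primary
left-ventricular ejection pulse and two central-artery reflections (the
"renal" and "iliac" reflections), plus two rapidly diminishing
re-reflections. The package provides:

- **`pulsedecomp.model`** — a forward model of component-pulse arrival
  times: pressure-dependent wave speeds (Moens–Korteweg relation with an
  exponential pressure factor; linearized response for central
  segments), component-pulse pressures, and the T12/T13 delays. Under the
  default calibration T13 sits in the physiological 180–400 ms window at
  120/80 mmHg and decreases as diastole rises toward systole.
- **`pulsedecomp.synth`** — ground-truthed synthesis of 512-Hz
  sensor-derivative streams: five-component beat morphology, lower-body
  negative pressure (LBNP) stage schedules (0 … −60 mmHg), heart-rate
  shifts and additive noise. Component delays can be driven by the
  forward model so the recorded ground truth and the model agree exactly.
- **`pulsedecomp.extract`** — the beat-level decomposition algorithm:
  peak finding on the derivative stream, Bessel-filtered digital
  integration, component localisation via second-derivative inversions
  inside physiological windows, a spectral S/N gate, and per-beat
  metrics (T13, P2P1, augmentation index, second-derivative d/a ratio).
- **`pulsedecomp.stats`** — cohort statistics: stage aggregation, linear
  and quadratic OLS fits, one-way within-subject (repeated-measures)
  ANOVA with optional Greenhouse–Geisser correction, and ROC stage
  discrimination from intra-subject deltas.
- **`pulsedecomp.config` / `pulsedecomp.cli`** — validated JSON run
  configuration, deterministic seeding, and the command-line pipeline.

## Command-line usage

```sh
# forward-model T13-vs-diastole curve with the shipped calibration
pulsedecomp fitcurve --systole 120 --diastole-grid 60:100:2 --out curve.csv

# synthesize a session stream + ground truth from a config
pulsedecomp simulate --config run.json --out stream.csv --truth truth.csv

# extract per-beat parameters (QC report includes detection efficiencies)
pulsedecomp extract --in stream.csv --rate 512 --out beats.csv \
    --qc qc.json --truth truth.csv

# cohort statistics over one or more beat tables
pulsedecomp analyze --beats beats.csv --stages stages.json --out report/

# full simulate -> extract -> analyze pipeline
pulsedecomp run --config run.json --out artifacts/ --seed 1
```

A complete default configuration can be produced in Python:

```python
from pulsedecomp import default_run_config, dump_config
dump_config(default_run_config(seed=1), "run.json")
```

Stream files are plain two-column CSV (`sample_index,value`) with a JSON
sidecar carrying the sample rate, seed and stage schedule; every output
carries a short hash of the configuration that produced it, and a fixed
seed reproduces every artifact byte for byte.

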