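# mmcyto

Multimodal particle classification for impedance cytometry with
synchronized high-speed imaging.

In a microfluidic impedance cytometer, every particle that crosses the
sensing electrodes leaves two traces: a pulse in the impedance amplitude
recorded by a multi-frequency lock-in amplifier, and a ring-shaped
signature in the difference image of a high-speed camera watching the
channel. `mmcyto` is for researchers who want to turn such co-registered
recordings into per-particle features and a classifier:

* **optical**: 50-frame rolling background, absolute difference image,
  thresholded 8-connected segmentation, centroid, radial intensity
  profile, diameter at the outer half-maximum crossing, sphere volume
  V = (π/6)·d³ (aggregates sum component volumes), and transit velocity;
* **electrical**: baseline normalization to ΔZ/Z₀ (rolling median),
  matched-filter peak detection at prominence ≥ k·σ̂, and per-carrier
  peak intensity PI at 8 frequencies (100 kHz–1.75 MHz);
* **fusion**: greedy nearest-in-time pairing (50 ms tolerance), feature
  tables (PI at 1 or 8 carriers, VOL, optional VEL), and the validation
  regression log₁₀ PI = a + b·log₁₀ VOL with per-frequency R²;
* **classification**: a "fine tree" (Gini CART, ≤100 splits) with
  stratified 5-fold cross-validation, independent-device test runs, and
  confusion-matrix metrics ACC/TPR/TNR/FPR/FNR computed one-vs-rest;
* **simulation**: a seeded generator of co-registered frame stacks,
  impedance traces and ground truth for four particle classes (2.0–2.9,
  4.0–4.5, 5.0–5.9 µm beads and 15.0–17.0 µm carcinoma cells), used by
  the test suite to validate the whole pipeline end to end.

See `docs/methods.md` for the model details and calibration rationale.

## Worked example

```python
from mmcyto import (AcquisitionConfig, SimulationParams, default_classes,
                    generate_run, regress_vol_pi, velocity_increment)
from mmcyto.classify import process_run
from mmcyto.fusion import build_feature_table

config = AcquisitionConfig()          # 125 fps, 0.2 um/px, 899 S/s, 8 carriers
params = SimulationParams(n_events_per_class=100, seed=7)
run = generate_run(config, default_classes(), params)

events = process_run(run)             # frames+trace -> fused, labelled events
table = build_feature_table(events, "multimodal", include_velocity=True)
for f in (100e3, 500e3, 1.75e6):
    r = regress_vol_pi(table, f)
    print(f"{f/1e3:6.0f} kHz  slope={r.slope:+.3f}  R2={r.r_squared:.3f}  n={r.n}")
r2, r2_vel = velocity_increment(table, 500e3)
print(f"velocity increment: {r2_vel - r2:.5f}")
```

prints

```
   100 kHz  slope=+1.018  R2=0.865  n=396
   500 kHz  slope=+1.032  R2=0.878  n=396
  1750 kHz  slope=+0.997  R2=0.869  n=396
velocity increment: 0.00029
```

i.e. peak intensity rises essentially linearly with particle volume on a
log-log scale (R² in the high 0.80s at every carrier), and velocity adds
no explanatory power — the flow does not sort particles by size.

The end-to-end comparison experiment trains the fine tree on three
pooled training runs and evaluates on an independent test run (~1/3 the
training size, its own device gain):

```python
from mmcyto.classify import experiment_from_config
report = experiment_from_config({"seed": 1})
print(report["summary"])
```

```
{'test_acc_electrical': 0.7107, 'test_acc_optical': 0.8143,
 'test_acc_multimodal': 0.8179}
```

showing the modality ordering the method exists to demonstrate: impedance
alone is weakest (absolute peak heights drift between devices and small
pulses are noisy), imaging alone is much better but mis-sizes one bead
product into its neighbour class, and fusing both repairs part of that
leak, with the full report carrying per-class TPR/TNR/FPR/FNR and
confusion matrices for every mode and frequency set.

A `mmcyto` command-line tool wraps the same pipeline
(`simulate`, `extract-optical`, `extract-electrical`, `fuse`,
`validate-regression`, `train`, `evaluate`, `experiment`); run
`mmcyto --help` for the options.

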