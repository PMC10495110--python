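# dcvpipe

Quantification pipeline for dense-core-vesicle (DCV) secretion and
trafficking imaging in neurons. It reimplements, as tested and reusable
code, the measurement procedures of a typical NPY-pHluorin / RUSH imaging
study:

- **Fusion-event detection** — NPY-pHluorin is quenched in the acidic DCV
  lumen and dequenches on fusion. Events are detected on 3×3-px ROI traces
  normalized as F/F₀ (F₀ = mean of the first 10 frames) with the classic
  criteria: amplitude ≥ 2 SD of the baseline F/F₀ and rise time < 1 s, on
  2 Hz recordings with 30 s baseline followed by electric-field
  stimulation (16 trains × 50 pulses @ 50 Hz).
- **Pool and released fraction** — an NH₄Cl pulse neutralizes every
  vesicle lumen and reveals the whole labelled pool; puncta are counted on
  the dequench difference image with an area-quotient correction for
  overlapping puncta. Released fraction = events / pool.
- **RUSH Golgi-flux kinetics** — after biotin releases the ER-retained
  SBP-EGFP-NPY cargo, the Golgi-region trace I(t), normalized to the
  pre-biotin baseline, rises to a peak and drains with first-order
  kinetics. The pipeline registers lateral drift, extracts the trace, and
  fits `I(t) = plateau + (I₀ − plateau)·e^(−k(t−t_peak))` to the decay
  phase for the export rate constant k (per minute) and the time-to-peak.
- **Kymograph transport analysis** — space-time plots along a neurite
  path, a deterministic particle tracer, and anterograde / retrograde /
  stationary classification with speeds (net displacement over duration).
- **Statistics** — SuperPlot-style nested comparisons (two-tailed unpaired
  t on biological-replicate means), 2^−ΔΔCt qRT-PCR fold changes with
  geometric-mean summaries and one-sample t on log₂FC, and EM morphometry
  derivations (diameter → volume change, prevalence changes, binned
  diameter distributions).

A first-class synthetic-data module generates movies for every experiment
type with known ground truth (puncta, event times and amplitudes, dequench
windows, Golgi kinetics, particle velocities) under a shot + read camera
noise model, so every stage of the pipeline is validated by parameter
recovery. See `docs/methods.md` for the full model descriptions and design
choices.

## Worked example

Simulate one neuron's secretion recording — 25 labelled vesicles, two
stimulus-locked fusion events, a terminal NH₄Cl pulse, realistic noise —
and run the full analysis:

```bash
dcvpipe simulate fusion --config fusion.yaml --out demo --seed 12
dcvpipe run demo/fusion.tif --out demo/out
```

with `fusion.yaml`:

```yaml
n_puncta: 25
punctum_min_separation: 8.0
image_shape: [96, 96]
nh4cl_window: [110.0, 120.0]
dequench_factor: 5.0
noise_gaussian_sd: 3.0
noise_poisson_scale: 2.0
events:
  - {punctum_id: 3,  onset_time: 35.0, peak_ratio: 2.0, rise_time: 0.25, decay_tau: 5.0}
  - {punctum_id: 11, onset_time: 42.5, peak_ratio: 2.2, rise_time: 0.25, decay_tau: 5.0}
```

prints

```json
{
  "n_events": 2,
  "mean_peak_ratio": 1.703855308569852,
  "events_per_window": {"pre": 0, "stim": 2, "post": 0},
  "raw_pool": 25,
  "pool": 25,
  "released_fraction": 0.08
}
```

Both simulated events are recovered, both fall in the stimulation window
(30–53.5 s), the NH₄Cl pool count matches the 25 simulated vesicles, and
the released fraction is 2/25 = 0.08. The mean F/F₀ peak (1.70) is below
the configured punctum peak ratios because the ROI average includes
background, which does not brighten with the vesicle.

The morphometry arithmetic works directly from printed group means — e.g.
a mean DCV diameter reduction from 71.52 nm to 65.01 nm and a drop from
17% to 12% of synaptic sections containing a DCV:

```bash
$ dcvpipe stats morph --d-control 71.52 --d-test 65.01 --p-control 17 --p-test 12
{
  "volume_change_pct": 24.89687973510216,
  "relative_change_pct": 29.411764705882348
}
```

i.e. ≈25% less volume per vesicle and ≈30% fewer DCV-containing sections.

Other subcommands: `dcvpipe simulate rush|kymo`, `dcvpipe detect-fusion`,
`dcvpipe quantify-pool`, `dcvpipe rush`, `dcvpipe kymo`,
`dcvpipe stats superplot|ddct`. Every command reads TIFF stacks with JSON
metadata sidecars and writes CSV/JSON results plus a manifest that makes
runs reproducible byte-for-byte.

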