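# radarbp

Contactless blood-pressure estimation from millimeter-wave FMCW radar
returns. The toolkit covers the whole measurement chain:

1. **Simulation** (`radarbp.sim`) — ground-truth chest/wrist skin-displacement
   traces (raised-cosine systolic pulse trains, chest respiration), raw
   complex IF frame cubes for a point target at 0.5 m, and whole synthetic
   cohorts in which blood pressure drives the pulse transit time (PTT) and
   systolic peak shape through known links.
2. **DSP** (`radarbp.dsp`) — fast-time range FFT, range-bin selection,
   least-squares (Kåsa circle-fit) DC compensation, arctangent phase
   demodulation, unwrapping, and conversion to displacement; optional
   zero-phase band-pass (0.7–10 Hz) for the chest respiration component.
3. **Features** (`radarbp.features`) — PTT via normalized cross-correlation
   between the chest and wrist traces, pulse wave velocity PWV = arm
   length / PTT, and the half-amplitude area-under-curve (AUC) sharpness
   feature averaged over the three most prominent peaks.
4. **Estimation** (`radarbp.estimate`) — third-order polynomial regressions
   (full bivariate basis for two inputs), a small fully connected network
   (hidden sizes 20 and 10, quasi-Newton/L-BFGS training, 5-fold
   cross-validation, 175/25 train/test split at 200 usable readings), and
   RMSE reporting over the {PWV, AUC, PWV+AUC} × {SBP, DBP} grid.
5. **Physiology** (`radarbp.physio`) — Moens–Korteweg and Hughes equations
   plus the BP = a·PWV² + b and BP = K1/PTT + K2 relations used both as
   reference models and as the simulator's ground-truth links.
6. **I/O + CLI** (`radarbp.io`, `radarbp.cli`) — portable `.npz` and raw
   int16 I/Q cube formats with JSON sidecars, CSV traces/cohorts/features,
   JSON reports, and run manifests with config hashes, file checksums and
   captured warnings.

## CLI

All stages are exposed through one `radarbp` entry point; `--seed` makes
every stochastic stage reproducible.

```sh
# synthetic cohort (5 subjects x 50 readings), optionally with raw IF cubes
radarbp simulate --subjects 5 --readings 50 --seed 1 --out runs/sim --write-cubes 1

# DSP chain: cubes -> displacement CSVs
radarbp process --chest runs/sim/cube_000_chest.npz \
                --wrist runs/sim/cube_000_wrist.npz --out runs/proc

# features from a displacement pair ...
radarbp features --chest runs/proc/chest_displacement.csv \
                 --wrist runs/proc/wrist_displacement.csv \
                 --arm-length 0.725 --out runs/feat.json

# ... or for a whole cohort
radarbp features --cohort runs/sim/cohort.csv \
                 --subjects-json runs/sim/subjects.json --out runs/features.csv

# polynomial fit and full evaluation grid
radarbp fit --features runs/features.csv --feature-set pwv --target dbp --out runs/model.json
radarbp evaluate --features runs/features.csv --seed 1 --out runs/report.json

# everything end to end
radarbp pipeline --seed 7 --out runs/full
```

Each command writes a `manifest_<stage>.json` recording the configuration
hash, software version, input/output checksums and all warnings emitted.

## Units

Seconds, meters and millimeters throughout the signal path; blood pressure
in mmHg. Feature CSV columns are fixed:
`subject_id, ptt_s, pwv_mps, auc_s, sbp_mmhg, dbp_mmhg, pp_mmhg`.
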