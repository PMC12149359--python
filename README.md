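# ustongue

Ultrasound B-mode monitoring of artificial-tongue deformation during
compression and shearing of food gels, rebuilt as a fully testable Python
pipeline. Because no recordings ship with the study, a synthetic speckle
phantom with analytic ground truth stands in for the bench: every estimator
is validated against the closed forms that generated its input.

Pipeline stages (one module each, under `src/ustongue/`):

| module     | role |
|------------|------|
| `protocol` | imposed motion schedule (15 mm compression at 2.5 mm/s, four shear strokes of 5/10/10/10 mm, 1.5 s rests), force/frame alignment, engineering strain |
| `phantom`  | synthetic B-mode frame stacks (scatterer field, Gaussian PSF or RF-carrier rendering, log compression), kinematic stick-slip deformation model, ground-truth surfaces/velocities, synthetic force traces |
| `preproc`  | frame conditioning chain: 2x10 Gaussian, 5x5 median, normalized edge gating at 0.6, 150-225 band threshold, dilations + clear-border + diamond erosion |
| `contour`  | open active-contour (snake) surface tracking at 100 lateral stations; px / mm (183 px per 10 mm) / two-way time-of-flight (1540 m/s) views; ToF fluctuation maps and deformation width |
| `piv`      | CLAHE, surface-anchored 370x105 px ROI, two-pass FFT PIV (64 then 32 px windows, 50% overlap, window deformation), validation + infill, surface velocity traces and depth profiles |
| `analysis` | friction-phase detection (onset/stop velocity peaks, static vs dynamic intervals, decay constants), residual deformation, Young's-modulus slope between 2.5% and 5% strain |
| `io`, `cli`, `config` | TIFF/PNG stacks with JSON sidecars, CSV/PNG exports, YAML run config, `ustongue` command line |

## CLI

```bash
ustongue simulate --config cfg.yaml --outdir out      # phantom stack + truth + forces
ustongue track    --stack out/stack.tif --outdir out  # contour tables, ToF maps
ustongue piv      --stack out/stack.tif --contour-csv out/contour_px.csv --outdir out
ustongue all      --config cfg.yaml --outdir out      # entire pipeline + figures
```

The config file is YAML with sections mirroring the module parameter sets
(`protocol`, `model`, `imaging`, `snake`, `roi`, `piv`, ...); omitted keys
take the published defaults. Every figure written by the CLI has a CSV twin
and each run emits a manifest with the config hash and seed.

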