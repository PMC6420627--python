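# fluidloop

Hardware-free automation stack for fluid-exchange microscopy experiments:

- **`fluidloop.kinematics`** — syringe-pump kinematics: volume ↔ motor-step
  conversion, flow-rate → step-period timing, and a seeded dispense-error
  simulator (diameter tolerance, step quantization, per-step jitter,
  backlash).
- **`fluidloop.network`** — a command/acknowledge bus connecting one
  controller to up to 128 syringe pumps plus a peristaltic extraction pump;
  length-prefixed ASCII framing and a fully in-memory simulated backend
  driven by an injected clock (tests never sleep).
- **`fluidloop.protocol`** — declarative fluid-exchange protocols
  (infuse/withdraw/extract/wait/await-event/notify) with validation, duration
  planning, chamber volume bookkeeping, execution logging, notification
  hooks, and the overflow loading model. Ships the 155-minute
  fixation/wash/permeabilise/stain/wash sequence as a factory.
- **`fluidloop.detection`** — unsupervised mitotic-rounding detection: Otsu
  segmentation + morphological opening, circularity `C = 4πA/P²` with a
  smoothed sub-pixel contour perimeter, per-FOV mean-circularity triggering
  (threshold 0.82) and the experiment-level 25 %-of-FOVs event rule.
- **`fluidloop.synth`** — deterministic synthetic time-lapse generator:
  spread (elongated) cells that round into discs at scheduled times, with
  Poisson + Gaussian noise, written as 16-bit TIFF stacks with a
  ground-truth manifest.
- **`fluidloop.calibration`** — dispense characterization (accuracy = mean
  error, precision = sample SD of the error, both as % of nominal; pass
  bound 5 %) and a least-squares per-pump calibration correction.
- **`fluidloop.orchestrator`** — the closed loop: live acquisition →
  detection → event → 15-min delay → fixation/staining protocol → post-fix
  z-stack plan, with phase tracking, manual-trigger support and notification
  hooks.

## CLI

```bash
fluidloop bus probe                         # enumerate the simulated bus
fluidloop bus send --address 0 --verb INFUSE --ul 100 --rate 300
fluidloop run protocol.yaml --log run.csv   # execute a YAML protocol
fluidloop synth --n-fov 45 --seed 42 --out stacks/
fluidloop calibrate --seed 42               # dispense characterization
fluidloop run-experiment --n-fov 45 --seed 42 --log experiment.csv
```

Protocol files are versioned YAML (`version: 1`, `steps:` list); execution
logs and per-frame trigger traces are CSV.

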