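# saccadekit

Hardware-free toolkit for standardized pro-/anti-saccade assessment:

- **protocol** — generates the standardized session schedule (10 pro practice,
  60 pro, 4 anti practice, 3×40 anti, 60 pro; 120 scored trials per task) with
  seeded side randomization and fore-periods drawn from [1, 3.5] s whose
  per-phase mean is exactly 1.5 s, plus the world-space stimulus geometry
  (8° eccentricity, 1° targets at 7 m).
- **eyedata_io** — TSV data model for per-frame binocular eye samples
  (two clocks, per-eye validity bitmask, openness, pupil diameter/position,
  gaze origin/direction) and trial-event logs; validity bit codec.
- **preprocess** — validity-31 cleaning, gaze-direction-to-degrees conversion
  (`atan(gd_x/gd_z)`, negative rightward), order-10 running-median despiking,
  task-specific trial segmentation ([100, 500] ms pro, [125, 750] ms anti),
  and time-aware velocity.
- **detect** — the five-case velocity-threshold saccade detector (normalized
  velocity, 0.5 peak / 0.25 onset thresholds, 1° / 0.001 no-movement
  criterion, sign-based direction errors with anti-saccade inversion, 3°
  reflexive-excursion rule) and per-task oculo-metric aggregation, including
  the pupil-position detection variant.
- **timing** — two-clock sampling-interval diagnostics: median / moving-average
  smoothing, sub-8 ms stabilization point, duplicate-frame detection
  (stalled-timestamp bug signature), and {8, 9, 16, 17} ms interval classes.
- **synthetic** — seeded binocular gaze-trace simulator with raised-cosine
  saccade kinematics, reflexive excursions, direction errors, noise, spikes,
  validity dropouts, pupil series, warm-up sampling regime, dropped frames,
  and duplicate reads, plus per-trial ground truth for recovery experiments.
- **cli** — `saccadekit protocol | simulate | analyze | timing`.

## Command-line usage

```sh
# 1. generate the standardized session schedule
saccadekit protocol --seed 0 --out runs/proto

# 2. simulate a recording of that schedule
saccadekit simulate --protocol runs/proto/protocol.tsv --seed 1 --out runs/sim

# 3. detect saccades and aggregate latency / peak velocity / error rate
saccadekit analyze --samples runs/sim/samples.tsv --events runs/sim/events.tsv \
    --out runs/metrics

# 4. sampling-interval diagnostics only
saccadekit timing --samples runs/sim/samples.tsv --out runs/timing --intervals-tsv
```

`analyze` writes `metrics.json` / `metrics.tsv` (one row per task × eye ×
signal kind, both-eyes rows pooled) and `timing.json`; `simulate` writes the
sample/event/ground-truth TSVs and the resolved simulator configuration.

## Python API sketch

```python
from saccadekit import (
    generate_session_protocol, simulate_session, analyze_session, timing_report,
)
from saccadekit.synthetic import SimConfig

proto = generate_session_protocol(seed=0)
sim = simulate_session(proto, SimConfig(), seed=1)
results, metrics = analyze_session(sim.samples, sim.events)
report = timing_report(sim.samples)
```
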