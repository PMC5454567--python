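# legdose

Simulation and analysis pipeline for thermally monitored leg-exercise
training. A furniture-mounted leg-training device is instrumented with a
temperature sensor on its resistance unit; the exercise-induced temperature
rise (Δt°, zeroed at each session start) is a proxy for mechanical work
output. `legdose` provides:

- **`legdose.device_simulator`** — a seeded generator of minute-resolution
  telemetry (temperature, heart rate, SpO2, blood pressure) for five session
  protocols: moderate continuous training (MICT, 10–120 min), the fixed
  30-minute dosed MICT at 100±10 BPM, a 10-cycle high/moderate interval
  protocol (25 min), and two opportunistic kinds (under-desk, in-bed) with
  stochastic break structure. The thermal model is a linear first-order
  system (`dT/dt = k·P − λ·(T − ambient)`); heart rate follows a first-order
  response with a self-pacing controller for HR-banded protocols.
- **`legdose.telemetry_io`** — validated CSV/JSON readers and writers
  (lossless, byte-stable round trips).
- **`legdose.session_analysis`** — Δt° traces, slope-based active-bout
  segmentation, deterministic regimen classification (MICT / HIIT /
  opportunistic), mobilization minutes, and model-inverted power estimates.
- **`legdose.dose_engine`** — personalized daily doses (Δt° at minute 30 of
  a calibration session), dose-progress fractions, per-day debounced
  threshold-crossing notification events, incomplete-bout detection, weekly
  adherence (compliant ⇔ dose taken on ≥ 5 days), and cohort tick/cross
  tables.

## CLI

```sh
# one session, or a week of dose sessions
legdose simulate --protocol hiit_wingate --seed 1 --out-dir out/
legdose simulate --dose-days 1,3,4,5,7 --seed 3 --out-dir week/

# per-session metrics and bouts
legdose analyze --telemetry week/telemetry.csv --boundaries week/boundaries.csv --out-dir week/

# dose calibration -> events -> weekly adherence
legdose calibrate --telemetry calib/telemetry.csv --boundaries calib/boundaries.csv --out rx.json
legdose dose-events --telemetry week/telemetry.csv --boundaries week/boundaries.csv \
    --prescription rx.json --out events.csv
legdose report --events events.csv --week-start 2026-01-05 --out-dir report/

# end-to-end cohort run from a config file
legdose pipeline --config examples/demo_cohort.json --out-dir run/
```

Exit codes: 0 success, 2 usage, 3 validation, 4 I/O. Every run is
bit-reproducible for a fixed `--seed`.

### File formats

Telemetry CSV: optional `# key=value` comment lines, then
`timestamp,temperature_c,heart_rate_bpm,spo2_pct,systolic_mmhg,diastolic_mmhg`
with ISO-8601 local timestamps, one row per minute; missing minutes are
absent rows, missing channels empty cells. Session boundaries:
`session_id,start,end,zero_reference_c`. Profiles/prescriptions: flat JSON
(see `legdose.telemetry_io`).

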