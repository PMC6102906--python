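# neurochair

A desk-scale, fully simulated re-implementation of a hybrid brain–computer
interface (BCI) control stack for a smart wheelchair with a robotic arm.
The package is aimed at BCI and assistive-robotics researchers who want to
study the *system-level* behaviour of such a stack — decoder accuracy,
validation latency, shared-control logic, task success — without hardware,
amplifiers or human subjects.

## What the system does

A user selects a target (a person, a door, a bottle of water, …) through a
**P300 oddball BCI**: six stimuli are intensified in random order for 120 ms
with 80 ms intervals, so one sequence of six takes 1.2 s and a standard
3-sequence trial takes 3.6 s. For each stimulus onset, the 800 ms of EEG
that follows is band-pass filtered to 2–25 Hz, decimated by block-means, and
scored by a **stepwise linear discriminant analysis (SWLDA)** classifier:

- stepwise regression of the ±1 target/nontarget label on the epoch
  features: the forward step adds the candidate with the smallest partial-F
  p-value (if < `p_enter`), backward steps drop included features with
  p > `p_remove`, stopping at `max_features`;
- each epoch's score is `w·x + b`; scores are summed per stimulus across
  sequences, and the trial output is the **argmax over the currently
  detected targets only** (≤ 6), which is why accuracy improves when fewer
  targets are present.

Selections are confirmed by a myoelectric **validation command**: the single
EMG channel is cut into 200 ms windows, filtered to 55–77 Hz, and each
window's variance is thresholded at 1500. The last four binary decisions
pass through a FIFO queue; the pattern `[1,1,0,0]` (clench, then two quiet
windows) fires the command exactly **0.4 s after the clench ceases**.

Around the BCI sits a shared-control state machine (auto-control and
command-control modes alternately pre-activated every 3 s), a perception
module (60 % bounding-box shrink → floor filter → point-cloud centroid;
PCA-based horizontal orientation using the v/vn/f rule), a rule-based
target-solution planner (stop 0.80 m from conversation targets, 0.20 m from
desks/beds/closed doors, pass through opened doors, arm-pick bottles and
cups inside the arm workspace), and a 2D holonomic wheelchair simulator
(0.1–0.4 m/s, 70 cm footprint, 5 cm occupancy-grid A*) that replays scenario
task lists and computes the evaluation metrics **TrP3, TiP3, VT, FV, SR**
and **EP/NV** deductions.

All signals are synthetic and seeded: EEG with a Gaussian-bump P300 template
on an oddball schedule, EMG with band-limited rest/clench regimes, and
depth-camera-style point clouds with ~1 cm noise.

## Worked example

Calibrate the decoder on a synthetic 60-trial session (five sets of 12
trials), then run three closed-loop sessions of scenario A — go to the desk,
pick up a bottle, drink, reverse, turn, pass the 80 cm door, turn, approach
a walking person, talk — with the trained decoder in the loop:

```sh
$ neurochair calibrate --seed 1 --out out/cal
selected 60/192 features; cross-validated trial accuracy 1.000 (chance 0.167)
model written to out/cal/swlda_model.json

$ neurochair run-scenario --scenario A --sessions 3 --seed 7 \
      --model out/cal/swlda_model.json --out out/run
session  TrP3  TiP3       VT  FV  SR  EP  NV
      1   1.0   3.6 1.779643 0.0 1.0 0.0 0.0
      2   1.0   3.6 1.689843 0.0 1.0 0.0 0.0
      3   1.0   3.6 1.692986 0.0 1.0 0.0 0.0
   mean   1.0   3.6 1.720824 0.0 1.0 0.0 0.0
    std   0.0   0.0 0.050963 0.0 0.0 0.0 0.0
```

Reading the output: `TrP3` is the mean number of 3.6 s P300 trials needed
per correct selection (1.0 = every prediction right first time at this
synthetic SNR); `TiP3 = TrP3 × 3.6 s`; `VT` is the delay from a correct
prediction to the validated confirmation (reaction time + clench + the
0.4 s detector latency); `FV` counts spurious validations; `SR` is the
session success rate; `EP`/`NV` count environment-perception and navigation
deductions. Per-session JSONL event logs and a reproducibility manifest
(config hash, seed, versions) are written next to `metrics.csv`.

Other commands: `neurochair validate-emg --in trace.csv` (detect jaw-clench
validations in a signal file) and `neurochair plan-demo --cls person --x 2`
(show the planned solution for a single target).

## Layout

- `src/neurochair/synth_signals.py` — stimulus schedules, synthetic EEG/EMG
- `src/neurochair/p300_decoder.py` — filtering, epochs, SWLDA, classification
- `src/neurochair/emg_validator.py` — windowed-variance FIFO detector
- `src/neurochair/perception.py` — simulated sensing, localization, PCA orientation, tracking
- `src/neurochair/planner.py` — solution rules, prioritization, state machine
- `src/neurochair/sim_env.py`, `session.py`, `scenarios.py` — 2D simulator, closed loop, metrics
- `src/neurochair/cli.py`, `config.py`, `io.py` — CLI, YAML config, file formats
- `docs/methods.md` — models, assumptions, parameter choices, limitations
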