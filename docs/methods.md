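# Methods

This note documents the models behind the simulation, the parameter choices
that matter, and what the synthetic setting does and does not establish.

## Synthetic EEG and the P300 model

One selection trial intensifies each of the six stimuli once per sequence in
seeded-random order (120 ms on, 80 ms off; stimulus-onset asynchrony 0.2 s),
with 3 sequences per trial by default so a trial spans 6 × 0.2 s × 3 =
3.6 s. EEG is generated at 500 Hz on the 12 listed scalp channels
(F3…P4); the hardware description mentions both "8 electrodes" and this
12-name list, so the channel set is configurable and the full list is the
default.

The attended stimulus adds a Gaussian bump to every channel:
amplitude × exp(−(t − onset − 300 ms)² / 2σ²) with σ = 60 ms, scaled by a
per-channel gain that peaks at Pz and decays linearly along the channel
list. Any smooth template peaking near 300 ms would serve; nothing
downstream depends on the exact shape. Background noise is white by default
(std 10 µV) with a 1/f option. Defaults give a clean decodable signal
(single-trial accuracy near 1 at 3 sequences); lowering the amplitude or
raising the noise produces the degraded regimes used in the monotonicity
tests.

## SWLDA decoding

Epochs are the 800 ms after each onset (consecutive epochs overlap; no
overlap correction is attempted). The causal 4th-order Butterworth band-pass
(2–25 Hz) is used for both calibration and online decoding so train and test
see the same filter transient. Features are block-means of 25 samples
(400-sample epoch → 16 features/channel, 192 total with 12 channels).

Training is classical stepwise regression on ±1 labels: forward entry at
the smallest partial-F p-value < 0.10, backward removal at p > 0.15, at most
60 features. `p_enter ≤ p_remove` is enforced to prevent entry/removal
cycling, and exactly collinear candidates are skipped. Weights are the OLS
coefficients of the final selected design. The implementation computes
partial-F values by residualization against a QR factorization of the
current design; the test suite checks exact agreement (selection order,
weights, intercept) with a brute-force oracle that refits statsmodels OLS
for every candidate at every step.

Per-stimulus scores are summed across sequences (equivalent to the mean for
an argmax) and the classification is restricted to the candidate set of
currently displayed targets, with ties broken toward the lowest index.
Because restriction to a subset containing the attended target can only
preserve or repair a decision made on the same scores, restricted accuracy
is never lower trial-by-trial — the property the online system exploits.

## EMG validation command

The detector consumes contiguous, non-overlapping 200 ms windows aligned to
the trace start, filters each window causally to 55–77 Hz, and thresholds
the window variance at 1500 (µV² on the filtered signal). The binary
decisions feed a length-4 FIFO (oldest first); `[1,1,0,0]` fires the
command, so the latency from (grid-aligned) clench cessation to the fire is
exactly 2 windows = 0.4 s. A fire clears the FIFO so a single clench cannot
fire twice, and clenches shorter than ~0.4 s may be missed — that is the
debouncing intent of the pattern.

The synthetic EMG is band-limited Gaussian noise with a rectangular clench
envelope. The windowed variance of such a signal has only ≈ 2·B·T ≈ 8.8
effective degrees of freedom (B = 22 Hz, T = 0.2 s), i.e. it is χ²-like with
heavy tails, so the rest/clench levels must leave generous margins around
the 100/1500 decision bounds. The defaults — rest in-band std 5 µV (mean
window variance ≈ 17) and clench 300 µV (mean ≈ 6 × 10⁴) — were calibrated
analytically against those tails so that 10⁴ consecutive windows stay on the
correct side of both bounds; jaw-clench artifacts at fronto-central sites
genuinely reach hundreds of µV, so the clench level is physiologically
plausible.

## Perception

The simulated camera is a 640×480 pinhole with a 57° horizontal field of
view, mounted 1.5 m high and pitched down 37° (the depression angle is a
free parameter). Objects inside the view cone and range produce a pixel
bounding box and a point cloud sampled on their camera-facing surface
(cylinder arc or visible box faces) with 1 cm Gaussian noise, matching the
stated point-cloud accuracy; misses and false detections are injectable.

Localization shrinks the bounding box linearly to 60 % per side about its
centre, keeps the cloud points whose pixels fall inside, drops points below
10 cm off the floor, and returns the arithmetic mean. Note this centroid
estimates the *visible face*, not the volumetric centre — for a desk the
perceived position is its front face, which is also the natural reference
for a docking distance. Orientation projects the cloud to the floor plane
and takes the first principal axis v (SVD); the axis returned is v or its
in-plane orthogonal vn, whichever makes the smaller sign-invariant angle
with the wheelchair-to-target vector f, signed so that it points back at the
wheelchair (face-to-face semantics). Clouds whose singular-value ratio is
below 1.2 are treated as isotropic and fall back to −f with a degeneracy
flag. Tracking re-runs sensing on the confirmed object each update and
raises a tracking failure (an EP deduction downstream) when the object
leaves the view cone.

## Target solutions and the state machine

The ten classes partition into four groups: person/chair/sofa (stop 0.80 m
away, facing), bed/closed door/desk (0.20 m, facing), opened door (reach,
then pass through), and switch/bottle/cup (translate until the target is in
the arm workspace, then press or pick + bring to mouth). Standoff goals lie
along the target's orientation vector at the group distance; the goal
position is the chassis *front* docking point, so the stopping position is
exactly 0.80 m / 0.20 m from the perceived target centre while the chassis
body stays clear. The arm workspace is the box x ∈ (−200, 0) mm,
y ∈ (0, 350) mm, z ∈ (−150, 300) mm in the arm frame (arm origin 0.6 m above
the floor on the left armrest); the target's z is checked *first* because
the planar chassis cannot change height — an unreachable z rejects the
operation outright. The manipulation docking pose turns the chassis
sideways-on (target to the left, where the arm is) and biases the grasp
point outboard (70 % of the lateral range) to keep the chassis clear of the
furniture the object stands on.

The pass-through goal is 0.8 m beyond the doorway centre. Half the 1.2 m
footprint (0.6 m) would clear the door plane at rest, but the task scripts
turn in place immediately after passing, and the footprint's circumscribed
radius is 0.69 m; 0.8 m also clears that rotation envelope.

The shared-control state machine alternates the pre-activated mode
(auto/command) every 3 s of simulated time, holds command mode when no
targets are detected, enters P300 selection on a validation, requires a
second validation to execute the predicted item, lets another validation
cease a command-mode execution, and resets to mode selection on completion,
collision, or a planner deadloop.

## Simulator and sessions

The chassis is holonomic with speed clamped to [0.1, 0.4] m/s when moving,
a 0.70 m × 1.2 m rectangular footprint (length is a package choice), and a
10 Hz control loop. Paths come from A* on a 5 cm occupancy grid inflated by
the footprint *half-width* (0.35 m): that inscribed-radius inflation is what
leaves the printed 5 cm margin per side in an 80 cm doorway, and it is valid
because navigation legs rotate in place at their start (in open space, by
construction of the solution goals) and then translate with the heading held
fixed, so the long axis stays aligned with the path through tight gaps.
A post-hoc sweep test verifies that the footprint never intersects an
obstacle over every logged pose of an accepted session.

Doorway transit needs lateral accuracy better than ±5 cm while a single
sensing frame localizes the door to ~4 cm; the session therefore averages
eight tracked frames at the pre-door pose (≈1.4 cm standard error) before
crossing — the same continuous re-localization the tracking contract
provides.

Scenario A (sickroom + gallery: desk with bottles, 80 cm opened door,
walking person) and scenario B (two furnished rooms) replay the printed
task tables. Scenario B's step 8 ("pick up the bottle") is executed in
auto-control because the six direct commands cannot actuate the arm. Room
dimensions are plausible reconstructions, not measurements. The walking
guest starts moving (0.5 m/s) when the wheelchair comes within 2.5 m and
stops at the corridor end; at these speeds it stays inside the view cone, so
tracking succeeds — a faster guest reproduces the tracking-failure EP event.

The simulated user has a clipped-Gaussian reaction time (0.5 ± 0.15 s)
between seeing a correct prediction and clenching; each validation is a real
synthesized clench passed through the detector, so VT = reaction + 0.2 s
lead + 0.6 s clench + 0.4 s latency ≈ 1.7 s. Metrics follow the evaluation
definitions: TrP3 = mean trials per correct selection, TiP3 = TrP3 × 3.6 s,
VT = mean confirmation delay, FV = validations beyond the necessary ones,
SR = completed sessions, EP/NV = perception/navigation deductions
(localization and tracking failures are EP; planning failures and collisions
are NV).

## Numerical choices and limitations

- Filters are causal Butterworth SOS everywhere online; synthetic band
  limiting uses zero-phase filtering so burst energy stays inside its
  interval.
- Classification ties break to the lowest stimulus index; stepwise ties on
  p-values break to the lowest feature index.
- Degenerate inputs: single-class training data, empty candidate sets,
  empty clouds after filtering, overlapping clench intervals and
  Nyquist-violating bands all raise explicit errors.
- Session-level problem sizes (60-trial calibration, 100-window EMG
  contracts, 200-trial restriction comparisons, 20-seed scenario sweeps)
  were chosen to make the Monte-Carlo checks sharp at desk scale.
- What passing tests show: the *pipeline logic* — timing, thresholds,
  geometry, state transitions, metric arithmetic — behaves as specified
  under signals with the assumed statistical structure. They do not show
  performance on real EEG/EMG (no artifacts other than jaw clench, no
  non-stationarity, no volume conduction), real detection (the detector and
  tracker are simulated stand-ins for a trained network and a correlation
  tracker), or real dynamics (no inertia or wheel slip). Human-subject
  outcome levels are therefore out of scope by design.
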