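# Methods

This note records the models the package implements, the defaults it ships,
and the design decisions taken where the method description left the design
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Kinematic model

The skeleton has a torso reference frame (origin at the upper chest) and
eight instrumented limb segments.  An attitude (pitch θ, roll γ, yaw φ, in
radians) defines the navigation-to-body rotation as the ordered product

    C = Roll(γ, y-axis) · Pitch(θ, x-axis) · Yaw(φ, z-axis).

Other Euler conventions exist; this one is fixed, documented, and pinned by
a term-by-term unit test (θ = π/2 alone gives rows (1,0,0), (0,0,1),
(0,−1,0)).  A segment's long axis is its body-frame x-axis, so a child
joint is `length · first_column(C_torso · C_segmentᵀ) + parent`.  Limb
lengths (upper arm 0.30 m, forearm 0.25 m, thigh/shank 0.40 m) and the
shoulder (±0.20, 0, 0) / hip (±0.10, 0, −0.50) anchors are plausible adult
proportions, all overridable through `BodyModel`.  Limb-length conservation
to 1e-9 is the module's invariant test.

The CSV attitude reader accepts degrees behind a flag because sensor
datasheets quote precision in degrees; everything internal is radians.

## State estimation

Per joint and axis the state is (position, velocity) with
T = [[1, δt], [0, 1]], position-only measurements, and a white-acceleration
process noise Q = q·[[δt³/3, δt²/2], [δt²/2, δt]].

Defaults, with reasoning:

| parameter | default | why |
|---|---|---|
| δt | 0.01 s | 100 Hz sensor rate |
| q | 1 m²/s³ | limb accelerations ~1 m/s² with sub-second correlation: q ≈ a²_rms · 2τ |
| r (vision) | (0.02 m)² | depth-camera white noise class |
| r (IMU branch) | (0.055 m)² | white noise *plus* typical accumulated drift over a minute-scale segment at 0.01 m/√s; see below |
| r (ELM branch) | (0.02 m)² | ELM 1 is trained against the vision solution, so its output noise is vision-class |
| N (FIR horizon) | 10 samples | 0.1 s of data; optimal-horizon search is out of scope |
| initial velocity variance | 1 m²/s² | loose prior on limb speed |

The IMU-branch measurement variance is the one genuinely consequential
choice.  Budgeting only the 5 mm white jitter makes the IMM prefer the IMU
model purely through its sharper likelihood density (the probability locks
at μ_IMU ≈ 1 and the fused track follows the drift); the branch's real
error budget is dominated by the random-walk drift the generator itself
defines, and the default reflects that.

**UFIR filter.** The window estimate initialises by exact batch least
squares on the first D = 2 position samples, with the generalized noise
power gain H = (CᵀC)⁻¹ from the same observation stack, then absorbs the
remaining window samples through H_j = (GᵀG + (T H_{j−1} Tᵀ)⁻¹)⁻¹,
K_j = H_j Gᵀ.  For this model the result is algebraically the ordinary
least-squares line fit evaluated at the window end — the filter needs no Q
or R, which is its robustness argument.  Because the gain sequence is
data-independent, the estimate is a fixed linear functional of the window;
the stateful filter and the series routines apply that precomputed
coefficient matrix, and a test pins them to the explicit iteration at
1e-10.  During the dead zone (fewer than N samples) a Kalman filter
substitutes bit-for-bit.

**IMM.** Two-model bank, Markov matrix Γ = [[0.95, 0.05], [0.05, 0.95]],
μ₀ = (0.5, 0.5) (neither is prescribed anywhere; both configurable).
Innovations are evaluated in measurement space (G·x̂).  Likelihoods are
floored at 1e-300 before normalisation so a far-outlying measurement cannot
zero the whole update; if every likelihood still vanishes the update falls
back to the predicted probabilities with a logged warning.  A model whose
predicted probability reaches exactly zero keeps its own unmixed state.
Mixing is what exposes a drifting branch: each model's prior is pulled
toward the consensus, so a branch that wanders away accumulates innovation
and loses probability.

**RTS smoothing** is fixed-interval over each contiguous vision-available
segment.  True online operation would need a fixed-lag variant; that
trade-off is deliberate and the smoother is only ever run on completed
segments.

## ELM regression

Hidden weights and biases are drawn once from seeded uniform(−1, 1)
(numpy PCG64; the same seed rebuilds the model bit for bit), inputs are
z-scored with training statistics stored in the model, and output weights
solve the hidden activation matrix against the targets by Moore–Penrose
pseudoinverse.  No ridge term: with hidden size ≥ sample count the model
interpolates (tested to 1e-6 relative), which a regularised solve would
break.

`elm_train`'s generic default of 100 hidden units suits function-fitting
tasks (the sin-regression test uses it).  The *pipeline* models use 32
units, and this is a deliberate, measured choice: the pipeline's networks
map 3-D joint positions that lie on a low-dimensional motion manifold, and
a large random-feature bank fitted by exact pseudoinverse develops large
mutually-cancelling output weights.  On the manifold the cancellation is
exact; on the drifted inputs an outage produces it fails, and the bridge
degrades below the raw IMU solution.  The output-weight norm is the
diagnostic: it grows monotonically with hidden size while bridge accuracy
falls, with a wide stable plateau up to ~32 units.

Two domain guards apply at prediction time, identically in the FIR and KF
variants: inputs are projected onto the training input box, and outputs
(ELM 1 positions, ELM 2 corrections) are clamped to their training-range
envelope widened by 10 % — random-feature fits carry no information outside
the region they were fitted on, while joint positions and residual
corrections live in a bounded workspace.

Whether the two mappings should be per-joint or shared is not specified
anywhere; the implementation trains per-joint models (matching the
per-joint filter structure), and the question only matters if training
data are scarce.

## Pipeline orchestration

Per joint, the availability mask is segmented independently.  Each
available segment runs branch filters → IMM → RTS and, when at least
`min_train_len` = 50 samples (0.5 s) long, retrains ELM 1/ELM 2 — so the
models in force during an outage always come from the immediately
preceding segment, which matters because ELM 1 can only compensate the
drift regime it has seen.  FIR filter 3 runs continuously across segment
boundaries (its window carries over), which keeps the hand-over jump at an
outage onset within the filter's normal step scale.  An outage that
precedes any trainable segment is bridged by filtering the raw IMU
positions, with a logged warning.  ELM 2's correction is additive, the
natural reading given its training target is a difference.

The ELM/KF baseline replaces every FIR filter with a Kalman filter sharing
the same Q, R and δt; everything else is identical.

## Evaluation

Per-axis RMSE; the "Mean" statistic is the arithmetic mean of the three
axis RMSEs (worked-example tests pin this convention to published-style
table rows at one unit in the last printed decimal).  The CDF readout is
the empirical q-quantile (default 0.9) of the per-step Euclidean error,
linear interpolation between order statistics.  Improvement between
methods a (baseline) and b is 100·(a−b)/a.  Reports can be restricted to a
boolean step selection, which is how outage-window accuracy is measured.

## Synthetic scenario

The generator emulates the statistical structure the method assumes, not
any particular recorded motion:

- attitudes: per segment and angle, four sinusoids with frequencies drawn
  from 0.1–0.5 Hz, random phases, amplitudes summing to ~0.5 rad (torso
  scaled to 0.3×) — smooth band-limited pseudo-motion;
- IMU error: random walk with rate 0.01 m/√s plus 0.005 m white noise;
- vision error: 0.02 m white noise;
- outages: Poisson(3) intervals per joint, uniform 1–3 s, positions uniform
  over the 60 s record, drawn independently per joint.

Everything derives from one integer seed.  What passing tests therefore
show is that the method behaves as designed under its own assumptions
(white vision noise, random-walk drift, smooth quasi-periodic motion).
They do not show robustness to the things real recordings add — soft-tissue
artefacts, vision outliers and identity switches, non-stationary drift,
heteroscedastic depth noise, or calibration error between the two systems.
Under these well-specified conditions the matched-noise Kalman baseline is
near-optimal, so the FIR variant's margin over it is small (fractions of a
percent in the 20-seed means computed by the acceptance suite); the FIR
variant's practical appeal is that it needs no noise statistics at all.

## Numerical choices

- Covariances are re-symmetrised after every update; innovation solves use
  `np.linalg.solve`, never explicit inverses, and a singular predicted
  covariance in the RTS pass is ridge-regularised (1e-12·I) with a logged
  warning.
- The sigmoid argument is clipped at ±500 (saturation is exact there in
  double precision).
- Quantiles use numpy's default linear interpolation; the convention is
  configurable at the call site.
- Per-joint ELM seeds derive deterministically from the config seed and the
  joint index, so a whole run is reproducible from its config file.

## Problem sizes

The simulation suites use the default 60 s / 100 Hz / 8-joint scenario.
The 20-seed comparisons in the test suite and the 10+5-seed summaries in
`scripts/acceptance.py` were sized so the whole check runs in minutes on a
single CPU while the Monte-Carlo error of the compared means stays an order
of magnitude below the effects being asserted.

## Known limitations

- The FIR horizon is fixed, not optimised; minimum-variance horizon
  selection is a separate problem.
- ELM 1 maps position to position and cannot disambiguate two visits to the
  same position under different drift; retraining per availability segment
  mitigates but does not remove this.
- The IMM bank is fixed at two constant-velocity models.
- `run_prediction_stage` advances FIR 3's state in place; reload a saved
  `TrainedFusion` to repeat a prediction from the same state.
- No quaternion attitude interface and no orientation estimation from raw
  inertial data: attitudes are taken as the IMU's own output.
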