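# mocapfusion

Wearable inertial motion capture drifts; depth-camera (Kinect-style) skeleton
tracking is accurate but drops out whenever the subject is occluded.
`mocapfusion` fuses the two for an eight-joint skeleton (elbows, wrists,
knees, ankles) and keeps producing positions through vision outages.  It is
aimed at people building wearable-sensor motion-capture pipelines who need a
tested, reproducible reference implementation of FIR/IMM-based fusion with
learned outage bridging.

## Method

**Forward kinematics.** Each body segment carries an IMU reporting pitch,
roll and yaw (θ, γ, φ).  The navigation-to-body rotation is the product
Roll(γ)·Pitch(θ)·Yaw(φ); a joint sits at its segment length along the first
column of the torso-relative rotation, chained shoulder → elbow → wrist and
hip → knee → ankle.

**Per-joint filtering.** Positions follow a constant-velocity model
x_{t+1} = T x_t + w, z_t = G x_t + v with T = [[1, δt], [0, 1]] per axis and
white-acceleration process noise.  Three estimators run on it:

- a Kalman filter;
- an *unbiased FIR (UFIR) filter*: state recovered from only the last N
  measurements via the gain recursion
  H_j = (GᵀG + (T H_{j−1} Tᵀ)⁻¹)⁻¹, K_j = H_j Gᵀ, which needs no noise
  statistics and equals the batch least-squares fit at the window end.
  While the window is unfilled (the *dead zone*, t < N) a Kalman filter
  substitutes, bit for bit;
- a Rauch–Tung–Striebel fixed-interval smoother.

**IMM fusion.** Two filters — one tracking the IMU branch, one the vision
branch — are combined by an interacting-multiple-model cycle: Markov mixing
(Γ), per-model update, Gaussian innovation likelihoods Λ_m, probability
update μ_m = Λ_m c̄_m / c, and a probability-weighted combination with a
spread-of-means covariance term.

**Outage bridging (the two-stage ELM scheme).** While vision is available,
two extreme learning machines — single hidden layers with random weights and
pseudoinverse-solved output weights — are trained per joint: ELM 1 maps the
IMU position to the vision position, and ELM 2 maps ELM 1's output to the
residual between the smoothed IMM estimate and a third FIR filter tracking
ELM 1.  During an outage the IMU position drives ELM 1 directly, FIR 3
filters its output, and ELM 2's correction is added.  The ELM/KF baseline is
the identical scheme with every FIR filter replaced by a Kalman filter.

Because no public recording accompanies the method, the package ships a
first-class synthetic generator: band-limited random attitude trajectories
through the forward kinematics, IMU random-walk drift plus white noise,
vision white noise, and independent per-joint outage intervals.

## Worked example

```python
import numpy as np
from mocapfusion import (MotionScenario, make_streams, FusionConfig,
                         run_full, run_baseline_elm_kf, compute_report,
                         improvement_percent)

streams = make_streams(MotionScenario(), seed=1)  # 60 s at 100 Hz, 8 joints

config = FusionConfig()
positions, report = run_full(streams, config)     # ELM/FIR variant
baseline, _ = run_baseline_elm_kf(streams, config)

outages = ~streams.available
ours = compute_report(positions, streams.truth, select=outages)
theirs = compute_report(baseline, streams.truth, select=outages)
raw = compute_report(streams.imu, streams.truth, select=outages)

print(f"overall mean RMSE    : {report.overall_mean_rmse:.4f} m")
print(f"outage RMSE ELM/FIR  : {np.nanmean(ours.mean_rmse):.4f} m")
print(f"outage RMSE ELM/KF   : {np.nanmean(theirs.mean_rmse):.4f} m")
print(f"outage RMSE raw IMU  : {np.nanmean(raw.mean_rmse):.4f} m")
print(f"improvement over IMU : "
      f"{improvement_percent(np.nanmean(raw.mean_rmse), np.nanmean(ours.mean_rmse)):.1f} %")
```

prints

```
overall mean RMSE    : 0.0136 m
outage RMSE ELM/FIR  : 0.0387 m
outage RMSE ELM/KF   : 0.0393 m
outage RMSE raw IMU  : 0.0420 m
improvement over IMU : 7.9 %
```

Over the whole recording the fused track is accurate to ~1.4 cm.  Inside
vision outages the learned bridge (3.9 cm) clearly beats the drifting raw
IMU solution (4.2 cm on this seed; the gap widens as drift accumulates), and
the FIR variant edges the KF baseline.

The same flows are available from the shell:

```bash
mocapfusion --seed 1 simulate --out streams.csv
mocapfusion run --input streams.csv --method elm-fir --out pos.csv --report report.csv
mocapfusion evaluate --estimates pos.csv --streams streams.csv --out report.csv
```

See `docs/methods.md` for the model details, parameter defaults and known
limitations.

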