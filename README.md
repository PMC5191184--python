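# gaitvel

Ambulatory estimation of the instantaneous 3-D velocity of the pelvis during
walking, from two body-worn inertial measurement units (IMUs): one on the
pelvis and one on a shank.

## Who this is for

Gait analysts and wearable-sensing researchers who want pelvis (≈ body
center of mass) velocity outside the motion-capture lab — for ambulatory
estimates of walking speed, external work, or gait symmetry — using only a
pelvis IMU, a shank IMU, and an orientation estimate for the pelvis sensor.

## The model

During steady-state walking the pelvis velocity is quasi-periodic, locked to
the gait cycle.  It is modeled as the sum of

* a **cyclical component** — zero-mean and stride-periodic, resolved in the
  medio-lateral (ML), vertical (VT) and antero-posterior (AP) directions —
  and
* the **average progression velocity (APV)** — the forward speed averaged
  over each gait cycle.

Each stride of pelvis linear acceleration (gravity removed by strap-down
rotation with the pelvis orientation quaternion) is fitted, per axis, with a
truncated Fourier series with the stride time *T* as fundamental period,

    acc(t) = a0 + Σ_{i=1..M} ( a_i sin(i·2πt/T) + b_i cos(i·2πt/T) ),   M = 6,

whose analytic time integral with the DC term removed is the cyclical
velocity,

    vel(t) = (T/2π) Σ_{i=1..M} (1/i) ( −a_i cos(i·2πt/T) + b_i sin(i·2πt/T) ).

Gait cycles are delimited by foot-strike (FS), flat-foot (FF), heel-off (HO)
and toe-off (TO) events detected from the shank ML angular velocity with a
**four-state left-right hidden Markov model** (circular topology, 3-mode
Gaussian-mixture emissions over the signal and its first time difference,
Viterbi decoding), trained supervised from labeled recordings.

The APV is predicted per stride by a **Bayesian linear regression with
automatic relevance determination (ARD)** over a d = 6M + 4 = 16 dimensional
feature vector (M = 2): the stride time, the FS→FF / FS→HO / FS→TO
durations, and the phase-angle harmonic amplitudes of the six shank
channels.  Each weight w_i carries a zero-mean Gaussian prior with its own
precision β_i; hyperparameters are learned by evidence maximization with the
classical fixed-point updates

    γ_i = 1 − β_i Σ_ii,   β_i = γ_i/μ_i²,   1/α = ‖v − Φμ‖²/(N − Σ γ_i),

and features whose prior precision grows beyond 200× the noise precision α
are pruned from the model.  Instantaneous velocity is the cyclical component
plus the predicted APV on the AP axis.

Method agreement is quantified with Bland–Altman limits of agreement using a
regression correction for non-uniform differences (bias and spread both
linear in the measurement magnitude), and with the two-stage error
statistics MBE, RMSE and ARMSE in which per-subject means are aggregated
before averaging across subjects.

Because no public recordings accompany the method, the package ships a
first-class synthetic-gait generator (`gaitvel.simulate`) that produces
pelvis and shank IMU trials with known stride events, harmonic coefficients
and APV, so every stage is testable against ground truth.

## Worked example

Simulate a four-subject cohort and run leave-one-subject-out (LOSO)
validation — for every held-out subject, the gait-phase HMM and the ARD
regression are trained on the remaining subjects only:

```python
from gaitvel import SimulationConfig, simulate_cohort, loso_validate

cfg = SimulationConfig(n_subjects=4, n_strides=50, seed=0)
cohort = simulate_cohort(cfg)
result = loso_validate(cohort)

stats = result.stats
print(f"strides evaluated : {len(result.apv_errors)}")
print(f"APV MBE   : {stats.mbe:+.4f} m/s")
print(f"APV RMSE  : {stats.rmse:.4f} m/s")
print(f"APV ARMSE : {stats.armse:.4f} m/s")
print(f"missed / spurious strides: {result.n_deleted} / {result.n_inserted}")
```

prints

```
strides evaluated : 200
APV MBE   : -0.0188 m/s
APV RMSE  : 0.0520 m/s
APV ARMSE : 0.0669 m/s
missed / spurious strides: 0 / 0
```

i.e. 200 strides were segmented with no insertions or deletions; the mean
walking-speed bias across held-out subjects is −1.9 cm/s, the RMS of the
per-subject mean errors 5.2 cm/s, and the average per-subject RMS error
(which retains stride-to-stride variability) 6.7 cm/s, against a generated
speed of ≈ 1.3 m/s with 5 cm/s target noise.

A fitted ARD model reports which features the evidence kept (here trained
on six subjects × 100 strides; the generator's APV depends on the stride
time, the stance duration and the shank acceleration harmonics — the
regression retains the stride time and all six acceleration amplitudes and
discards every gyroscope harmonic):

```python
from gaitvel import ARDLinearRegression, extract_features
import numpy as np

feats, targets = [], []
for t in simulate_cohort(SimulationConfig(n_subjects=6, n_strides=100, seed=0)):
    X, names, kept = extract_features(t.shank, t.events)
    feats.append(X); targets.append(t.apv[kept])
res = ARDLinearRegression(np.vstack(feats), np.concatenate(targets),
                          feature_names=names).fit()
print(res.summary())
```

```
ARD Bayesian linear regression
  observations: 600
  iterations:   9 (converged)
  noise precision alpha: 397.519 (sigma = 0.05016)
  retained features: 7 / 16

  term           kept        coef     post sd        beta   gamma
  bias            yes      1.2874      0.0020      0.6034   1.000
  T_FS            yes     -0.0799      0.0021       156.7   0.999
  T_FF             no      0.0000      0.0000   2.961e+04   0.000
  ...
  acc_vt_c2       yes      0.0340      0.0033       856.8   0.991
  gyr_ap_c1        no      0.0000      0.0000   2.887e+05   0.000
  ...
```

The estimated noise σ = 0.050 m/s matches the generator's APV target noise.
The stance duration is strongly collinear with the stride time and its small
unique contribution is sometimes pruned along with it, as here.

## Command line

```bash
gaitvel simulate --config cfg.yaml --out trials/
gaitvel segment  --model hmm.json --imu shank.csv --out events.csv
gaitvel train    --features f.csv --targets t.csv --out ard.json
gaitvel predict  --model ard.json --features f.csv
gaitvel run      --pelvis p.csv --shank s.csv --quat q.csv \
                 --hmm hmm.json --ard ard.json --out est.csv
gaitvel evaluate --est est.csv --ref ref.csv --group-by subject
```

IMU streams are plain CSV (`time_s, acc_x..z, gyr_x..z`; X = AP forward,
Y = ML right, Z = VT down), orientations are scalar-first quaternion CSV,
models serialize to JSON.

## Scope

Orientation estimation is an input, not part of the package; magnetic and
barometric channels, curved-path heading tracking and pathological-gait
models are out of scope.  See `docs/methods.md` for the full model
description, parameter defaults and limitations.
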