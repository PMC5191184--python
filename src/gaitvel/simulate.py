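"""Synthetic pelvis + shank IMU walking trials with known ground truth.

The generator emulates the signal structure the estimation pipeline assumes:
within each stride, pelvis linear acceleration on every axis is exactly a
truncated Fourier series (up to six harmonics) locked to the stride, so the
ground-truth cyclical velocity is available in closed form as the analytic
integral of the noise-free harmonic part.  Stride times vary from stride to
stride; harmonic phases and shank amplitude levels are drawn once per
subject, so features carry subject-level structure and leave-one-subject-out
validation is meaningfully stressed.  The per-stride average progression
velocity (APV) is generated from a configured linear model of the stride
time, the stance duration and the shank acceleration harmonic amplitudes,
plus optional target noise — the same quantities the regression stage later
extracts, so its best attainable accuracy is known.

The shank medio-lateral angular velocity follows a stride-locked template
with four clearly distinguishable phases (a deep negative excursion after
foot strike, a near-zero flat-foot plateau, a moderate negative heel-off
dip, and a large positive swing peak), giving the gait-phase HMM learnable
structure.  The template is a documented implementation constant chosen to
be qualitatively similar to shank angular velocity in walking; its
biomechanical realism is not asserted.

What the generator does **not** emulate: soft-tissue artifacts, sensor bias
drift and scale errors, curved-path heading changes, double-support
asymmetries, or pathological gait.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .fourier import FourierSeries
from .segmentation import StrideEvents
from .streams import AXIS_NAMES, TIME_EPS, IMUStream, OrientationStream

__all__ = [
    "APVModel",
    "SimulationConfig",
    "SimulatedTrial",
    "simulate_trial",
    "simulate_cohort",
    "write_trial",
]

GRAVITY = 9.80665  # m/s^2, Z-down global frame
_G_VEC = np.array([0.0, 0.0, GRAVITY])


@dataclass
class APVModel:
    """Linear map from per-stride gait quantities to the APV target (m/s).

    ``apv = intercept + w_T * T + w_stance * T_TO + sum w_c * c`` where ``c``
    runs over the shank acceleration harmonic amplitudes, plus Gaussian
    target noise.  The negative stride-time weights encode the usual inverse
    relation between cadence and speed.
    """

    intercept: float = 1.95
    stride_time: float = -1.5
    stance_time: float = -0.6
    accel_weights: dict = field(
        default_factory=lambda: {
            "ap": (0.15, 0.25),
            "ml": (0.20, 0.50),
            "vt": (0.12, 0.20),
        }
    )
    noise_sd: float = 0.05

    def evaluate(
        self, stride_time, stance_time, accel_amplitudes: dict
    ) -> np.ndarray:
        """Noise-free APV for arrays of per-stride quantities."""
        apv = (
            self.intercept
            + self.stride_time * np.asarray(stride_time, dtype=float)
            + self.stance_time * np.asarray(stance_time, dtype=float)
        )
        for axis, w in self.accel_weights.items():
            amps = np.asarray(accel_amplitudes[axis], dtype=float)
            apv = apv + amps @ np.asarray(w, dtype=float)
        return apv


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults describe healthy adults walking at a comfortable self-selected
    speed, recorded at 100 Hz: ten subjects with one hundred strides each,
    a mean stride time of 1.1 s with 4% stride-to-stride variability, pelvis
    acceleration amplitudes of order 1 m/s^2 concentrated in the first
    harmonics, and white sensor noise of 0.05 m/s^2 (accelerometer) and
    0.02 rad/s (gyroscope).
    """

    n_subjects: int = 10
    n_strides: int = 100
    sampling_rate: float = 100.0
    mean_stride_time: float = 1.1
    stride_time_cv: float = 0.04
    #: pelvis acceleration amplitudes (m/s^2) per axis, harmonics 1..6
    pelvis_harmonics: dict = field(
        default_factory=lambda: {
            "ap": (1.2, 0.5, 0.2, 0.08, 0.03, 0.01),
            "ml": (0.8, 0.3, 0.1, 0.05, 0.02, 0.01),
            "vt": (1.5, 0.8, 0.3, 0.1, 0.05, 0.02),
        }
    )
    #: shank acceleration amplitudes (m/s^2) per axis, harmonics 1..2
    shank_accel_harmonics: dict = field(
        default_factory=lambda: {
            "ap": (2.0, 0.8),
            "ml": (1.0, 0.4),
            "vt": (2.5, 1.0),
        }
    )
    #: shank AP/VT angular-velocity amplitudes (rad/s), harmonics 1..2
    shank_gyro_harmonics: dict = field(
        default_factory=lambda: {"ap": (0.3, 0.1), "vt": (0.15, 0.05)}
    )
    #: between-subject relative spread of shank amplitude levels
    subject_amp_cv: float = 0.15
    #: stride-to-stride relative spread of shank amplitudes within a subject
    stride_amp_cv: float = 0.05
    apv_model: APVModel = field(default_factory=APVModel)
    #: FF, HO, TO event times as fractions of the stride time
    event_fractions: tuple = (0.12, 0.40, 0.62)
    #: per-stride jitter of the event fractions (SD, absolute)
    event_fraction_jitter_sd: float = 0.008
    accel_noise_sd: float = 0.05
    gyro_noise_sd: float = 0.02
    #: swing-phase peak of the shank ML angular-velocity template (rad/s)
    swing_peak: float = 4.0
    swing_peak_subject_cv: float = 0.08
    #: optional sinusoidal pelvis roll tilt exercising the strap-down rotation
    tilt_amplitude_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.apv_model, dict):
            self.apv_model = APVModel(**self.apv_model)
        scalars = [
            self.sampling_rate, self.mean_stride_time, self.stride_time_cv,
            self.subject_amp_cv, self.stride_amp_cv, self.accel_noise_sd,
            self.gyro_noise_sd, self.swing_peak, self.event_fraction_jitter_sd,
            self.tilt_amplitude_deg,
        ]
        if not all(np.isfinite(s) for s in scalars):
            raise ValueError("configuration values must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.mean_stride_time <= 0:
            raise ValueError("mean_stride_time must be positive")
        if self.n_strides < 1 or self.n_subjects < 1:
            raise ValueError("counts must be positive")
        fr = np.asarray(self.event_fractions, dtype=float)
        if fr.size != 3 or not np.isfinite(fr).all():
            raise ValueError("event_fractions must be three finite values")
        if not (0 < fr[0] < fr[1] < fr[2] < 1):
            raise ValueError(
                "event_fractions must be strictly increasing within (0, 1)"
            )
        if min(self.accel_noise_sd, self.gyro_noise_sd,
               self.apv_model.noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for d in (self.pelvis_harmonics, self.shank_accel_harmonics,
                  self.shank_gyro_harmonics):
            for amps in d.values():
                if not np.isfinite(np.asarray(amps, dtype=float)).all():
                    raise ValueError("harmonic amplitudes must be finite")
        if len(np.asarray(self.pelvis_harmonics["ap"]).ravel()) > 6:
            raise ValueError("at most 6 pelvis harmonics are supported")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["event_fractions"] = list(self.event_fractions)
        return d


@dataclass
class SimulatedTrial:
    """One subject's trial: streams, ground-truth events, per-stride APV and
    the closed-form cyclical-velocity truth."""

    subject_id: str
    config: SimulationConfig
    pelvis: IMUStream
    shank: IMUStream
    orientation: OrientationStream
    events: StrideEvents            # full-precision (un-snapped) truth times
    apv: np.ndarray                 # (n_strides,) m/s
    cyclical_velocity: np.ndarray   # (n_samples, 3) noise-free truth, m/s
    linear_acceleration: np.ndarray  # (n_samples, 3) noise-free truth, m/s^2
    velocity_models: list           # per stride: {axis: FourierSeries}
    stride_features: pd.DataFrame   # per-stride generating quantities + apv

    @property
    def n_strides(self) -> int:
        return self.events.n_cycles

    def instantaneous_velocity(self) -> np.ndarray:
        """Ground-truth instantaneous velocity: cyclical plus APV on the AP
        axis, per stride."""
        out = self.cyclical_velocity.copy()
        k = np.searchsorted(
            np.r_[self.events.fs, self.events.fs_next[-1]],
            self.pelvis.time + TIME_EPS, side="right",
        ) - 1
        inside = (k >= 0) & (k < self.n_strides)
        out[inside, 0] += self.apv[k[inside]]
        return out


def _harmonic_signal(tloc, period, amps, phases):
    i = np.arange(1, len(amps) + 1)
    ang = np.multiply.outer(tloc, i) * (2.0 * np.pi / period) + phases[: len(amps)]
    return np.sin(ang) @ np.asarray(amps, dtype=float)


def _template_ml_gyro(t, fs, ff, ho, to, fs_next, peak):
    """Stride-locked shank ML angular-velocity template (rad/s).

    Four phases with distinct, non-overlapping levels and a large swing
    bump; all values are implementation constants documented here, not
    physiological claims.
    """
    out = np.empty_like(t)
    seg = [
        (fs, ff, lambda u: -1.5 - 0.5 * np.sin(np.pi * u)),
        (ff, ho, lambda u: 0.03 * np.sin(2.0 * np.pi * u)),
        (ho, to, lambda u: -0.6 - 0.3 * np.sin(np.pi * u)),
        (to, fs_next, lambda u: 0.5 + (peak - 0.5) * np.sin(np.pi * u)),
    ]
    for lo, hi, shape in seg:
        m = (t >= lo) & (t < hi)
        if m.any():
            out[m] = shape((t[m] - lo) / (hi - lo))
    return out


def simulate_trial(
    config: SimulationConfig, subject_id: str = "S00", subject_index: int = 0
) -> SimulatedTrial:
    """Generate one subject's trial.

    Per-subject randomness derives deterministically from
    ``(config.seed, subject_index)``: identical seeds reproduce bitwise-
    identical trials.  The trial starts at steady-state gait; the first foot
    strike is at t = 0 and the recording ends at the last foot strike.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, subject_index])
    axes = AXIS_NAMES

    # ---- subject-level draws (fixed order for determinism) --------------
    pelvis_phase = {
        ax: rng.uniform(-np.pi, np.pi, size=len(cfg.pelvis_harmonics[ax]))
        for ax in axes
    }
    shank_base = {
        ax: np.maximum(
            np.asarray(cfg.shank_accel_harmonics[ax], dtype=float)
            * (1.0 + cfg.subject_amp_cv
               * rng.standard_normal(len(cfg.shank_accel_harmonics[ax]))),
            0.05,
        )
        for ax in axes
    }
    shank_phase = {
        ax: rng.uniform(-np.pi, np.pi, size=len(cfg.shank_accel_harmonics[ax]))
        for ax in axes
    }
    gyro_amp = {
        ax: np.asarray(cfg.shank_gyro_harmonics[ax], dtype=float)
        for ax in ("ap", "vt")
    }
    gyro_phase = {
        ax: rng.uniform(-np.pi, np.pi, size=len(gyro_amp[ax]))
        for ax in ("ap", "vt")
    }
    swing_peak = max(
        cfg.swing_peak
        * (1.0 + cfg.swing_peak_subject_cv * rng.standard_normal()),
        2.0,
    )

    # ---- stride timing and events ---------------------------------------
    # one extra partial stride is generated past the last reported foot
    # strike so that a decoder can observe the closing FS of the last cycle
    K = cfg.n_strides
    K1 = K + 1
    stride_t = cfg.mean_stride_time * (
        1.0 + cfg.stride_time_cv * rng.standard_normal(K1)
    )
    stride_t = np.clip(
        stride_t, 0.5 * cfg.mean_stride_time, 1.5 * cfg.mean_stride_time
    )
    fs = np.concatenate([[0.0], np.cumsum(stride_t)])
    frac = np.asarray(cfg.event_fractions, dtype=float) + (
        cfg.event_fraction_jitter_sd * rng.standard_normal((K1, 3))
    )
    frac = np.clip(
        frac,
        np.asarray(cfg.event_fractions) - 0.03,
        np.asarray(cfg.event_fractions) + 0.03,
    )
    ff = fs[:-1] + frac[:, 0] * stride_t
    ho = fs[:-1] + frac[:, 1] * stride_t
    to = fs[:-1] + frac[:, 2] * stride_t
    events = StrideEvents(
        fs=fs[:K], ff=ff[:K], ho=ho[:K], to=to[:K], fs_next=fs[1 : K + 1]
    )
    stance_t = to - fs[:-1]

    # ---- per-stride shank amplitudes and the APV target ------------------
    amps_k = {
        ax: np.maximum(
            shank_base[ax]
            * (1.0 + cfg.stride_amp_cv
               * rng.standard_normal((K1, len(shank_base[ax])))),
            0.02,
        )
        for ax in axes
    }
    apv_noise = cfg.apv_model.noise_sd * rng.standard_normal(K)
    apv = (
        cfg.apv_model.evaluate(
            stride_t[:K], stance_t[:K], {ax: amps_k[ax][:K] for ax in axes}
        )
        + apv_noise
    )

    # ---- time base and per-sample stride assignment ----------------------
    duration = fs[K] + 0.3 * stride_t[K]
    n = int(np.floor(duration * cfg.sampling_rate - 1e-9))
    time = np.arange(n) / cfg.sampling_rate
    k_of = np.clip(
        np.searchsorted(fs, time + TIME_EPS, side="right") - 1, 0, K1 - 1
    )

    pelvis_true = np.zeros((n, 3))
    cyc_vel = np.zeros((n, 3))
    shank_acc_true = np.zeros((n, 3))
    vel_models = []
    for k in range(K1):
        m = k_of == k
        tloc = time[m] - fs[k]
        T = stride_t[k]
        models = {}
        for j, ax in enumerate(axes):
            A = np.asarray(cfg.pelvis_harmonics[ax], dtype=float)
            ph = pelvis_phase[ax]
            pelvis_true[m, j] = _harmonic_signal(tloc, T, A, ph)
            acc_model = FourierSeries(
                c0=0.0,
                a=A * np.cos(ph[: A.size]),
                b=A * np.sin(ph[: A.size]),
                period=T,
            )
            vel_model = acc_model.integrate()
            models[ax] = vel_model
            cyc_vel[m, j] = vel_model(tloc)
            shank_acc_true[m, j] = _harmonic_signal(
                tloc, T, amps_k[ax][k], shank_phase[ax]
            )
        if k < K:
            vel_models.append(models)

    # ---- orientation and sensor-frame measurements -----------------------
    if cfg.tilt_amplitude_deg > 0:
        theta = np.deg2rad(cfg.tilt_amplitude_deg) * np.sin(
            2.0 * np.pi * time / cfg.mean_stride_time
        )
        rot = Rotation.from_euler("x", theta[:, None])
        quat_xyzw = rot.as_quat()
        quats = np.column_stack([quat_xyzw[:, 3], quat_xyzw[:, :3]])
        orientation = OrientationStream(time=time, quaternions=quats)
        pelvis_meas = rot.inv().apply(pelvis_true - _G_VEC)
        theta_dot = (
            np.deg2rad(cfg.tilt_amplitude_deg)
            * (2.0 * np.pi / cfg.mean_stride_time)
            * np.cos(2.0 * np.pi * time / cfg.mean_stride_time)
        )
        pelvis_gyro = np.column_stack([theta_dot, np.zeros(n), np.zeros(n)])
    else:
        orientation = OrientationStream.identity(time)
        pelvis_meas = pelvis_true - _G_VEC
        pelvis_gyro = np.zeros((n, 3))

    pelvis_meas = pelvis_meas + cfg.accel_noise_sd * rng.standard_normal((n, 3))
    pelvis_gyro = pelvis_gyro + cfg.gyro_noise_sd * rng.standard_normal((n, 3))

    shank_acc = (
        shank_acc_true - _G_VEC
        + cfg.accel_noise_sd * rng.standard_normal((n, 3))
    )
    shank_gyro = np.zeros((n, 3))
    for k in range(K1):
        m = k_of == k
        shank_gyro[m, 1] = _template_ml_gyro(
            time[m], fs[k], ff[k], ho[k], to[k], fs[k + 1], swing_peak
        )
    for j, ax in ((0, "ap"), (2, "vt")):
        for k in range(K1):
            m = k_of == k
            shank_gyro[m, j] = _harmonic_signal(
                time[m] - fs[k], stride_t[k], gyro_amp[ax], gyro_phase[ax]
            )
    shank_gyro = shank_gyro + cfg.gyro_noise_sd * rng.standard_normal((n, 3))

    pelvis = IMUStream(
        time=time, accel=pelvis_meas, gyro=pelvis_gyro,
        sampling_rate=cfg.sampling_rate, site="pelvis", subject_id=subject_id,
    )
    shank = IMUStream(
        time=time, accel=shank_acc, gyro=shank_gyro,
        sampling_rate=cfg.sampling_rate, site="shank", subject_id=subject_id,
    )

    feat = {"stride": np.arange(K), "T_FS": stride_t[:K], "T_TO": stance_t[:K]}
    for ax in axes:
        for i in range(amps_k[ax].shape[1]):
            feat[f"acc_{ax}_c{i + 1}"] = amps_k[ax][:K, i]
    feat["apv"] = apv
    return SimulatedTrial(
        subject_id=subject_id,
        config=cfg,
        pelvis=pelvis,
        shank=shank,
        orientation=orientation,
        events=events,
        apv=apv,
        cyclical_velocity=cyc_vel,
        linear_acceleration=pelvis_true,
        velocity_models=vel_models,
        stride_features=pd.DataFrame(feat),
    )


def simulate_cohort(config: SimulationConfig) -> "list[SimulatedTrial]":
    """One trial per subject, with per-subject seeds derived deterministically
    from the master seed.  Requires at least two subjects (leave-one-subject-
    out validation is undefined otherwise)."""
    if config.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    return [
        simulate_trial(config, subject_id=f"S{i:02d}", subject_index=i)
        for i in range(config.n_subjects)
    ]


def write_trial(trial: SimulatedTrial, outdir) -> None:
    """Write the trial as delimited text plus a ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trial.pelvis.to_csv(outdir / "pelvis.csv")
    trial.shank.to_csv(outdir / "shank.csv")
    trial.orientation.to_csv(outdir / "quat.csv")
    truth = {
        "subject_id": trial.subject_id,
        "events": {
            "t_FS": trial.events.fs.tolist(),
            "t_FF": trial.events.ff.tolist(),
            "t_HO": trial.events.ho.tolist(),
            "t_TO": trial.events.to.tolist(),
            "t_FS_next": trial.events.fs_next.tolist(),
        },
        "apv": trial.apv.tolist(),
        "config": trial.config.to_dict(),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
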