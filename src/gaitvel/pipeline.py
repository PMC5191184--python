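"""End-to-end pelvis instantaneous-velocity estimation.

Processing chain for one trial:

1. segment gait cycles from the shank ML angular velocity (HMM decode);
2. strap-down rotate the pelvis accelerometer output into the gravity-
   aligned global frame and remove gravity, giving linear acceleration;
3. per stride, fit a 6-harmonic Fourier series to each linear-acceleration
   axis and integrate it analytically into the zero-mean cyclical velocity;
4. per stride, build the regression feature vector (stride time and the
   FS-to-FF/HO/TO durations plus the first-M phase-angle amplitudes of the
   six shank channels, d = 6M + 4, with M = 2 by default giving d = 16);
5. predict the average progression velocity (APV) with a fitted ARD
   regression;
6. compose instantaneous velocity as cyclical + APV on the AP axis.

Composition assumes straight-heading walking: the APV is added along the AP
axis of the gravity-aligned frame.  Heading tracking for curved paths is out
of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .agreement import ErrorStats, error_stats
from .ard import ARDLinearRegression, ARDResults
from .fourier import fit_fourier
from .segmentation import (
    GaitPhaseHMM,
    StrideEvents,
    build_emissions,
    extract_events,
    label_states,
)
from .simulate import GRAVITY, SimulatedTrial
from .streams import TIME_EPS, IMUStream, OrientationStream

__all__ = [
    "PipelineConfig",
    "StrideVelocity",
    "PipelineResult",
    "LOSOResult",
    "strapdown_rotate",
    "cyclical_velocity",
    "extract_features",
    "feature_names",
    "compose_velocity",
    "run_pipeline",
    "loso_validate",
]

_G_VEC = np.array([0.0, 0.0, GRAVITY])

#: shank measurement channels in feature order
SHANK_CHANNELS = ("acc_ap", "acc_ml", "acc_vt", "gyr_ap", "gyr_ml", "gyr_vt")


@dataclass
class PipelineConfig:
    """Tunable pipeline settings.

    ``pelvis_order`` is the harmonic order used to integrate pelvis
    acceleration (6 by default), ``shank_order`` the order of the shank
    feature harmonics (2 by default, giving 16 features).  The first
    ``transient_seconds`` of a recording are discarded as a non-steady-state
    transient; set to 0 for recordings that start at steady state.
    """

    pelvis_order: int = 6
    shank_order: int = 2
    transient_seconds: float = 30.0


def strapdown_rotate(
    pelvis: IMUStream, orientation: OrientationStream
) -> np.ndarray:
    """Linear acceleration (m/s^2) in the gravity-aligned global frame.

    ``a = R(q) f + g_vec`` with ``g_vec = (0, 0, +g)`` in the Z-down global
    frame; a static sensor therefore maps to zero.  The orientation stream
    must share the pelvis time base to within half a sample.
    """
    if orientation.time.size != pelvis.time.size or np.any(
        np.abs(orientation.time - pelvis.time) > 0.5 / pelvis.sampling_rate
    ):
        raise ValueError("orientation and pelvis streams are not time-aligned")
    rot = Rotation.from_quat(pelvis_quat_xyzw(orientation))
    return rot.apply(pelvis.accel) + _G_VEC


def pelvis_quat_xyzw(orientation: OrientationStream) -> np.ndarray:
    """Scalar-first stored quaternions reordered to scipy's (x, y, z, w)."""
    q = orientation.quaternions
    return np.column_stack([q[:, 1], q[:, 2], q[:, 3], q[:, 0]])


def cyclical_velocity(
    accel: np.ndarray, times: np.ndarray, period: float, order: int = 6
) -> np.ndarray:
    """Zero-mean cyclical velocity of one stride from its linear acceleration.

    Per axis: Fourier fit, DC removal, analytic integration, evaluation on
    the stride's own time grid.  Adding any constant vector to the input
    leaves the result unchanged.
    """
    accel = np.asarray(accel, dtype=float)
    times = np.asarray(times, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3 or accel.shape[0] != times.size:
        raise ValueError("accel must be (n, 3) matching times")
    out = np.empty_like(accel)
    tloc = times - times[0]
    for j in range(3):
        model = fit_fourier(accel[:, j], times, period, order)
        out[:, j] = model.integrate()(tloc)
    return out


def feature_names(order: int = 2) -> "list[str]":
    """Names of the 6M + 4 regression features, in their fixed order."""
    names = ["T_FS", "T_FF", "T_HO", "T_TO"]
    for ch in SHANK_CHANNELS:
        names += [f"{ch}_c{i}" for i in range(1, order + 1)]
    return names


def extract_features(
    shank: IMUStream, events: StrideEvents, order: int = 2
):
    """Per-stride regression features from the shank IMU.

    Returns ``(X, names, kept)`` where ``X`` is (n_kept, 6 * order + 4),
    ``names`` labels the columns and ``kept`` indexes the cycles of
    ``events`` that produced a feature row.  Cycles with inconsistent event
    ordering or too few samples for the harmonic basis are skipped with a
    warning.
    """
    names = feature_names(order)
    channels = np.column_stack([shank.accel, shank.gyro])  # axis order ap,ml,vt
    time = shank.time
    rows, kept = [], []
    n_skipped = 0
    for k in range(events.n_cycles):
        t0, t1 = events.fs[k], events.fs_next[k]
        T = t1 - t0
        durations = np.array(
            [T, events.ff[k] - t0, events.ho[k] - t0, events.to[k] - t0]
        )
        if not (0 < durations[1] < durations[2] < durations[3] < T):
            n_skipped += 1
            continue
        sl = (time >= t0 - TIME_EPS) & (time < t1 - TIME_EPS)
        if np.count_nonzero(sl) < 2 * order + 1:
            n_skipped += 1
            continue
        amps = []
        for c in range(6):
            model = fit_fourier(channels[sl, c], time[sl], T, order)
            amps.append(model.to_phase_angle().amplitude)
        rows.append(np.concatenate([durations, np.concatenate(amps)]))
        kept.append(k)
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} strides unsuitable for feature extraction",
            stacklevel=2,
        )
    X = np.array(rows) if rows else np.empty((0, len(names)))
    return X, names, np.asarray(kept, dtype=int)


def compose_velocity(cyclical: np.ndarray, apv: float) -> np.ndarray:
    """Instantaneous velocity: APV added to the AP axis of the cyclical
    component; ML and VT components are cyclical only."""
    if apv < 0:
        raise ValueError("apv must be non-negative")
    out = np.asarray(cyclical, dtype=float).copy()
    out[:, 0] += apv
    return out


@dataclass
class StrideVelocity:
    """Velocity estimate over one stride interval [t_start, t_end)."""

    index: int
    t_start: float
    t_end: float
    times: np.ndarray
    cyclical: np.ndarray   # (n, 3), zero stride mean per axis
    apv: float
    velocity: np.ndarray   # (n, 3) composed instantaneous velocity


@dataclass
class PipelineResult:
    """All per-stride estimates of one trial."""

    strides: "list[StrideVelocity]"
    events: StrideEvents
    features: np.ndarray
    feature_names: "list[str]"

    @property
    def apv(self) -> np.ndarray:
        return np.array([s.apv for s in self.strides])

    @property
    def n_strides(self) -> int:
        return len(self.strides)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time, velocity components, stride index, APV."""
        parts = []
        for s in self.strides:
            parts.append(
                pd.DataFrame(
                    {
                        "time_s": s.times,
                        "vel_ml": s.velocity[:, 1],
                        "vel_vt": s.velocity[:, 2],
                        "vel_ap": s.velocity[:, 0],
                        "stride_index": s.index,
                        "apv": s.apv,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(
                columns=["time_s", "vel_ml", "vel_vt", "vel_ap",
                         "stride_index", "apv"]
            )
        return pd.concat(parts, ignore_index=True)


def run_pipeline(
    pelvis: IMUStream,
    shank: IMUStream,
    orientation: OrientationStream,
    hmm: GaitPhaseHMM | None,
    ard: ARDResults,
    config: PipelineConfig | None = None,
    events: StrideEvents | None = None,
) -> PipelineResult:
    """Run the full estimation chain on one trial.

    ``events`` may be supplied to bypass the HMM (oracle segmentation);
    otherwise ``hmm`` is required.  Re-running on identical inputs yields
    identical outputs.
    """
    cfg = config or PipelineConfig()
    if events is None:
        if hmm is None:
            raise ValueError("either a trained HMM or explicit events are needed")
        emissions = build_emissions(shank.gyro[:, 1], shank.sampling_rate)
        events = extract_events(hmm.decode(emissions), shank.time)
    if events.n_cycles == 0:
        warnings.warn("no gait cycles detected; returning empty result",
                      stacklevel=2)
        return PipelineResult(
            strides=[], events=events, features=np.empty((0, 0)),
            feature_names=feature_names(cfg.shank_order),
        )

    steady = events.fs >= cfg.transient_seconds
    events = StrideEvents(
        fs=events.fs[steady], ff=events.ff[steady], ho=events.ho[steady],
        to=events.to[steady], fs_next=events.fs_next[steady],
    )

    lin_acc = strapdown_rotate(pelvis, orientation)
    X, names, kept = extract_features(shank, events, order=cfg.shank_order)
    if X.shape[0] == 0:
        warnings.warn("no usable strides after feature extraction",
                      stacklevel=2)
        return PipelineResult(strides=[], events=events,
                              features=X, feature_names=names)
    apv_pred = np.maximum(ard.predict(X).mean, 0.0)

    strides = []
    for row, k in enumerate(kept):
        t0, t1 = events.fs[k], events.fs_next[k]
        sl = (pelvis.time >= t0 - TIME_EPS) & (pelvis.time < t1 - TIME_EPS)
        times = pelvis.time[sl]
        cyc = cyclical_velocity(lin_acc[sl], times, t1 - t0,
                                order=cfg.pelvis_order)
        strides.append(
            StrideVelocity(
                index=int(k), t_start=float(t0), t_end=float(t1),
                times=times, cyclical=cyc, apv=float(apv_pred[row]),
                velocity=compose_velocity(cyc, float(apv_pred[row])),
            )
        )
    return PipelineResult(strides=strides, events=events,
                          features=X, feature_names=names)


# ---------------------------------------------------------------------------
# leave-one-subject-out validation
# ---------------------------------------------------------------------------


@dataclass
class LOSOResult:
    """Leave-one-subject-out validation outcome on a simulated cohort."""

    results: dict                 # subject_id -> PipelineResult
    apv_errors: pd.DataFrame      # subject, stride, apv_est, apv_ref, error
    stats: ErrorStats
    event_errors: pd.DataFrame    # subject, cycle, event, error_s
    n_inserted: int
    n_deleted: int


def _match_strides(est_fs: np.ndarray, ref_fs: np.ndarray, tol: float):
    """Greedy one-to-one matching of estimated to reference foot strikes."""
    pairs = []
    used = np.zeros(ref_fs.size, dtype=bool)
    for i, t in enumerate(est_fs):
        if ref_fs.size == 0:
            break
        j = int(np.argmin(np.abs(ref_fs - t)))
        if not used[j] and abs(ref_fs[j] - t) <= tol:
            used[j] = True
            pairs.append((i, j))
    return pairs, used


def loso_validate(
    cohort: "list[SimulatedTrial]",
    config: PipelineConfig | None = None,
) -> LOSOResult:
    """Train on all-but-one subject, test on the held-out subject, rotate.

    The HMM is trained supervised from the ground-truth phase labels of the
    training subjects; the ARD regression is trained on features extracted
    at the ground-truth events with the ground-truth APV as target.  The
    held-out subject is processed by the full pipeline (HMM segmentation
    included).  Simulated trials are steady-state from the first stride, so
    no transient window is discarded.
    """
    if len(cohort) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    cfg = config or PipelineConfig(transient_seconds=0.0)

    # per-trial training material, computed once
    emissions, labels, feats, targets = [], [], [], []
    names = feature_names(cfg.shank_order)
    for trial in cohort:
        emissions.append(
            build_emissions(trial.shank.gyro[:, 1], trial.shank.sampling_rate)
        )
        labels.append(label_states(trial.events, trial.shank.time))
        X, names, kept = extract_features(trial.shank, trial.events,
                                          order=cfg.shank_order)
        feats.append(X)
        targets.append(trial.apv[kept])

    results = {}
    err_rows, event_rows = [], []
    n_inserted = n_deleted = 0
    for i, trial in enumerate(cohort):
        train = [j for j in range(len(cohort)) if j != i]
        hmm = GaitPhaseHMM.train_supervised(
            [emissions[j] for j in train], [labels[j] for j in train]
        )
        ard = ARDLinearRegression(
            np.vstack([feats[j] for j in train]),
            np.concatenate([targets[j] for j in train]),
            feature_names=names,
        ).fit()
        res = run_pipeline(
            trial.pelvis, trial.shank, trial.orientation, hmm, ard, cfg
        )
        results[trial.subject_id] = res

        ref = trial.events
        tol = 0.5 * float(np.median(ref.fs_next - ref.fs))
        est_fs = np.array([s.t_start for s in res.strides])
        pairs, used = _match_strides(est_fs, ref.fs, tol)
        n_inserted += est_fs.size - len(pairs)
        n_deleted += ref.fs.size - len(pairs)
        est_events = res.events
        for ei, rj in pairs:
            s = res.strides[ei]
            err_rows.append(
                {
                    "subject": trial.subject_id,
                    "stride": int(rj),
                    "apv_est": s.apv,
                    "apv_ref": float(trial.apv[rj]),
                    "error": s.apv - float(trial.apv[rj]),
                }
            )
            k = int(s.index)
            for name, est_t, ref_t in (
                ("FS", est_events.fs[k], ref.fs[rj]),
                ("FF", est_events.ff[k], ref.ff[rj]),
                ("HO", est_events.ho[k], ref.ho[rj]),
                ("TO", est_events.to[k], ref.to[rj]),
            ):
                event_rows.append(
                    {
                        "subject": trial.subject_id,
                        "cycle": int(rj),
                        "event": name,
                        "error_s": float(est_t - ref_t),
                    }
                )

    apv_errors = pd.DataFrame(err_rows)
    stats = error_stats(apv_errors, subject="subject", error="error")
    return LOSOResult(
        results=results,
        apv_errors=apv_errors,
        stats=stats,
        event_errors=pd.DataFrame(event_rows),
        n_inserted=n_inserted,
        n_deleted=n_deleted,
    )
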