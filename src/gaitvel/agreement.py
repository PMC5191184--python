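"""Method-comparison statistics for velocity estimates.

Three ingredients:

* reference progression velocity from optical-marker trajectories — the
  horizontal-plane speed of a low-pass-filtered marker trace, averaged over
  each gait cycle;
* the two-stage error statistics MBE / RMSE / ARMSE, in which per-subject
  mean (or RMS) errors are formed first and only then aggregated across
  subjects, so that subjects with many strides do not dominate;
* Bland-Altman limits of agreement with a regression correction for
  non-uniform differences: the bias and the residual spread are each
  allowed to vary linearly with the measurement magnitude, and the limits
  are the bias line plus/minus a fixed multiple of the absolute-residual
  line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

from .segmentation import StrideEvents
from .streams import TIME_EPS, MarkerTrajectory

__all__ = [
    "ErrorStats",
    "AgreementReport",
    "reference_apv",
    "error_stats",
    "bland_altman_regression",
    "cyclical_agreement",
    "REGRESSION_LA_MULTIPLIER",
]

#: multiplier applied to the absolute-residual regression line when forming
#: the regression-based limits of agreement (the constant is used as
#: conventionally printed, not recomputed from 1.96 * sqrt(pi / 2))
REGRESSION_LA_MULTIPLIER = 2.46

_BUTTER_ORDER = 2
_BUTTER_CUTOFF_HZ = 3.0


def reference_apv(marker: MarkerTrajectory, events: StrideEvents) -> np.ndarray:
    """Per-stride reference average progression velocity (m/s).

    The horizontal (X, Y) marker coordinates are low-pass filtered with a
    forward-backward second-order Butterworth filter (3 Hz cut-off),
    differentiated by first central differences, combined into the
    horizontal-plane speed and averaged over each gait cycle.  Because only
    the horizontal norm enters, the result is invariant to rigid rotations
    of the trajectory about the vertical axis.
    """
    if events.n_cycles and (
        events.fs[0] < marker.time[0] - 1e-9
        or events.fs_next[-1] > marker.time[-1] + 1.0 / marker.sampling_rate
    ):
        raise ValueError("marker trajectory does not span the gait events")
    padlen = 3 * (_BUTTER_ORDER + 1)
    if marker.time.size <= padlen:
        raise ValueError("trajectory shorter than the filter warm-up length")
    b, a = sps.butter(
        _BUTTER_ORDER, _BUTTER_CUTOFF_HZ, btype="low", fs=marker.sampling_rate
    )
    xy = sps.filtfilt(b, a, marker.position[:, :2], axis=0)
    vel = np.gradient(xy, 1.0 / marker.sampling_rate, axis=0)
    speed = np.hypot(vel[:, 0], vel[:, 1])
    out = np.empty(events.n_cycles)
    for k in range(events.n_cycles):
        m = (marker.time >= events.fs[k] - TIME_EPS) & (
            marker.time < events.fs_next[k] - TIME_EPS
        )
        out[k] = speed[m].mean()
    return out


@dataclass
class ErrorStats:
    """Two-stage error statistics across subjects.

    With per-stride errors ``e_ln`` (stride l of subject n), the per-subject
    means are ``m_n`` and per-subject RMS values ``e_n``; then

    * ``MBE  = mean_n(m_n)`` — mean bias error,
    * ``RMSE = sqrt(mean_n(m_n^2))`` — RMS of the per-subject means,
    * ``ARMSE = mean_n(e_n)`` — average per-subject RMS, which, unlike RMSE,
      keeps the intra-subject stride-to-stride variability.
    """

    subjects: list
    subject_means: np.ndarray
    subject_rms: np.ndarray
    stride_counts: np.ndarray
    mbe: float
    rmse: float
    armse: float

    def to_dict(self) -> dict:
        return {
            "MBE": self.mbe,
            "RMSE": self.rmse,
            "ARMSE": self.armse,
            "subjects": list(self.subjects),
            "subject_means": self.subject_means.tolist(),
            "subject_rms": self.subject_rms.tolist(),
            "stride_counts": self.stride_counts.tolist(),
        }


def error_stats(
    errors, subject: str = "subject", error: str = "error"
) -> ErrorStats:
    """Compute MBE / RMSE / ARMSE from per-stride errors grouped by subject.

    ``errors`` is either a DataFrame with subject and error columns or a
    mapping ``{subject: array of errors}``.  Subjects with no strides are
    excluded with a warning.  The two-stage averaging (subject means first)
    is intrinsic to these statistics, not an implementation choice.
    """
    if isinstance(errors, pd.DataFrame):
        groups = {
            key: grp[error].to_numpy(dtype=float)
            for key, grp in errors.groupby(subject, sort=True)
        }
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in errors.items()}
    empty = [k for k, v in groups.items() if v.size == 0]
    if empty:
        warnings.warn(f"excluding subjects with no strides: {empty}",
                      stacklevel=2)
        groups = {k: v for k, v in groups.items() if v.size > 0}
    if not groups:
        raise ValueError("need at least one subject with at least one stride")
    subjects = list(groups)
    m = np.array([groups[k].mean() for k in subjects])
    e = np.array([np.sqrt(np.mean(groups[k] ** 2)) for k in subjects])
    counts = np.array([groups[k].size for k in subjects])
    return ErrorStats(
        subjects=subjects,
        subject_means=m,
        subject_rms=e,
        stride_counts=counts,
        mbe=float(m.mean()),
        rmse=float(np.sqrt(np.mean(m**2))),
        armse=float(e.mean()),
    )


@dataclass
class AgreementReport:
    """Regression-based Bland-Altman limits of agreement.

    With differences ``D = est - ref`` and averages ``A = (est + ref) / 2``,
    the bias line is the OLS fit of D on A and the residual line the OLS fit
    of |D - bias line| on A; the limits of agreement are
    ``bias(A) +/- multiplier * residual(A)``.  ``mean_half_width`` averages
    the (non-negative) half-width over the central 95% range of A.  The
    classical constant limits (mean difference +/- 1.96 SD) are reported for
    comparison.
    """

    bias_slope: float
    bias_intercept: float
    resid_slope: float
    resid_intercept: float
    multiplier: float
    mean_half_width: float
    a_range: tuple
    classical_md: float
    classical_half_width: float
    n: int
    bias_slope_se: float = np.nan
    resid_slope_se: float = np.nan

    def limits(self, a) -> tuple:
        """Lower and upper limit of agreement evaluated at average value(s) a."""
        a = np.asarray(a, dtype=float)
        bias = self.bias_slope * a + self.bias_intercept
        half = self.multiplier * np.maximum(
            self.resid_slope * a + self.resid_intercept, 0.0
        )
        return bias - half, bias + half

    def format(self) -> str:
        """Report line in the conventional 'D = sA + i +/- m (sr A + ir)' form."""
        return (
            f"D = {self.bias_slope:.4f}A + {self.bias_intercept:.4f} "
            f"± {self.multiplier:.2f} "
            f"({self.resid_slope:.4f}A + {self.resid_intercept:.4f})"
        )

    def to_dict(self) -> dict:
        return {
            "bias_slope": self.bias_slope,
            "bias_intercept": self.bias_intercept,
            "resid_slope": self.resid_slope,
            "resid_intercept": self.resid_intercept,
            "multiplier": self.multiplier,
            "mean_half_width": self.mean_half_width,
            "a_range": list(self.a_range),
            "classical_md": self.classical_md,
            "classical_half_width": self.classical_half_width,
            "n": self.n,
        }


def bland_altman_regression(estimates, reference) -> AgreementReport:
    """Limits of agreement with linear bias and spread corrections.

    Requires at least 10 paired samples.  A degenerate average (zero
    variance of A) falls back to the classical constant limits with a
    warning (slopes set to zero).
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimates and reference must be equal-length vectors")
    if est.size < 10:
        raise ValueError("need at least 10 paired samples")
    d = est - ref
    a = 0.5 * (est + ref)
    md = float(d.mean())
    sd = float(d.std(ddof=1))

    if np.ptp(a) == 0 or a.std() == 0:
        warnings.warn(
            "degenerate averages: falling back to classical limits",
            stacklevel=2,
        )
        return AgreementReport(
            bias_slope=0.0, bias_intercept=md,
            resid_slope=0.0, resid_intercept=sd,
            multiplier=1.96, mean_half_width=1.96 * sd,
            a_range=(float(a.min()), float(a.max())),
            classical_md=md, classical_half_width=1.96 * sd, n=est.size,
        )

    bias_fit = sstats.linregress(a, d)
    resid = d - (bias_fit.slope * a + bias_fit.intercept)
    resid_fit = sstats.linregress(a, np.abs(resid))

    lo, hi = np.percentile(a, [2.5, 97.5])
    a_central = a[(a >= lo) & (a <= hi)]
    half = REGRESSION_LA_MULTIPLIER * (
        resid_fit.slope * a_central + resid_fit.intercept
    )
    if np.any(half < 0):
        warnings.warn(
            "residual line negative at part of the reporting range; "
            "floored at zero for the width summary",
            stacklevel=2,
        )
        half = np.maximum(half, 0.0)
    return AgreementReport(
        bias_slope=float(bias_fit.slope),
        bias_intercept=float(bias_fit.intercept),
        resid_slope=float(resid_fit.slope),
        resid_intercept=float(resid_fit.intercept),
        multiplier=REGRESSION_LA_MULTIPLIER,
        mean_half_width=float(half.mean()),
        a_range=(float(lo), float(hi)),
        classical_md=md,
        classical_half_width=1.96 * sd,
        n=est.size,
        bias_slope_se=float(bias_fit.stderr),
        resid_slope_se=float(resid_fit.stderr),
    )


def cyclical_agreement(est_velocity, ref_velocity) -> dict:
    """Per-axis agreement of time-aligned cyclical-velocity series.

    ``est_velocity`` and ``ref_velocity`` are (n, 3) arrays in AP/ML/VT
    column order on a common time grid, with samples from all strides and
    subjects pooled.  Returns ``{"ml": ..., "vt": ..., "ap": ...}``; the
    axes are processed independently.
    """
    est = np.asarray(est_velocity, dtype=float)
    ref = np.asarray(ref_velocity, dtype=float)
    if est.shape != ref.shape or est.ndim != 2 or est.shape[1] != 3:
        raise ValueError("velocity arrays must be (n, 3) and time-aligned")
    cols = {"ap": 0, "ml": 1, "vt": 2}
    return {
        axis: bland_altman_regression(est[:, j], ref[:, j])
        for axis, j in cols.items()
    }
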