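"""Per-stride Fourier series fitting and analytic time integration.

During steady-state walking, body-segment accelerations are well described,
within each stride, by a truncated Fourier series with the stride time as the
fundamental period.  Fitting the series to a single stride of acceleration
data and integrating it term by term gives the zero-mean ("cyclical")
component of the segment velocity without numerical drift: the DC term of the
acceleration is discarded before integration, which is equivalent to removing
a constant offset from the stride data, and the integrated series has zero
mean over the stride by construction.

Coefficients are obtained by discrete Fourier projection when the samples
form a uniform grid tiling exactly one period (the projection is then exact
to machine precision for band-limited signals, and the coefficients of low
orders do not change when further harmonics are added, unlike e.g. a
polynomial fit).  Otherwise — strides whose duration is not a whole number
of samples, or non-uniformly sampled data — the coefficients come from
ordinary least squares on the harmonic basis evaluated at the sample times,
which avoids any interpolation error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FourierSeries",
    "PhaseAngleSeries",
    "fit_fourier",
    "evaluate_fourier",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class FourierSeries:
    """Truncated Fourier series ``f(t) = c0 + sum_i a_i sin(i w t) + b_i cos(i w t)``
    with ``w = 2 pi / period``.

    Times are stride-local: ``t = 0`` is the start of the stride.

    Parameters
    ----------
    c0 : float
        DC level, in the units of the modeled signal.  For a velocity signal
        in the direction of progression this is the average progression
        velocity; for per-stride acceleration it is discarded before
        integration.
    a, b : ndarray, shape (M,)
        Sine and cosine coefficients of harmonics ``1..M``.
    period : float
        Fundamental period in seconds (the stride time).
    """

    c0: float
    a: np.ndarray
    b: np.ndarray
    period: float

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape or a.size < 1:
            raise ValueError("a and b must be 1-D arrays of equal length >= 1")
        if not (np.isfinite(self.c0) and np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("Fourier coefficients must be finite")
        if not (np.isfinite(self.period) and self.period > 0):
            raise ValueError(f"period must be positive and finite, got {self.period}")

    @property
    def order(self) -> int:
        """Harmonic order M."""
        return self.a.size

    def __call__(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        i = np.arange(1, self.order + 1)
        ang = np.multiply.outer(t, i) * (_TWO_PI / self.period)
        return self.c0 + np.sin(ang) @ self.a + np.cos(ang) @ self.b

    def to_phase_angle(self) -> "PhaseAngleSeries":
        """Convert to the amplitude/phase form ``c0 + sum_i c_i sin(i w t + phi_i)``.

        ``c_i = sqrt(a_i^2 + b_i^2)`` and ``phi_i = atan2(b_i, a_i)``, with
        the phase branch fixed to ``(-pi, pi]``.
        """
        amp = np.hypot(self.a, self.b)
        phase = np.arctan2(self.b, self.a)
        phase[phase == -np.pi] = np.pi
        return PhaseAngleSeries(
            c0=self.c0, amplitude=amp, phase=phase, period=self.period
        )

    def integrate(self) -> "FourierSeries":
        """Analytic time integral of the harmonic part, with zero DC.

        The DC term of the input is dropped (mean subtraction) so the
        integral is the zero-mean cyclical component:
        ``a'_i = (T / 2 pi) b_i / i`` and ``b'_i = -(T / 2 pi) a_i / i``.
        """
        i = np.arange(1, self.order + 1)
        scale = self.period / (_TWO_PI * i)
        return FourierSeries(
            c0=0.0, a=scale * self.b, b=-scale * self.a, period=self.period
        )

    def differentiate(self) -> "FourierSeries":
        """Analytic time derivative (inverse of :meth:`integrate` on the
        harmonic part; the DC level of the original signal is not recoverable)."""
        i = np.arange(1, self.order + 1)
        w = _TWO_PI * i / self.period
        return FourierSeries(c0=0.0, a=-w * self.b, b=w * self.a, period=self.period)

    def to_dict(self) -> dict:
        return {
            "c0": float(self.c0),
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "period": float(self.period),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FourierSeries":
        return cls(
            c0=d["c0"],
            a=np.asarray(d["a"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            period=d["period"],
        )


@dataclass(frozen=True)
class PhaseAngleSeries:
    """Fourier series in phase-angle form ``f(t) = c0 + sum_i c_i sin(i w t + phi_i)``.

    Amplitudes are non-negative; phases lie in ``(-pi, pi]``.
    """

    c0: float
    amplitude: np.ndarray
    phase: np.ndarray
    period: float

    def __post_init__(self) -> None:
        amp = np.atleast_1d(np.asarray(self.amplitude, dtype=float))
        ph = np.atleast_1d(np.asarray(self.phase, dtype=float))
        object.__setattr__(self, "amplitude", amp)
        object.__setattr__(self, "phase", ph)
        if amp.shape != ph.shape or amp.ndim != 1 or amp.size < 1:
            raise ValueError("amplitude and phase must be 1-D arrays of equal length")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be non-negative")
        if np.any(ph <= -np.pi) or np.any(ph > np.pi):
            raise ValueError("phases must lie in (-pi, pi]")
        if not (self.period > 0 and np.isfinite(self.period)):
            raise ValueError("period must be positive and finite")

    @property
    def order(self) -> int:
        return self.amplitude.size

    def __call__(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        i = np.arange(1, self.order + 1)
        ang = np.multiply.outer(t, i) * (_TWO_PI / self.period) + self.phase
        return self.c0 + np.sin(ang) @ self.amplitude

    def to_sine_cosine(self) -> FourierSeries:
        """Back-convert to sine/cosine coefficient form."""
        return FourierSeries(
            c0=self.c0,
            a=self.amplitude * np.cos(self.phase),
            b=self.amplitude * np.sin(self.phase),
            period=self.period,
        )


def _is_uniform_full_period(times: np.ndarray, period: float) -> bool:
    """True when the samples form a uniform grid spanning exactly one period."""
    if times.size < 2:
        return False
    dt = np.diff(times)
    dt0 = dt.mean()
    if dt0 <= 0 or np.ptp(dt) > 1e-9 * max(1.0, abs(dt0)):
        return False
    # exactness of the discrete projection needs the grid to tile the period
    return abs(times.size * dt0 - period) <= 1e-9 * period


def fit_fourier(signal, times, period: float, order: int) -> FourierSeries:
    """Fit a truncated Fourier series to one stride of sampled data.

    Parameters
    ----------
    signal : array_like, shape (N,)
        Sampled signal covering (approximately) one stride.
    times : array_like, shape (N,)
        Sample times in seconds, strictly increasing.  The stride-local time
        origin of the returned model is ``times[0]``.
    period : float
        Stride time T in seconds.
    order : int
        Number of harmonics M to retain (M >= 1).

    Returns
    -------
    FourierSeries
        Least-squares projection of the stride onto the harmonic basis
        (discrete Fourier projection on grids that tile the period exactly,
        ordinary least squares on the sampled basis otherwise).

    Notes
    -----
    Requires at least ``2 * order + 1`` samples.  Non-uniform sampling beyond
    tolerance triggers a warning; the fit proceeds by least squares.
    """
    s = np.asarray(signal, dtype=float)
    t = np.asarray(times, dtype=float)
    if s.ndim != 1 or t.shape != s.shape:
        raise ValueError("signal and times must be 1-D arrays of equal length")
    if not (np.isfinite(period) and period > 0):
        raise ValueError(f"period must be positive, got {period}")
    if order < 1:
        raise ValueError("order must be >= 1")
    if s.size < 2 * order + 1:
        raise ValueError(
            f"need at least {2 * order + 1} samples to identify {order} harmonics, "
            f"got {s.size}"
        )
    if not np.isfinite(s).all() or not np.isfinite(t).all():
        raise ValueError("signal and times must be finite")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    i = np.arange(1, order + 1)
    if _is_uniform_full_period(t, period):
        # uniform grid tiling exactly one period: the discrete basis is
        # orthogonal, so projection is exact and order-stable
        tloc = t - t[0]
        ang = np.multiply.outer(tloc, i) * (_TWO_PI / period)
        n = tloc.size
        c0 = s.mean()
        a = 2.0 / n * (s @ np.sin(ang))
        b = 2.0 / n * (s @ np.cos(ang))
    else:
        dt = np.diff(t)
        if np.ptp(dt) > 1e-6 * dt.mean():
            warnings.warn(
                "non-uniform sample times: fitting by least squares on the "
                "sampled harmonic basis",
                stacklevel=2,
            )
        tloc = t - t[0]
        ang = np.multiply.outer(tloc, i) * (_TWO_PI / period)
        basis = np.column_stack([np.ones(tloc.size), np.sin(ang), np.cos(ang)])
        coef, *_ = np.linalg.lstsq(basis, s, rcond=None)
        c0 = float(coef[0])
        a = coef[1 : order + 1]
        b = coef[order + 1 :]
    return FourierSeries(c0=c0, a=a, b=b, period=period)


def evaluate_fourier(model: FourierSeries, times) -> np.ndarray:
    """Evaluate a Fourier series model at the given stride-local times."""
    return model(times)
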