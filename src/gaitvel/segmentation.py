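"""Gait-cycle segmentation with a four-state left-right HMM.

The medio-lateral component of the shank angular velocity has a stereotyped
within-stride shape: a large swing-phase peak and a near-zero plateau while
the foot is flat on the ground.  Each gait cycle is partitioned into four
phases delimited by the events Foot Strike (FS), Flat Foot (FF), Heel Off
(HO) and Toe Off (TO).  A hidden Markov model with one state per phase,
left-right circular topology (each state may only persist or advance to the
next phase, with TO-phase wrapping back to FS-phase so consecutive strides
chain) and three-component Gaussian-mixture emissions over the 2-D
observation (angular velocity, first time difference) is trained in a
supervised way from labeled recordings and decoded with the Viterbi
algorithm.

Event times are taken as the time of the first sample of each new phase
occurrence; phase labels use half-open intervals, so a sample exactly at an
event boundary belongs to the later phase.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

from .streams import TIME_EPS

__all__ = [
    "PHASE_NAMES",
    "N_STATES",
    "EmissionSequence",
    "StrideEvents",
    "TemporalFeatures",
    "GaitPhaseHMM",
    "build_emissions",
    "label_states",
    "extract_events",
    "temporal_features",
]

PHASE_NAMES = ("FS", "FF", "HO", "TO")
N_STATES = 4
_LOG_ZERO = -np.inf


@dataclass
class EmissionSequence:
    """2-D HMM observations: shank ML angular velocity and its backward first
    time difference (per sample, not divided by dt — the scale is absorbed by
    the learned emission covariances)."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("values must have shape (n_samples, 2)")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not np.isfinite(self.values).all():
            raise ValueError("emissions must be finite")

    def __len__(self) -> int:
        return self.values.shape[0]


def build_emissions(gyro_ml, sampling_rate: float) -> EmissionSequence:
    """Build the emission sequence from the shank ML angular velocity.

    The second column is the backward first difference with its first element
    replicated, so the output length equals the input length.
    """
    x = np.asarray(gyro_ml, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("gyro_ml must be a 1-D array with at least 2 samples")
    d = np.empty_like(x)
    d[1:] = x[1:] - x[:-1]
    d[0] = d[1]
    return EmissionSequence(
        values=np.column_stack([x, d]), sampling_rate=sampling_rate
    )


@dataclass
class StrideEvents:
    """Per-cycle gait-event times (s).

    Each of the ``n_cycles`` rows holds FS, FF, HO, TO and the FS of the next
    cycle; within every cycle ``t_FS < t_FF < t_HO < t_TO < t_FS_next``.
    Cycles need not be contiguous (cycles rejected during decoding may leave
    gaps), but when they are, ``fs_next[k] == fs[k+1]``.
    """

    fs: np.ndarray
    ff: np.ndarray
    ho: np.ndarray
    to: np.ndarray
    fs_next: np.ndarray

    def __post_init__(self) -> None:
        arrays = [
            np.atleast_1d(np.asarray(a, dtype=float))
            for a in (self.fs, self.ff, self.ho, self.to, self.fs_next)
        ]
        self.fs, self.ff, self.ho, self.to, self.fs_next = arrays
        n = self.fs.size
        if any(a.size != n for a in arrays):
            raise ValueError("event arrays must have equal length")
        if n:
            stacked = np.stack(arrays)  # (5, n)
            if not (np.diff(stacked, axis=0) > 0).all():
                raise ValueError(
                    "events must satisfy t_FS < t_FF < t_HO < t_TO < next t_FS "
                    "within every cycle"
                )
            if not (self.fs[1:] >= self.fs_next[:-1] - 1e-12).all():
                raise ValueError("cycles must be ordered and non-overlapping")

    @property
    def n_cycles(self) -> int:
        return self.fs.size

    @classmethod
    def from_event_times(cls, fs, ff, ho, to) -> "StrideEvents":
        """Build from K+1 FS times and K FF/HO/TO times of contiguous cycles."""
        fs = np.atleast_1d(np.asarray(fs, dtype=float))
        if fs.size < 2:
            return cls(
                fs=np.empty(0), ff=np.empty(0), ho=np.empty(0),
                to=np.empty(0), fs_next=np.empty(0),
            )
        return cls(fs=fs[:-1], ff=ff, ho=ho, to=to, fs_next=fs[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles),
                "t_FS": self.fs,
                "t_FF": self.ff,
                "t_HO": self.ho,
                "t_TO": self.to,
                "t_FS_next": self.fs_next,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class TemporalFeatures:
    """Per-cycle durations (s): stride time ``T_FS = t_FS(k+1) - t_FS(k)`` and
    the FS-to-FF, FS-to-HO and FS-to-TO durations ``T_FF, T_HO, T_TO``."""

    t_stride: np.ndarray
    t_ff: np.ndarray
    t_ho: np.ndarray
    t_to: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.t_stride.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_FS": self.t_stride,
                "T_FF": self.t_ff,
                "T_HO": self.t_ho,
                "T_TO": self.t_to,
            }
        )


def temporal_features(events: StrideEvents) -> TemporalFeatures:
    """Durations of the gait phases relative to each cycle's foot strike.

    Cycles violating the ordering ``0 < T_FF < T_HO < T_TO < T_FS`` are
    excluded with a warning.
    """
    t_stride = events.fs_next - events.fs
    t_ff = events.ff - events.fs
    t_ho = events.ho - events.fs
    t_to = events.to - events.fs
    valid = (t_ff > 0) & (t_ho > t_ff) & (t_to > t_ho) & (t_stride > t_to)
    if not valid.all():
        warnings.warn(
            f"excluding {np.count_nonzero(~valid)} cycles with inconsistent "
            "event ordering",
            stacklevel=2,
        )
    return TemporalFeatures(
        t_stride=t_stride[valid], t_ff=t_ff[valid], t_ho=t_ho[valid],
        t_to=t_to[valid],
    )


def label_states(events: StrideEvents, times) -> np.ndarray:
    """Phase label of every sample: 0..3 for the FS/FF/HO/TO phases, -1 for
    samples outside any complete cycle.  Intervals are half-open, so a sample
    exactly at an event time belongs to the later phase."""
    t = np.asarray(times, dtype=float)
    labels = np.full(t.size, -1, dtype=int)
    for k in range(events.n_cycles):
        bounds = [events.fs[k], events.ff[k], events.ho[k], events.to[k],
                  events.fs_next[k]]
        idx = np.searchsorted(bounds, t + TIME_EPS, side="right") - 1
        inside = (idx >= 0) & (idx < 4)
        labels[inside] = idx[inside]
    return labels


def _state_log_likelihood(
    weights: np.ndarray, means: np.ndarray, covs: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Log density of a Gaussian mixture at each row of X."""
    comps = [
        np.log(w) + multivariate_normal.logpdf(X, mean=m, cov=c)
        for w, m, c in zip(weights, means, covs)
        if w > 0
    ]
    return logsumexp(np.stack(comps, axis=0), axis=0)


@dataclass
class GaitPhaseHMM:
    """Four-state left-right HMM over 2-D shank-gyroscope emissions.

    States 0..3 correspond to the phases starting at FS, FF, HO and TO.  The
    transition matrix is constrained to the circular left-right topology:
    only self-loops and ``k -> (k+1) mod 4`` have non-zero probability.
    Emissions are per-state Gaussian mixtures with (by default) three full-
    covariance components.
    """

    startprob: np.ndarray
    transmat: np.ndarray
    weights: np.ndarray  # (n_states, n_components)
    means: np.ndarray    # (n_states, n_components, 2)
    covariances: np.ndarray  # (n_states, n_components, 2, 2)

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        if self.transmat.shape != (N_STATES, N_STATES):
            raise ValueError("transmat must be 4x4")
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValueError("transmat rows must sum to 1")
        forbidden = ~_topology_mask()
        if np.any(self.transmat[forbidden] != 0.0):
            raise ValueError("transmat violates the circular left-right topology")

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    # -- training ---------------------------------------------------------

    @classmethod
    def train_supervised(
        cls,
        emissions: "list[EmissionSequence]",
        labels: "list[np.ndarray]",
        n_components: int = 3,
        random_state: int = 0,
    ) -> "GaitPhaseHMM":
        """Estimate all parameters from labeled sequences.

        Transition probabilities come from labeled transition counts with the
        circular left-right zero pattern enforced; emission mixtures are fit
        per state by EM (k-means initialization, full covariances); the
        initial distribution comes from the first valid label of each
        sequence.

        Raises ``ValueError`` when a state has fewer than ``3 * n_components``
        samples.
        """
        if len(emissions) != len(labels):
            raise ValueError("need one label array per emission sequence")
        trans_counts = np.zeros((N_STATES, N_STATES))
        start_counts = np.zeros(N_STATES)
        samples: list[list[np.ndarray]] = [[] for _ in range(N_STATES)]
        for seq, lab in zip(emissions, labels):
            lab = np.asarray(lab, dtype=int)
            if lab.size != len(seq):
                raise ValueError("labels must match the emission length")
            valid = lab >= 0
            if valid.any():
                start_counts[lab[valid][0]] += 1
            pair_ok = valid[:-1] & valid[1:]
            np.add.at(trans_counts, (lab[:-1][pair_ok], lab[1:][pair_ok]), 1)
            for s in range(N_STATES):
                samples[s].append(seq.values[lab == s])

        mask = _topology_mask()
        off_topology = trans_counts[~mask].sum()
        if off_topology:
            warnings.warn(
                f"{int(off_topology)} labeled transitions violate the "
                "left-right topology and were ignored",
                stacklevel=2,
            )
            trans_counts[~mask] = 0.0
        row_sums = trans_counts.sum(axis=1)
        if np.any(row_sums == 0):
            raise ValueError("every state needs at least one outgoing transition")
        transmat = trans_counts / row_sums[:, None]

        if start_counts.sum() == 0:
            raise ValueError("no valid starting labels")
        # tiny floor keeps decoding of sequences starting in an unseen phase
        # well defined without visibly changing the estimated distribution
        startprob = start_counts + 1e-12
        startprob /= startprob.sum()

        weights = np.zeros((N_STATES, n_components))
        means = np.zeros((N_STATES, n_components, 2))
        covs = np.zeros((N_STATES, n_components, 2, 2))
        for s in range(N_STATES):
            X = np.concatenate(samples[s], axis=0) if samples[s] else np.empty((0, 2))
            if X.shape[0] < 3 * n_components:
                raise ValueError(
                    f"state {PHASE_NAMES[s]} has only {X.shape[0]} samples; "
                    f"needs at least {3 * n_components}"
                )
            gm = GaussianMixture(
                n_components=n_components,
                covariance_type="full",
                max_iter=200,
                tol=1e-6,
                init_params="kmeans",
                random_state=random_state,
            ).fit(X)
            weights[s] = gm.weights_
            means[s] = gm.means_
            covs[s] = gm.covariances_
        return cls(
            startprob=startprob, transmat=transmat, weights=weights,
            means=means, covariances=covs,
        )

    # -- inference --------------------------------------------------------

    def emission_log_likelihood(self, emissions: EmissionSequence) -> np.ndarray:
        """(n_samples, n_states) per-state log emission density."""
        X = emissions.values
        if X.shape[1] != self.means.shape[2]:
            raise ValueError("emission dimensionality mismatch")
        return np.column_stack(
            [
                _state_log_likelihood(
                    self.weights[s], self.means[s], self.covariances[s], X
                )
                for s in range(N_STATES)
            ]
        )

    def decode(self, emissions: EmissionSequence) -> np.ndarray:
        """Most probable state path (Viterbi).

        Ties are broken toward the lower state index.  The decoded path can
        never take a forbidden transition because those have probability 0.
        """
        log_b = self.emission_log_likelihood(emissions)
        with np.errstate(divide="ignore"):
            log_a = np.log(self.transmat)
            log_pi = np.log(self.startprob)
        n = log_b.shape[0]
        delta = log_pi + log_b[0]
        psi = np.zeros((n, N_STATES), dtype=int)
        for t in range(1, n):
            scores = delta[:, None] + log_a  # (from, to)
            psi[t] = np.argmax(scores, axis=0)
            delta = scores[psi[t], np.arange(N_STATES)] + log_b[t]
        path = np.empty(n, dtype=int)
        path[-1] = int(np.argmax(delta))
        for t in range(n - 2, -1, -1):
            path[t] = psi[t + 1, path[t + 1]]
        return path

    def segment(self, emissions: EmissionSequence, t0: float = 0.0) -> StrideEvents:
        """Decode and convert the state path to per-cycle event times."""
        times = t0 + np.arange(len(emissions)) / emissions.sampling_rate
        return extract_events(self.decode(emissions), times)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GaitPhaseHMM":
        return cls(
            startprob=np.asarray(d["startprob"], dtype=float),
            transmat=np.asarray(d["transmat"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            covariances=np.asarray(d["covariances"], dtype=float),
        )

    @classmethod
    def from_json(cls, path) -> "GaitPhaseHMM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _topology_mask() -> np.ndarray:
    """Boolean mask of allowed transitions: self-loops and k -> k+1 (mod 4)."""
    mask = np.zeros((N_STATES, N_STATES), dtype=bool)
    idx = np.arange(N_STATES)
    mask[idx, idx] = True
    mask[idx, (idx + 1) % N_STATES] = True
    return mask


def extract_events(states, times) -> StrideEvents:
    """Convert a decoded state path to per-cycle FS/FF/HO/TO event times.

    An event time is the time of the first sample of each new phase
    occurrence.  Cycles missing a phase are dropped with a warning; a path
    with no complete cycle yields an empty result.
    """
    states = np.asarray(states, dtype=int)
    times = np.asarray(times, dtype=float)
    if states.size != times.size:
        raise ValueError("states and times must have equal length")
    if states.size == 0:
        return StrideEvents.from_event_times([], [], [], [])
    starts = np.flatnonzero(np.r_[True, np.diff(states) != 0])
    run_states = states[starts]
    run_times = times[starts]

    fs_list, ff_list, ho_list, to_list, fsn_list = [], [], [], [], []
    dropped = 0
    i = 0
    while i < run_states.size:
        if run_states[i] != 0:
            i += 1
            continue
        # candidate cycle: FS phase at i, expect 1, 2, 3, 0 next
        if i + 4 < run_states.size and tuple(run_states[i + 1 : i + 5]) == (1, 2, 3, 0):
            fs_list.append(run_times[i])
            ff_list.append(run_times[i + 1])
            ho_list.append(run_times[i + 2])
            to_list.append(run_times[i + 3])
            fsn_list.append(run_times[i + 4])
            i += 4  # next cycle starts at the closing FS
        else:
            if i + 4 < run_states.size:
                dropped += 1
            i += 1
    if dropped:
        warnings.warn(f"dropped {dropped} incomplete cycles", stacklevel=2)
    if not fs_list:
        warnings.warn("no complete gait cycle found", stacklevel=2)
    return StrideEvents(
        fs=np.array(fs_list), ff=np.array(ff_list), ho=np.array(ho_list),
        to=np.array(to_list), fs_next=np.array(fsn_list),
    )
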