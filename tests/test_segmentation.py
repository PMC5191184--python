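"""Gait-phase HMM: emissions, supervised training, decoding, event extraction."""

import itertools

import numpy as np
import pytest

from gaitvel import (
    EmissionSequence,
    GaitPhaseHMM,
    StrideEvents,
    build_emissions,
    extract_events,
    label_states,
    loso_validate,
    temporal_features,
)
from gaitvel.segmentation import N_STATES, _topology_mask


class TestEmissions:
    def test_constant_signal_has_zero_difference(self):
        em = build_emissions(np.full(50, 2.5), 100.0)
        assert np.array_equal(em.values[:, 1], np.zeros(50))

    def test_ramp_has_constant_difference(self):
        em = build_emissions(0.3 * np.arange(40), 100.0)
        assert np.allclose(em.values[:, 1], 0.3)

    def test_length_preserved(self, rng):
        x = rng.normal(size=333)
        em = build_emissions(x, 100.0)
        assert em.values.shape == (333, 2)
        assert np.array_equal(em.values[:, 0], x)


class TestLabels:
    def test_sample_counts_per_phase(self):
        events = StrideEvents(
            fs=[0.0], ff=[0.1], ho=[0.4], to=[0.6], fs_next=[1.0]
        )
        labels = label_states(events, np.arange(100) / 100.0)
        counts = [np.count_nonzero(labels == s) for s in range(4)]
        assert counts == [10, 30, 20, 40]

    def test_boundary_sample_belongs_to_later_phase(self):
        events = StrideEvents(
            fs=[0.0], ff=[0.1], ho=[0.4], to=[0.6], fs_next=[1.0]
        )
        labels = label_states(events, np.array([0.1, 0.4, 0.6]))
        assert labels.tolist() == [1, 2, 3]

    def test_outside_samples_unlabeled(self):
        events = StrideEvents(
            fs=[1.0], ff=[1.1], ho=[1.4], to=[1.6], fs_next=[2.0]
        )
        labels = label_states(events, np.array([0.5, 1.5, 2.5]))
        assert labels.tolist() == [-1, 2, -1]

    def test_empty_events_give_empty_labels(self):
        empty = StrideEvents.from_event_times([], [], [], [])
        labels = label_states(empty, np.arange(10) / 10.0)
        assert np.array_equal(labels, np.full(10, -1))


class TestTemporalFeatures:
    def test_durations_from_event_times(self):
        events = StrideEvents(
            fs=[10.00], ff=[10.15], ho=[10.45], to=[10.65], fs_next=[11.10]
        )
        feats = temporal_features(events)
        assert feats.t_stride[0] == pytest.approx(1.10)
        assert feats.t_ff[0] == pytest.approx(0.15)
        assert feats.t_ho[0] == pytest.approx(0.45)
        assert feats.t_to[0] == pytest.approx(0.65)

    def test_k_plus_one_foot_strikes_give_k_rows(self):
        fs = np.arange(6) * 1.0
        events = StrideEvents.from_event_times(
            fs, fs[:-1] + 0.1, fs[:-1] + 0.4, fs[:-1] + 0.6
        )
        assert temporal_features(events).n_cycles == 5

    def test_truth_events_reproduce_configured_fractions(self, grid_trial):
        cfg = grid_trial.config
        feats = temporal_features(grid_trial.events)
        assert np.allclose(feats.t_stride, cfg.mean_stride_time, atol=1e-12)
        for frac, arr in zip(
            cfg.event_fractions, (feats.t_ff, feats.t_ho, feats.t_to)
        ):
            assert np.allclose(arr, frac * cfg.mean_stride_time, atol=1e-12)


def _labeled_cycles(n_cycles=12, lengths=(10, 30, 20, 40)):
    """A label sequence of repeated cycles with the given phase lengths."""
    cycle = np.concatenate(
        [np.full(n, s) for s, n in enumerate(lengths)]
    )
    return np.tile(cycle, n_cycles)


def _emissions_for_labels(labels, rng, means=None, scale=0.05):
    if means is None:
        means = np.array([[-1.5, 0.0], [0.0, 0.0], [-0.7, 0.0], [3.0, 0.0]])
    X = means[labels] + scale * rng.normal(size=(labels.size, 2))
    return EmissionSequence(values=X, sampling_rate=100.0)


class TestSupervisedTraining:
    def test_transition_counts(self, rng):
        # state 2 lasts exactly one sample per cycle -> no self transitions
        labels = _labeled_cycles(lengths=(10, 30, 1, 40))
        em = _emissions_for_labels(labels, rng)
        hmm = GaitPhaseHMM.train_supervised([em], [labels])
        assert hmm.transmat[2, 2] == 0.0
        assert hmm.transmat[2, 3] == 1.0
        assert np.allclose(hmm.transmat.sum(axis=1), 1.0)

    def test_forbidden_transitions_exactly_zero(self, rng):
        labels = _labeled_cycles()
        em = _emissions_for_labels(labels, rng)
        hmm = GaitPhaseHMM.train_supervised([em], [labels])
        assert np.all(hmm.transmat[~_topology_mask()] == 0.0)

    def test_underpopulated_state_rejected(self, rng):
        labels = _labeled_cycles(n_cycles=1, lengths=(2, 30, 30, 30))
        em = _emissions_for_labels(labels, rng)
        with pytest.raises(ValueError, match="samples"):
            GaitPhaseHMM.train_supervised([em], [labels])

    def test_mixture_means_recovered(self, rng):
        """Emissions drawn from a known 3-mode mixture per state are
        recovered within 3 standard errors of the component means."""
        n_per_comp = 5000
        comp_means = np.array([[-4.0, -4.0], [0.0, 4.0], [4.0, -4.0]])
        sd = 0.3
        labels, values = [], []
        for state in range(4):
            offset = 20.0 * state  # keep states apart
            for m in comp_means:
                values.append(
                    m + offset + sd * rng.normal(size=(n_per_comp, 2))
                )
                labels.append(np.full(n_per_comp, state))
        labels = np.concatenate(labels)
        em = EmissionSequence(np.vstack(values), 100.0)
        hmm = GaitPhaseHMM.train_supervised([em], [labels])
        se = 3 * sd / np.sqrt(n_per_comp)
        for state in range(4):
            want = comp_means + 20.0 * state
            got = hmm.means[state]
            # match fitted components to true ones by nearest distance
            for w in want:
                d = np.linalg.norm(got - w, axis=1)
                assert d.min() < 3 * se * np.sqrt(2) + 0.05


def _random_hmm(rng):
    mask = _topology_mask()
    transmat = np.where(mask, rng.uniform(0.1, 1.0, (4, 4)), 0.0)
    transmat /= transmat.sum(axis=1, keepdims=True)
    startprob = rng.uniform(0.1, 1.0, 4)
    startprob /= startprob.sum()
    weights = rng.uniform(0.2, 1.0, (4, 3))
    weights /= weights.sum(axis=1, keepdims=True)
    means = rng.normal(scale=3.0, size=(4, 3, 2))
    covs = np.zeros((4, 3, 2, 2))
    for s in range(4):
        for c in range(3):
            L = rng.normal(scale=0.5, size=(2, 2))
            covs[s, c] = L @ L.T + 0.3 * np.eye(2)
    return GaitPhaseHMM(
        startprob=startprob, transmat=transmat, weights=weights,
        means=means, covariances=covs,
    )


def _exhaustive_decode(hmm, emissions):
    """Brute-force maximization over all 4^N state paths."""
    log_b = hmm.emission_log_likelihood(emissions)
    with np.errstate(divide="ignore"):
        log_a = np.log(hmm.transmat)
        log_pi = np.log(hmm.startprob)
    n = log_b.shape[0]
    paths = np.array(list(itertools.product(range(N_STATES), repeat=n)))
    scores = log_pi[paths[:, 0]] + log_b[0, paths[:, 0]]
    for t in range(1, n):
        scores = scores + log_a[paths[:, t - 1], paths[:, t]]
        scores = scores + log_b[t, paths[:, t]]
    best = int(np.argmax(scores))
    return paths[best], scores[best]


class TestDecoding:
    @pytest.mark.parametrize("seed", range(20))
    def test_viterbi_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        hmm = _random_hmm(rng)
        n = int(rng.integers(2, 9))
        em = EmissionSequence(rng.normal(scale=3.0, size=(n, 2)), 100.0)
        path = hmm.decode(em)
        brute_path, brute_score = _exhaustive_decode(hmm, em)
        log_b = hmm.emission_log_likelihood(em)
        with np.errstate(divide="ignore"):
            log_a = np.log(hmm.transmat)
            log_pi = np.log(hmm.startprob)
        score = log_pi[path[0]] + log_b[0, path[0]] + sum(
            log_a[path[t - 1], path[t]] + log_b[t, path[t]]
            for t in range(1, n)
        )
        assert score == pytest.approx(brute_score, abs=1e-9)
        assert np.array_equal(path, brute_path)

    def test_decoded_path_respects_topology(self, rng):
        hmm = _random_hmm(rng)
        em = EmissionSequence(rng.normal(scale=3.0, size=(500, 2)), 100.0)
        path = hmm.decode(em)
        steps = (path[1:] - path[:-1]) % N_STATES
        assert set(np.unique(steps)).issubset({0, 1})

    def test_decode_invariant_to_likelihood_rescaling(self, rng):
        hmm = _random_hmm(rng)
        em = EmissionSequence(rng.normal(scale=3.0, size=(200, 2)), 100.0)
        base = hmm.decode(em)
        original = GaitPhaseHMM.emission_log_likelihood
        try:
            GaitPhaseHMM.emission_log_likelihood = (
                lambda self, e: original(self, e) + 7.3
            )
            rescaled = hmm.decode(em)
        finally:
            GaitPhaseHMM.emission_log_likelihood = original
        assert np.array_equal(base, rescaled)

    def test_well_separated_emissions_decoded_exactly(self, rng):
        labels = _labeled_cycles(n_cycles=6)
        em = _emissions_for_labels(labels, rng, scale=0.02)
        hmm = GaitPhaseHMM.train_supervised([em], [labels])
        assert np.array_equal(hmm.decode(em), labels)

    def test_dimension_mismatch_rejected(self, rng):
        hmm = _random_hmm(rng)
        bad = EmissionSequence(rng.normal(size=(10, 2)), 100.0)
        bad.values = rng.normal(size=(10, 3))  # bypass constructor check
        with pytest.raises(ValueError, match="dimensionality"):
            hmm.decode(bad)


class TestEventExtraction:
    def test_event_times_from_state_path(self):
        path = [0, 0, 1, 1, 2, 3, 3, 0]
        times = np.arange(8) / 100.0
        ev = extract_events(path, times)
        assert ev.n_cycles == 1
        assert ev.fs[0] == pytest.approx(0.0)
        assert ev.ff[0] == pytest.approx(0.02)
        assert ev.ho[0] == pytest.approx(0.04)
        assert ev.to[0] == pytest.approx(0.05)
        assert ev.fs_next[0] == pytest.approx(0.07)

    def test_stuck_path_yields_no_cycles(self):
        with pytest.warns(UserWarning, match="no complete"):
            ev = extract_events(np.zeros(100, dtype=int), np.arange(100) / 100)
        assert ev.n_cycles == 0

    def test_simulator_round_trip_within_one_sample(self, noise_free_cohort):
        """Noise-free trials: HMM trained on other subjects localizes every
        event within one sample of the ground truth."""
        res = loso_validate(noise_free_cohort[:3])
        assert res.n_inserted == 0 and res.n_deleted == 0
        dt = 1.0 / noise_free_cohort[0].pelvis.sampling_rate
        assert np.all(np.abs(res.event_errors["error_s"]) <= dt + 1e-9)


class TestSerialization:
    def test_json_round_trip(self, rng):
        hmm = _random_hmm(rng)
        clone = GaitPhaseHMM.from_dict(hmm.to_dict())
        em = EmissionSequence(rng.normal(scale=3.0, size=(50, 2)), 100.0)
        assert np.array_equal(hmm.decode(em), clone.decode(em))


class TestStrideEventsValidation:
    def test_disordered_events_rejected(self):
        with pytest.raises(ValueError):
            StrideEvents(fs=[0.0], ff=[0.5], ho=[0.4], to=[0.6], fs_next=[1.0])

    def test_ordering_invariant_of_temporal_features(self, trial):
        feats = temporal_features(trial.events)
        assert np.all(feats.t_ff > 0)
        assert np.all(feats.t_ff < feats.t_ho)
        assert np.all(feats.t_ho < feats.t_to)
        assert np.all(feats.t_to < feats.t_stride)
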