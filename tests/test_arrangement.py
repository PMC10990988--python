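"""Adaptive arrangement engine: evidence, utility, subset selection, combining."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from multiarrange import (
    RDM,
    SessionConfig,
    combine_trials,
    evidence_increments,
    run_session,
    select_next_subset,
    sentence_session_config,
    utility,
)
from multiarrange.arrangement import SessionState, TrialArrangement, UnseenPairsError
from multiarrange.rater_sim import RaterProfile, SimulatedRater
from multiarrange.rdm import n_pairs


def planted_2d_rdm(n, seed):
    """Exactly 2D-embeddable ground truth from random arena positions."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-0.7, 0.7, (n, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return RDM([f"i{k}" for k in range(n)], d)


class TestUtility:
    def test_anchor_values(self):
        assert utility(0.0, 10.0) == 0.0
        assert utility(0.5, 10.0) == pytest.approx(1.0 - np.exp(-5.0), abs=1e-12)

    @given(st.floats(0, 1), st.floats(0.001, 0.3))
    def test_strictly_increasing_and_bounded(self, w, dw):
        assert utility(w + dw, 10.0) > utility(w, 10.0)
        assert utility(w + dw, 10.0) <= 1.0

    def test_negative_evidence_rejected(self):
        with pytest.raises(ValueError):
            utility(-0.1, 10.0)
        with pytest.raises(ValueError):
            utility(0.1, 0.0)


class TestEvidence:
    def test_increment_is_squared_snr(self):
        sigma = 0.3
        coords = np.array([[0.0, 0.0], [sigma, 0.0], [2 * sigma, 0.0]])
        arr = TrialArrangement(0, [0, 1, 2], coords)
        idx, inc = evidence_increments(arr, sigma, 3)
        # pairs (0,1) distance sigma -> 1; (0,2) distance 2*sigma -> 4 (square law)
        assert inc[list(idx).index(0)] == pytest.approx(1.0)
        assert inc[list(idx).index(1)] == pytest.approx(4.0)

    def test_coincident_items_contribute_zero(self):
        arr = TrialArrangement(0, [0, 1], np.zeros((2, 2)))
        _, inc = evidence_increments(arr, 0.3, 2)
        assert inc[0] == 0.0

    def test_coordinates_outside_arena_rejected(self):
        with pytest.raises(ValueError, match="arena"):
            TrialArrangement(0, [0, 1], np.array([[1.5, 0.0], [0.0, 0.0]]))

    def test_evidence_nondecreasing_and_pair_count(self):
        cfg = SessionConfig(first_trial_size=5)
        state = SessionState(list("abcde"), cfg)
        assert state.evidence.shape == (n_pairs(5),)
        rng = np.random.default_rng(1)
        prev = state.evidence.copy()
        for t in range(4):
            ids = sorted(rng.choice(5, 3, replace=False).tolist())
            state.add_trial(TrialArrangement(t, ids, rng.uniform(-0.5, 0.5, (3, 2))))
            assert np.all(state.evidence >= prev)
            prev = state.evidence.copy()


class TestCombineTrials:
    def _state(self, n=5):
        return SessionState([f"i{k}" for k in range(n)],
                            SessionConfig(first_trial_size=n))

    def test_single_full_trial_is_proportional_to_distances(self):
        state = self._state(4)
        rng = np.random.default_rng(2)
        coords = rng.uniform(-0.6, 0.6, (4, 2))
        state.add_trial(TrialArrangement(0, [0, 1, 2, 3], coords))
        est = combine_trials(state).utv
        d = np.linalg.norm(
            coords[np.triu_indices(4, 1)[0]] - coords[np.triu_indices(4, 1)[1]], axis=1
        )
        ratio = est / d
        assert np.allclose(ratio, ratio[0])

    def test_duplicated_trial_leaves_estimate_unchanged(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-0.6, 0.6, (4, 2))
        one = self._state(4)
        one.add_trial(TrialArrangement(0, [0, 1, 2, 3], coords))
        two = self._state(4)
        two.add_trial(TrialArrangement(0, [0, 1, 2, 3], coords))
        two.add_trial(TrialArrangement(1, [0, 1, 2, 3], coords))
        assert np.allclose(combine_trials(one).values, combine_trials(two).values)

    def test_invariant_to_rescaling_one_trial(self):
        rng = np.random.default_rng(4)
        full = rng.uniform(-0.6, 0.6, (4, 2))
        sub = rng.uniform(-0.6, 0.6, (3, 2))
        a = self._state(4)
        a.add_trial(TrialArrangement(0, [0, 1, 2, 3], full))
        a.add_trial(TrialArrangement(1, [0, 1, 2], sub))
        b = self._state(4)
        b.add_trial(TrialArrangement(0, [0, 1, 2, 3], full))
        b.add_trial(TrialArrangement(1, [0, 1, 2], sub * 0.4))
        assert np.allclose(combine_trials(a).values, combine_trials(b).values, atol=1e-5)

    def test_unseen_pairs_raise_with_listing(self):
        state = self._state(4)
        state.add_trial(
            TrialArrangement(0, [0, 1, 2], np.random.default_rng(5).uniform(-0.5, 0.5, (3, 2)))
        )
        with pytest.raises(UnseenPairsError, match="i3"):
            combine_trials(state)


class TestSubsetSelection:
    def test_minimum_evidence_pair_seeds_the_subset(self):
        state = SessionState([f"i{k}" for k in range(6)], SessionConfig(first_trial_size=6))
        rng = np.random.default_rng(6)
        state.add_trial(TrialArrangement(0, list(range(6)), rng.uniform(-0.6, 0.6, (6, 2))))
        state.evidence[:] = 1.0
        from multiarrange import pair_index

        state.evidence[pair_index(6, 1, 3)] = 0.01
        subset = select_next_subset(state)
        assert 1 in subset and 3 in subset
        assert 3 <= len(subset) <= 6

    def test_unseen_pairs_prioritized(self):
        state = SessionState([f"i{k}" for k in range(6)],
                             SessionConfig(first_trial_size=4, max_subset=4))
        rng = np.random.default_rng(7)
        state.add_trial(TrialArrangement(0, [0, 1, 2, 3], rng.uniform(-0.6, 0.6, (4, 2))))
        subset = select_next_subset(state)
        assert {4, 5} <= set(subset)

    def test_subset_sizes_respect_bounds_throughout_session(self):
        gt = planted_2d_rdm(8, 11)
        rater = SimulatedRater(RaterProfile({"x": 1.0}, 0.05, seed=1), ground_truth=gt)
        _, state = run_session(rater, gt.labels, SessionConfig(max_subset=5, seed=2))
        for arr in state.trials[1:]:
            assert 3 <= len(arr.item_ids) <= 5
        assert len(state.trials[0].item_ids) == 8  # full first display


class TestRunSession:
    def test_first_display_full_set_by_default(self):
        gt = planted_2d_rdm(6, 0)
        rater = SimulatedRater(RaterProfile({"x": 1.0}, 0.0, seed=0), ground_truth=gt)
        _, state = run_session(rater, gt.labels, SessionConfig(seed=0))
        assert state.trials[0].item_ids == list(range(6))

    def test_sentence_config_first_display_shows_ten(self):
        labels = [f"s{k:02d}" for k in range(48)]
        gt = RDM(labels, planted_2d_rdm(48, 1).values)
        rater = SimulatedRater(RaterProfile({"x": 1.0}, 0.0, seed=0), ground_truth=gt)
        cfg = sentence_session_config(seed=4)
        cfg.trial_budget = 2  # only the opening of the session matters here
        _, state = run_session(rater, labels, cfg)
        assert len(state.trials[0].item_ids) == 10

    def test_termination_by_evidence_or_budget(self):
        gt = planted_2d_rdm(6, 5)
        rater = SimulatedRater(RaterProfile({"x": 1.0}, 0.0, seed=0), ground_truth=gt)
        _, state = run_session(rater, gt.labels, SessionConfig(seed=1))
        assert (
            state.min_evidence() >= state.config.evidence_target
            or len(state.trials) == state.config.trial_budget
        )

    def test_noise_free_small_instance_recovery(self):
        rhos = []
        for seed in range(5):
            gt = planted_2d_rdm(6, seed + 100)
            rater = SimulatedRater(RaterProfile({"x": 1.0}, 0.0, seed=seed),
                                   ground_truth=gt)
            est, _ = run_session(rater, gt.labels, SessionConfig(seed=seed))
            rhos.append(spearmanr(est.utv, gt.utv).statistic)
        assert np.mean(rhos) >= 0.99

    def test_rater_failure_carries_trial_context(self):
        def broken(trial, labels):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="trial 0"):
            run_session(broken, list("abcd"), SessionConfig(seed=0))
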