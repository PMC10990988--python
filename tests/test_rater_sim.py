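"""Synthetic raters: ground-truth mixtures, 2D placements, cohorts."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from multiarrange import RDM, SessionConfig
from multiarrange.rater_sim import (
    CohortConfig,
    RaterProfile,
    SimulatedRater,
    arrange_subset,
    default_dimensions,
    ground_truth_rdm,
    mixture_cohort_rdms,
    planted_ensemble_rdms,
    random_binary_dimensions,
    sample_profiles,
    simulate_cohort,
)


def two_binary_dims(n=6):
    labels = [f"i{k}" for k in range(n)]
    a = np.zeros((n, n))
    a[: n // 2, n // 2 :] = 1
    a += a.T
    b = np.zeros((n, n))
    b[::2, 1::2] = 1
    b = np.maximum(b, b.T)
    np.fill_diagonal(b, 0)
    return {"A": RDM(labels, a), "B": RDM(labels, b)}


class TestGroundTruth:
    def test_identity_mixture_returns_first_dimension(self):
        dims = two_binary_dims()
        p = RaterProfile({"A": 1.0, "B": 0.0}, 0.0, seed=0)
        assert np.array_equal(ground_truth_rdm(p, dims).values, dims["A"].values)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            RaterProfile({"A": 0.0, "B": 0.0}, 0.0, seed=0)

    def test_two_dim_mixture_entries_enumerate(self):
        dims = two_binary_dims()
        a, b = 0.3, 1.1
        gt = ground_truth_rdm(RaterProfile({"A": a, "B": b}, 0.0, 0), dims)
        allowed = {0.0, a, b, a + b}
        assert {round(v, 12) for v in gt.utv} <= {round(v, 12) for v in allowed}

    def test_linearity_in_weights(self):
        dims = two_binary_dims()
        g1 = ground_truth_rdm(RaterProfile({"A": 0.2, "B": 0.5}, 0.0, 0), dims)
        g2 = ground_truth_rdm(RaterProfile({"A": 0.6, "B": 1.5}, 0.0, 0), dims)
        assert np.allclose(3.0 * g1.values, g2.values)
        assert spearmanr(g1.utv, g2.utv).statistic == pytest.approx(1.0)

    def test_mismatched_labels_rejected(self):
        dims = two_binary_dims()
        other = RDM(["x", "y"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="labels"):
            ground_truth_rdm(RaterProfile({"A": 1.0, "C": 1.0}, 0.0, 0),
                             {"A": dims["A"], "C": other})


class TestArrangeSubset:
    def test_two_items_distance_proportional_to_dissimilarity(self):
        labels = ["a", "b", "c"]
        m = np.array([[0, 1.0, 2.0], [1.0, 0, 1.5], [2.0, 1.5, 0]])
        gt = RDM(labels, m)
        c1 = arrange_subset(gt, ["a", "b"], 0.0, 0)
        c2 = arrange_subset(gt, ["a", "c"], 0.0, 0)
        d1 = np.linalg.norm(c1[0] - c1[1])
        d2 = np.linalg.norm(c2[0] - c2[1])
        assert d2 / d1 == pytest.approx(1.0)  # both rescaled to span the arena

    def test_equilateral_dissimilarities_give_equal_distances(self):
        labels = ["a", "b", "c"]
        gt = RDM(labels, np.ones((3, 3)) - np.eye(3))
        c = arrange_subset(gt, labels, 0.0, 0)
        d = [np.linalg.norm(c[i] - c[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert max(d) - min(d) < 1e-9

    def test_all_coordinates_inside_unit_disc(self):
        gt = RDM([f"i{k}" for k in range(10)],
                 np.random.default_rng(0).uniform(0.5, 2.0, (10, 10)) * 0 + 1 - np.eye(10))
        for sigma in (0.0, 0.5, 2.0):
            c = arrange_subset(gt, gt.labels, sigma, 7)
            assert np.all(np.linalg.norm(c, axis=1) <= 1.0 + 1e-12)

    def test_noise_free_recovers_embeddable_subrdm_up_to_scale(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-1, 1, (7, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        gt = RDM([f"i{k}" for k in range(7)], d)
        coords = arrange_subset(gt, gt.labels[:5], 0.0, 3)
        got = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        want = gt.sub_rdm(gt.labels[:5]).values
        iu = np.triu_indices(5, 1)
        ratio = got[iu] / want[iu]
        assert np.max(np.abs(ratio / ratio[0] - 1.0)) < 1e-6

    def test_deterministic_given_seed(self):
        dims = two_binary_dims()
        rater = SimulatedRater(RaterProfile({"A": 0.7, "B": 0.3}, 0.2, seed=9), dims=dims)
        a = rater(4, ["i0", "i2", "i5"])
        b = rater(4, ["i0", "i2", "i5"])
        assert np.array_equal(a, b)


class TestCohorts:
    def test_fixed_seed_reproducible(self, tiny_stimuli):
        cfg = CohortConfig(n_subjects=3, placement_noise=0.05, seed=12)
        a = simulate_cohort(tiny_stimuli, cfg, SessionConfig(seed=0), mode="single_arrangement")
        b = simulate_cohort(tiny_stimuli, cfg, SessionConfig(seed=0), mode="single_arrangement")
        for x, y in zip(a, b):
            assert np.array_equal(x.rdm.values, y.rdm.values)
            assert x.profile.weights == y.profile.weights

    def test_session_mode_returns_states(self, tiny_stimuli):
        cfg = CohortConfig(n_subjects=2, placement_noise=0.05, seed=1)
        out = simulate_cohort(tiny_stimuli, cfg, SessionConfig(seed=0, trial_budget=30))
        for subj in out:
            assert subj.state is not None
            assert subj.state.n_rated_pairs == subj.rdm.n * (subj.rdm.n - 1) // 2

    def test_verb_bias_shifts_cohort_average_toward_verb_model(self, tiny_stimuli):
        from multiarrange.analysis import group_average_rdm, rdm_model_correlation

        dims = default_dimensions(tiny_stimuli)
        cfg = CohortConfig(n_subjects=8, verb_bias=20.0, placement_noise=0.05, seed=5)
        out = simulate_cohort(tiny_stimuli, cfg, mode="single_arrangement")
        avg = group_average_rdm([s.rdm for s in out])
        rho_verb = rdm_model_correlation(avg, dims["verb_category"])
        rho_agent = rdm_model_correlation(avg, dims["agent_category"])
        rho_patient = rdm_model_correlation(avg, dims["patient_category"])
        assert rho_verb > rho_agent and rho_verb > rho_patient

    def test_uniform_weights_average_tracks_equal_mixture(self, tiny_stimuli):
        # a uniform five-dimensional mixture is maximally high-dimensional,
        # so 2D arrangements compress it; rank agreement plateaus ~0.81
        # (generative consistency, not exact recovery)
        dims = default_dimensions(tiny_stimuli)
        uniform = {name: 1.0 for name in dims}
        mix = ground_truth_rdm(RaterProfile(uniform, 0.0, 0), dims)
        rdms = []
        for s in range(6):
            rater = SimulatedRater(RaterProfile(uniform, 0.02, seed=s), dims=dims)
            est, _ = run_session_quick(rater, tiny_stimuli.labels, seed=s)
            rdms.append(est)
        avg = np.mean([r.normalized().values for r in rdms], axis=0)
        rho = spearmanr(avg[np.triu_indices(16, 1)], mix.utv).statistic
        assert rho >= 0.8

    def test_profile_sampler_respects_alpha_names(self):
        cfg = CohortConfig(n_subjects=4, alpha={"A": 5.0, "B": 1.0}, seed=0)
        profs = sample_profiles(cfg)
        assert all(set(p.weights) == {"A", "B"} for p in profs)
        assert all(abs(sum(p.weights.values()) - 1.0) < 1e-9 for p in profs)


def run_session_quick(rater, labels, seed):
    from multiarrange import run_session

    return run_session(rater, labels, SessionConfig(seed=seed))


class TestPlantedGenerators:
    def test_random_binary_dimensions_are_near_orthogonal(self):
        dims = random_binary_dimensions([f"s{k}" for k in range(48)], 5, seed=2)
        M = np.array([d.utv for d in dims.values()])
        off = np.abs(np.corrcoef(M) - np.eye(5))
        assert off.max() < 0.25
        for d in dims.values():
            assert set(np.unique(d.values)) <= {0.0, 1.0}

    def test_planted_ensemble_dominance_and_noise_scale(self):
        dims = random_binary_dimensions([f"s{k}" for k in range(20)], 3, seed=0)
        rdms, W, names = planted_ensemble_rdms(dims, n_subjects=9, seed=4)
        assert len(rdms) == 9 and W.shape == (9, 3)
        # round-robin dominance: subject s is dominated by dim s mod 3
        assert all(np.argmax(W[s]) == s % 3 for s in range(9))
        assert np.allclose(W.sum(axis=1), 1.0)

    def test_mixture_cohort_shapes_and_determinism(self, sentence_dims):
        a, Wa, names = mixture_cohort_rdms(sentence_dims, n_subjects=4, seed=8)
        b, Wb, _ = mixture_cohort_rdms(sentence_dims, n_subjects=4, seed=8)
        assert names[-1] == "idiosyncratic"
        assert np.array_equal(Wa, Wb)
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))
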