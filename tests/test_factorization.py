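"""NMF ensemble pipeline: stacking, fitting, k-selection, stability, refit."""

import numpy as np
import pytest

from multiarrange import RDM, build_ensemble, n_pairs
from multiarrange.factorization import (
    component_model_correlation,
    nmf_fit,
    refit_mixing,
    select_k,
    stability_cluster,
    variance_explained,
)
from multiarrange.rater_sim import planted_ensemble_rdms, random_binary_dimensions


def exact_low_rank(n_subjects=12, n_items=10, k=3, seed=0):
    """D = W0 H0 with H0 rows from near-orthogonal binary dimensions."""
    rng = np.random.default_rng(seed)
    dims = random_binary_dimensions([f"i{x}" for x in range(n_items)], k, seed=seed)
    H0 = np.array([d.utv for d in dims.values()])
    W0 = rng.uniform(0.2, 1.0, (n_subjects, k))
    return W0 @ H0, W0, H0


class TestBuildEnsemble:
    def test_shape_and_unit_row_sd(self):
        rng = np.random.default_rng(0)
        rdms = []
        for s in range(5):
            m = rng.uniform(0.1, 1.5, (9, 9))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            rdms.append(RDM([f"i{k}" for k in range(9)], m))
        ens = build_ensemble(rdms)
        assert ens.D.shape == (5, n_pairs(9))
        assert np.allclose(np.std(ens.D, axis=1), 1.0, atol=1e-9)

    def test_study_scale_shape(self):
        # 86 retained subjects x 48 items -> 86 x 1128
        rng = np.random.default_rng(1)
        labels = [f"s{k}" for k in range(48)]
        rdms = []
        for s in range(86):
            m = rng.uniform(0.1, 1.0, (48, 48))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            rdms.append(RDM(labels, m))
        assert build_ensemble(rdms).D.shape == (86, 1128)

    def test_constant_rdm_named_in_error(self):
        labels = ["a", "b", "c"]
        good = RDM(labels, np.ones((3, 3)) - np.eye(3) + 0)
        good.values[0, 1] = good.values[1, 0] = 2.0
        flat = RDM(labels, np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValueError, match="subject 1"):
            build_ensemble([good, flat])


class TestNMFFit:
    def test_exact_low_rank_data_recovered(self):
        D, _, _ = exact_low_rank()
        comp = nmf_fit(D, 3, seed=1)
        assert comp.fit < 1e-6 * np.linalg.norm(D) ** 2
        assert np.all(comp.W >= 0) and np.all(comp.H >= 0)

    def test_rank_one_identical_rows(self):
        row = np.abs(np.random.default_rng(2).normal(1, 0.3, 20))
        D = np.tile(row, (6, 1))
        comp = nmf_fit(D, 1, seed=0)
        h = comp.H[0]
        assert np.corrcoef(h, row)[0, 1] > 0.999999

    def test_deterministic_given_seed_and_fit_matches_residual(self):
        D, _, _ = exact_low_rank(seed=3)
        a = nmf_fit(D, 2, seed=7)
        b = nmf_fit(D, 2, seed=7)
        assert np.array_equal(a.H, b.H)
        assert a.fit == pytest.approx(
            float(np.linalg.norm(D - a.W @ a.H) ** 2), abs=1e-9
        )

    def test_k_out_of_range_rejected(self):
        D, _, _ = exact_low_rank()
        with pytest.raises(ValueError):
            nmf_fit(D, 0, seed=0)
        with pytest.raises(ValueError):
            nmf_fit(D, 200, seed=0)


class TestSelectK:
    def test_identical_single_pattern_cohort_gives_one(self):
        row = np.abs(np.random.default_rng(4).normal(1, 0.2, 45))
        D = np.tile(row, (8, 1)) * np.random.default_rng(5).uniform(0.5, 2, (8, 1))
        assert select_k(D, k_range=range(2, 6), n_restarts=5, seed=0) == 1

    def test_planted_five_dimension_cohort(self):
        dims = random_binary_dimensions([f"i{x}" for x in range(16)], 5, seed=6)
        rdms, _, _ = planted_ensemble_rdms(dims, n_subjects=25, seed=6)
        ens = build_ensemble(rdms)
        assert select_k(ens, k_range=range(2, 9), n_restarts=8, seed=1) == 5

    def test_component_dominating_single_subject_not_general(self):
        # one outlier subject with a private pattern: its component is argmax
        # for exactly that subject, so k=2 must not qualify as general
        rng = np.random.default_rng(7)
        shared = np.abs(rng.normal(1, 0.2, 30))
        private = np.zeros(30)
        private[:5] = 5.0
        D = np.vstack([np.tile(shared, (6, 1)), private + 0.1 * shared])
        assert select_k(D, k_range=range(2, 4), n_restarts=5, seed=2) == 1


class TestStabilityCluster:
    def test_reproducible_components_give_k_full_reliability_clusters(self):
        # dominance-structured (identifiable) mixtures over near-orthogonal
        # dimensions: every restart finds the same components, so the cut
        # yields exactly k clusters spanning all restarts
        dims = random_binary_dimensions([f"i{x}" for x in range(32)], 3, seed=8)
        rdms, _, _ = planted_ensemble_rdms(dims, n_subjects=15, noise_sd_frac=0.0, seed=8)
        D = build_ensemble(rdms).D
        sol = stability_cluster(D, 3, n_restarts=10, seed=0)
        assert len(sol.retained) == 3
        assert all(sol.reliability[c] == 10 for c in sol.retained)
        assert np.allclose(np.linalg.norm(sol.centroids, axis=1), 1.0)

    def test_deterministic_given_seed(self):
        D, _, _ = exact_low_rank(seed=9)
        a = stability_cluster(D, 3, n_restarts=8, seed=5)
        b = stability_cluster(D, 3, n_restarts=8, seed=5)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.reliability == b.reliability

    def test_unreliable_structure_raises_advice(self):
        rng = np.random.default_rng(10)
        D = rng.uniform(0, 1, (10, 40))  # pure noise: restarts disagree
        with pytest.raises(ValueError, match="threshold"):
            # a near-zero cut means only numerically identical components
            # cluster together, which random restarts never achieve
            stability_cluster(D, 6, n_restarts=12, threshold=1e-9,
                              reliability_fraction=1.0, seed=0)


class TestRefitAndVariance:
    def test_exact_refit_recovers_weights(self):
        D, W0, H0 = exact_low_rank(seed=11)
        W = refit_mixing(D, H0)
        assert np.max(np.abs(W - W0)) < 1e-6
        assert np.all(W >= 0)

    def test_orthogonal_support_subject_flagged(self):
        H = np.zeros((1, 10))
        H[0, :5] = 1.0
        D = np.zeros((2, 10))
        D[0, :5] = 2.0  # explainable
        D[1, 5:] = 3.0  # orthogonal in support
        with pytest.warns(UserWarning, match="unexplained"):
            W = refit_mixing(D, H)
        assert W[1, 0] == pytest.approx(0.0, abs=1e-9)

    def test_variance_explained_extremes(self):
        D, W0, H0 = exact_low_rank(seed=12)
        assert variance_explained(D, W0, H0) == pytest.approx(1.0, abs=1e-12)
        assert variance_explained(D, np.zeros_like(W0), H0) == 0.0


class TestComponentModelCorrelation:
    def test_model_against_itself_and_complement(self):
        dims = random_binary_dimensions([f"i{x}" for x in range(10)], 1, seed=13)
        model = dims["dim_1"]
        assert component_model_correlation(model.utv, model) == pytest.approx(1.0)
        assert component_model_correlation(1.0 - model.utv, model) == pytest.approx(-1.0)

    def test_noisy_planted_component_stays_high(self):
        # Spearman against a *binary* model with mid-ranked ties has an
        # analytic ceiling of ~0.866 for a balanced split, so a component
        # equal to the model plus tiny noise sits just below it
        dims = random_binary_dimensions([f"i{x}" for x in range(20)], 1, seed=14)
        vec = dims["dim_1"].utv + np.random.default_rng(0).normal(0, 0.05, n_pairs(20))
        assert component_model_correlation(vec, dims["dim_1"]) >= 0.85

    def test_zero_variance_returns_nan_with_warning(self):
        dims = random_binary_dimensions([f"i{x}" for x in range(8)], 1, seed=15)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = component_model_correlation(np.ones(n_pairs(8)), dims["dim_1"])
        assert np.isnan(out)
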