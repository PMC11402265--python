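"""Shape model: PCA correctness, projection identities, generalization."""

import numpy as np
import pytest

import neckssm as ns
from neckssm.errors import InvalidParameterError
from neckssm.ssm import (
    build_ssm,
    generalization_ability,
    grid_to_mesh,
    project,
    project_cohort,
    reconstruct,
    reconstruction_error,
    synthesize,
)


def random_grids(n, levels=5, angles=20, seed=0, scale=5.0):
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, scale, size=(n, levels, angles, 3))


def covariance_pca_oracle(grids):
    """Brute-force oracle: eigendecomposition of the explicitly formed
    sample covariance matrix (divisor n-1)."""
    X = grids.reshape(len(grids), -1)
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (len(X) - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    return w[order], V[:, order].T


class TestBuildSSM:
    def test_matches_covariance_eigendecomposition_oracle(self):
        grids = random_grids(20)
        model = build_ssm(grids)
        w, V = covariance_pca_oracle(grids)
        k = model.n_components
        assert np.allclose(model.variances, w[:k], rtol=1e-6)
        for j in range(k):
            dot = abs(model.components[j] @ V[j])
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_nonzero_component_count_is_n_minus_one(self):
        grids = random_grids(12)
        model = build_ssm(grids)
        assert model.n_nonzero == 11

    def test_identical_shapes_degenerate(self):
        grids = np.tile(random_grids(1), (8, 1, 1, 1))
        model = build_ssm(grids)
        assert model.variances.sum() == pytest.approx(0.0, abs=1e-18)
        assert model.n_retained == 0

    def test_variance_fractions_sum_to_one(self, small_cohort):
        necks, _ = small_cohort
        model = build_ssm(necks)
        assert model.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(model.variances) <= 1e-12).all()
        # orthonormality of the basis
        G = model.components @ model.components.T
        assert np.abs(G - np.eye(len(G))).max() < 1e-8

    def test_total_variance_identity(self):
        """Sum of mode variances equals mean squared centered norm / (n-1)."""
        grids = random_grids(15, seed=3)
        model = build_ssm(grids)
        X = grids.reshape(15, -1)
        Xc = X - X.mean(axis=0)
        assert model.variances.sum() == pytest.approx(
            (Xc**2).sum() / 14, rel=1e-10
        )

    def test_deterministic_components(self):
        grids = random_grids(10, seed=7)
        m1, m2 = build_ssm(grids), build_ssm(grids)
        assert np.array_equal(m1.components, m2.components)

    def test_too_few_subjects_and_nans_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_ssm(random_grids(1))
        bad = random_grids(5)
        bad[2, 0, 0, 0] = np.nan
        with pytest.raises(InvalidParameterError):
            build_ssm(bad)


@pytest.fixture(scope="module")
def model_and_grids():
    grids = random_grids(18, seed=5)
    return build_ssm(grids, retention_threshold=0.98), grids


class TestProjectSynthesizeReconstruct:

    def test_mean_shape_scores_zero(self, model_and_grids):
        model, _ = model_and_grids
        s = project(model.mean_shape.reshape(5, 20, 3), model)
        assert np.abs(s).max() < 1e-9

    def test_unit_mode_offset_recovers_score(self, model_and_grids):
        model, _ = model_and_grids
        k = 2
        shape = model.mean_shape + 2 * model.sd(k) * model.components[k]
        s = project(shape.reshape(5, 20, 3), model, n_components=model.n_components)
        expected = np.zeros(model.n_components)
        expected[k] = 2 * model.sd(k)
        assert np.abs(s - expected).max() < 1e-9

    def test_training_score_variance_equals_model_variance(self, model_and_grids):
        model, grids = model_and_grids
        S = np.stack([project(g, model, n_components=model.n_components) for g in grids])
        assert np.allclose(S.var(axis=0, ddof=1), model.variances, rtol=1e-6)
        assert np.abs(S.mean(axis=0)).max() < 1e-8

    def test_synthesize_zero_sd_is_mean(self, model_and_grids):
        model, _ = model_and_grids
        assert np.array_equal(synthesize(model, 0, 0.0).reshape(-1), model.mean_shape)

    def test_synthesize_project_roundtrip(self, model_and_grids):
        model, _ = model_and_grids
        for k in range(3):
            s = project(synthesize(model, k, 3.0), model, n_components=model.n_components)
            assert s[k] == pytest.approx(3.0 * model.sd(k), abs=1e-9)

    def test_full_reconstruction_is_exact(self, model_and_grids):
        model, grids = model_and_grids
        g = grids[4]
        s = project(g, model, n_components=model.n_components)
        recon = reconstruct(s, model)
        assert np.abs(recon - g).max() < 1e-8

    def test_zero_component_reconstruction_is_mean(self, model_and_grids):
        model, _ = model_and_grids
        recon = reconstruct(np.zeros(0), model)
        assert np.array_equal(recon.reshape(-1), model.mean_shape)

    def test_residual_norm_nonincreasing_in_components(self, model_and_grids):
        """Orthogonal projection onto nested mode subspaces: the residual
        norm of a held-out shape cannot grow as modes are added."""
        model, _ = model_and_grids
        held_out = random_grids(1, seed=99)[0].reshape(-1)
        errs = []
        for k in range(model.n_components + 1):
            s = project(held_out.reshape(5, 20, 3), model, n_components=k)
            recon = model.mean_shape + s @ model.components[:k]
            errs.append(np.linalg.norm(held_out - recon))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_out_of_range_mode_rejected(self, model_and_grids):
        model, _ = model_and_grids
        with pytest.raises(InvalidParameterError):
            synthesize(model, model.n_components, 1.0)

    def test_synthesized_mesh_is_closed(self, small_cohort):
        necks, _ = small_cohort
        model = build_ssm(necks)
        mesh = grid_to_mesh(synthesize(model, 0, 3.0))
        assert mesh.is_watertight


class TestDominantModeRecovery:
    def test_planted_modes_dominate_scree(self):
        """K independent latent modes + small noise -> K dominant variances."""
        rng = np.random.default_rng(4)
        d = 5 * 40 * 3
        K = 3
        modes = np.linalg.qr(rng.normal(size=(d, K)))[0].T
        a = rng.normal(0, [12.0, 8.0, 5.0], size=(60, K))
        X = a @ modes + rng.normal(0, 0.1, size=(60, d))
        model = build_ssm(X.reshape(60, 5, 40, 3))
        assert model.variances[K - 1] / model.variances[K] > 10

    def test_length_mode_dominates_axial_extent(self, small_cohort):
        """In a cohort whose main variation is neck length, the leading mode
        moves the distal level much more than any other mode does."""
        necks, _ = small_cohort
        model = build_ssm(necks)
        z_range = []
        for k in range(max(model.n_retained, 2)):
            z_lo = synthesize(model, k, -3.0)[-1, :, 2].mean()
            z_hi = synthesize(model, k, 3.0)[-1, :, 2].mean()
            z_range.append(abs(z_hi - z_lo))
        assert np.argmax(z_range) == 0


class TestGeneralization:
    def test_identical_cohort_zero_error(self):
        grids = np.tile(random_grids(1, seed=2), (6, 1, 1, 1))
        res = generalization_ability(grids)
        assert res.mean_error == pytest.approx(0.0, abs=1e-9)

    def test_noise_floor_matches_chi_distribution(self):
        """3-mode linear generative model with iid Gaussian landmark noise:
        the leave-one-out error converges to sigma * E[chi_3]
        = sigma * 2 * sqrt(2/pi)."""
        rng = np.random.default_rng(8)
        levels, angles = 5, 40
        d = levels * angles * 3
        sigma = 0.3
        modes = np.linalg.qr(rng.normal(size=(d, 3)))[0].T
        a = rng.normal(0, 10.0, size=(50, 3))
        X = a @ modes + rng.normal(0, sigma, size=(50, d))
        res = generalization_ability(X.reshape(50, levels, angles, 3), retention_threshold=0.80)
        assert (res.n_components_used == 3).all()
        expected = sigma * 2 * np.sqrt(2 / np.pi)
        assert res.mean_error == pytest.approx(expected, rel=0.10)
        assert res.ci95[0] <= res.mean_error <= res.ci95[1]

    def test_lower_threshold_cannot_reduce_error(self, small_cohort):
        necks, _ = small_cohort
        hi = generalization_ability(necks, retention_threshold=0.98)
        lo = generalization_ability(necks, retention_threshold=0.50)
        assert hi.mean_error <= lo.mean_error + 1e-9

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InvalidParameterError):
            generalization_ability(random_grids(2))


def test_project_cohort_carries_labels(small_cohort):
    necks, _ = small_cohort
    model = build_ssm(necks)
    scores = project_cohort(necks, model)
    assert scores.scores.shape == (len(necks), model.n_retained)
    assert set(scores.groups) == {"case", "control"}
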