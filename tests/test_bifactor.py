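import numpy as np
import pytest

from neurofactors import bifactor as bf
from neurofactors import simulate as sim
from neurofactors import tetrachoric as tc

from _oracles import geomin_angle_grid


def exact_population_matrix():
    cfg = sim.SimulationConfig(n_individuals=100, n_snps=10, h2=(0, 0, 0))
    return cfg, sim.latent_item_correlation(cfg)


class TestExtraction:
    def test_identity_input_gives_zero_loadings(self):
        L = bf.extract_unrotated(np.eye(12), 3)
        assert np.abs(L).max() < 1e-6

    def test_known_orthogonal_three_factor_subspace(self, rng):
        Lt = np.zeros((12, 3))
        Lt[:4, 0] = 0.7
        Lt[4:8, 1] = 0.6
        Lt[8:, 2] = 0.65
        R = Lt @ Lt.T
        np.fill_diagonal(R, 1.0)
        L = bf.extract_unrotated(R, 3)
        # principal angles between column spaces ~ 0
        Qa, _ = np.linalg.qr(L)
        Qb, _ = np.linalg.qr(Lt)
        s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
        assert np.abs(s - 1.0).max() < 1e-6

    def test_one_factor_closed_form(self):
        R = np.full((6, 6), 0.36)
        np.fill_diagonal(R, 1.0)
        L = bf.extract_unrotated(R, 1)
        assert np.abs(L - 0.6).max() < 1e-6


class TestGeominCriterion:
    def test_zero_matrix_value(self):
        # 3 rows x 2 columns of zeros at eps = 0.01: 3 * sqrt(1e-4) = 0.03
        assert bf.geomin_criterion(np.zeros((3, 2)), 0.01) == pytest.approx(0.03)

    def test_single_row_hand_value(self):
        val = bf.geomin_criterion(np.array([[0.5, 0.0]]), 0.01)
        assert val == pytest.approx(np.sqrt(0.26 * 0.01), abs=1e-12)

    def test_simple_structure_beats_rotated(self):
        L = np.zeros((6, 2))
        L[:3, 0] = 0.7
        L[3:, 1] = 0.7
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        R = np.array([[c, -s], [s, c]])
        assert bf.geomin_criterion(L, 0.01) < bf.geomin_criterion(L @ R, 0.01)


class TestRotation:
    def test_exact_structure_is_fixed_point(self):
        _, R = exact_population_matrix()
        A = bf.extract_unrotated(R, 3)
        m = bf.bifactor_geomin_rotate(A, n_starts=10, seed=0)
        # re-rotating the solved loadings changes nothing material
        m2 = bf.bifactor_geomin_rotate(m.loadings, n_starts=10, seed=1)
        assert m2.criterion_value <= m.criterion_value + 1e-8
        assert np.abs(np.abs(m2.loadings) - np.abs(m.loadings)).max() < 0.02

    def test_parameter_recovery_on_population_matrix(self):
        cfg, R = exact_population_matrix()
        A = bf.extract_unrotated(R, 3)
        m = bf.bifactor_geomin_rotate(A, seed=3)
        assert np.abs(m.loadings - cfg.loading_matrix).max() < 0.02
        assert m.phi[1, 2] == pytest.approx(sim.PHI_SPECIAL, abs=0.02)
        assert m.phi[0, 1] == 0.0 and m.phi[0, 2] == 0.0

    def test_brute_force_angle_grid_oracle(self):
        # orthogonal-specials toy: the only degree of freedom that changes
        # the criterion materially is the rotation angle of the two special
        # columns; gradient projection must match a dense grid
        Lt = sim.DEFAULT_LOADINGS
        rng = np.random.default_rng(8)
        th = rng.uniform(0.2, 1.2)
        c, s = np.cos(th), np.sin(th)
        Rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        A = Lt @ Rot  # scrambled special columns, orthogonal factors
        m = bf.bifactor_geomin_rotate(A, epsilon=0.01, n_starts=20, seed=2,
                                      oblique=False, fix_general=True)
        grid = geomin_angle_grid(A, epsilon=0.01)
        assert m.criterion_value <= grid + 1e-6
        assert m.criterion_value == pytest.approx(grid, abs=1e-4)
        # the unrestricted rotation can only do better
        free = bf.bifactor_geomin_rotate(A, epsilon=0.01, n_starts=20, seed=2)
        assert free.criterion_value <= m.criterion_value + 1e-8

    def test_rotation_preserves_common_covariance(self):
        _, R = exact_population_matrix()
        A = bf.extract_unrotated(R, 3)
        m = bf.bifactor_geomin_rotate(A, seed=0)
        before = A @ A.T
        after = m.loadings @ m.phi @ m.loadings.T
        assert np.abs(before - after).max() < 1e-8

    def test_criterion_not_above_identity_rotation(self):
        _, R = exact_population_matrix()
        A = bf.extract_unrotated(R, 3)
        m = bf.bifactor_geomin_rotate(A, seed=0)
        assert m.criterion_value <= bf.geomin_criterion(A[:, 1:], bf.DEFAULT_EPSILON) + 1e-10

    def test_sign_alignment(self):
        _, R = exact_population_matrix()
        A = bf.extract_unrotated(R, 3)
        m = bf.bifactor_geomin_rotate(A, seed=0)
        assert m.loadings[:, 0].mean() > 0
        for r in (1, 2):
            assert m.loadings[np.argmax(np.abs(m.loadings[:, r])), r] > 0


class TestFitIndices:
    def test_perfect_fit(self):
        _, R = exact_population_matrix()
        A = bf.extract_unrotated(R, 3)
        m = bf.bifactor_geomin_rotate(A, seed=0)
        m.uniqueness = 1.0 - np.diag(m.loadings @ m.phi @ m.loadings.T)
        fit = bf.fit_indices(m.implied_corr(), m, n=100_000)
        assert fit["srmr"] == pytest.approx(0.0, abs=1e-8)
        assert fit["rmsea"] == pytest.approx(0.0, abs=1e-6)
        assert fit["cfi"] == 1.0
        assert fit["tli"] == pytest.approx(1.0, abs=1e-6)

    def test_independence_model_gives_cfi_zero(self):
        _, R = exact_population_matrix()
        null = bf.BifactorModel(
            loadings=np.zeros((12, 3)), phi=np.eye(3), uniqueness=np.ones(12)
        )
        fit = bf.fit_indices(R, null, n=10_000)
        assert fit["cfi"] == pytest.approx(0.0, abs=1e-12)
        assert fit["srmr"] > 0.1

    def test_df_error(self):
        null = bf.BifactorModel(loadings=np.zeros((4, 3)), phi=np.eye(3))
        with pytest.raises(ValueError, match="degrees of freedom"):
            bf.fit_indices(np.eye(4), null, n=100)


class TestFactorScores:
    def test_identity_measurement_returns_items(self, rng):
        m = bf.BifactorModel(loadings=np.eye(3), phi=np.eye(3),
                             uniqueness=np.zeros(3) + 1e-12)
        X = rng.standard_normal((500, 3))
        X01 = (X > 0).astype(int)
        s = bf.factor_scores(X01, m)
        Xs = (X01 - X01.mean(0)) / X01.std(0)
        r = [np.corrcoef(s.scores[:, j], Xs[:, j])[0, 1] for j in range(3)]
        assert min(r) > 0.999

    def test_general_score_tracks_true_general_factor(self, measurement_cohort):
        cfg, factors, items = measurement_cohort
        poly = tc.tetrachoric_matrix(items)
        model = bf.fit_bifactor(poly, n=poly.n_used, seed=1)
        s = bf.factor_scores(items, model)
        cors = [
            abs(np.corrcoef(s.scores[:, j], factors.scores_true[:, 0])[0, 1])
            for j in range(3)
        ]
        assert np.argmax(cors) == 0
        assert cors[0] > 0.8

    def test_score_correlations_nonzero_despite_zero_phi(self, measurement_cohort):
        # estimated scores correlate even though the model fixes the
        # general-special correlations at zero - expected behaviour of
        # regression-method scoring
        cfg, factors, items = measurement_cohort
        poly = tc.tetrachoric_matrix(items)
        model = bf.fit_bifactor(poly, n=poly.n_used, seed=1)
        s = bf.factor_scores(items, model)
        C = np.corrcoef(s.scores.T)
        assert abs(C[0, 1]) > 0.01 or abs(C[0, 2]) > 0.01
        assert C[1, 2] > 0.05  # specials' scores clearly correlated


class TestCongruence:
    def test_identical_matrices(self):
        L = sim.DEFAULT_LOADINGS
        c, perm, signs = bf.congruence(L, L)
        assert np.allclose(c, 1.0)
        assert perm == (0, 1, 2)

    def test_negated_column_recovered_with_flip(self):
        L = sim.DEFAULT_LOADINGS
        L2 = L.copy()
        L2[:, 1] *= -1
        c, perm, signs = bf.congruence(L, L2)
        assert np.allclose(c, 1.0)
        assert signs[list(perm).index(1)] == -1.0

    def test_hand_value_single_column(self):
        a = np.array([[1.0], [0.0]])
        b = np.array([[1.0], [1.0]])
        c, _, _ = bf.congruence(a, b)
        assert c[0] == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_zero_column_raises(self):
        a = np.zeros((4, 2))
        with pytest.raises(ValueError, match="zero"):
            bf.congruence(a, np.ones((4, 2)))
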