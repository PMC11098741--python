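"""GRM, PCA coordinates and projection Procrustes."""

import numpy as np
import pytest

from oracles import numeric_procrustes_objective
from scsnv.ancestry import AncestryProjector, grm, pca_coords, procrustes_project


def two_populations(n_per=12, L=60, delta=0.6, seed=0):
    rng = np.random.default_rng(seed)
    p1 = rng.uniform(0.1, 0.9, L)
    p2 = np.clip(p1 + rng.choice([-delta, delta], L) * rng.random(L), 0.02, 0.98)
    g1 = rng.binomial(2, p1, size=(n_per, L))
    g2 = rng.binomial(2, p2, size=(n_per, L))
    return np.vstack([g1, g2]).astype(float)


class TestGRM:
    def test_matches_explicit_double_loop(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, size=(10, 50)).astype(float)
        R = grm(G)
        centered = G - G.mean(axis=0)
        expected = np.array(
            [[float(np.dot(centered[i], centered[j])) for j in range(10)] for i in range(10)]
        )
        assert np.allclose(R, expected)

    def test_identical_rows_give_identical_entries(self):
        G = np.vstack([np.arange(8), np.arange(8), np.arange(8) % 3]).astype(float)
        R = grm(G)
        assert np.allclose(R[0], R[1])
        assert np.linalg.matrix_rank(R) < 3

    def test_missing_imputed_to_column_mean(self):
        G = np.array([[0.0, 2.0], [2.0, np.nan], [1.0, 1.0]])
        R = grm(G, center=False)
        G_imp = np.array([[0.0, 2.0], [2.0, 1.5], [1.0, 1.0]])
        assert np.allclose(R, G_imp @ G_imp.T)

    def test_all_missing_column_dropped(self):
        G = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.warns(UserWarning):
            R = grm(G, center=False)
        assert np.allclose(R, np.outer([1, 2], [1, 2]))


class TestPCACoords:
    def test_populations_separate_on_first_component(self):
        G = two_populations()
        Y = pca_coords(grm(G), K=2)
        labels = np.array([0] * 12 + [1] * 12)
        between = abs(Y[labels == 0, 0].mean() - Y[labels == 1, 0].mean())
        within = Y[labels == 0, 0].std() + Y[labels == 1, 0].std()
        assert between > within

    def test_duplicated_sample_identical_coordinates(self):
        G = two_populations(seed=3)
        G = np.vstack([G, G[0]])
        Y = pca_coords(grm(G), K=2)
        assert np.allclose(Y[0], Y[-1])

    def test_k_beyond_rank_rejected(self):
        G = np.vstack([np.arange(6.0)] * 4)  # rank 1 after centering
        with pytest.raises(ValueError):
            pca_coords(grm(G), K=3)


class TestProcrustes:
    def test_identity_fit(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(15, 3))
        proj = procrustes_project(Y, np.vstack([Y, rng.normal(size=(1, 3))]))
        assert proj.rho == pytest.approx(1.0, abs=1e-10)
        assert proj.error < 1e-10
        assert np.allclose(proj.A.T @ proj.A, np.eye(3), atol=1e-8)

    def test_known_rotation_and_scale_recovered(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(20, 3))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        Z = 2.0 * Y @ Q  # combined coords: rotated by Q, scaled by 2
        proj = procrustes_project(Y, np.vstack([Z, rng.normal(size=(1, 3))]))
        assert proj.rho == pytest.approx(0.5, abs=1e-8)
        assert np.allclose(proj.A, Q.T, atol=1e-8)
        assert proj.error < 1e-8

    def test_objective_matches_numeric_minimizer(self):
        """Closed-form solution equals brute-force optimisation (<= 1e-6)."""
        rng = np.random.default_rng(6)
        for trial in range(3):
            Y = rng.normal(size=(20, 2))
            Z = rng.normal(size=(20, 4))
            proj = procrustes_project(Y, np.vstack([Z, rng.normal(size=(1, 4))]))
            brute = numeric_procrustes_objective(Y, Z, seed=trial)
            assert proj.error <= brute + 1e-6

    def test_objective_never_increases_with_extra_dimensions(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(18, 2))
        Z4 = rng.normal(size=(18, 4))
        e4 = procrustes_project(Y, np.vstack([Z4, np.zeros((1, 4))])).error
        Z5 = np.hstack([Z4, rng.normal(size=(18, 1))])
        e5 = procrustes_project(Y, np.vstack([Z5, np.zeros((1, 5))])).error
        assert e5 <= e4 + 1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            procrustes_project(np.zeros((5, 3)), np.zeros((6, 2)))


class TestProjector:
    def test_reference_samples_self_project_close(self):
        """Each reference individual re-projects near its own coordinates."""
        G = two_populations(seed=8)
        projector = AncestryProjector(K=2, K_prime=4).fit(G)
        spread = np.linalg.norm(
            projector.reference_coords_ - projector.reference_coords_.mean(axis=0),
            axis=1,
        ).mean()
        for i in (0, 5, 20):
            y = projector.transform(G[i])
            dist = np.linalg.norm(y[0] - projector.reference_coords_[i])
            assert dist < 0.35 * spread

    def test_new_sample_lands_with_its_population(self):
        G = two_populations(seed=9)
        rng = np.random.default_rng(10)
        p2_like = G[12:].mean(axis=0) / 2
        new = rng.binomial(2, np.clip(p2_like, 0.02, 0.98)).astype(float)
        projector = AncestryProjector(K=2, K_prime=4).fit(G)
        y = projector.transform(new)[0]
        d1 = np.linalg.norm(y - projector.reference_coords_[:12].mean(axis=0))
        d2 = np.linalg.norm(y - projector.reference_coords_[12:].mean(axis=0))
        assert d2 < d1
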