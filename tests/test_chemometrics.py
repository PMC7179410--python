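"""PCA/OPLS-DA numerics: brute-force CV oracle, algebraic identities,
equivalence with an independent NIPALS PLS, and permutation behaviour."""

import numpy as np
import pytest

from metabomark.chemometrics import (
    ChemometricsError,
    OPLSDA,
    PCAModel,
    fit_oplsda,
    fit_pca,
    fold_assignment,
)
from metabomark.preprocessing import ScaledMatrix


def scaled(x, sample_ids=None):
    x = np.asarray(x, dtype=float)
    return ScaledMatrix(
        values=x,
        centers=np.zeros(x.shape[1]),
        scale_factors=np.ones(x.shape[1]),
        feature_ids=[f"f{j}" for j in range(x.shape[1])],
        sample_ids=sample_ids,
    )


def informative_data(n_a=20, n_b=20, p=30, n_inf=5, noise=0.5, seed=0,
                     orth_strength=0.0):
    """Centered matrix with group structure in the first n_inf features and an
    optional class-orthogonal latent component; returns (x, y, latent)."""
    rng = np.random.default_rng(seed)
    y = np.array(["a"] * n_a + ["b"] * n_b)
    signs = np.where(y == "a", 1.0, -1.0)
    x = rng.normal(0, noise, size=(n_a + n_b, p))
    x[:, :n_inf] += signs[:, None]
    latent = rng.normal(0, 1, n_a + n_b)
    if orth_strength:
        load = rng.normal(0, 1, p)
        load[:n_inf] = 0
        x += orth_strength * np.outer(latent, load)
    x -= x.mean(axis=0)
    return x, y, latent


class TestPCA:
    def test_rank_one_matrix_explained_by_pc1(self):
        v = np.array([1.0, 2.0, 3.0])
        x = np.outer([1.0, 2.0, 3.0, 4.0], v)
        x -= x.mean(axis=0)
        res = PCAModel(x).fit(1, cv_folds=2)
        assert res.r2x_per_component[0] == pytest.approx(1.0)

    def test_full_rank_fit_captures_everything(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 4))
        x -= x.mean(axis=0)
        res = PCAModel(x).fit(4, cv_folds=5)
        assert res.r2x_cum == pytest.approx(1.0)
        # loadings orthonormal
        gram = res.loadings.T @ res.loadings
        assert np.allclose(gram, np.eye(4), atol=1e-8)

    def test_r2x_nondecreasing_and_q2_below_r2x(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 12)) + np.outer(rng.normal(size=30),
                                                 rng.normal(size=12))
        x -= x.mean(axis=0)
        res = PCAModel(x).fit(5)
        assert np.all(res.r2x_per_component >= -1e-12)
        assert res.q2_cum <= res.r2x_cum

    def test_q2_matches_bruteforce_press_oracle(self):
        """Q² equals an independent, naively coded fold loop to 1e-10."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(23, 9)) + 2 * np.outer(rng.normal(size=23),
                                                    rng.normal(size=9))
        x -= x.mean(axis=0)
        ids = [f"s{i:02d}" for i in range(23)]
        n_comp, folds = 3, 7
        res = PCAModel(scaled(x, ids)).fit(n_comp, cv_folds=folds)

        # oracle: explicit loop, recomputing everything from definitions
        order = np.argsort(np.asarray(ids))
        assign = np.empty(23, dtype=int)
        assign[order] = np.arange(23) % folds
        press = ss = 0.0
        for k in range(folds):
            tr, te = assign != k, assign == k
            mu = x[tr].mean(axis=0)
            _, _, vt = np.linalg.svd(x[tr] - mu, full_matrices=False)
            pk = vt[:n_comp].T
            xc = x[te] - mu
            press += ((xc - xc @ pk @ pk.T) ** 2).sum()
            ss += (xc ** 2).sum()
        assert res.q2_cum == pytest.approx(1 - press / ss, abs=1e-10)

    def test_q2_invariant_to_row_order(self):
        x, _, _ = informative_data(seed=4)
        ids = [f"s{i:02d}" for i in range(x.shape[0])]
        res1 = PCAModel(scaled(x, ids)).fit(3)
        perm = np.random.default_rng(0).permutation(len(ids))
        res2 = PCAModel(scaled(x[perm], [ids[i] for i in perm])).fit(3)
        assert res1.q2_cum == pytest.approx(res2.q2_cum, abs=1e-12)

    def test_too_many_components_rejected(self):
        with pytest.raises(ChemometricsError, match="n_components"):
            PCAModel(np.zeros((5, 3))).fit(5)


class TestOPLSDA:
    def test_perfect_predictor_dominates(self):
        rng = np.random.default_rng(5)
        y = np.array(["a"] * 10 + ["b"] * 10)
        x = rng.normal(0, 0.1, (20, 6))
        x[:, 0] = np.where(y == "a", 1.0, -1.0)
        x -= x.mean(axis=0)
        res = fit_oplsda(scaled(x), y, k_orth=0, cv_folds=5)
        assert res.vip.idxmax() == "f0"
        assert res.r2y_cum >= 0.99

    def test_vip_normalisation_identity(self):
        x, y, _ = informative_data(seed=6, orth_strength=1.0)
        res = fit_oplsda(scaled(x), y, k_orth=2, cv_folds=5)
        assert (res.vip ** 2).mean() == pytest.approx(1.0, abs=1e-6)
        assert (res.vip >= 0).all()

    def test_identical_features_share_unit_vip(self):
        rng = np.random.default_rng(7)
        y = np.array(["a"] * 8 + ["b"] * 8)
        col = np.where(y == "a", 1.0, -1.0) + rng.normal(0, 0.3, 16)
        x = np.tile((col - col.mean())[:, None], (1, 4))
        res = fit_oplsda(scaled(x), y, k_orth=0, cv_folds=4)
        assert np.allclose(res.vip.to_numpy(), 1.0, atol=1e-9)

    def test_two_feature_toy_vip_values(self):
        """One perfect predictor + one noise feature: VIP -> (sqrt(2), ~0)."""
        rng = np.random.default_rng(8)
        y = np.array(["a"] * 12 + ["b"] * 12)
        x = np.column_stack([
            np.where(y == "a", 1.0, -1.0),
            rng.normal(0, 1, 24) * 1e-3,
        ])
        x -= x.mean(axis=0)
        res = fit_oplsda(scaled(x), y, k_orth=0, cv_folds=4)
        assert res.vip["f0"] == pytest.approx(np.sqrt(2), abs=1e-3)
        assert res.vip["f1"] < 0.1

    def test_scores_orthogonal_and_variance_conserved(self):
        x, y, _ = informative_data(seed=9, orth_strength=1.5)
        res = fit_oplsda(scaled(x), y, k_orth=3, cv_folds=5)
        for a in range(res.k_orth):
            t_o = res.t_orth[:, a]
            assert abs(res.t_pred @ t_o) < 1e-8 * np.linalg.norm(res.t_pred) * np.linalg.norm(t_o)
        # total SS = captured (pred + orth) + residual
        captured = np.outer(res.t_pred, res.p_pred)
        for a in range(res.k_orth):
            captured = captured + np.outer(res.t_orth[:, a], res.p_orth[:, a])
        resid = x - captured
        total = (x ** 2).sum()
        assert total == pytest.approx((captured ** 2).sum() + (resid ** 2).sum(),
                                      rel=1e-8)

    def test_k0_equals_independent_nipals_pls(self):
        """With no orthogonal components the model is 1-component PLS-DA;
        scores match an independently coded NIPALS iteration exactly."""
        x, y, _ = informative_data(seed=10)
        res = fit_oplsda(scaled(x), y, k_orth=0, cv_folds=5)
        # independent NIPALS for a univariate y (converges in one step from y)
        yc = np.where(y == "a", 1.0, -1.0)
        yc = yc - yc.mean()
        u = yc.copy()
        for _ in range(200):
            w = x.T @ u / (u @ u)
            w /= np.linalg.norm(w)
            t = x @ w
            q = yc @ t / (t @ t)
            u_new = yc * q / (q * q)
            if np.allclose(u_new, u, atol=1e-13):
                break
            u = u_new
        corr = np.corrcoef(res.t_pred, t)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_component_captures_planted_structure(self):
        x, y, latent = informative_data(seed=11, orth_strength=2.0)
        ids = [f"s{i:02d}" for i in range(x.shape[0])]
        res0 = fit_oplsda(scaled(x, ids), y, k_orth=0)
        res1 = fit_oplsda(scaled(x, ids), y, k_orth=1)
        assert res1.q2_cum >= res0.q2_cum - 1e-9
        r = np.corrcoef(res1.t_orth[:, 0], latent)[0, 1]
        assert abs(r) >= 0.8

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ChemometricsError, match="two levels"):
            OPLSDA(x, ["a"] * 10)

    def test_summary_mentions_key_statistics(self):
        x, y, _ = informative_data(seed=12)
        res = fit_oplsda(scaled(x), y, k_orth=1, cv_folds=5)
        text = res.summary()
        assert "R2Y(cum)" in text and "Q2" in text

    def test_s_plot_correlations_bounded(self):
        x, y, _ = informative_data(seed=13)
        res = fit_oplsda(scaled(x), y, k_orth=1, cv_folds=5)
        assert res.s_plot["pcorr1"].between(-1, 1).all()
        # informative features sit in the high-|covariance|, high-|corr| corner
        assert res.s_plot["pcorr1"].iloc[:5].abs().min() > 0.5


class TestPermutationTest:
    def test_identity_relabelling_reproduces_original(self):
        x, y, _ = informative_data(seed=14)
        model = OPLSDA(scaled(x), y)
        res = model.fit(k_orth=1, cv_folds=5)
        res_again = OPLSDA(scaled(x), y).fit(k_orth=1, cv_folds=5)
        assert res.r2y_cum == pytest.approx(res_again.r2y_cum, abs=1e-12)
        assert res.q2_cum == pytest.approx(res_again.q2_cum, abs=1e-12)

    def test_informative_data_beats_all_permutations(self):
        x, y, _ = informative_data(seed=15, noise=0.4)
        perm = OPLSDA(scaled(x), y).permutation_test(
            k_orth=1, cv_folds=5, n_permutations=50, seed=1
        )
        assert perm.q2_original > perm.q2_perm.max()
        assert perm.empirical_p_q2() <= 1 / 50

    def test_pure_noise_q2_intercept_near_original(self):
        intercept_gaps = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(60, 10))
            x -= x.mean(axis=0)
            y = np.array(["a"] * 30 + ["b"] * 30)
            perm = OPLSDA(scaled(x), y).permutation_test(
                k_orth=0, cv_folds=5, n_permutations=30, seed=seed
            )
            intercept_gaps.append(abs(perm.q2_intercept - perm.q2_original))
        assert np.median(intercept_gaps) < 0.2

    def test_vector_lengths(self):
        x, y, _ = informative_data(seed=16)
        perm = OPLSDA(scaled(x), y).permutation_test(
            k_orth=0, cv_folds=4, n_permutations=25, seed=3
        )
        assert len(perm.r2_perm) == len(perm.q2_perm) == 25
        assert np.all((perm.y_correlations >= 0) & (perm.y_correlations <= 1))


def test_fold_assignment_round_robin():
    folds = fold_assignment(10, 3, [f"s{i}" for i in range(10)])
    assert sorted(np.bincount(folds)) == [3, 3, 4]
    with pytest.raises(ChemometricsError):
        fold_assignment(5, 1)
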