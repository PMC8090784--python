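"""Weighted PCA, variable statistics, and component-retention rules."""

import numpy as np
import pandas as pd
import pytest

from msvlot import (RetentionCriteria, broken_stick,
                    contributions_from_coordinates, cos2_from_coordinates,
                    scree_elbow, select_from_spectrum, variable_stats,
                    weighted_pca)


def random_matrix(rng, n=40, p=6):
    cols = [f"v{j}" for j in range(p)]
    return pd.DataFrame(rng.normal(size=(n, p)) @ rng.normal(size=(p, p)),
                        columns=cols)


class TestWeightedPCA:
    def test_uniform_weights_match_plain_pca(self, rng):
        X = random_matrix(rng)
        ours = weighted_pca(X)
        # plain PCA: eigenvalues of the (population) covariance matrix
        Xc = X.to_numpy() - X.to_numpy().mean(0)
        lam_ref = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / len(X)))[::-1]
        np.testing.assert_allclose(ours.eigenvalues, lam_ref, rtol=1e-9)
        explicit = weighted_pca(X, np.ones(len(X)))
        np.testing.assert_allclose(ours.eigenvalues, explicit.eigenvalues)
        pd.testing.assert_frame_equal(ours.scores, explicit.scores)

    def test_collinear_data_has_single_nonzero_eigenvalue(self, rng):
        t = rng.normal(size=30)
        direction = rng.normal(size=6)
        X = pd.DataFrame(np.outer(t, direction), columns=list("abcdef"))
        res = weighted_pca(X)
        total = np.var(X.to_numpy(), axis=0).sum()
        assert res.eigenvalues[0] == pytest.approx(total, rel=1e-9)
        np.testing.assert_allclose(res.eigenvalues[1:], 0.0, atol=1e-9 * total)

    def test_zero_weight_rows_equal_pca_on_subset(self, rng):
        X = random_matrix(rng, n=30)
        w = np.ones(30)
        w[[3, 7, 20]] = 0.0
        full = weighted_pca(X, w)
        sub = weighted_pca(X.iloc[[i for i in range(30) if w[i] > 0]])
        np.testing.assert_allclose(full.eigenvalues, sub.eigenvalues, rtol=1e-9)
        np.testing.assert_allclose(
            full.variable_coordinates.to_numpy(),
            sub.variable_coordinates.to_numpy(),
            atol=1e-9,
        )
        # zero-weight rows still receive scores by projection
        assert np.isfinite(full.scores.iloc[3].to_numpy()).all()

    def test_weight_scale_invariance(self, rng):
        X = random_matrix(rng)
        w = rng.uniform(0.5, 2.0, size=len(X))
        a = weighted_pca(X, w)
        b = weighted_pca(X, 17.0 * w)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, rtol=1e-12)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_reconstruction_of_weighted_covariance(self, rng):
        X = random_matrix(rng)
        w = rng.uniform(0.1, 1.0, size=len(X))
        res = weighted_pca(X, w)
        wn = w / w.sum()
        Xc = X.to_numpy() - wn @ X.to_numpy()
        cov = Xc.T @ (wn[:, None] * Xc)
        V = res.variable_coordinates.to_numpy() / np.where(
            res.eigenvalues > 0, np.sqrt(res.eigenvalues), 1.0
        )
        recon = (V * res.eigenvalues) @ V.T
        assert np.linalg.norm(recon - cov) <= 1e-9 * np.linalg.norm(cov)

    def test_score_weighted_covariance_is_diagonal(self, rng):
        X = random_matrix(rng)
        w = rng.uniform(0.1, 1.0, size=len(X))
        res = weighted_pca(X, w)
        wn = w / w.sum()
        S = res.scores.to_numpy()
        cov = S.T @ (wn[:, None] * S)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-9 * res.eigenvalues[0]
        np.testing.assert_allclose(np.diag(cov), res.eigenvalues, atol=1e-9)

    def test_eigenvalue_sum_is_total_weighted_variance(self, rng):
        X = random_matrix(rng)
        w = rng.uniform(0.1, 1.0, size=len(X))
        res = weighted_pca(X, w)
        wn = w / w.sum()
        Xc = X.to_numpy() - wn @ X.to_numpy()
        assert res.eigenvalues.sum() == pytest.approx(
            (wn[:, None] * Xc**2).sum(), rel=1e-9
        )

    def test_rotation_leaves_eigenvalues_unchanged(self, rng):
        X = random_matrix(rng)
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        rotated = pd.DataFrame(X.to_numpy() @ Q, columns=X.columns)
        a = weighted_pca(X)
        b = weighted_pca(rotated)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, rtol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        res = weighted_pca(random_matrix(rng))
        V = res.variable_coordinates.to_numpy()
        for j in range(V.shape[1]):
            if res.eigenvalues[j] > 1e-12:
                assert V[np.argmax(np.abs(V[:, j])), j] > 0

    def test_degenerate_inputs_rejected(self, rng):
        X = random_matrix(rng, n=10)
        with pytest.raises(ValueError, match="positive sum"):
            weighted_pca(X, np.zeros(10))
        with pytest.raises(ValueError, match="positive weight"):
            weighted_pca(X, np.r_[1.0, 1.0, np.zeros(8)])
        with pytest.raises(ValueError):
            weighted_pca(X, np.ones(9))


class TestVariableStats:
    def test_invariant_sums(self, rng):
        res = weighted_pca(random_matrix(rng))
        assert res.percent_variance.sum() == pytest.approx(100, abs=1e-9)
        np.testing.assert_allclose(res.contributions.sum(axis=0), 100, atol=1e-9)
        np.testing.assert_allclose(res.cos2.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_variance_variable_reported_missing(self, rng):
        coords = pd.DataFrame([[1.0, 0.5], [0.0, 0.0]], index=["a", "b"],
                              columns=["PC1", "PC2"])
        with pytest.warns(UserWarning, match="zero-variance"):
            cos2 = cos2_from_coordinates(coords)
        assert cos2.loc["b"].isna().all()
        assert cos2.loc["a", "PC1"] == pytest.approx(0.8)

    def test_tidy_table_shape(self, rng):
        res = weighted_pca(random_matrix(rng))
        table = variable_stats(res)
        assert len(table) == 6 * res.n_components
        assert set(table.columns) == {
            "variable", "component", "coordinate", "cos2", "contribution"
        }


class TestBrokenStick:
    def test_single_and_two_piece_closed_forms(self):
        np.testing.assert_allclose(broken_stick(1), [1.0])
        np.testing.assert_allclose(broken_stick(2), [0.75, 0.25])

    def test_six_piece_harmonic_sums(self):
        b = broken_stick(6)
        harmonic = [sum(1.0 / i for i in range(k, 7)) / 6 for k in range(1, 7)]
        np.testing.assert_allclose(b, harmonic, rtol=1e-12)
        assert b.sum() == pytest.approx(1.0)
        assert (np.diff(b) < 0).all()

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            broken_stick(0)


class TestScreeElbow:
    @pytest.mark.parametrize("spectrum,expected", [
        ((10, 1, 0.9, 0.8), 2),        # single sharp drop
        ((4, 3, 2, 1), 2),             # all second differences 0: tie rule
        ((5, 4, 1, 0.9, 0.8), 3),      # drop after the second component
    ])
    def test_elbow_location(self, spectrum, expected):
        assert scree_elbow(spectrum) == expected

    def test_too_short_spectrum(self):
        with pytest.raises(ValueError):
            scree_elbow([2, 1])


class TestSelectComponents:
    def test_published_spectrum_retains_four(self):
        """Eigenvalues 2.69/1.81/1.09/0.77 at 38.9/26.1/15.8/11.2 percent
        (remainder ~8.0 percent over two trailing components) keep the
        first four components."""
        lam = np.array([2.69, 1.81, 1.09, 0.77, 0.35, 0.21])
        pv = np.array([38.9, 26.1, 15.8, 11.2, 5.0, 3.0])
        m, diag = select_from_spectrum(lam, pv)
        assert m == 4
        assert diag["cumulative_percent"][3] == pytest.approx(92.0)

    def test_single_component_spectrum(self):
        m, _ = select_from_spectrum([5.0], [100.0])
        assert m == 1

    def test_eigen_floor_fallback_warns(self):
        """Cumulative variance first reaches 90% at a component whose
        eigenvalue is below the floor: fall back with a warning."""
        lam = np.array([5.0, 2.0, 1.5, 0.5, 0.4, 0.2])
        pv = 100 * lam / lam.sum()
        with pytest.warns(UserWarning, match="cumulative variance alone"):
            m, diag = select_from_spectrum(lam, pv)
        assert m == 4
        assert diag.get("eigen_min_warning")

    def test_diagnostics_attached_not_enforced(self):
        lam = np.array([5.0, 3.0, 1.0, 0.9, 0.8, 0.71])
        m, diag = select_from_spectrum(lam)
        assert "broken_stick" in diag and "elbow_k" in diag
        # retention ignores the diagnostics entirely
        crit = RetentionCriteria(broken_stick_diagnostic=False,
                                 elbow_diagnostic=False)
        m2, diag2 = select_from_spectrum(lam, criteria=crit)
        assert m2 == m
        assert "broken_stick" not in diag2

    def test_invalid_criteria(self):
        with pytest.raises(ValueError):
            RetentionCriteria(cum_var_min=0.0)
        with pytest.raises(ValueError):
            RetentionCriteria(eigen_min=-1)
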