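"""Index derivation: standardization, diagnostics, SMOTE balance, PCA fit."""

import numpy as np
import pandas as pd
import pytest

from driglucose import (
    DiabetesRiskIndex,
    balance_calibration_sets,
    bartlett_sphericity,
    fit_index,
    index_variant,
    kmo,
    one_factor_profiles,
    published_model,
    smote,
    standardize,
)
from driglucose.exposure import ALL_VARIABLES, NDVI_METRICS, SES_VARIABLES
from driglucose.index import DegenerateVariableError, ScoringError


class TestStandardize:
    def test_three_point_column(self):
        z, means, sds = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert np.allclose(z[:, 0], [-1, 0, 1])
        assert means[0] == 2.0 and sds[0] == 1.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(100, 15)))
        z1, _, _ = standardize(X)
        z2, _, _ = standardize(pd.DataFrame(z1))
        assert np.allclose(z1, z2, atol=1e-10)
        assert np.abs(z1.mean(axis=0)).max() < 1e-10
        assert np.allclose(z1.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_constant_column_named_in_error(self):
        X = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(DegenerateVariableError, match="flat"):
            standardize(X)


class TestBartlett:
    def test_identity_is_spherical(self):
        res = bartlett_sphericity(np.eye(6), n=100)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_df_formula(self):
        assert bartlett_sphericity(np.eye(15), n=500).df == 105

    def test_two_by_two_hand_oracle(self):
        """r = 0.5, n = 100: chi2 = -(99 - 9/6) ln(det [[1,.5],[.5,1]])."""
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        res = bartlett_sphericity(R, n=100)
        expected = -(100 - 1 - (2 * 2 + 5) / 6) * np.log(0.75)
        assert res.chi2 == pytest.approx(expected)
        assert res.df == 1

    def test_singular_matrix_rejected(self):
        R = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            bartlett_sphericity(R, n=50)


def _partial_corr_oracle(R):
    """Partial correlations via regression residuals (independent of the
    anti-image inverse-matrix formula used by the implementation)."""
    rng = np.random.default_rng(42)
    X = rng.multivariate_normal(np.zeros(len(R)), R, size=200_000)
    p = len(R)
    Q = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            Z = X[:, others]
            proj = Z @ np.linalg.lstsq(Z, X[:, [i, j]], rcond=None)[0]
            resid = X[:, [i, j]] - proj
            Q[i, j] = Q[j, i] = np.corrcoef(resid[:, 0], resid[:, 1])[0, 1]
    return Q


class TestKMO:
    def test_single_factor_matches_residual_oracle(self):
        """All pairwise r = 0.8, p = 5: MSA agrees with a Monte-Carlo
        regression-residual anti-image oracle."""
        p = 5
        R = np.full((p, p), 0.8)
        np.fill_diagonal(R, 1.0)
        Q = _partial_corr_oracle(R)
        off = ~np.eye(p, dtype=bool)
        expected = (R[off] ** 2).sum() / ((R[off] ** 2).sum() + (Q[off] ** 2).sum())
        assert kmo(R) == pytest.approx(expected, abs=0.01)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(200, 6))
        A[:, 3:] += A[:, :3]
        R = np.corrcoef(A, rowvar=False)
        perm = rng.permutation(6)
        assert kmo(R) == pytest.approx(kmo(R[np.ix_(perm, perm)]), abs=1e-12)

    def test_diffuse_structure_gives_poor_adequacy(self):
        """With only weak, diffuse correlations the partials are as large as
        the raw correlations, so MSA sits near 0.5 — far below the ~0.74
        adequacy benchmark for a usable factor structure."""
        R = np.eye(8) + 0.01 * (np.ones((8, 8)) - np.eye(8))
        assert kmo(R) < 0.6

    def test_value_in_unit_interval(self):
        R = np.full((4, 4), 0.5)
        np.fill_diagonal(R, 1.0)
        assert 0 <= kmo(R) <= 1


class TestSMOTE:
    def test_two_points_interpolate_on_segment(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        synth = smote(X, k=1, n_synthetic=50, seed=0)
        # on the segment y = x, within the endpoints
        assert np.allclose(synth[:, 0], synth[:, 1], atol=1e-12)
        assert (synth >= 0).all() and (synth <= 2).all()

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            smote(np.zeros((3, 2)), k=3, n_synthetic=5, seed=0)

    def test_deterministic_under_seed(self):
        X = np.random.default_rng(5).normal(size=(30, 4))
        a = smote(X, k=5, n_synthetic=40, seed=9)
        b = smote(X, k=5, n_synthetic=40, seed=9)
        assert np.array_equal(a, b)

    def test_synthetics_inside_minority_hull(self):
        from scipy.spatial import Delaunay
        X = np.random.default_rng(2).normal(size=(40, 3))
        synth = smote(X, k=5, n_synthetic=200, seed=3)
        hull = Delaunay(X)
        assert (hull.find_simplex(synth) >= 0).all()


class TestBalanceCalibrationSets:
    @staticmethod
    def _imbalanced(n=500, frac=0.1, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        y = (rng.random(n) < frac).astype(int)
        return X, y

    def test_balanced_input_is_noop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        y = np.repeat([0, 1], 50)
        sets = balance_calibration_sets(X, y, n_iterations=3, seed=1,
                                        undersample_factor=1.0)
        for s in sets:
            assert (s.provenance == "original").all()
            assert s.y.sum() == 50 and len(s.y) == 100

    def test_label_ratio_band(self):
        X, y = self._imbalanced()
        sets = balance_calibration_sets(X, y, n_iterations=5, seed=2)
        for s in sets:
            assert s.label_ratio() == pytest.approx(1.0, abs=0.1)

    def test_reproducible_sequence(self):
        X, y = self._imbalanced(seed=3)
        a = balance_calibration_sets(X, y, n_iterations=4, seed=7)
        b = balance_calibration_sets(X, y, n_iterations=4, seed=7)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.X, s2.X) and np.array_equal(s1.y, s2.y)
        # iterations differ from each other
        assert not np.array_equal(a[0].X, a[1].X)

    def test_minority_too_small_rejected(self):
        X = np.zeros((20, 2))
        y = np.array([1] * 3 + [0] * 17)
        with pytest.raises(ValueError):
            balance_calibration_sets(X, y, n_iterations=1, seed=0, k_neighbours=5)


class TestFitIndex:
    @staticmethod
    def _balanced_profiles(n=400, seed=0, loadings=None):
        if loadings is None:
            loadings = np.full(len(ALL_VARIABLES), 0.7)
            loadings[[i for i, v in enumerate(ALL_VARIABLES) if v.startswith("ndvi")]] *= -1
            # deprivation-oriented variables load positively on the latent
            for i, v in enumerate(ALL_VARIABLES):
                if "income" in v or v in ("labour_participation_pct", "dwellings_owned_pct"):
                    loadings[i] *= -1
        X, y, f = one_factor_profiles(loadings, n, prevalence=0.5, seed=seed)
        return X, y, f

    def test_two_correlated_variables_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=300)
        X = pd.DataFrame({"transfer_payments_pct": a, "lone_parent_pct": 2 * a + 1})
        y = np.repeat([0, 1], 150)
        res = DiabetesRiskIndex(X, y, variables=list(X.columns)).fit(
            n_iterations=1, seed=0, drop_threshold=0.0
        )
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(np.abs(res.loadings), 1 / np.sqrt(2), atol=1e-10)

    def test_loadings_unit_norm(self):
        X, y, _ = self._balanced_profiles()
        res = fit_index(X, y, n_iterations=5, seed=1)
        assert np.sum(res.loadings**2) == pytest.approx(1.0, abs=1e-10)
        assert res.variance_explained[0] >= res.variance_explained[1:].max()

    def test_single_iteration_matches_sklearn_pca(self):
        """With one already-balanced calibration set the loadings equal the
        first principal axis from sklearn on the standardized data."""
        from sklearn.decomposition import PCA
        X, y, _ = self._balanced_profiles(seed=4)
        res = DiabetesRiskIndex(X, y).fit(n_iterations=1, seed=0, drop_threshold=0.0,
                                          k_neighbours=5)
        # reconstruct the single balanced set the fit used
        sets = balance_calibration_sets(X.to_numpy(), y, n_iterations=1, seed=0)
        Z = (sets[0].X - sets[0].X.mean(0)) / sets[0].X.std(0, ddof=1)
        ref = PCA(n_components=1).fit(Z).components_[0]
        if ref @ res.loadings < 0:
            ref = -ref
        assert np.allclose(res.loadings, ref, atol=1e-8)

    def test_score_endpoints_and_clamping(self):
        X, y, _ = self._balanced_profiles(seed=6)
        model = DiabetesRiskIndex(X, y)
        res = model.fit(n_iterations=1, seed=0, drop_threshold=0.0)
        raw = res.raw_score(X)
        lo, hi = int(np.argmin(raw)), int(np.argmax(raw))
        scores = res.score(X)
        # calibration pool == X here (balanced input, one iteration)
        assert scores[lo] == pytest.approx(-1.0, abs=1e-9)
        assert scores[hi] == pytest.approx(1.0, abs=1e-9)
        far = X.iloc[[hi]] * 10
        clamped, flags = res.score(far, return_flags=True)
        assert clamped[0] == 1.0 and flags[0]

    def test_sign_convention_tracks_deprivation(self):
        """Where deprivation rises and greenspace falls together, the score
        correlates strongly and positively with the latent deprivation."""
        lam = np.full(len(ALL_VARIABLES), 0.8)
        for i, v in enumerate(ALL_VARIABLES):
            if "income" in v or v.startswith("ndvi") or v in (
                "labour_participation_pct", "dwellings_owned_pct"):
                lam[i] = -0.8
        X, y, f = one_factor_profiles(lam, 2000, prevalence=0.5, seed=8)
        res = fit_index(X, y, n_iterations=5, seed=2)
        r = np.corrcoef(res.score(X), f)[0, 1]  # f is the deprivation latent
        assert r > 0.9

    def test_weak_variables_dropped_and_refit(self):
        lam = np.full(10, 0.8)
        lam[-2:] = 0.0  # two pure-noise variables
        X, y, _ = one_factor_profiles(lam, 2000, prevalence=0.5, seed=11)
        res = DiabetesRiskIndex(X, y, variables=list(X.columns)).fit(
            n_iterations=5, seed=1, drop_threshold=0.05, anchor="var_1"
        )
        assert set(res.dropped) == {"var_9", "var_10"}
        assert len(res.variables) == 8

    def test_save_load_roundtrip(self, tmp_path):
        X, y, _ = self._balanced_profiles(seed=12)
        res = fit_index(X, y, n_iterations=2, seed=0)
        path = tmp_path / "model.txt"
        res.save(path)
        from driglucose import IndexModelResults
        back = IndexModelResults.load(path)
        assert back.variables == res.variables
        assert np.allclose(back.loadings, res.loadings)
        assert np.allclose(back.score(X), res.score(X))


class TestPublishedModel:
    def test_shipped_constants(self):
        res = published_model()
        lut = dict(zip(res.variables, res.loadings))
        assert lut["transfer_payments_pct"] == -0.35
        assert lut["ndvi_median"] == 0.26
        assert len(res.variables) == 15

    def test_scoring_requires_calibration(self):
        X, _, _ = one_factor_profiles(np.full(15, 0.5), 50, seed=0)
        with pytest.raises(ScoringError):
            published_model().score(X)

    def test_calibrated_scores_in_range(self):
        X, _, _ = one_factor_profiles(np.full(15, 0.5), 200, seed=1)
        res = published_model().calibrate(X)
        s = res.score(X)
        assert s.min() >= -1 and s.max() <= 1
        assert s.min() == pytest.approx(-1) and s.max() == pytest.approx(1)


class TestVariants:
    @staticmethod
    def _data():
        lam = np.full(len(ALL_VARIABLES), 0.7)
        return one_factor_profiles(lam, 500, prevalence=0.5, seed=5)[:2]

    def test_variant_variable_subsets(self):
        X, y = self._data()
        ses = index_variant(X, y, "ses_only", n_iterations=2, seed=0, drop_threshold=0.0)
        green = index_variant(X, y, "greenspace_only", n_iterations=2, seed=0,
                              drop_threshold=0.0)
        combined = index_variant(X, y, "combined", n_iterations=2, seed=0,
                                 drop_threshold=0.0)
        assert set(ses.variables) <= set(SES_VARIABLES) and len(ses.variables) == 11
        assert set(green.variables) == set(NDVI_METRICS)
        assert set(combined.variables) == set(ses.variables) | set(green.variables)

    def test_empty_subset_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError):
            index_variant(X[list(SES_VARIABLES)], y, "greenspace_only")
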