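"""Decomposition stages: strength, Grubbs gate, mirror, SVD, varimax, scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from olsa import OLSA, OLSAConfig
from olsa.decomposition import (
    build_concatenated,
    compute_scores,
    extract_components,
    grubbs_critical_value,
    normalize_profiles,
    run_olsa,
    select_mirror_samples,
    total_strength,
    varimax_criterion,
    varimax_rotate,
)


def _frame(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestTotalStrength:
    def test_pythagorean_column(self):
        d = _frame(np.zeros((10, 1)))
        d.iloc[0, 0], d.iloc[1, 0] = 3, 4
        assert total_strength(d).iloc[0] == pytest.approx(5.0)

    def test_matches_brute_force_sum_of_squares(self):
        rng = np.random.default_rng(1)
        d = _frame(rng.normal(size=(100, 5)))
        expected = [
            sum(v * v for v in d.iloc[:, j]) ** 0.5 for j in range(5)
        ]
        np.testing.assert_allclose(total_strength(d), expected, atol=1e-12)

    def test_zero_column_named_in_error(self):
        d = _frame(np.ones((4, 3)))
        d["s1"] = 0.0
        with pytest.raises(ValueError, match="s1"):
            total_strength(d)


class TestGrubbs:
    def test_critical_value_closed_form(self):
        # independent evaluation of the t-based closed form at n=10
        n, alpha = 10, 0.05
        t = stats.t.ppf(1 - alpha / n, n - 2)
        expected = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        assert grubbs_critical_value(10, 0.05) == pytest.approx(expected, abs=1e-12)
        assert grubbs_critical_value(10, 0.05) == pytest.approx(2.176, abs=1e-3)

    def test_identical_norms_remove_nothing(self):
        ts = pd.Series(np.ones(10), index=[f"s{i}" for i in range(10)])
        sel = select_mirror_samples(ts, 0.05)
        assert sel.removed_sample_ids == []
        assert sel.n_kept == 10

    def test_single_gross_outlier_removed(self):
        rng = np.random.default_rng(5)
        vals = 1.0 + 0.01 * rng.normal(size=20)
        vals[7] = 10.0
        ts = pd.Series(vals, index=[f"s{i}" for i in range(20)])
        sel = select_mirror_samples(ts, 0.05)
        assert sel.removed_sample_ids == ["s7"]

    def test_only_upper_tail_is_tested(self):
        rng = np.random.default_rng(5)
        vals = 10.0 + 0.01 * rng.normal(size=20)
        vals[3] = 1.0  # extreme *low* norm must survive
        ts = pd.Series(vals, index=[f"s{i}" for i in range(20)])
        assert select_mirror_samples(ts, 0.05).removed_sample_ids == []

    def test_audit_trail_records_each_iteration(self):
        vals = np.concatenate([np.full(15, 1.0) + np.arange(15) * 1e-3, [50.0, 90.0]])
        ts = pd.Series(vals, index=[f"s{i}" for i in range(17)])
        sel = select_mirror_samples(ts, 0.05)
        assert sel.removed_sample_ids == ["s16", "s15"]
        assert len(sel.history) == len(sel.removed_sample_ids) + 1
        assert all(h[3] == 17 - i for i, h in enumerate(sel.history))

    def test_too_few_samples_rejected(self):
        ts = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="at least 4"):
            select_mirror_samples(ts, 0.05)


class TestNormalizeAndMirror:
    def test_unit_columns_and_example(self):
        d = _frame([[3.0, 1.0], [4.0, 0.0]])
        dp = normalize_profiles(d)
        np.testing.assert_allclose(dp["s0"], [0.6, 0.8])
        np.testing.assert_allclose(np.linalg.norm(dp, axis=0), 1.0, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        d = _frame(rng.normal(size=(20, 6)))
        once = normalize_profiles(d)
        pd.testing.assert_frame_equal(once, normalize_profiles(once))

    def test_mirror_is_exact_negation_and_zero_centroid(self):
        rng = np.random.default_rng(3)
        dp = normalize_profiles(_frame(rng.normal(size=(15, 8))))
        sel = select_mirror_samples(total_strength(dp) * 0 + 1.0, 0.05)
        dm = build_concatenated(dp, sel)
        assert dm.shape == (15, 16)
        np.testing.assert_array_equal(
            dm.iloc[:, 8:].to_numpy(), -dp.to_numpy()
        )
        assert np.abs(dm.mean(axis=1)).max() < 1e-12

    def test_centroid_residual_with_removal(self):
        rng = np.random.default_rng(4)
        d = _frame(rng.normal(size=(30, 12)))
        d["s5"] *= 40  # gross outlier
        ts = total_strength(d)
        sel = select_mirror_samples(ts, 0.05)
        assert "s5" in sel.removed_sample_ids
        dp = normalize_profiles(d, ts)
        dm = build_concatenated(dp, sel)
        # removed columns survive only in the positive block
        closed_form = dp[sel.removed_sample_ids].sum(axis=1).to_numpy() / dm.shape[1]
        np.testing.assert_allclose(dm.mean(axis=1), closed_form, atol=1e-14)


class TestExtractComponents:
    def test_single_profile_is_rank_one(self):
        v = np.random.default_rng(0).normal(size=30)
        d = _frame(np.tile((v / np.linalg.norm(v))[:, None], (1, 5)))
        sel = select_mirror_samples(pd.Series(np.ones(5), d.columns), 0.05)
        cs = extract_components(build_concatenated(d, sel), 0.99)
        assert cs.n_components == 1
        assert cs.contribution_ratio[0] == pytest.approx(1.0)

    def test_variance_split_governs_retention(self):
        # two orthogonal directions carrying 70% / 30% of variance
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.normal(size=(50, 2)))
        coef = np.concatenate(
            [np.sqrt(0.7) * rng.choice([-1, 1], 40)[None, :],
             np.sqrt(0.3) * rng.choice([-1, 1], 40)[None, :]]
        )
        d = _frame(q @ coef)
        sel = select_mirror_samples(total_strength(d) * 0 + 1, 0.05)
        dm = build_concatenated(normalize_profiles(d), sel)
        cs = extract_components(dm, 0.8)
        assert cs.n_components == 2
        np.testing.assert_allclose(cs.contribution_ratio[:2], [0.7, 0.3], atol=0.05)

    def test_orthonormal_loadings(self, small_response):
        sel = select_mirror_samples(total_strength(small_response), 0.05)
        dm = build_concatenated(normalize_profiles(small_response), sel)
        cs = extract_components(dm, 0.9)
        u = cs.loadings.to_numpy()
        np.testing.assert_allclose(u.T @ u, np.eye(u.shape[1]), atol=1e-8)

    def test_uncentred_svd_equals_centred_pca_without_removals(self, small_response):
        from sklearn.decomposition import PCA

        dp = normalize_profiles(small_response)
        sel = select_mirror_samples(
            pd.Series(np.ones(12), dp.columns), 0.05
        )
        dm = build_concatenated(dp, sel)  # exactly zero-mean
        cs = extract_components(dm, 0.9)
        pca = PCA(n_components=cs.n_components).fit(dm.to_numpy().T)
        # identical subspaces, component by component, up to sign
        cos = np.abs(np.sum(pca.components_.T * cs.loadings.to_numpy(), axis=0))
        np.testing.assert_allclose(cos, 1.0, atol=1e-8)

    def test_rank_deficient_input_drops_zero_components(self):
        # 8 columns but only rank 4: zero-sigma components are never retained,
        # and threshold 1.0 keeps exactly the nonzero ones
        d = _frame(np.eye(4))
        dd = pd.concat([d, d], axis=1)
        dd.columns = [f"s{i}" for i in range(8)]
        sel = select_mirror_samples(pd.Series(np.ones(8), dd.columns), 0.05)
        cs = extract_components(build_concatenated(dd, sel), 1.0)
        assert cs.n_components == 4


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        # each gene loads on exactly one factor: already maximally simple
        L = np.zeros((12, 3))
        L[:4, 0] = 0.5
        L[4:8, 1] = 0.5
        L[8:, 2] = 0.5
        before = varimax_criterion(L)
        from olsa.decomposition import _varimax

        rotated, Q, _, _ = _varimax(L, 1e-10, 100)
        assert varimax_criterion(rotated) == pytest.approx(before, abs=1e-12)
        # rotation is identity up to sign/permutation
        np.testing.assert_allclose(np.abs(Q) @ np.abs(Q.T), np.eye(3), atol=1e-8)

    def test_k2_matches_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.normal(size=(500, 2)))
            from olsa.decomposition import _varimax

            rotated, _, _, _ = _varimax(q, 1e-12, 1000)
            achieved = varimax_criterion(rotated)
            best = _grid_best(q)
            assert achieved >= best - 1e-6

    def test_criterion_never_decreases(self, small_response):
        sel = select_mirror_samples(total_strength(small_response), 0.05)
        dm = build_concatenated(normalize_profiles(small_response), sel)
        cs = extract_components(dm, 0.95)
        rv = varimax_rotate(cs)
        assert rv.rotation["criterion"] >= varimax_criterion(
            cs.loadings.to_numpy()
        ) - 1e-12

    def test_rows_orthonormal_and_sign_canonical(self, small_response):
        sel = select_mirror_samples(total_strength(small_response), 0.05)
        dm = build_concatenated(normalize_profiles(small_response), sel)
        rv = varimax_rotate(extract_components(dm, 0.95))
        R = rv.loadings.to_numpy()
        np.testing.assert_allclose(R @ R.T, np.eye(R.shape[0]), atol=1e-8)
        peaks = R[np.arange(R.shape[0]), np.abs(R).argmax(axis=1)]
        assert (peaks > 0).all()

    def test_subspace_preserved(self, small_response):
        sel = select_mirror_samples(total_strength(small_response), 0.05)
        dm = build_concatenated(normalize_profiles(small_response), sel)
        cs = extract_components(dm, 0.95)
        rv = varimax_rotate(cs)
        angles = linalg.subspace_angles(
            cs.loadings.to_numpy(), rv.loadings.to_numpy().T
        )
        assert np.max(angles) < 1e-6

    def test_factors_sorted_by_post_rotation_contribution(self, small_response):
        sel = select_mirror_samples(total_strength(small_response), 0.05)
        dm = build_concatenated(normalize_profiles(small_response), sel)
        rv = varimax_rotate(extract_components(dm, 0.95))
        assert list(rv.loadings.index) == [
            f"P{i + 1}" for i in range(rv.loadings.shape[0])
        ]
        assert (np.diff(rv.contribution_ratio) <= 1e-12).all()


def _grid_best(L, step=0.001):
    """Brute-force varimax criterion over planar rotation angles (k=2)."""
    x, y = L[:, 0], L[:, 1]
    best = -np.inf
    for phi in np.arange(0.0, np.pi / 2, step):
        c, s = np.cos(phi), np.sin(phi)
        best = max(best, varimax_criterion(np.column_stack([c * x + s * y,
                                                            -s * x + c * y])))
    return best


class TestScoresAndPipeline:
    def test_profile_equal_to_vector_scores_one(self, small_response):
        res = run_olsa(small_response, OLSAConfig(cum_threshold=0.95))
        rv = res.response_vectors
        probe = rv.loadings.iloc[[0]].T  # a sample that *is* factor P1
        probe.columns = ["probe"]
        s = compute_scores(rv, probe)
        assert s.loc["P1", "probe"] == pytest.approx(1.0, abs=1e-10)
        assert np.abs(s.drop("P1").to_numpy()).max() < 1e-10

    def test_score_columns_are_subunit_projections(self, small_response):
        res = run_olsa(small_response)
        norms2 = (res.response_scores.to_numpy() ** 2).sum(axis=0)
        assert (norms2 <= 1 + 1e-10).all()

    def test_reconstruction_matches_projection(self, small_response):
        res = run_olsa(small_response, OLSAConfig(cum_threshold=0.95))
        dprime = normalize_profiles(small_response)
        u = res.components.loadings.to_numpy()
        proj = u @ (u.T @ dprime.to_numpy())
        recon = res.response_vectors.loadings.to_numpy().T @ res.response_scores.to_numpy()
        np.testing.assert_allclose(recon, proj, atol=1e-10)

    def test_gene_mismatch_is_hard_error(self, small_response):
        res = run_olsa(small_response)
        other = normalize_profiles(small_response).rename(index={"g00": "weird"})
        with pytest.raises(ValueError, match="weird"):
            compute_scores(res.response_vectors, other)

    def test_deterministic_rerun(self, small_response):
        a = run_olsa(small_response)
        b = run_olsa(small_response)
        pd.testing.assert_frame_equal(
            a.response_vectors.loadings, b.response_vectors.loadings
        )
        pd.testing.assert_frame_equal(a.response_scores, b.response_scores)

    def test_total_strength_factorization_exact(self, small_response):
        res = run_olsa(small_response)
        dprime = normalize_profiles(small_response, res.total_strength)
        recon = dprime * res.total_strength.to_numpy()[None, :]
        np.testing.assert_allclose(
            recon.to_numpy(), small_response.to_numpy(), rtol=1e-12, atol=1e-12
        )

    def test_identical_profiles_collapse_to_one_factor(self):
        v = np.random.default_rng(1).normal(size=25)
        d = _frame(np.tile(v[:, None], (1, 4)))
        res = run_olsa(d)
        assert res.response_vectors.loadings.shape[0] == 1
        s = res.response_scores.to_numpy().ravel()
        np.testing.assert_allclose(s, s[0], atol=1e-10)


class TestSklearnEstimator:
    def test_fit_transform_shapes_and_orthonormality(self, small_response):
        X = small_response.to_numpy().T  # samples x genes
        est = OLSA(cum_threshold=0.95).fit(X)
        R = est.components_
        np.testing.assert_allclose(R @ R.T, np.eye(est.n_components_), atol=1e-8)
        S = est.transform(X)
        assert S.shape == (12, est.n_components_)
        # matches the functional pipeline's scores
        res = run_olsa(small_response, OLSAConfig(cum_threshold=0.95))
        np.testing.assert_allclose(S.T, res.response_scores.to_numpy(), atol=1e-10)

    def test_get_params_round_trip(self):
        from sklearn.base import clone

        est = OLSA(cum_threshold=0.9, grubbs_alpha=0.01)
        params = clone(est).get_params()
        assert params["cum_threshold"] == 0.9
        assert params["grubbs_alpha"] == 0.01

    def test_pipeline_composability(self, small_response):
        from sklearn.pipeline import Pipeline

        X = small_response.to_numpy().T
        pipe = Pipeline([("olsa", OLSA(cum_threshold=0.9))])
        assert pipe.fit_transform(X).shape[0] == X.shape[0]
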