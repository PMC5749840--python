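import numpy as np
import pandas as pd
import pytest

from lomaspulse.ordination import (
    correspondence_analysis,
    dca,
    detrend_by_segments,
    downweight_rare,
)
from oracles import ca_eigenvalues_oracle, spearman_oracle


def gradient_community(
    n_species=25, n_sites=15, sd=1.2, seed=0, noise=0.0
) -> pd.DataFrame:
    """Single-gradient Gaussian-response community: species optima spread
    along one latent axis, sites ordered along it."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 10, n_sites)
    optima = np.linspace(0, 10, n_species)
    M = np.exp(-((x[None, :] - optima[:, None]) ** 2) / (2 * sd**2)) * 50
    if noise:
        M = M * np.exp(rng.normal(0, noise, M.shape))
    return pd.DataFrame(
        M,
        index=[f"sp{i:02d}" for i in range(n_species)],
        columns=[f"site{j:02d}" for j in range(n_sites)],
    )


class TestCorrespondenceAnalysis:
    def test_block_diagonal_separation(self):
        M = np.zeros((6, 6))
        M[:3, :3] = np.array([[5, 2, 1], [1, 4, 2], [2, 1, 6]])
        M[3:, 3:] = np.array([[3, 1, 2], [2, 5, 1], [1, 2, 4]])
        res = correspondence_analysis(M, n_axes=1)
        scores = res.site_scores["axis1"].to_numpy()
        assert np.sign(scores[:3]).min() == np.sign(scores[:3]).max()
        assert np.sign(scores[3:]).min() == np.sign(scores[3:]).max()
        assert np.sign(scores[0]) != np.sign(scores[3])

    def test_duplicate_sites_identical_scores(self):
        rng = np.random.default_rng(1)
        M = rng.integers(0, 9, size=(6, 4)).astype(float) + 0.5
        M = np.hstack([M, M[:, [1]]])  # duplicate column 1
        res = correspondence_analysis(M, n_axes=2)
        np.testing.assert_allclose(
            res.site_scores.iloc[1].to_numpy(),
            res.site_scores.iloc[-1].to_numpy(),
            atol=1e-10,
        )

    def test_eigenvalues_match_dense_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            M = rng.integers(0, 10, size=(6, 5)).astype(float)
            if (M.sum(axis=1) == 0).any() or (M.sum(axis=0) == 0).any():
                continue
            res = correspondence_analysis(M, n_axes=4)
            expected = ca_eigenvalues_oracle(M)[: len(res.eigenvalues)]
            np.testing.assert_allclose(res.eigenvalues, expected, atol=1e-10)

    def test_eigenvalues_in_unit_interval_and_sorted(self):
        M = gradient_community()
        res = correspondence_analysis(M, n_axes=5)
        assert (res.eigenvalues > 0).all() and (res.eigenvalues <= 1).all()
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.axis_inertia_fraction.sum() <= 1 + 1e-12

    def test_eigenvalues_invariant_to_scaling(self):
        M = gradient_community(seed=3, noise=0.2)
        e1 = correspondence_analysis(M, n_axes=3).eigenvalues
        e2 = correspondence_analysis(M * 123.4, n_axes=3).eigenvalues
        np.testing.assert_allclose(e1, e2, atol=1e-12)

    def test_reciprocal_averaging_consistency(self):
        M = gradient_community(seed=4, noise=0.3)
        res = correspondence_analysis(M, n_axes=3)
        A = M.to_numpy()
        profiles = A / A.sum(axis=1, keepdims=True)
        # weighted mean of site *principal* scores = sqrt(eigenvalue) times
        # the species score for each axis
        implied = profiles @ res.site_scores.to_numpy()
        expected = res.species_scores.to_numpy() * np.sqrt(res.eigenvalues)
        np.testing.assert_allclose(implied, expected, atol=1e-8)

    def test_column_permutation_equivariance(self):
        M = gradient_community(n_sites=9, seed=5, noise=0.2)
        res = correspondence_analysis(M, n_axes=2)
        perm = [4, 0, 7, 2, 8, 1, 6, 3, 5]
        resp = correspondence_analysis(M.iloc[:, perm], n_axes=2)
        pd.testing.assert_frame_equal(
            resp.site_scores.sort_index(),
            res.site_scores.sort_index(),
            atol=1e-10,
            rtol=0,
        )

    def test_all_zero_row_filtered_with_warning(self):
        M = gradient_community(n_species=6, n_sites=5)
        M.iloc[2] = 0.0
        with pytest.warns(UserWarning, match="all-zero row"):
            res = correspondence_analysis(M, n_axes=2)
        assert "sp02" not in res.species_scores.index

    def test_rank_deficient_returns_fewer_axes(self):
        M = np.array([[4.0, 1.0], [1.0, 5.0], [2.0, 2.0]])
        with pytest.warns(UserWarning, match="nontrivial axes"):
            res = correspondence_analysis(M, n_axes=4)
        assert res.site_scores.shape[1] == 1

    def test_negative_matrix_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            correspondence_analysis(np.array([[1.0, -1.0], [2.0, 3.0]]))


class TestDownweightRare:
    def test_equal_profiles_unchanged(self):
        M = np.tile(np.array([3.0, 1.0, 2.0, 4.0]), (5, 1))
        np.testing.assert_allclose(downweight_rare(M), M)

    def test_rare_species_scaled_down(self):
        M = np.array(
            [
                [10.0, 10.0, 10.0, 10.0, 10.0],
                [0.0, 0.0, 1.0, 0.0, 0.0],
            ]
        )
        out = downweight_rare(M)
        np.testing.assert_allclose(out[0], M[0])
        assert (out[1] < M[1]).any() or out[1].sum() < M[1].sum()

    def test_hill_rule_transcription_3x3(self):
        # effective frequencies (Σx)²/Σx²: sp0 = 9/3 = 3, sp1 = 1,
        # sp2 = 4/4 = 1; threshold = 3/5 = 0.6 → nothing below, unchanged.
        M = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 0.0], [2.0, 0.0, 0.0]])
        np.testing.assert_allclose(downweight_rare(M), M, atol=1e-9)
        # with fraction 1/2 (→ 2): threshold 1.5, sp1 and sp2 scale by 1/1.5
        out = downweight_rare(M, fraction=2.0)
        np.testing.assert_allclose(out[0], M[0], atol=1e-9)
        np.testing.assert_allclose(out[1], M[1] / 1.5, rtol=1e-6)
        np.testing.assert_allclose(out[2], M[2] / 1.5, rtol=1e-6)

    def test_dataframe_in_dataframe_out(self):
        M = gradient_community(n_species=5, n_sites=4)
        out = downweight_rare(M)
        assert isinstance(out, pd.DataFrame)
        assert list(out.index) == list(M.index)


class TestDetrendBySegments:
    def test_centered_input_fixed_point(self):
        x1 = np.linspace(0, 1, 52)
        x2 = np.tile([1.0, -1.0], 26)  # mean 0 in every 2-point segment
        out = detrend_by_segments(x1, x2, n_segments=26)
        np.testing.assert_allclose(out, x2, atol=1e-12)

    def test_perfect_arch_proxy_removed(self):
        x1 = np.linspace(0, 10, 200)
        out = detrend_by_segments(x1, x1.copy(), n_segments=26)
        assert np.abs(out).max() < (x1.max() - x1.min()) / 26

    def test_arch_corr_below_threshold(self):
        M = gradient_community(n_sites=30, seed=7, noise=0.15)
        res = correspondence_analysis(M, n_axes=2)
        x1 = res.site_scores["axis1"].to_numpy()
        x2 = res.site_scores["axis2"].to_numpy()
        detr = detrend_by_segments(x1, x2)
        rho, _ = spearman_oracle(list(x1), list(detr))
        assert abs(rho) < 0.2

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="zero range"):
            detrend_by_segments(np.ones(5), np.arange(5.0))

    def test_empty_segments_merged(self):
        # two clusters leave most of the 26 segments empty; must not raise
        x1 = np.concatenate([np.zeros(5), np.ones(5) * 10])
        x2 = np.arange(10.0)
        out = detrend_by_segments(x1, x2)
        assert np.isfinite(out).all()


class TestDCA:
    def test_gradient_recovery(self):
        M = gradient_community(n_sites=15, seed=8, noise=0.25)
        res = dca(M, n_axes=2)
        scores = res.site_scores["axis1"].to_numpy()
        rho, _ = spearman_oracle(list(scores), list(range(15)))
        assert abs(rho) >= 0.9

    def test_single_axis_no_detrending(self):
        M = gradient_community(seed=9, noise=0.1)
        res = dca(M, n_axes=1)
        assert not res.detrended
        assert res.site_scores.shape[1] == 1

    def test_detrended_flag_and_shapes(self):
        M = gradient_community(seed=10, noise=0.1)
        res = dca(M, n_axes=2)
        assert res.detrended and res.downweighted
        assert res.site_scores.shape == (15, 2)
        assert res.species_scores.shape[1] == 2
        assert np.isfinite(res.site_scores.to_numpy()).all()
        assert np.isfinite(res.species_scores.to_numpy()).all()

    def test_orientation_deterministic(self):
        M = gradient_community(seed=11, noise=0.2)
        r1 = dca(M)
        r2 = dca(M.copy())
        pd.testing.assert_frame_equal(r1.site_scores, r2.site_scores)
        first = sorted(r1.site_scores.index)[0]
        assert r1.site_scores.loc[first, "axis1"] >= 0
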