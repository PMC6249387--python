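"""Marker PCA, pseudo-time orientation, binning and cubic trend fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from scidseq import (
    SimConfig,
    bin_cells,
    compute_pseudotime,
    fit_trend,
    marker_pca,
    orient_and_scale,
    scale_minmax,
    filter_cells,
    subsample_counts,
    simulate_truth,
    trend_all,
    truth_count_matrix,
)

from conftest import toy_matrix


def scaled_from_truth(truth, seed=0):
    raw = truth_count_matrix(truth)
    return scale_minmax(subsample_counts(filter_cells(raw, "auto"), "min", seed=seed))


@pytest.fixture(scope="module")
def trajectory_truth():
    return simulate_truth(SimConfig(n_cell_wells=220, n_empty_wells=48, seed=2))


@pytest.fixture(scope="module")
def trajectory_scaled(trajectory_truth):
    return scaled_from_truth(trajectory_truth, seed=2)


class TestMarkerPCA:
    def test_rank_one_data_loads_everything_on_pc1(self):
        t = np.linspace(0, 1, 40)
        values = np.column_stack([t, 0.5 * t, 0.25 * t, t, t, t])
        m = toy_matrix(values, state="scaled")
        _, var = marker_pca(m, [f"Ab{j}" for j in range(6)])
        assert var[0] == pytest.approx(1.0)

    def test_scores_match_svd_oracle_up_to_sign(self, rng):
        values = rng.random((50, 6))
        m = toy_matrix(values, state="scaled")
        scores, var = marker_pca(m, [f"Ab{j}" for j in range(6)])
        centered = values - values.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        oracle_scores = u * s
        for k in range(6):
            a = scores.iloc[:, k].to_numpy()
            b = oracle_scores[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8
        oracle_var = s**2 / (s**2).sum()
        assert np.allclose(var, oracle_var, atol=1e-8)

    def test_duplicated_cells_get_identical_scores(self, rng):
        values = rng.random((20, 6))
        values[10] = values[0]
        m = toy_matrix(values, state="scaled")
        scores, _ = marker_pca(m, [f"Ab{j}" for j in range(6)])
        assert np.allclose(scores.iloc[0], scores.iloc[10])

    def test_missing_marker_listed_in_error(self, rng):
        m = toy_matrix(rng.random((10, 3)), state="scaled")
        with pytest.raises(KeyError, match="TGM1"):
            marker_pca(m, ["Ab0", "TGM1"])

    def test_too_few_cells_rejected(self, rng):
        m = toy_matrix(rng.random((5, 6)), state="scaled")
        with pytest.raises(ValueError, match="at least"):
            marker_pca(m, [f"Ab{j}" for j in range(6)])


class TestOrientAndScale:
    def test_anticorrelated_pc1_is_flipped(self, rng):
        up = rng.random(30)
        m = toy_matrix(np.column_stack([up, 1 - up]), state="scaled")
        pc1 = pd.Series(-up + 0.01 * rng.random(30), index=m.values.index)
        pt, flipped, _ = orient_and_scale(pc1, m, up_marker="Ab0", down_marker="Ab1")
        assert flipped
        assert np.corrcoef(pt, up)[0, 1] > 0

    def test_output_spans_unit_interval(self, rng):
        m = toy_matrix(rng.random((25, 2)), state="scaled")
        pc1 = pd.Series(rng.normal(size=25), index=m.values.index)
        pt, _, _ = orient_and_scale(pc1, m, "Ab0", "Ab1")
        assert pt.min() == 0.0 and pt.max() == 1.0

    def test_ambiguous_orientation_flagged(self):
        m = toy_matrix(np.ones((10, 2)), state="scaled")
        pc1 = pd.Series(np.arange(10.0), index=m.values.index)
        with pytest.warns(UserWarning, match="ambiguous"):
            _, flipped, ambiguous = orient_and_scale(pc1, m, "Ab0", "Ab1")
        assert ambiguous and not flipped

    def test_rank_agreement_with_independent_rank_correlation(self, trajectory_truth, trajectory_scaled):
        result = compute_pseudotime(trajectory_scaled)
        t = trajectory_truth.latent_time.loc[result.pseudotime.index]
        rho_lib = abs(spearmanr(result.pseudotime, t)[0])
        # independent oracle: Pearson correlation of the two rank vectors
        r1 = result.pseudotime.rank().to_numpy()
        r2 = t.rank().to_numpy()
        rho_oracle = abs(np.corrcoef(r1, r2)[0, 1])
        assert rho_lib == pytest.approx(rho_oracle, abs=1e-10)


class TestBinCells:
    def test_220_cells_make_22_full_bins(self, rng):
        pt = pd.Series(rng.random(220))
        bins = bin_cells(pt, 10)
        sizes = bins.value_counts()
        assert len(sizes) == 22 and (sizes == 10).all()

    def test_small_remainder_merges_into_last_bin(self, rng):
        pt = pd.Series(rng.random(23))
        sizes = bin_cells(pt, 10).value_counts().sort_index()
        assert list(sizes) == [10, 13]

    def test_large_remainder_stays_separate(self, rng):
        pt = pd.Series(rng.random(27))
        sizes = bin_cells(pt, 10).value_counts().sort_index()
        assert list(sizes) == [10, 10, 7]

    def test_membership_invariant_under_row_permutation(self, rng):
        pt = pd.Series(rng.random(57), index=[f"c{i}" for i in range(57)])
        bins = bin_cells(pt, 10)
        perm = rng.permutation(57)
        shuffled = pt.iloc[perm]
        bins_shuffled = bin_cells(shuffled, 10)
        assert (bins_shuffled.loc[bins.index] == bins).all()

    def test_fewer_cells_than_bin_warns_single_bin(self, rng):
        pt = pd.Series(rng.random(6))
        with pytest.warns(UserWarning, match="single bin"):
            bins = bin_cells(pt, 10)
        assert (bins == 0).all()

    def test_bins_are_contiguous_in_rank_order(self, rng):
        pt = pd.Series(rng.random(100))
        bins = bin_cells(pt, 10)
        ordered = bins.iloc[np.argsort(pt.to_numpy())].to_numpy()
        assert (np.diff(ordered) >= 0).all()


class TestFitTrend:
    def test_noiseless_cubic_recovered(self):
        x = np.linspace(0, 1, 22)
        coeffs = np.array([0.3, -1.2, 2.0, 0.7])
        y = coeffs[0] + coeffs[1] * x + coeffs[2] * x**2 + coeffs[3] * x**3
        fit = fit_trend(x, y)
        rss = float(np.sum((fit.predict(x) - y) ** 2))
        assert rss < 1e-9
        assert np.allclose(fit.coefficients, coeffs, atol=1e-7)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = np.sort(rng.random(22))
        y = rng.normal(size=22)
        fit = fit_trend(x, y)
        X = np.vander(x, 4, increasing=True)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coefficients, oracle, atol=1e-8)

    def test_constant_means_give_flat_fit(self):
        x = np.linspace(0, 1, 10)
        fit = fit_trend(x, np.full(10, 0.4))
        assert fit.coefficients[0] == pytest.approx(0.4, abs=1e-9)
        assert np.allclose(fit.coefficients[1:], 0, atol=1e-9)
        assert fit.r_squared == 0.0

    def test_too_few_bins_suggests_lower_degree(self):
        with pytest.raises(ValueError, match="degree"):
            fit_trend(np.array([0.0, 0.5, 1.0]), np.zeros(3), degree=3)


class TestTrendAll:
    def test_one_fit_per_column(self, trajectory_scaled):
        result = compute_pseudotime(trajectory_scaled)
        fits = trend_all(trajectory_scaled, result)
        assert set(fits) == set(trajectory_scaled.values.columns)

    def test_bin_means_match_groupby_oracle(self, trajectory_scaled):
        result = compute_pseudotime(trajectory_scaled)
        fits = trend_all(trajectory_scaled, result)
        name = trajectory_scaled.values.columns[0]
        oracle = (
            trajectory_scaled.values[name].groupby(result.bin_id).mean().to_numpy()
        )
        assert np.allclose(fits[name].bin_means, oracle)

    def test_simulated_up_marker_trends_upward(self, trajectory_scaled):
        result = compute_pseudotime(trajectory_scaled)
        fits = trend_all(trajectory_scaled, result)
        assert fits["TGM1"].direction == 1
        assert fits["ITGB1"].direction == -1


class TestPipelineDeterminismAndLocality:
    def test_identical_input_identical_result(self, trajectory_scaled):
        r1 = compute_pseudotime(trajectory_scaled)
        r2 = compute_pseudotime(trajectory_scaled)
        pd.testing.assert_series_equal(r1.pseudotime, r2.pseudotime)
        pd.testing.assert_series_equal(r1.rank, r2.rank)

    def test_nonmarker_perturbation_leaves_pseudotime_unchanged(self, trajectory_scaled, rng):
        r1 = compute_pseudotime(trajectory_scaled)
        values = trajectory_scaled.values.copy()
        nonmarker = next(
            c for c in values.columns if c not in r1.marker_names
        )
        values[nonmarker] = rng.random(len(values))
        perturbed = trajectory_scaled.with_values(values, "scaled")
        r2 = compute_pseudotime(perturbed)
        pd.testing.assert_series_equal(r1.pseudotime, r2.pseudotime)

    def test_recovers_latent_ordering(self, trajectory_truth, trajectory_scaled):
        result = compute_pseudotime(trajectory_scaled)
        t = trajectory_truth.latent_time.loc[result.pseudotime.index]
        assert abs(spearmanr(result.pseudotime, t)[0]) >= 0.9
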