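"""PCA, orthogonal regression, KS tests, histograms and count maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hcodb.stats import (AnalysisMatrix, build_analysis_matrix, ks_two_sample,
                         odr_line_3d, pairwise_count_map, pca_group,
                         axis_distribution, select_main_components)


def group_frame(n=20, isolated=False, seed=0):
    rng = np.random.default_rng(seed)
    levels = np.array([0, 25, 50, 75, 100, 125, 150, 175])
    df = pd.DataFrame({
        c: rng.choice(levels, n) for c in ("P", "K2", "h", "CaS", "Leak")})
    df["SynS"] = 0 if isolated else rng.choice((100, 150), n)
    df["SynG"] = 0 if isolated else rng.choice((0, 100), n)
    df["E_Leak"] = rng.choice((-70, -65, -60, -55, -50), n)
    return df


class TestAnalysisMatrix:
    def test_isolated_group_drops_synaptic_columns(self):
        M = build_analysis_matrix(group_frame(isolated=True))
        assert len(M.columns) == 6
        assert "SynS" not in M.columns and "SynG" not in M.columns

    def test_coupled_group_keeps_all_eight(self):
        M = build_analysis_matrix(group_frame(isolated=False))
        assert M.columns == ("SynS", "SynG", "P", "K2", "h", "CaS", "Leak", "E_Leak")

    def test_units_are_fractions_and_volts(self):
        df = group_frame(isolated=True).iloc[:3].copy()
        df.loc[df.index[0], "P"] = 175
        df.loc[df.index[0], "E_Leak"] = -70
        M = build_analysis_matrix(df)
        i = M.columns.index("P")
        assert M.X[0, i] == pytest.approx(1.75)
        assert M.X[0, M.columns.index("E_Leak")] == pytest.approx(-0.070)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            build_analysis_matrix(group_frame().iloc[0:0])


class TestPCA:
    def test_collinear_points_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 50)
        X = np.outer(t, [1.0, 2.0, -1.0])
        res = pca_group(AnalysisMatrix(X, ("a", "b", "c")))
        assert res.variance_pct[0] == pytest.approx(100.0, abs=1e-9)
        assert res.n_main == 1

    def test_isotropic_cloud_splits_variance_evenly(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(100_000, 3))
        res = pca_group(AnalysisMatrix(X, ("a", "b", "c")))
        assert np.all(np.abs(res.variance_pct - 100 / 3) < 1.0)

    def test_orthonormal_coefficients_and_variance_conservation(self):
        X = group_frame(n=200, seed=3)
        res = pca_group(build_analysis_matrix(X))
        C = res.coefficients
        assert np.allclose(C.T @ C, np.eye(C.shape[1]), atol=1e-9)
        assert res.variance_pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(res.variance_pct) <= 1e-9)
        # component variances partition the total variance
        Xc = build_analysis_matrix(X).X
        Xc = Xc - Xc.mean(0)
        total = (Xc ** 2).sum()
        scores = Xc @ C
        assert (scores ** 2).sum() == pytest.approx(total, rel=1e-9)

    def test_matches_sklearn_decomposition(self):
        from sklearn.decomposition import PCA

        X = build_analysis_matrix(group_frame(n=300, seed=7)).X
        res = pca_group(AnalysisMatrix(X, tuple(range(X.shape[1]))))
        sk = PCA().fit(X)
        assert np.allclose(res.variance_pct, sk.explained_variance_ratio_ * 100,
                           atol=1e-9)
        for j in range(X.shape[1]):
            dot = abs(np.dot(res.coefficients[:, j], sk.components_[j]))
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_largest_coefficient_negative(self):
        res = pca_group(build_analysis_matrix(group_frame(n=100, seed=1)))
        for j in range(res.coefficients.shape[1]):
            col = res.coefficients[:, j]
            assert col[np.argmax(np.abs(col))] <= 0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            pca_group(AnalysisMatrix(np.zeros((3, 4)), tuple("abcd")))


class TestMainComponents:
    @pytest.mark.parametrize("variances, expected", [
        ([60, 20, 10, 6, 3, 1], 4),        # 96 > 95 at four components
        ([100.0], 1),
        ([50, 44, 6], 3),                  # 94 at two, 100 with the third
        ([96, 4], 1),
    ])
    def test_smallest_set_exceeding_threshold(self, variances, expected):
        assert select_main_components(variances) == expected

    def test_increasing_fractions_rejected(self):
        with pytest.raises(ValueError):
            select_main_components([10, 90])


class TestODRLine:
    def test_collinear_points_have_zero_residual(self):
        t = np.linspace(-1, 1, 30)
        d = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        P = np.array([0.5, 0.5, 0.5]) + np.outer(t, d)
        line = odr_line_3d(P)
        assert line.residual_ss == pytest.approx(0.0, abs=1e-12)
        assert abs(np.dot(line.direction, d)) == pytest.approx(1.0)
        assert np.allclose(line.centroid, [0.5, 0.5, 0.5])

    def test_direction_equals_first_principal_component(self):
        rng = np.random.default_rng(11)
        P = rng.normal(size=(200, 3)) * [3.0, 1.0, 0.3]
        line = odr_line_3d(P)
        pc1 = pca_group(AnalysisMatrix(P, ("x", "y", "z"))).first_component
        assert abs(np.dot(line.direction, pc1)) == pytest.approx(1.0, abs=1e-9)

    def test_beats_randomly_perturbed_directions(self):
        rng = np.random.default_rng(12)
        P = rng.normal(size=(50, 3)) * [2.0, 1.0, 0.5]
        line = odr_line_3d(P)

        def ss(direction):
            d = direction / np.linalg.norm(direction)
            rel = P - P.mean(0)
            proj = rel @ d
            return float(((rel - np.outer(proj, d)) ** 2).sum())

        best = ss(line.direction)
        for _ in range(100):
            other = line.direction + rng.normal(scale=0.2, size=3)
            assert best <= ss(other) + 1e-9

    def test_multiplicity_weights_equal_repetition(self):
        P = np.array([[0, 0, 0], [1, 1, 0.5], [2, 1.8, 1.2]], float)
        w = np.array([3.0, 1.0, 2.0])
        expanded = np.repeat(P, [3, 1, 2], axis=0)
        lw = odr_line_3d(P, weights=w)
        le = odr_line_3d(expanded)
        assert np.allclose(lw.centroid, le.centroid)
        assert abs(np.dot(lw.direction, le.direction)) == pytest.approx(1.0)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            odr_line_3d(np.ones((5, 3)))


def brute_force_ks(x, y):
    """sup |ECDF_x - ECDF_y| by direct evaluation at every sample point."""
    best = 0.0
    for v in list(x) + list(y):
        fx = sum(xi <= v for xi in x) / len(x)
        fy = sum(yi <= v for yi in y) / len(y)
        best = max(best, abs(fx - fy))
    return best


class TestKSTest:
    def test_identical_samples_give_zero_statistic(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = ks_two_sample(x, x)
        assert res.k == 0.0 and res.h is False

    def test_disjoint_supports_give_unit_statistic(self):
        res = ks_two_sample([1, 2, 3] * 10, [10, 11, 12] * 10)
        assert res.k == 1.0
        assert res.h is True

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_reject_flag_matches_alpha(self):
        rng = np.random.default_rng(0)
        res = ks_two_sample(rng.normal(size=500), rng.normal(3.0, size=500))
        assert res.h is True and res.p < 1e-6
        res2 = ks_two_sample(rng.normal(size=50), rng.normal(size=50))
        assert res2.h == (res2.p < 0.05)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.integers(0, 7), min_size=1, max_size=200),
           st.lists(st.integers(0, 7), min_size=1, max_size=200))
    def test_statistic_equals_brute_force_oracle_on_tied_levels(self, xs, ys):
        """Lattice-level samples are heavily tied; k must equal the
        brute-force double-loop ECDF supremum."""
        res = ks_two_sample(xs, ys)
        assert res.k == pytest.approx(brute_force_ks(xs, ys), abs=1e-12)

    def test_statistic_matches_scipy(self):
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(5)
        x = rng.choice([0, 25, 50, 75, 100], 80)
        y = rng.choice([50, 75, 100, 125], 60)
        res = ks_two_sample(x, y)
        assert res.k == pytest.approx(ks_2samp(x, y).statistic, abs=1e-12)


class TestHistogramsAndCountMaps:
    def test_axis_distribution_totals_group_size(self):
        df = group_frame(n=37, seed=2)
        counts = axis_distribution(df, "K2")
        assert counts.sum() == 37

    def test_single_level_group_has_one_bin(self):
        df = group_frame(n=10, seed=3)
        df["P"] = 75
        counts = axis_distribution(df, "P", levels=(0, 25, 50, 75, 100))
        assert counts.loc[75] == 10 and counts.drop(75).sum() == 0

    def test_pairwise_map_counts_and_log_sizes(self):
        df = pd.DataFrame({"P": [0, 0, 100], "K2": [50, 50, 75]})
        df = pd.concat([df] + [df.iloc[[2]]] * (int(np.e ** 2) - 1),
                       ignore_index=True)  # cell (100, 75) holds e^2 rounded
        out = pairwise_count_map(df, "P", "K2")
        assert out["count"].sum() == len(df)
        row1 = out[(out["P"] == 0) & (out["K2"] == 50)].iloc[0]
        assert row1["count"] == 2 and row1["size"] == pytest.approx(np.log(2) + 1)
        single = out[out["count"] == 1]
        assert np.allclose(single["size"], 1.0)  # ln(1) + 1

    def test_same_parameter_twice_rejected(self):
        with pytest.raises(ValueError):
            pairwise_count_map(group_frame(), "P", "P")
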