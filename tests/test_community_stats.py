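import numpy as np
import pandas as pd
import pytest

from rhizonet import (
    OtuTable,
    bray_curtis_matrix,
    pcoa,
    permanova,
    permdisp,
    indicator_analysis,
    chi_square_detection,
)


def counts_table(arr, samples=None):
    arr = np.asarray(arr, dtype=float)
    cols = samples or [f"s{j}" for j in range(arr.shape[1])]
    return OtuTable(data=pd.DataFrame(arr, index=[f"o{i}" for i in range(arr.shape[0])],
                                      columns=cols))


class TestBrayCurtis:
    def test_known_pairs(self):
        t = counts_table(np.array([[2, 1, 2, 0], [0, 1, 0, 2]]))
        d = bray_curtis_matrix(t)
        assert d.at["s0", "s1"] == pytest.approx(0.5)   # (2,0) vs (1,1)
        assert d.at["s0", "s2"] == 0.0                   # identical
        assert d.at["s0", "s3"] == 1.0                   # disjoint
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_matches_skbio(self):
        from skbio.diversity import beta_diversity
        rng = np.random.default_rng(0)
        t = counts_table(rng.integers(0, 30, (10, 6)))
        d = bray_curtis_matrix(t)
        ref = beta_diversity("braycurtis", t.values.T.astype(int), ids=t.sample_ids)
        assert np.allclose(d.values, ref.data, atol=1e-12)


class TestPcoa:
    def test_recovers_collinear_spacing(self):
        pts = np.array([[0.0], [3.0], [10.0]])
        d = np.abs(pts - pts.T)
        dm = pd.DataFrame(d, index=list("abc"), columns=list("abc"))
        coords, eigvals = pcoa(dm)
        recon = np.abs(coords.iloc[:, 0].to_numpy()[:, None]
                       - coords.iloc[:, 0].to_numpy()[None, :])
        assert np.allclose(recon, d, atol=1e-9)

    def test_zero_matrix_gives_no_axes(self):
        dm = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        coords, eigvals = pcoa(dm)
        assert coords.shape[1] == 0
        assert np.allclose(eigvals, 0.0, atol=1e-12)

    def test_euclidean_input_nonnegative_eigenvalues(self):
        rng = np.random.default_rng(1)
        pts = rng.random((6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = pd.DataFrame(d, index=[f"p{i}" for i in range(6)],
                          columns=[f"p{i}" for i in range(6)])
        _, eigvals = pcoa(dm)
        assert eigvals.min() > -1e-9

    def test_matches_skbio_coordinates(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix
        rng = np.random.default_rng(3)
        t = counts_table(rng.integers(0, 40, (12, 7)))
        d = bray_curtis_matrix(t)
        coords, eigvals = pcoa(d)
        ref = skbio_pcoa(DistanceMatrix(d.values, ids=d.index))
        k = coords.shape[1]
        assert np.allclose(np.sort(eigvals[:k]), np.sort(ref.eigvals.values[:k]), atol=1e-9)
        for ax in range(min(k, 3)):  # same up to sign
            mine = coords.iloc[:, ax].to_numpy()
            theirs = ref.samples.iloc[:, ax].to_numpy()
            assert np.allclose(np.abs(mine), np.abs(theirs), atol=1e-8)


def two_cloud_table(sep=10.0, n=5, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(10, 1, size=(8, n))
    b = rng.normal(10, 1, size=(8, n)) + sep
    return counts_table(np.hstack([np.abs(a), np.abs(b)]))


class TestPermanova:
    def test_separated_clouds_saturate_significance(self):
        t = two_cloud_table(n=8)
        d = bray_curtis_matrix(t)
        groups = {s: ("A" if i < 8 else "B") for i, s in enumerate(t.sample_ids)}
        res = permanova(d, groups, n_permutations=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.R_squared > 0.5

    def test_f_matches_skbio(self):
        from skbio.stats.distance import permanova as skbio_permanova, DistanceMatrix
        rng = np.random.default_rng(5)
        t = counts_table(rng.integers(1, 50, (10, 9)))
        d = bray_curtis_matrix(t)
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        res = permanova(d, groups, n_permutations=99, seed=0)
        ref = skbio_permanova(DistanceMatrix(d.values, ids=d.index),
                              grouping=groups, permutations=99)
        assert res.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_equal_distance_f_and_r2_against_ss_oracle(self):
        n, k = 9, 3
        d = pd.DataFrame(1.0 - np.eye(n),
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"s{i}" for i in range(n)])
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        res = permanova(d, groups, n_permutations=9, seed=0)
        # direct SS oracle on squared distances
        ss_total = (d.values ** 2)[np.triu_indices(n, 1)].sum() / n
        ss_within = sum((d.values[i:i + 3, i:i + 3] ** 2)[np.triu_indices(3, 1)].sum() / 3
                        for i in (0, 3, 6))
        f_oracle = ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))
        assert res.pseudo_F == pytest.approx(f_oracle)
        assert res.R_squared == pytest.approx((ss_total - ss_within) / ss_total)
        assert np.isfinite(res.pseudo_F)

    def test_group_of_one_rejected(self):
        d = pd.DataFrame(1 - np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(d, {"a": "A", "b": "A", "c": "B"}, n_permutations=9, seed=0)

    def test_permutation_stream_reproducible(self):
        t = two_cloud_table(sep=1.0)
        d = bray_curtis_matrix(t)
        groups = {s: ("A" if i < 5 else "B") for i, s in enumerate(t.sample_ids)}
        r1 = permanova(d, groups, n_permutations=199, seed=7)
        r2 = permanova(d, groups, n_permutations=199, seed=7)
        assert r1 == r2


class TestPermdisp:
    def test_f_matches_anova_on_centroid_distances(self):
        # independent oracle: full eigendecomposition with the
        # imaginary-axis correction, then a plain one-way ANOVA
        from scipy.stats import f_oneway
        rng = np.random.default_rng(2)
        t = counts_table(rng.integers(1, 50, (10, 10)))
        d = bray_curtis_matrix(t)
        groups = ["A"] * 5 + ["B"] * 5
        f_obs, p = permdisp(d, groups, n_permutations=99, seed=0)
        dv, n = d.values, 10
        j = np.eye(n) - 1 / n
        b = j @ (-0.5 * dv ** 2) @ j
        w, v = np.linalg.eigh((b + b.T) / 2)
        pos, neg = w > 1e-10, w < -1e-10
        cp = v[:, pos] * np.sqrt(w[pos])
        cn = v[:, neg] * np.sqrt(-w[neg])
        z = np.empty(n)
        for idx in (np.arange(5), np.arange(5, 10)):
            mp, mn = cp[idx].mean(0), cn[idx].mean(0)
            z[idx] = np.sqrt(np.maximum(
                ((cp[idx] - mp) ** 2).sum(1) - ((cn[idx] - mn) ** 2).sum(1), 0))
        assert f_obs == pytest.approx(f_oneway(z[:5], z[5:]).statistic, rel=1e-9)

    def test_matches_skbio_on_euclidean_distances(self):
        # with no negative eigenvalues both centroid conventions coincide
        from skbio.stats.distance import permdisp as skbio_permdisp, DistanceMatrix
        rng = np.random.default_rng(4)
        pts = rng.random((10, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(10)]
        dm = pd.DataFrame(d, index=ids, columns=ids)
        groups = ["A"] * 5 + ["B"] * 5
        f_obs, _ = permdisp(dm, groups, n_permutations=49, seed=0)
        ref = skbio_permdisp(DistanceMatrix(d, ids=ids), grouping=groups,
                             permutations=49, test="centroid")
        assert f_obs == pytest.approx(ref["test statistic"], rel=1e-6)

    def test_duplicated_points_have_zero_dispersion(self):
        arr = np.hstack([np.tile([[5.0], [3.0], [1.0]], 4),
                         np.random.default_rng(0).integers(1, 9, (3, 4))])
        t = counts_table(arr)
        d = bray_curtis_matrix(t)
        groups = ["dup"] * 4 + ["var"] * 4
        f_obs, _ = permdisp(d, groups, n_permutations=49, seed=0)
        assert np.isfinite(f_obs) and f_obs > 0


class TestIndicator:
    def test_perfect_indicator_stat_one(self):
        arr = np.zeros((1, 6))
        arr[0, :3] = 5
        t = counts_table(arr)
        groups = ["G1"] * 3 + ["G2"] * 3
        res = indicator_analysis(t, groups, n_permutations=99, seed=0)
        assert res[0].stat == pytest.approx(1.0)
        assert res[0].best_combination == ("G1",)
        assert res[0].A == 1.0 and res[0].B == 1.0

    def test_uniform_otu_specificity_is_one_over_k(self):
        t = counts_table(np.full((1, 6), 4.0))
        res = indicator_analysis(t, ["a"] * 2 + ["b"] * 2 + ["c"] * 2,
                                 n_permutations=49, seed=0)
        assert res[0].A == pytest.approx(1 / 3)

    def test_group_combinations_explored(self):
        arr = np.zeros((1, 9))
        arr[0, :6] = 7  # present in groups a+b, absent in c
        t = counts_table(arr)
        res = indicator_analysis(t, ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                                 allow_combinations=True, n_permutations=49, seed=0)
        assert res[0].best_combination == ("a", "b")
        assert res[0].stat == pytest.approx(1.0)

    def test_stat_scale_invariant(self):
        rng = np.random.default_rng(6)
        arr = rng.integers(0, 20, (5, 8)).astype(float)
        groups = ["A"] * 4 + ["B"] * 4
        r1 = indicator_analysis(counts_table(arr), groups, n_permutations=19, seed=3)
        r2 = indicator_analysis(counts_table(arr * 7.5), groups, n_permutations=19, seed=3)
        for a, b in zip(r1, r2):
            assert a.stat == pytest.approx(b.stat)
            assert a.p_value == b.p_value


class TestChiSquare:
    def test_uniform_table(self):
        stat, p = chi_square_detection(pd.DataFrame([[10, 10], [10, 10]]))
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(0)
        obs = rng.integers(5, 50, (3, 4)).astype(float)
        stat, p = chi_square_detection(pd.DataFrame(obs))
        row, col = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True)
        exp = row @ col / obs.sum()
        assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_one_row_reduces_to_goodness_of_fit(self):
        from scipy.stats import chisquare
        obs = np.array([12, 8, 10.0])
        stat, p = chi_square_detection(pd.DataFrame([obs]))
        ref = chisquare(obs)
        assert stat == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)
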