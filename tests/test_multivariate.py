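import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.spatial.distance import pdist, squareform

from methylrad.multivariate import (
    DistanceSet,
    compare_distance_groups,
    detect_outliers,
    epi_distances,
    mantel,
    pca,
    wilcoxon_rank_sum,
)


def random_rpm(n_sites, n_samples, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.gamma(2.0, 50.0, size=(n_sites, n_samples)),
        index=[f"s{i}" for i in range(n_sites)],
        columns=[f"lib{j}" for j in range(n_samples)],
    )


def random_distance_matrix(n, seed):
    rng = np.random.default_rng(seed)
    points = rng.normal(size=(n, 3))
    mat = squareform(pdist(points))
    return pd.DataFrame(mat, index=[f"x{i}" for i in range(n)],
                        columns=[f"x{i}" for i in range(n)])


class TestPCA:
    def test_duplicated_samples_have_identical_scores(self):
        rpm = random_rpm(20, 4, seed=1)
        rpm["lib3"] = rpm["lib0"]
        result = pca(rpm)
        assert np.allclose(result.scores.loc["lib0"],
                           result.scores.loc["lib3"])

    def test_variance_explained_sums_to_100(self):
        result = pca(random_rpm(30, 8, seed=2))
        assert result.variance_explained.sum() == pytest.approx(100.0)
        assert (np.diff(result.variance_explained) <= 1e-9).all()

    def test_two_variable_closed_form(self):
        # independent oracle: eigendecomposition of the 2x2 covariance
        rng = np.random.default_rng(10)
        latent = rng.normal(size=100)
        x1 = latent + 0.3 * rng.normal(size=100)
        x2 = -2.0 * latent + 0.3 * rng.normal(size=100)
        rpm = pd.DataFrame({"lib" + str(i): [x1[i], x2[i]]
                            for i in range(100)}, index=["s1", "s2"])
        result = pca(rpm, scale_unit=False)
        X = np.column_stack([x1, x2])
        cov = np.cov(X.T, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        # leading eigenvector, sign-fixed like the implementation
        v = evecs[:, np.argmax(evals)]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        assert np.allclose(result.loadings.loc["PC1"], v, atol=1e-8)
        expected_ve = 100 * evals.max() / evals.sum()
        assert result.variance_explained[0] == pytest.approx(expected_ve)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            pca(random_rpm(10, 1, seed=0))

    def test_zero_variance_sites_dropped(self):
        rpm = random_rpm(10, 5, seed=3)
        rpm.loc["s0"] = 42.0
        result = pca(rpm)
        assert "s0" not in result.loadings.columns


class TestOutliers:
    def test_homogeneous_cloud_rarely_flagged(self):
        n_clean = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = pd.DataFrame(rng.normal(size=(20, 3)),
                                  index=[f"x{i}" for i in range(20)])
            rpm = pd.DataFrame(scores.T.to_numpy() * 10 + 100)
            result = pca(scores.T, scale_unit=False)
            if len(detect_outliers(result)) == 0:
                n_clean += 1
        assert n_clean >= 17  # >= 95% of seeds within sampling slack

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(20, 5))
        data[0] += 10 * data.std() * np.ones(5)
        rpm = pd.DataFrame(data.T, columns=[f"x{i}" for i in range(20)])
        result = pca(rpm, scale_unit=False)
        flagged = detect_outliers(result)
        assert "x0" in flagged.index

    def test_tiny_identical_set_unflagged(self):
        rpm = pd.DataFrame(np.ones((6, 4)) + np.eye(6, 4) * 1e-9)
        result = pca(rpm, scale_unit=False)
        assert len(detect_outliers(result)) == 0


class TestEpiDistances:
    def test_identical_samples_distance_zero(self):
        rpm = random_rpm(15, 3, seed=6)
        rpm["lib2"] = rpm["lib0"]
        result = pca(rpm)
        dset = epi_distances(result, {c: "g" for c in rpm.columns})
        assert dset.matrix.loc["lib0", "lib2"] == pytest.approx(0.0, abs=1e-8)

    def test_three_four_five(self):
        scores = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"],
                              columns=["PC1", "PC2"])
        from methylrad.multivariate import PCAResult
        result = PCAResult(scores=scores, loadings=pd.DataFrame(),
                           variance_explained=np.array([60.0, 40.0]),
                           center=pd.Series(dtype=float), scale=None)
        dset = epi_distances(result, {"a": "g", "b": "g"})
        assert dset.matrix.loc["a", "b"] == pytest.approx(5.0)

    def test_within_group_counts_are_combinatorial(self):
        rpm = random_rpm(25, 9, seed=7)
        result = pca(rpm)
        grouping = {c: ("g1" if i < 5 else "g2")
                    for i, c in enumerate(rpm.columns)}
        dset = epi_distances(result, grouping)
        assert len(dset.within_group["g1"]) == math.comb(5, 2)
        assert len(dset.within_group["g2"]) == math.comb(4, 2)

    def test_rotation_invariance_of_distances(self):
        # with all components and no unit scaling, PCA-space distances
        # equal distances on the centered data directly
        rpm = random_rpm(40, 10, seed=8)
        result = pca(rpm, scale_unit=False)
        dset = epi_distances(result, {c: "g" for c in rpm.columns})
        direct = squareform(pdist(rpm.T.to_numpy()
                                  - rpm.T.to_numpy().mean(axis=0)))
        assert np.allclose(dset.matrix.to_numpy(), direct, atol=1e-8)

    def test_singleton_group_warned_and_empty(self, caplog):
        rpm = random_rpm(10, 4, seed=9)
        result = pca(rpm)
        grouping = {c: ("solo" if i == 0 else "rest")
                    for i, c in enumerate(rpm.columns)}
        import logging
        with caplog.at_level(logging.WARNING):
            dset = epi_distances(result, grouping)
        assert len(dset.within_group["solo"]) == 0


def exact_rank_sum_p(x, y):
    """Oracle: enumerate every assignment of the pooled ranks."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(combo)].sum()
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_greater = (us >= u_obs - 1e-12).mean()
    p_less = (us <= u_obs + 1e-12).mean()
    return min(1.0, 2 * min(p_greater, p_less))


class TestDistanceComparison:
    def test_exact_small_sample_p(self):
        assert wilcoxon_rank_sum(np.array([1.0, 2.0]),
                                 np.array([100.0, 200.0])) \
            == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert wilcoxon_rank_sum(x, x.copy()) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for n1, n2 in [(3, 3), (4, 5), (6, 8)]:
            x = rng.normal(size=n1)
            y = rng.normal(loc=0.5, size=n2)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                exact_rank_sum_p(x, y), rel=1e-9)

    def test_group_comparison_table(self):
        rng = np.random.default_rng(12)
        dset = DistanceSet(
            matrix=pd.DataFrame(),
            grouping=pd.Series(dtype=object),
            within_group={"lab": rng.gamma(5, 10, size=40),
                          "field": rng.gamma(5, 6, size=30)},
        )
        out = compare_distance_groups(dset)
        row = out.iloc[0]
        assert row["n1"] == 40 and row["n2"] == 30
        assert 0 <= row["wilcoxon_p"] <= 1
        assert row["median1"] == pytest.approx(
            np.median(dset.within_group["lab"]))

    def test_too_few_distances_rejected(self):
        dset = DistanceSet(
            matrix=pd.DataFrame(), grouping=pd.Series(dtype=object),
            within_group={"a": np.array([1.0, 2.0]),
                          "b": np.array([1.0, 2.0, 3.0])},
        )
        with pytest.raises(ValueError, match=">= 3"):
            compare_distance_groups(dset)


class TestMantel:
    def test_self_correlation(self):
        d = random_distance_matrix(10, seed=13)
        res = mantel(d, d, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_exhaustive_enumeration_n4(self):
        d1 = random_distance_matrix(4, seed=14)
        d2 = random_distance_matrix(4, seed=15)
        res = mantel(d1, d2, n_perm=999, seed=0)  # auto-exact at n=4
        # independent oracle: enumerate all 4! joint row/col permutations
        a1, a2 = d1.to_numpy(), d2.to_numpy()
        iu = np.triu_indices(4, k=1)
        r_obs = np.corrcoef(a1[iu], a2[iu])[0, 1]
        count = 0
        for perm in itertools.permutations(range(4)):
            perm = np.array(perm)
            r = np.corrcoef(a1[iu], a2[np.ix_(perm, perm)][iu])[0, 1]
            if r >= r_obs - 1e-12:
                count += 1
        assert res.n_perm == 24
        assert res.p == pytest.approx(count / 24)
        assert res.r == pytest.approx(r_obs)

    def test_relabelling_invariance_exact(self):
        d1 = random_distance_matrix(5, seed=16)
        d2 = random_distance_matrix(5, seed=17)
        res = mantel(d1, d2, n_perm=999, seed=0)
        perm = [3, 1, 4, 0, 2]
        labels = [d1.index[i] for i in perm]
        res2 = mantel(d1.loc[labels, labels], d2.loc[labels, labels],
                      n_perm=999, seed=0)
        assert res2.r == pytest.approx(res.r)
        assert res2.p == pytest.approx(res.p)

    def test_agrees_with_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(18)
        d1 = random_distance_matrix(12, seed=19)
        noise = rng.normal(0, 0.2, size=d1.shape)
        d2 = d1 + (noise + noise.T) / 2
        d2 = d2.clip(lower=0)
        np.fill_diagonal(d2.values, 0.0)
        ours = mantel(d1, d2, n_perm=999, seed=1)
        r_skbio, p_skbio, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.to_numpy(), ids=list(d1.index)),
            skbio_distance.DistanceMatrix(d2.to_numpy(), ids=list(d2.index)),
            method="pearson", permutations=999, alternative="greater")
        assert ours.r == pytest.approx(r_skbio, abs=1e-10)
        assert ours.p == pytest.approx(p_skbio, abs=0.02)

    def test_constant_matrix_rejected(self):
        d = pd.DataFrame(np.ones((4, 4)) - np.eye(4))
        good = random_distance_matrix(4, seed=20)
        d.index = d.columns = good.index
        with pytest.raises(ValueError, match="constant"):
            mantel(good, d)

    def test_mismatched_samples_rejected(self):
        d1 = random_distance_matrix(4, seed=21)
        d2 = random_distance_matrix(4, seed=22)
        d2.index = d2.columns = ["y0", "y1", "y2", "y3"]
        with pytest.raises(ValueError, match="different sample sets"):
            mantel(d1, d2)
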