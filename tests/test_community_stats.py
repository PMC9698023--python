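import math
import warnings

import numpy as np
import pandas as pd
import pytest

from felicore.community_stats import (
    DistanceMatrix,
    PermutationConfig,
    bray_curtis,
    bray_curtis_matrix,
    gini_simpson,
    metric_vs_age,
    observed_richness,
    pairwise_permanova,
    pcoa,
    permanova,
    permdisp,
    pielou,
    shannon,
)


class TestAlphaDiversity:
    def test_richness(self):
        assert observed_richness([0, 0, 0]) == 0
        assert observed_richness([1, 0, 3, 2, 9]) == 4

    def test_richness_monotone_under_detection_threshold(self):
        c = np.array([0, 10, 24, 25, 300])
        thresholded = np.where(c >= 25, c, 0)
        assert observed_richness(thresholded) <= observed_richness(c)

    def test_shannon_known_values(self):
        assert shannon([1.0]) == 0.0
        assert shannon([0.25] * 4) == pytest.approx(math.log(4), abs=1e-12)
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_gini_simpson(self):
        assert gini_simpson([1.0]) == 0.0
        assert gini_simpson([0.25] * 4) == pytest.approx(0.75)
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(10))
        assert gini_simpson(p) < 1.0

    def test_pielou(self):
        assert pielou([0.5, 0.5]) == pytest.approx(1.0)
        assert pielou([0.2] * 5) == pytest.approx(1.0)
        assert math.isnan(pielou([1.0]))
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(6))
        assert 0 < pielou(p) <= 1


class TestBrayCurtis:
    def test_identical_zero(self):
        assert bray_curtis([0.7, 0.3], [0.7, 0.3]) == 0.0

    def test_disjoint_one(self):
        assert bray_curtis([1, 0], [0, 1]) == 1.0

    def test_hand_value(self):
        # sum|x-y| = 0.8, sum(x+y) = 2 -> 0.4
        assert bray_curtis([0.7, 0.3], [0.3, 0.7]) == pytest.approx(0.4)

    def test_all_zero_pair_warns_zero(self):
        with pytest.warns(UserWarning):
            assert bray_curtis([0, 0], [0, 0]) == 0.0

    def test_matrix_agrees_with_scipy(self):
        from scipy.spatial.distance import braycurtis as scipy_bc

        rng = np.random.default_rng(5)
        rel = rng.dirichlet(np.ones(6), size=8).T
        df = pd.DataFrame(rel, columns=[f"s{i}" for i in range(8)])
        dm = bray_curtis_matrix(df)
        for i in range(8):
            for j in range(i):
                assert dm.values[i, j] == pytest.approx(
                    scipy_bc(rel[:, i], rel[:, j]), abs=1e-12
                )


class TestPCoA:
    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(10)], d)
        coords, evals = pcoa(dm)
        c = coords.to_numpy()
        d2 = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        assert np.allclose(d2, d, atol=1e-8)

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(7)], d)
        _, evals = pcoa(dm)
        a = -0.5 * d**2
        centered = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
        assert evals.sum() == pytest.approx(np.trace(centered), abs=1e-9)

    def test_first_axis_fraction_in_unit_interval(self):
        rng = np.random.default_rng(12)
        rel = rng.dirichlet(np.ones(5), size=12).T
        dm = bray_curtis_matrix(pd.DataFrame(rel, columns=[f"s{i}" for i in range(12)]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, evals = pcoa(dm)
        frac = evals[0] / evals[evals > 0].sum()
        assert 0 <= frac <= 1

    def test_too_few_samples(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            pcoa(dm)


def _two_group_dm(sep=10.0, n_per=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack(
        [rng.normal(0, 1 + noise, (n_per, 2)), rng.normal(sep, 1 + noise, (n_per, 2))]
    )
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    ids = [f"s{i}" for i in range(2 * n_per)]
    groups = pd.Series(["a"] * n_per + ["b"] * n_per, index=ids)
    return DistanceMatrix(ids, d), groups


class TestPermanova:
    def test_exact_enumeration_two_identical_point_groups(self):
        """Maximal separation, n=6: only the true labeling and its mirror
        achieve the extreme pseudo-F, so the exact p over all relabelings
        is 2/20 = 0.1."""
        pts = np.array([[0.0, 0]] * 3 + [[100.0, 0]] * 3)
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = list("abcdef")
        dm = DistanceMatrix(ids, d)
        groups = pd.Series(list("xxxyyy"), index=ids)
        res = permanova(dm, groups, permutations="exact")[0]
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_univariate_euclidean_matches_classical_anova(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(3)
        y = np.concatenate([rng.normal(0, 1, 8), rng.normal(1.0, 1, 7),
                            rng.normal(2.0, 1, 9)])
        labels = ["a"] * 8 + ["b"] * 7 + ["c"] * 9
        d = np.abs(y[:, None] - y[None, :])
        ids = [f"s{i}" for i in range(len(y))]
        dm = DistanceMatrix(ids, d)
        res = permanova(dm, pd.Series(labels, index=ids),
                        PermutationConfig(49, 1))[0]
        f_classic = f_oneway(y[:8], y[8:15], y[15:]).statistic
        assert res.statistic == pytest.approx(f_classic, abs=1e-9)

    def test_invariant_under_joint_reordering(self):
        dm, groups = _two_group_dm(sep=3.0, n_per=5, seed=7)
        res1 = permanova(dm, groups, PermutationConfig(99, 5))[0]
        perm = np.random.default_rng(1).permutation(dm.n)
        ids2 = [dm.ids[i] for i in perm]
        dm2 = dm.submatrix(ids2)
        res2 = permanova(dm2, groups.loc[ids2], PermutationConfig(99, 5))[0]
        assert res2.statistic == pytest.approx(res1.statistic, abs=1e-10)
        assert res2.r2 == pytest.approx(res1.r2, abs=1e-10)

    def test_agrees_with_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        dm, groups = _two_group_dm(sep=2.0, n_per=6, seed=11)
        res = permanova(dm, groups, PermutationConfig(999, 0))[0]
        sk = sk_permanova(
            skbio.DistanceMatrix(dm.values, ids=dm.ids), groups.to_numpy(),
            permutations=999,
        )
        assert res.statistic == pytest.approx(sk["test statistic"], abs=1e-9)
        assert res.p == pytest.approx(sk["p-value"], abs=0.05)

    def test_continuous_predictor_and_sequential_terms(self):
        rng = np.random.default_rng(13)
        n = 20
        age = rng.uniform(0, 10, n)
        pts = np.column_stack([age * 0.5 + rng.normal(0, 1, n), rng.normal(0, 1, n)])
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(ids, d)
        design = pd.DataFrame(
            {"age": age, "grp": ["a", "b"] * (n // 2)}, index=ids
        )
        res = permanova(dm, design, PermutationConfig(199, 2))
        assert len(res) == 2
        assert res[0].p <= 0.05  # planted age gradient
        assert 0 <= res[0].r2 + res[1].r2 <= 1

    def test_constant_predictor_rejected(self):
        dm, groups = _two_group_dm()
        const = pd.Series(["x"] * dm.n, index=dm.ids)
        with pytest.raises(ValueError):
            permanova(dm, const)

    def test_permutation_p_never_zero(self):
        dm, groups = _two_group_dm(sep=50.0, n_per=5)
        res = permanova(dm, groups, PermutationConfig(99, 0))[0]
        assert res.p >= 1 / 100


class TestPermdisp:
    def test_equal_dispersion_symmetric_groups(self):
        pts = np.array(
            [[-1, 0], [1, 0], [0, 1], [99, 0], [101, 0], [100, 1]], dtype=float
        )
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(6)]
        dm = DistanceMatrix(ids, d)
        res = permdisp(dm, pd.Series(["a"] * 3 + ["b"] * 3, index=ids),
                       PermutationConfig(99, 0))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.5

    def test_detects_dispersion_gap(self):
        rng = np.random.default_rng(4)
        tight = rng.normal(0, 0.01, (10, 2))
        loose = rng.normal(0, 5.0, (10, 2))
        pts = np.vstack([tight, loose])
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(20)]
        dm = DistanceMatrix(ids, d)
        res = permdisp(dm, pd.Series(["t"] * 10 + ["l"] * 10, index=ids),
                       PermutationConfig(199, 0))
        assert res.p <= 0.05

    def test_agrees_with_scikit_bio_centroid_f(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permdisp as sk_permdisp

        dm, groups = _two_group_dm(sep=1.0, n_per=7, seed=19)
        res = permdisp(dm, groups, PermutationConfig(99, 0))
        sk = sk_permdisp(
            skbio.DistanceMatrix(dm.values, ids=dm.ids), groups.to_numpy(),
            permutations=99, test="centroid",
        )
        assert res.statistic == pytest.approx(sk["test statistic"], rel=1e-6)

    def test_singleton_group_rejected(self):
        dm, _ = _two_group_dm()
        groups = pd.Series(["a"] + ["b"] * (dm.n - 1), index=dm.ids)
        with pytest.raises(ValueError, match="singleton"):
            permdisp(dm, groups)


class TestPairwise:
    def _three_group_dm(self):
        rng = np.random.default_rng(6)
        pts = np.vstack(
            [rng.normal(i * 3, 1, (5, 2)) for i in range(3)]
        )
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(15)]
        return DistanceMatrix(ids, d), pd.Series(
            ["a"] * 5 + ["b"] * 5 + ["c"] * 5, index=ids
        )

    def test_three_groups_three_rows_adjusted_ge_raw(self):
        dm, groups = self._three_group_dm()
        table = pairwise_permanova(dm, groups, PermutationConfig(99, 0))
        assert len(table) == 3
        assert (table["q"] >= table["p"] - 1e-12).all()

    def test_two_groups_equals_single_permanova(self):
        dm, groups = _two_group_dm(sep=3.0, n_per=5, seed=2)
        table = pairwise_permanova(dm, groups, PermutationConfig(199, 3))
        single = permanova(dm, groups.astype(str), PermutationConfig(199, 3))[0]
        assert table.loc[0, "F"] == pytest.approx(single.statistic, abs=1e-10)
        assert table.loc[0, "p"] == pytest.approx(single.p, abs=1e-12)
        assert table.loc[0, "q"] == pytest.approx(single.p, abs=1e-12)


class TestMetricVsAge:
    def test_exact_line(self):
        age = np.arange(10, dtype=float)
        res = metric_vs_age(2.0 * age, age)
        assert res.statistic == pytest.approx(2.0, abs=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(200):
            age = rng.uniform(0, 14, 40)
            y = rng.normal(size=40)
            ps.append(metric_vs_age(y, age).p)
        ps = np.array(ps)
        # mean of uniform p is 0.5 +- 3*sd
        assert abs(ps.mean() - 0.5) < 3 * (1 / np.sqrt(12 * 200))

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            metric_vs_age([1.0, 2.0], [1.0, 2.0])
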