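import numpy as np
import pandas as pd
import pytest

from oligopipe.diversity import (
    alpha_rarefaction_curve,
    bray_curtis,
    faith_pd,
    observed_richness,
    pairwise_distance_matrix,
    pcoa_coordinates,
    permanova,
    shannon_index,
    unweighted_unifrac,
)


class TestAlpha:
    def test_shannon_uniform_and_single(self):
        assert shannon_index({"a": 1, "b": 1, "c": 1, "d": 1}) == pytest.approx(2.0)
        assert shannon_index({"a": 10}) == 0.0

    def test_shannon_worked_example(self):
        expected = -(0.8 * np.log2(0.8) + 0.2 * np.log2(0.2))
        assert shannon_index({"a": 8, "b": 2}) == pytest.approx(expected, abs=1e-9)
        nat = -(0.8 * np.log(0.8) + 0.2 * np.log(0.2))
        assert shannon_index({"a": 8, "b": 2}, base=np.e) == pytest.approx(nat)

    def test_shannon_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon_index({"a": 0})

    def test_richness(self):
        assert observed_richness({"a": 5, "b": 0, "c": 1}) == 2
        assert observed_richness({}) == 0

    def test_faith_pd_toy_tree(self, toy_tree):
        assert faith_pd(set(), toy_tree) == 0.0
        assert faith_pd({"A"}, toy_tree) == pytest.approx(2.0)
        assert faith_pd({"A", "B", "C"}, toy_tree) == pytest.approx(5.0)

    def test_faith_pd_monotone(self, toy_tree):
        assert faith_pd({"A"}, toy_tree) <= faith_pd({"A", "B"}, toy_tree) \
            <= faith_pd({"A", "B", "C"}, toy_tree)

    def test_faith_pd_missing_feature_named(self, toy_tree):
        with pytest.raises(ValueError, match="Z"):
            faith_pd({"Z"}, toy_tree)


class TestBeta:
    def test_bray_curtis_cases(self):
        assert bray_curtis([3, 1], [3, 1]) == 0.0
        assert bray_curtis([1, 0], [0, 2]) == 1.0
        assert bray_curtis([6, 4, 0], [2, 3, 5]) == pytest.approx(0.5)

    def test_bray_curtis_zero_totals_error(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    def test_unifrac_cases(self, quartet_tree):
        assert unweighted_unifrac({"A"}, {"A"}, quartet_tree) == 0.0
        assert unweighted_unifrac({"A"}, {"C"}, quartet_tree) == pytest.approx(1.0)
        assert unweighted_unifrac({"A"}, {"A", "C"}, quartet_tree) == \
            pytest.approx(0.5)

    def test_unifrac_symmetry_and_range(self, quartet_tree, rng):
        leaves = ["A", "B", "C", "D"]
        for _ in range(10):
            x = {l for l in leaves if rng.random() < 0.5} or {"A"}
            y = {l for l in leaves if rng.random() < 0.5} or {"B"}
            d = unweighted_unifrac(x, y, quartet_tree)
            assert d == pytest.approx(unweighted_unifrac(y, x, quartet_tree))
            assert 0.0 <= d <= 1.0


def euclidean_dm(points):
    pts = np.asarray(points, dtype=float).reshape(len(points), -1)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return pd.DataFrame(d, index=[f"s{i}" for i in range(len(points))],
                        columns=[f"s{i}" for i in range(len(points))])


class TestPermanova:
    def test_two_cluster_toy_values(self):
        dm = euclidean_dm([0, 1, 10, 11])
        res = permanova(dm, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert res.R2 == pytest.approx(100 / 101, abs=1e-9)
        assert res.F == pytest.approx(200.0, abs=1e-9)

    def test_degenerate_identical_points(self):
        dm = euclidean_dm([5, 5, 5, 5])
        res = permanova(dm, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert res.R2 == 0.0 and res.p == 1.0

    def test_ss_partition_sums_to_total(self, rng):
        pts = rng.normal(size=(8, 2))
        dm = euclidean_dm(list(pts))
        labels = ["a"] * 4 + ["b"] * 4
        res = permanova(dm, labels, n_perm=9, seed=0)
        from oligopipe.diversity import _permanova_ss
        ss_t, ss_w = _permanova_ss(dm.to_numpy() ** 2, np.array(labels))
        assert res.R2 + ss_w / ss_t == pytest.approx(1.0, abs=1e-9)

    def test_matches_skbio_f_statistic(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova
        pts = rng.normal(size=(10, 3))
        pts[5:] += 1.5
        dm = euclidean_dm(list(pts))
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(dm, labels, n_perm=9, seed=0)
        theirs = skbio_permanova(DistanceMatrix(dm.to_numpy(), ids=dm.index),
                                 grouping=labels, permutations=9)
        assert ours.F == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_type_i_error_conservative(self, rng):
        # random labels vs random distances: rejection rate near alpha
        rej = 0
        trials = 200
        for _ in range(trials):
            pts = rng.normal(size=(8, 2))
            dm = euclidean_dm(list(pts))
            labels = rng.permutation(["a"] * 4 + ["b"] * 4)
            res = permanova(dm, labels, n_perm=99,
                            seed=int(rng.integers(2 ** 31)))
            rej += res.p <= 0.05
        se = np.sqrt(0.05 * 0.95 / trials)
        assert rej / trials <= 0.05 + 3 * se

    def test_singleton_groups_error(self):
        dm = euclidean_dm([0, 1])
        with pytest.raises(ValueError):
            permanova(dm, ["a", "b"], n_perm=9, seed=0)


class TestPCoA:
    def test_collinear_points_single_axis(self):
        dm = euclidean_dm([0, 1, 2])
        coords, frac = pcoa_coordinates(dm, k=2)
        assert frac[0] == pytest.approx(1.0)

    def test_round_trip_euclidean_distances(self, rng):
        pts = rng.normal(size=(6, 3))
        dm = euclidean_dm(list(pts))
        coords, _ = pcoa_coordinates(dm, k=6)
        rec = euclidean_dm(list(coords.to_numpy()))
        assert np.allclose(rec.to_numpy(), dm.to_numpy(), atol=1e-9)

    def test_duplicate_samples_identical_coordinates(self):
        dm = euclidean_dm([0, 0, 3])
        coords, _ = pcoa_coordinates(dm, k=2)
        assert np.allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)

    def test_matches_skbio_variance_fractions(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa
        pts = rng.normal(size=(7, 3))
        dm = euclidean_dm(list(pts))
        _, frac = pcoa_coordinates(dm, k=3)
        ref = skbio_pcoa(DistanceMatrix(dm.to_numpy(), ids=dm.index))
        assert np.allclose(frac, ref.proportion_explained[:3], atol=1e-9)


class TestRarefactionCurve:
    def test_full_depth_equals_direct_metric(self):
        counts = {"a": 30, "b": 20}
        out = alpha_rarefaction_curve(counts, [50], reps=3, seed=0,
                                      metric="shannon")
        assert out["mean"].iloc[0] == pytest.approx(shannon_index(counts))

    def test_richness_curve_non_decreasing(self):
        counts = {"a": 50, "b": 50}
        out = alpha_rarefaction_curve(counts, [1, 10, 100], reps=20, seed=1,
                                      metric="richness")
        means = out["mean"].to_numpy()
        assert means[0] == pytest.approx(1.0)
        assert means[-1] == pytest.approx(2.0)
        assert (np.diff(means) >= -1e-12).all()

    def test_reproducible_with_fixed_seed(self):
        counts = {"a": 40, "b": 25, "c": 10}
        a = alpha_rarefaction_curve(counts, [5, 20], reps=1, seed=9)
        b = alpha_rarefaction_curve(counts, [5, 20], reps=1, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_depth_above_total_errors(self):
        with pytest.raises(ValueError):
            alpha_rarefaction_curve({"a": 5}, [10], reps=1, seed=0)


def test_pairwise_distance_matrix_properties(quartet_tree):
    table = pd.DataFrame({"s1": [5, 3, 0, 0], "s2": [0, 0, 4, 4],
                          "s3": [5, 3, 0, 0]},
                         index=["A", "B", "C", "D"])
    for metric in ("braycurtis", "unifrac"):
        dm = pairwise_distance_matrix(table, metric, tree=quartet_tree)
        arr = dm.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert dm.loc["s1", "s3"] == pytest.approx(0.0)
        assert dm.loc["s1", "s2"] == pytest.approx(1.0)
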