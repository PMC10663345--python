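"""Rarefaction, alpha metrics, log-ratio transforms and distance metrics
against closed forms and brute-force oracles."""

from io import StringIO

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import endostat as es
from endostat.diversity import InsufficientDepthError, _sample_rng
from conftest import random_count_table


@pytest.fixture
def four_tip_tree():
    return TreeNode.read(StringIO("((a:0.5,b:0.3):0.2,(c:0.7,d:0.1):0.4);"))


class TestRarefyOnce:
    def test_exhaustive_draw_is_identity(self, rng):
        counts = np.array([5, 0, 5])
        out = es.rarefy_once(counts, 10, rng)
        np.testing.assert_array_equal(out, counts)

    def test_sum_and_support(self, rng):
        counts = np.array([90, 10, 0, 3])
        for _ in range(50):
            out = es.rarefy_once(counts, 25, rng)
            assert out.sum() == 25
            assert (out[counts == 0] == 0).all()

    def test_below_depth_raises_not_zero_fills(self, rng):
        with pytest.raises(InsufficientDepthError):
            es.rarefy_once(np.array([3, 2]), 10, rng)

    def test_hypergeometric_expectation(self, rng):
        # counts [90, 10] at depth 10: first coordinate is Hypergeom(100,90,10)
        draws = np.array([es.rarefy_once(np.array([90, 10]), 10, rng)[0]
                          for _ in range(20000)])
        se = np.sqrt(10 * 0.9 * 0.1 * (90 / 99)) / np.sqrt(20000)
        assert abs(draws.mean() - 9.0) < 3 * se


class TestRepeatRarefyMean:
    def test_single_iteration_reduces_to_one_draw(self, tiny_table):
        scheme = es.RarefactionScheme(depth=3, iterations=1, seed=5)
        mean = es.repeat_rarefy_mean(tiny_table, scheme)
        expected = {
            sid: es.rarefy_once(tiny_table.counts.loc[sid].to_numpy(), 3,
                                _sample_rng(5, 0, si))
            for si, sid in enumerate(mean.sample_ids)
        }
        for sid in mean.sample_ids:
            np.testing.assert_allclose(mean.counts.loc[sid], expected[sid])

    def test_rows_sum_exactly_to_depth(self, rng):
        table = random_count_table(rng, depth_low=200, depth_high=900)
        scheme = es.RarefactionScheme(depth=150, iterations=20, seed=1)
        mean = es.repeat_rarefy_mean(table, scheme)
        np.testing.assert_allclose(mean.totals(), 150.0, atol=1e-9)

    def test_mean_approaches_depth_times_proportions(self):
        table = es.AsvTable(pd.DataFrame([[90.0, 10.0]], index=["s"],
                                         columns=["a", "b"]))
        scheme = es.RarefactionScheme(depth=10, iterations=1000, seed=3)
        mean = es.repeat_rarefy_mean(table, scheme)
        sd = np.sqrt(10 * 0.9 * 0.1 * (90 / 99))
        tol = 3 * sd / np.sqrt(1000)
        assert abs(mean.counts.loc["s", "a"] - 9.0) < tol

    def test_low_depth_samples_excluded(self, tiny_table):
        scheme = es.RarefactionScheme(depth=4, iterations=2, seed=0)
        mean = es.repeat_rarefy_mean(tiny_table, scheme)
        assert mean.sample_ids == ["s1", "s3"]  # s2 totals 3 < 4


class TestAlphaMetrics:
    def test_shannon_uniform_closed_form(self):
        assert es.shannon([3, 3, 3, 3]) == pytest.approx(np.log(4))
        assert es.pielou([3, 3, 3, 3]) == pytest.approx(1.0)

    def test_shannon_single_taxon_zero(self):
        assert es.shannon([7, 0, 0]) == 0.0

    def test_pielou_undefined_at_richness_one(self):
        assert np.isnan(es.pielou([7, 0]))

    def test_shannon_direct_formula(self):
        c = np.array([1, 2, 3, 4], dtype=float)
        p = c / c.sum()
        expected = -(p * np.log(p)).sum()  # independent evaluation
        assert es.shannon(c) == pytest.approx(expected, abs=1e-12)


class TestFaithPd:
    def test_single_tip_depth_from_root(self, four_tip_tree):
        # tip a: 0.5 (tip) + 0.2 (its parent edge)
        assert es.faith_pd(pd.Series({"a": 1.0}), four_tip_tree) == \
            pytest.approx(0.7)

    def test_two_tip_tree(self):
        tree = TreeNode.read(StringIO("(a:1,b:1);"))
        assert es.faith_pd(pd.Series({"a": 1.0, "b": 2.0}), tree) == \
            pytest.approx(2.0)

    def test_missing_taxon_listed(self, four_tip_tree):
        with pytest.raises(KeyError, match="zzz"):
            es.faith_pd(pd.Series({"zzz": 1.0}), four_tip_tree)

    def test_random_tree_matches_edge_union_oracle(self, rng):
        from endostat.simulate import _random_tree

        tips = [f"t{i}" for i in range(16)]
        tree = _random_tree(tips, rng, 0.5)
        for _ in range(10):
            present = rng.choice(tips, size=rng.integers(1, 10),
                                 replace=False)
            counts = pd.Series(1.0, index=present)
            # oracle: union of root-to-tip edge sets
            edges = set()
            for name in present:
                node = tree.find(name)
                while node.parent is not None:
                    edges.add(id(node))
                    node = node.parent
            expected = sum(n.length for n in tree.traverse(include_self=False)
                           if id(n) in edges)
            assert es.faith_pd(counts, tree) == pytest.approx(expected)

    def test_matches_skbio(self, rng):
        from skbio.diversity.alpha import faith_pd as sk_faith
        from endostat.simulate import _random_tree

        tips = [f"t{i}" for i in range(12)]
        tree = _random_tree(tips, rng, 0.3)
        counts = rng.integers(0, 5, 12)
        mine = es.faith_pd(pd.Series(counts, index=tips, dtype=float), tree)
        ref = sk_faith(counts, taxa=tips, tree=tree)
        assert mine == pytest.approx(ref)

    def test_richness_correction_divides_by_richness(self, four_tip_tree):
        counts = pd.Series({"a": 1.0, "b": 1.0})
        pd_val = es.faith_pd(counts, four_tip_tree)
        assert es.richness_corrected_pd(counts, four_tip_tree) == \
            pytest.approx(pd_val / 2)


class TestPairMetrics:
    def test_identical_vectors_zero(self):
        x = np.array([1.0, 2, 3])
        assert es.bray_curtis(x, x) == 0.0
        assert es.jaccard_binary(x, x) == 0.0

    def test_disjoint_supports_one(self):
        x, y = np.array([1.0, 0]), np.array([0.0, 5])
        assert es.bray_curtis(x, y) == 1.0
        assert es.jaccard_binary(x, y) == 1.0

    def test_hand_values(self):
        assert es.bray_curtis([2, 2], [1, 3]) == pytest.approx(0.25)
        # supports {0,1} vs {1,2}: intersection 1, union 3
        assert es.jaccard_binary([1, 1, 0], [0, 1, 1]) == pytest.approx(2 / 3)

    def test_bray_curtis_bounded(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 10, 8)
            y = rng.uniform(0, 10, 8)
            assert 0.0 <= es.bray_curtis(x, y) <= 1.0

    def test_metric_axioms_random_triples(self, rng):
        for _ in range(30):
            x, y, z = rng.uniform(0, 5, (3, 6))
            for f in (es.bray_curtis, es.jaccard_binary):
                assert f(x, y) == pytest.approx(f(y, x))
                assert f(x, y) >= 0
            # Jaccard and Euclidean satisfy the triangle inequality
            assert es.jaccard_binary(x, z) <= \
                es.jaccard_binary(x, y) + es.jaccard_binary(y, z) + 1e-12
            de = lambda a, b: float(np.linalg.norm(a - b))
            assert de(x, z) <= de(x, y) + de(y, z) + 1e-12


class TestWeightedUnifrac:
    def test_identical_compositions_zero(self, four_tip_tree):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        assert es.weighted_unifrac(x, 2 * x, four_tip_tree) == \
            pytest.approx(0.0)

    def test_two_tip_opposite_mass(self):
        tree = TreeNode.read(StringIO("(a:1,b:1);"))
        x = pd.Series({"a": 1.0, "b": 0.0})
        y = pd.Series({"a": 0.0, "b": 1.0})
        assert es.weighted_unifrac(x, y, tree) == pytest.approx(2.0)

    def test_star_tree_equals_l1(self, rng):
        tips = [f"t{i}" for i in range(6)]
        star = TreeNode.read(StringIO("(" + ",".join(f"{t}:1" for t in tips)
                                      + ");"))
        x = pd.Series(rng.uniform(0.1, 5, 6), index=tips)
        y = pd.Series(rng.uniform(0.1, 5, 6), index=tips)
        l1 = np.abs(x / x.sum() - y / y.sum()).sum()
        assert es.weighted_unifrac(x, y, star) == pytest.approx(l1)

    def test_edge_loop_oracle_and_skbio(self, rng):
        from skbio.diversity.beta import weighted_unifrac as sk_wu
        from endostat.simulate import _random_tree

        tips = [f"t{i}" for i in range(10)]
        tree = _random_tree(tips, rng, 0.4)
        x = pd.Series(rng.integers(0, 20, 10).astype(float) + 1, index=tips)
        y = pd.Series(rng.integers(0, 20, 10).astype(float) + 1, index=tips)
        # brute force: loop over every edge summing b_e |p_x - p_y|
        expected = 0.0
        for node in tree.traverse(include_self=False):
            sub = {t.name for t in node.tips()} or {node.name}
            px = x[list(sub)].sum() / x.sum()
            py = y[list(sub)].sum() / y.sum()
            expected += (node.length or 0.0) * abs(px - py)
        mine = es.weighted_unifrac(x, y, tree)
        assert mine == pytest.approx(expected)
        ref = sk_wu(x.to_numpy(), y.to_numpy(), taxa=tips, tree=tree)
        assert mine == pytest.approx(float(ref))


class TestRclr:
    def test_geometric_mean_hand_computation(self):
        table = es.AsvTable(pd.DataFrame([[1.0, 10.0, 100.0]], index=["s"],
                                         columns=["a", "b", "c"]))
        out = es.rclr_transform(table, scale_to_median_depth=False)
        np.testing.assert_allclose(out.loc["s"],
                                   [-np.log(10), 0.0, np.log(10)])

    def test_flat_sample_all_zero(self):
        table = es.AsvTable(pd.DataFrame([[4.0, 4.0, 4.0]], index=["s"],
                                         columns=["a", "b", "c"]))
        out = es.rclr_transform(table)
        np.testing.assert_allclose(out.loc["s"], 0.0, atol=1e-12)

    def test_observed_entries_center_to_zero(self, rng):
        table = random_count_table(rng)
        out = es.rclr_transform(table)
        sums = np.nansum(out.to_numpy(), axis=1)
        np.testing.assert_allclose(sums, 0.0, atol=1e-10)

    def test_zeros_become_missing(self, tiny_table):
        out = es.rclr_transform(tiny_table)
        assert np.isnan(out.loc["s1", "a2"])


class TestAlrBySpike:
    def test_direct_formula(self):
        table = es.AsvTable(pd.DataFrame([[10.0, 100.0]], index=["s"],
                                         columns=["a", "b"]))
        out = es.alr_by_spike(table, pd.Series({"s": 10.0}))
        np.testing.assert_allclose(out.loc["s"], [0.0, np.log(10)])

    def test_ratio_invariance_under_joint_doubling(self, rng):
        table = random_count_table(rng)
        spikes = pd.Series(rng.integers(5, 200, len(table.sample_ids)),
                           index=table.counts.index, dtype=float)
        a = es.alr_by_spike(table, spikes, pseudocount=0.5)
        doubled = es.AsvTable(table.counts * 2)
        b = es.alr_by_spike(doubled, spikes * 2, pseudocount=1.0)
        # pseudocount only hits zeros; nonzero entries are scale-free
        nz = table.counts.to_numpy() > 0
        np.testing.assert_allclose(a.to_numpy()[nz], b.to_numpy()[nz],
                                   atol=1e-12)

    def test_zero_spike_errors(self, tiny_table):
        with pytest.raises(ValueError, match="spike"):
            es.alr_by_spike(tiny_table,
                            pd.Series(0.0, index=tiny_table.sample_ids))


class TestDistanceMatrix:
    def test_shape_symmetry_diagonal(self, rng):
        table = random_count_table(rng, n_samples=7)
        dm = es.distance_matrix(table, "bray_curtis")
        assert len(dm) == 7
        np.testing.assert_allclose(np.diag(dm.values), 0.0)
        np.testing.assert_allclose(dm.values, dm.values.T)

    def test_euclidean_1d(self):
        frame = pd.DataFrame([[2.0], [5.0]], index=["s1", "s2"],
                             columns=["x"])
        dm = es.distance_matrix(frame, "euclidean")
        assert dm.values[0, 1] == pytest.approx(3.0)

    @pytest.mark.parametrize("metric", ["bray_curtis", "jaccard", "euclidean"])
    def test_matches_scalar_ops_entrywise(self, rng, metric):
        table = random_count_table(rng, n_samples=6, n_asvs=9)
        dm = es.distance_matrix(table, metric)
        mat = table.matrix
        scalar = {"bray_curtis": es.bray_curtis,
                  "jaccard": es.jaccard_binary,
                  "euclidean": lambda a, b: float(np.linalg.norm(a - b))}
        for i in range(6):
            for j in range(6):
                assert dm.values[i, j] == pytest.approx(
                    scalar[metric](mat[i], mat[j]) if i != j else 0.0)

    def test_unifrac_matrix_matches_scalar(self, rng):
        from endostat.simulate import _random_tree

        tips = [f"t{i}" for i in range(8)]
        tree = _random_tree(tips, rng, 0.4)
        counts = pd.DataFrame(rng.integers(1, 30, (5, 8)).astype(float),
                              index=[f"s{i}" for i in range(5)], columns=tips)
        table = es.AsvTable(counts)
        dm = es.distance_matrix(table, "weighted_unifrac", tree=tree)
        for i in range(5):
            for j in range(i + 1, 5):
                ref = es.weighted_unifrac(counts.iloc[i], counts.iloc[j], tree)
                assert dm.values[i, j] == pytest.approx(ref)

    def test_invalid_metric_transform_pairing(self, tiny_table):
        rclr = es.rclr_transform(tiny_table)
        with pytest.raises(ValueError, match="euclidean"):
            es.distance_matrix(rclr, "bray_curtis")
        with pytest.raises(ValueError, match="tree"):
            es.distance_matrix(tiny_table, "weighted_unifrac")

    def test_pairwise_complete_scaling(self):
        # two samples sharing 2 of 4 coordinates; distance rescaled by
        # sqrt(4/2)
        frame = pd.DataFrame(
            [[1.0, 2.0, np.nan, 4.0], [2.0, np.nan, 3.0, 1.0]],
            index=["s1", "s2"], columns=list("abcd"))
        dm = es.distance_matrix(frame, "euclidean")
        expected = np.sqrt((1.0 + 9.0) * 4 / 2)
        assert dm.values[0, 1] == pytest.approx(expected)
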