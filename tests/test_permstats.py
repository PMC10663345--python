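"""PERMANOVA/PERMDISP machinery against classical ANOVA, exhaustive
enumeration, hand algebra and original-space geometry."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

import endostat as es
from endostat.permstats import gower_center, spatial_median


def _euclid_dm(points, ids=None):
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    ids = ids or [f"s{i}" for i in range(len(pts))]
    return es.DistanceMatrix(ids, squareform(pdist(pts)))


class TestGowerCenter:
    def test_two_points_hand_algebra(self):
        dm = es.DistanceMatrix(["s1", "s2"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        g = gower_center(dm)
        np.testing.assert_allclose(g, [[2.25, -2.25], [-2.25, 2.25]])

    def test_zero_distances_zero_matrix(self):
        dm = es.DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        np.testing.assert_allclose(gower_center(dm), 0.0)

    def test_huygens_identity(self, rng):
        a = rng.uniform(0.1, 2, (9, 9))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        dm = es.DistanceMatrix([f"s{i}" for i in range(9)], d)
        g = gower_center(dm)
        total = sum(d[i, j] ** 2 for i in range(9) for j in range(i + 1, 9)) / 9
        assert np.trace(g) == pytest.approx(total)
        np.testing.assert_allclose(g.sum(axis=0), 0.0, atol=1e-10)


class TestPermanova:
    def test_perfect_separation(self):
        d = np.zeros((6, 6))
        d[:3, 3:] = 1.0
        d[3:, :3] = 1.0
        dm = es.DistanceMatrix([f"s{i}" for i in range(6)], d)
        meta = pd.DataFrame({"g": list("aaabbb")}, index=dm.sample_ids)
        res = es.permanova(dm, meta, es.ModelSpec(["g"], exact=True))
        assert res.table["R2"].iloc[0] == pytest.approx(1.0)
        # smallest attainable exact p: splits preserving the partition
        import math

        assert res.table["p"].iloc[0] == pytest.approx(
            (math.factorial(3) ** 2 * 2) / math.factorial(6))

    def test_univariate_euclidean_equals_classical_anova(self, rng):
        y = rng.normal(0, 1, 15) + np.repeat([0.0, 0.4, 1.0], 5)
        meta = pd.DataFrame({"g": np.repeat(list("abc"), 5)},
                            index=[f"s{i}" for i in range(15)])
        resp = pd.Series(y, index=meta.index)
        res = es.perm_anova_univariate(resp, meta,
                                       es.ModelSpec(["g"], n_perm=49, seed=1))
        f_classical = f_oneway(y[:5], y[5:10], y[10:]).statistic
        assert res.table["F"].iloc[0] == pytest.approx(f_classical, abs=1e-10)
        ss_total = ((y - y.mean()) ** 2).sum()
        assert res.total_ss == pytest.approx(ss_total)

    def test_exact_p_matches_split_enumeration(self, rng):
        y = rng.normal(0, 1, 6)
        labels = np.array(list("aaabbb"))
        meta = pd.DataFrame({"g": labels}, index=[f"s{i}" for i in range(6)])
        res = es.perm_anova_univariate(pd.Series(y, index=meta.index), meta,
                                       es.ModelSpec(["g"], exact=True))
        # oracle: enumerate the 6!/(3!3!) distinct splits and compute
        # classical F for each
        f_obs = f_oneway(y[labels == "a"], y[labels == "b"]).statistic
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(combo)] = True
            f = f_oneway(y[mask], y[~mask]).statistic
            total += 1
            if f >= f_obs - 1e-10:
                count += 1
        assert res.table["p"].iloc[0] == pytest.approx(count / total)

    def test_matches_skbio_one_factor(self, rng):
        x = rng.normal(0, 1, (14, 6))
        x[:7] += 0.7
        dm = _euclid_dm(x)
        meta = pd.DataFrame({"g": ["a"] * 7 + ["b"] * 7}, index=dm.sample_ids)
        mine = es.permanova(dm, meta, es.ModelSpec(["g"], n_perm=99, seed=0))
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        ref = sk_permanova(SkDM(dm.values, dm.sample_ids), meta, column="g",
                           permutations=99)
        assert mine.table["F"].iloc[0] == pytest.approx(
            ref["test statistic"], rel=1e-10)

    def test_sequential_ss_sums_to_total(self, rng):
        x = rng.normal(0, 1, (20, 4))
        dm = _euclid_dm(x)
        meta = pd.DataFrame({
            "block": rng.choice(["b1", "b2"], 20),
            "g": rng.choice(["u", "v"], 20),
            "t": rng.choice(["r", "s"], 20),
        }, index=dm.sample_ids)
        spec = es.ModelSpec.from_formula("block + g*t", block="block",
                                         n_perm=19, seed=2)
        res = es.permanova(dm, meta, spec)
        assert res.table["SS"].sum() + res.residual_ss == pytest.approx(
            res.total_ss, rel=1e-8)
        assert list(res.table.index) == ["block", "g", "t", "g:t"]

    def test_invariant_to_simultaneous_reordering(self, rng):
        x = rng.normal(0, 1, (12, 3))
        dm = _euclid_dm(x)
        meta = pd.DataFrame({"g": rng.choice(["a", "b", "c"], 12)},
                            index=dm.sample_ids)
        res1 = es.permanova(dm, meta, es.ModelSpec(["g"], n_perm=99, seed=5))
        order = list(rng.permutation(dm.sample_ids))
        dm2 = dm.subset(order)
        res2 = es.permanova(dm2, meta.loc[order],
                            es.ModelSpec(["g"], n_perm=99, seed=5))
        assert res1.table["F"].iloc[0] == pytest.approx(
            res2.table["F"].iloc[0])
        assert res1.table["SS"].iloc[0] == pytest.approx(
            res2.table["SS"].iloc[0])

    def test_confounded_term_raises(self, rng):
        x = rng.normal(0, 1, (8, 2))
        dm = _euclid_dm(x)
        g = ["a", "a", "a", "a", "b", "b", "b", "b"]
        meta = pd.DataFrame({"g": g, "copy": g}, index=dm.sample_ids)
        with pytest.raises(ValueError, match="confounded"):
            es.permanova(dm, meta,
                         es.ModelSpec(["g", "copy"], n_perm=9, seed=0))

    def test_within_block_permutation_runs(self, rng):
        x = rng.normal(0, 1, (16, 3))
        dm = _euclid_dm(x)
        meta = pd.DataFrame({
            "blk": ["b1"] * 8 + ["b2"] * 8,
            "g": rng.choice(["u", "v"], 16),
        }, index=dm.sample_ids)
        spec = es.ModelSpec(["blk", "g"], block="blk", n_perm=49, seed=3,
                            permute_within_block=True)
        res = es.permanova(dm, meta, spec)
        assert 0 < res.table.loc["g", "p"] <= 1

    def test_marginal_mode_single_factor_agrees_with_sequential(self, rng):
        x = rng.normal(0, 1, (10, 3))
        dm = _euclid_dm(x)
        meta = pd.DataFrame({"g": rng.choice(["a", "b"], 10)},
                            index=dm.sample_ids)
        seq = es.permanova(dm, meta, es.ModelSpec(["g"], n_perm=49, seed=1))
        marg = es.permanova(dm, meta, es.ModelSpec(["g"], n_perm=49, seed=1,
                                                   ss_mode="marginal"))
        assert seq.table["SS"].iloc[0] == pytest.approx(
            marg.table["SS"].iloc[0])


class TestPairwise:
    def test_bh_step_up_hand_formula(self, rng):
        from statsmodels.stats.multitest import multipletests

        raw = np.array([0.01, 0.02, 0.03])
        adj = multipletests(raw, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_two_levels_adjusted_equals_raw(self, rng):
        x = rng.normal(0, 1, (10, 3))
        dm = _euclid_dm(x)
        meta = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5}, index=dm.sample_ids)
        out = es.permanova_pairwise(dm, meta, "g", n_perm=99, seed=1)
        assert len(out) == 1
        assert out["p_adjusted"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_small_level_skipped(self, rng):
        x = rng.normal(0, 1, (7, 2))
        dm = _euclid_dm(x)
        meta = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3 + ["c"]},
                            index=dm.sample_ids)
        out = es.permanova_pairwise(dm, meta, "g", n_perm=19, seed=1)
        assert set(zip(out["level_a"], out["level_b"])) == {("a", "b")}

    def test_null_fdr_controlled_on_average(self, rng):
        rejections = 0
        trials = 40
        for t in range(trials):
            x = rng.normal(0, 1, (18, 3))
            dm = _euclid_dm(x)
            meta = pd.DataFrame({"g": np.repeat(["a", "b", "c"], 6)},
                                index=dm.sample_ids)
            out = es.permanova_pairwise(dm, meta, "g", n_perm=99, seed=t)
            rejections += (out["p_adjusted"] <= 0.05).any()
        assert rejections / trials <= 0.12  # ~alpha with slack at 40 trials


class TestPcoa:
    def test_planar_points_reproduced(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        dm = _euclid_dm(pts)
        emb = es.pcoa_embed(dm)
        assert emb.imaginary.shape[1] == 0
        rec = squareform(pdist(emb.real))
        np.testing.assert_allclose(rec, dm.values, atol=1e-8)

    def test_collinear_points_one_axis(self):
        dm = _euclid_dm(np.array([0.0, 1.0, 2.5, 4.0]))
        emb = es.pcoa_embed(dm)
        assert emb.real.shape[1] == 1

    def test_non_euclidean_corrected_reconstruction(self, rng):
        a = rng.uniform(0.2, 1.0, (11, 11))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        dm = es.DistanceMatrix([f"s{i}" for i in range(11)], d)
        emb = es.pcoa_embed(dm)
        assert emb.imaginary.shape[1] > 0  # random dissimilarity not metric
        for i in range(11):
            for j in range(11):
                dr2 = ((emb.real[i] - emb.real[j]) ** 2).sum()
                di2 = ((emb.imaginary[i] - emb.imaginary[j]) ** 2).sum()
                assert dr2 - di2 == pytest.approx(d[i, j] ** 2, abs=1e-6)


class TestSpatialMedian:
    def test_two_points_midpoint(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0]])
        np.testing.assert_allclose(spatial_median(pts), [1.0, 0.0],
                                   atol=1e-7)

    def test_minimises_summed_norms(self, rng):
        pts = rng.normal(0, 1, (15, 3))
        m = spatial_median(pts)
        obj = np.linalg.norm(pts - m, axis=1).sum()
        for _ in range(200):
            trial = m + rng.normal(0, 0.05, 3)
            assert obj <= np.linalg.norm(pts - trial, axis=1).sum() + 1e-6

    def test_coincident_points(self):
        pts = np.zeros((4, 2))
        np.testing.assert_allclose(spatial_median(pts), 0.0)


class TestPermdisp:
    def test_euclidean_centroid_matches_original_space(self, rng):
        x = rng.normal(0, 1, (16, 4))
        x[8:] += 0.5
        dm = _euclid_dm(x)
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=dm.sample_ids)
        res = es.permdisp(dm, groups, center="centroid", n_perm=49, seed=2)
        direct = np.concatenate([
            np.linalg.norm(x[:8] - x[:8].mean(0), axis=1),
            np.linalg.norm(x[8:] - x[8:].mean(0), axis=1),
        ])
        np.testing.assert_allclose(res.extras["distances"].to_numpy(),
                                   direct, atol=1e-8)

    def test_euclidean_median_matches_original_space(self, rng):
        x = rng.normal(0, 1, (12, 3))
        dm = _euclid_dm(x)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=dm.sample_ids)
        res = es.permdisp(dm, groups, n_perm=49, seed=2)
        direct = np.concatenate([
            np.linalg.norm(x[:6] - spatial_median(x[:6]), axis=1),
            np.linalg.norm(x[6:] - spatial_median(x[6:]), axis=1),
        ])
        np.testing.assert_allclose(res.extras["distances"].to_numpy(),
                                   direct, atol=1e-6)

    def test_coincident_groups_reported_no_dispersion(self):
        d = np.zeros((4, 4))
        dm = es.DistanceMatrix(list("abcd"), d)
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=dm.sample_ids)
        res = es.permdisp(dm, groups, n_perm=19, seed=0)
        assert res.extras.get("no_dispersion")
        assert np.isnan(res.table["F"].iloc[0])

    def test_singleton_group_errors(self, rng):
        dm = _euclid_dm(rng.normal(0, 1, (5, 2)))
        groups = pd.Series(["a"] * 4 + ["b"], index=dm.sample_ids)
        with pytest.raises(ValueError, match="fewer than 2"):
            es.permdisp(dm, groups, n_perm=9, seed=0)

    def test_unequal_dispersion_detected(self, rng):
        x = np.vstack([rng.normal(0, 0.2, (10, 3)),
                       rng.normal(0, 2.0, (10, 3))])
        dm = _euclid_dm(x)
        groups = pd.Series(["tight"] * 10 + ["loose"] * 10,
                           index=dm.sample_ids)
        res = es.permdisp(dm, groups, n_perm=199, seed=1)
        assert res.table["p"].iloc[0] <= 0.01


class TestSuperUniformity:
    @pytest.mark.parametrize("alpha", [0.05, 0.1])
    def test_null_permutation_p_super_uniform(self, rng, alpha):
        hits = 0
        trials = 60
        for t in range(trials):
            x = rng.normal(0, 1, (16, 3))
            dm = _euclid_dm(x)
            meta = pd.DataFrame({"g": np.repeat(["a", "b"], 8)},
                                index=dm.sample_ids)
            res = es.permanova(dm, meta,
                               es.ModelSpec(["g"], n_perm=99, seed=1000 + t))
            hits += res.table["p"].iloc[0] <= alpha
        from scipy.stats import binom

        lo = binom.ppf(0.005, trials, alpha)
        hi = binom.ppf(0.995, trials, alpha)
        assert lo <= hits <= hi
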