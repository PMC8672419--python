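"""Loess/aquantile normalization, PCA outlier flagging, ANOVA filter, clustering."""

import numpy as np
import pandas as pd
import pytest

from trendmeta import (
    ExpressionMatrix,
    TwoColorArray,
    anova_filter,
    aquantile_normalize_between,
    flag_outliers_pca,
    hierarchical_cluster,
    normalize_within_array,
)


def make_array(m, a, ids=None):
    m = np.asarray(m, dtype=float)
    if ids is None:
        ids = np.array([f"P{i:04d}" for i in range(len(m))])
    return TwoColorArray(ids, m, np.asarray(a, dtype=float))


def decile_medians(m, a):
    edges = np.quantile(a, np.linspace(0, 1, 11))
    meds = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (a >= lo) & (a <= hi)
        meds.append(np.median(m[mask]))
    return np.asarray(meds)


class TestLoess:
    def test_noop_limit_unbiased_input(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(6, 14, 2000)
        m = rng.normal(0, 0.1, 2000)
        out = normalize_within_array(make_array(m, a))
        assert np.max(np.abs(out.m - m)) < 0.05
        assert np.array_equal(out.a, a)

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(6, 14, 300)
        out = normalize_within_array(make_array(np.full(300, 0.7), a))
        assert np.max(np.abs(out.m)) < 1e-6

    def test_constructed_bias_removed_per_decile(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(6, 14, 2000)
        m = 0.3 * (a - a.mean()) + rng.normal(0, 0.1, 2000)
        out = normalize_within_array(make_array(m, a))
        assert np.max(np.abs(decile_medians(out.m, a))) < 0.05

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(6, 14, 800)
        m = 0.4 * np.sin(a) + rng.normal(0, 0.15, 800)
        once = normalize_within_array(make_array(m, a))
        twice = normalize_within_array(once)
        assert np.max(np.abs(twice.m - once.m)) < 1e-3  # projection: exact up to float

    def test_too_few_probes(self):
        with pytest.raises(ValueError, match="50"):
            normalize_within_array(make_array([0.1] * 10, np.arange(10.0)))

    def test_constant_a_fallback_median_centering(self):
        m = np.concatenate([np.full(50, 1.0), np.full(50, 3.0)])
        out = normalize_within_array(make_array(m, np.full(100, 8.0)))
        assert np.median(out.m) == pytest.approx(0.0, abs=1e-12)


class TestAquantile:
    def test_identical_arrays_fixed_point(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(6, 14, 200)
        arrays = [make_array(np.zeros(200), a), make_array(np.zeros(200), a.copy())]
        out = aquantile_normalize_between(arrays)
        for o in out:
            assert np.allclose(o.a, a, atol=1e-12)

    def test_shift_removed(self):
        rng = np.random.default_rng(5)
        a1 = rng.uniform(6, 14, 300)
        out = aquantile_normalize_between(
            [make_array(np.zeros(300), a1), make_array(np.zeros(300), a1 + 3.0)]
        )
        assert np.allclose(np.sort(out[0].a), np.sort(out[1].a), atol=1e-12)

    def test_monotone_distortions_equalized(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(6, 14, 400)
        arrays = [
            make_array(np.zeros(400), base),
            make_array(np.zeros(400), base**1.2),
            make_array(np.zeros(400), 2 * base + np.log(base)),
        ]
        out = aquantile_normalize_between(arrays)
        q0 = np.sort(out[0].a)
        for o in out[1:]:
            assert np.allclose(np.sort(o.a), q0, atol=1e-12)

    def test_m_untouched_and_probe_order_respected(self):
        rng = np.random.default_rng(7)
        ids = np.array([f"P{i}" for i in range(100)])
        a1, m1 = rng.uniform(6, 14, 100), rng.normal(size=100)
        perm = rng.permutation(100)
        arr1 = make_array(m1, a1, ids)
        arr2 = make_array(m1[perm], a1[perm] + 1.0, ids[perm])
        out = aquantile_normalize_between([arr1, arr2])
        assert np.array_equal(out[1].m, m1[perm])
        # same probe ends up with the same normalized A in both arrays (same ranks)
        lookup = dict(zip(out[1].probe_ids.tolist(), out[1].a))
        assert np.allclose(out[0].a, [lookup[p] for p in ids], atol=1e-12)

    def test_mismatched_universes_rejected(self):
        a = np.linspace(6, 14, 100)
        arr1 = make_array(np.zeros(100), a)
        arr2 = make_array(np.zeros(100), a, ids=np.array([f"Q{i}" for i in range(100)]))
        with pytest.raises(ValueError, match="universes differ"):
            aquantile_normalize_between([arr1, arr2])


class TestPCAOutliers:
    def _cloud(self, n_samples=40, n_genes=200, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(8, 1, size=(n_genes, n_samples))
        return vals, rng

    def test_displaced_samples_flagged_exactly(self):
        vals, rng = self._cloud()
        # push 3 samples far along a common direction
        direction = rng.normal(size=vals.shape[0])
        direction /= np.linalg.norm(direction)
        for j in (5, 11, 23):
            vals[:, j] += 30.0 * direction
        cols = [f"S{i:02d}" for i in range(vals.shape[1])]
        mat = ExpressionMatrix(pd.DataFrame(vals, index=[f"G{i}" for i in range(vals.shape[0])], columns=cols))
        report = flag_outliers_pca(mat, threshold_sd=4.0)
        assert set(report.flagged_outliers) == {"S05", "S11", "S23"}

    def test_infinite_threshold_flags_none(self):
        vals, _ = self._cloud(seed=1)
        mat = ExpressionMatrix(pd.DataFrame(vals, index=[f"G{i}" for i in range(200)], columns=[f"S{i}" for i in range(40)]))
        assert flag_outliers_pca(mat, threshold_sd=np.inf).flagged_outliers == ()

    def test_null_cloud_rarely_flags(self):
        n_clean = 0
        for seed in range(10):
            vals, _ = self._cloud(seed=100 + seed)
            mat = ExpressionMatrix(
                pd.DataFrame(vals, index=[f"G{i}" for i in range(200)], columns=[f"S{i}" for i in range(40)])
            )
            n_clean += flag_outliers_pca(mat, threshold_sd=4.0).flagged_outliers == ()
        assert n_clean >= 9

    def test_too_few_samples(self):
        mat = ExpressionMatrix(pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)),
                                            index=[f"G{i}" for i in range(10)], columns=list("abc")))
        with pytest.raises(ValueError, match="4 samples"):
            flag_outliers_pca(mat)

    def test_report_serializes(self, tmp_path):
        vals, _ = self._cloud(seed=2)
        mat = ExpressionMatrix(pd.DataFrame(vals, index=[f"G{i}" for i in range(200)], columns=[f"S{i}" for i in range(40)]))
        report = flag_outliers_pca(mat)
        report.to_json(tmp_path / "qc.json")
        assert (tmp_path / "qc.json").exists()


class TestAnovaFilter:
    def _groups(self, sizes, prefix="S"):
        labels = []
        for gi, n in enumerate(sizes):
            labels += [f"g{gi}"] * n
        ids = [f"{prefix}{i:03d}" for i in range(sum(sizes))]
        return pd.Series(labels, index=ids)

    def test_constant_gene_excluded(self):
        groups = self._groups((3, 3))
        vals = np.vstack([np.ones(6), np.random.default_rng(0).normal(size=6)])
        mat = ExpressionMatrix(pd.DataFrame(vals, index=["const", "noisy"], columns=groups.index))
        passes, table = anova_filter(mat, groups, alpha=0.999)
        assert "const" not in passes
        assert table.set_index("gene_id").loc["const", "constant"]

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        sizes = (10, 11, 7, 5, 7)
        groups = self._groups(sizes)
        vals = rng.normal(size=(50, sum(sizes)))
        vals[0, :10] += 3.0  # one group shifted by 3 SD
        mat = ExpressionMatrix(pd.DataFrame(vals, index=[f"G{i}" for i in range(50)], columns=groups.index))
        passes, _ = anova_filter(mat, groups, alpha=0.05)
        assert "G0" in passes

    def test_matches_scipy_f_oneway(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        sizes = (4, 5, 6)
        groups = self._groups(sizes)
        vals = rng.normal(size=(20, sum(sizes)))
        mat = ExpressionMatrix(pd.DataFrame(vals, index=[f"G{i}" for i in range(20)], columns=groups.index))
        _, table = anova_filter(mat, groups)
        blocks = np.split(vals, np.cumsum(sizes)[:-1], axis=1)
        f_ref, p_ref = stats.f_oneway(*blocks, axis=1)
        assert np.allclose(table["F"], f_ref, atol=1e-10)
        assert np.allclose(table["p"], p_ref, atol=1e-12)

    def test_small_group_rejected(self):
        groups = self._groups((1, 5))
        vals = np.random.default_rng(0).normal(size=(5, 6))
        mat = ExpressionMatrix(pd.DataFrame(vals, index=[f"G{i}" for i in range(5)], columns=groups.index))
        with pytest.raises(ValueError, match="< 2 samples"):
            anova_filter(mat, groups)


class TestHierarchicalCluster:
    def test_identical_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(30, 5))
        vals[:, 1] = vals[:, 0]
        mat = ExpressionMatrix(pd.DataFrame(vals, index=[f"G{i}" for i in range(30)], columns=list("abcde")))
        link, _ = hierarchical_cluster(mat, [f"G{i}" for i in range(30)])
        assert link[0, 2] == 0.0
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}  # 'a' and 'b' after lexical sort

    def test_two_planted_clusters_split_at_top(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(50, 12))
        vals[:, 6:] += 8.0
        cols = [f"S{i:02d}" for i in range(12)]
        mat = ExpressionMatrix(pd.DataFrame(vals, index=[f"G{i}" for i in range(50)], columns=cols))
        from scipy.cluster.hierarchy import fcluster

        link, leaves = hierarchical_cluster(mat, [f"G{i}" for i in range(50)])
        labels = fcluster(link, t=2, criterion="maxclust")
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(40, 8))
        cols = [f"S{i}" for i in range(8)]
        mat1 = ExpressionMatrix(pd.DataFrame(vals, index=[f"G{i}" for i in range(40)], columns=cols))
        perm = rng.permutation(8)
        mat2 = ExpressionMatrix(pd.DataFrame(vals[:, perm], index=[f"G{i}" for i in range(40)], columns=[cols[i] for i in perm]))
        link1, leaves1 = hierarchical_cluster(mat1, [f"G{i}" for i in range(40)])
        link2, leaves2 = hierarchical_cluster(mat2, [f"G{i}" for i in range(40)])
        assert np.allclose(link1, link2)
        assert leaves1 == leaves2

    def test_empty_subset_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="empty"):
            hierarchical_cluster(small_matrix, [])
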