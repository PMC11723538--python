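"""The expression arm: transform, normalisation, vst, clustering,
labelling and differential expression, each against an oracle."""

import numpy as np
import pandas as pd
import pytest

from perivasc.synthetic import ExprSimConfig, simulate_de_counts, simulate_expression
from perivasc.transcriptomics import (
    DispersionTrend,
    differential_expression,
    cluster_subtype_association,
    fit_dispersion_trend,
    hierarchical_cluster,
    label_clusters,
    reverse_log_transform,
    size_factors,
    standardize_rows,
    vst,
)


class TestReverseLog:
    def test_closed_form_points(self):
        df = pd.DataFrame({"s": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
        out = reverse_log_transform(df)
        assert list(out["s"]) == [0.0, 1.0, 1023.0]

    def test_round_trip_exact_on_integers(self):
        r = np.random.default_rng(0)
        y = pd.DataFrame(r.integers(0, 2**40, size=(20, 5)).astype(float))
        back = reverse_log_transform(np.log2(y + 1.0))
        assert np.array_equal(back.to_numpy(), y.to_numpy())

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            reverse_log_transform(pd.DataFrame({"s": [-0.1]}))


class TestSizeFactors:
    def test_identical_columns(self):
        df = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3]}, dtype=float)
        assert np.allclose(size_factors(df), 1.0)

    def test_scale_equivariance(self):
        r = np.random.default_rng(1)
        base = r.integers(1, 100, size=(50, 1)).astype(float)
        df = pd.DataFrame(np.hstack([base, 2.0 * base]), columns=["a", "b"])
        sf = size_factors(df)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_definitional_oracle_50x10(self):
        """Factors equal a literal median-of-ratios implementation."""
        r = np.random.default_rng(2)
        df = pd.DataFrame(r.integers(0, 500, size=(50, 10)).astype(float))
        sf = size_factors(df)
        arr = df.to_numpy()
        geo = np.exp(np.mean(np.log(arr), axis=1, where=arr > 0,
                             out=np.full(50, -np.inf)))
        # restrict to genes positive in all samples (finite log-geomean)
        pos = (arr > 0).all(axis=1)
        geo = np.exp(np.log(arr[pos]).mean(axis=1))
        oracle = np.median(arr[pos] / geo[:, None], axis=0)
        assert np.allclose(sf.to_numpy(), oracle, rtol=1e-12)

    def test_no_common_gene_errors(self):
        df = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        with pytest.raises(ValueError):
            size_factors(df)


class TestVst:
    def test_monotone_and_log2_asymptote(self):
        trend = DispersionTrend(a0=0.05, a1=2.0)
        n = pd.DataFrame({"s": np.arange(0.0, 2000.0)})
        sf = pd.Series({"s": 1.0})
        out = vst(n, sf, trend)["s"].to_numpy()
        assert np.all(np.diff(out) > 0)                       # strictly increasing
        big = vst(pd.DataFrame({"s": [2.0**20, 2.0**21]}), sf, trend)["s"]
        assert big.iloc[1] - big.iloc[0] == pytest.approx(1.0, abs=1e-3)

    def test_rank_preserving_per_sample(self, small_cohort):
        _, em = small_cohort
        sf = size_factors(em.values)
        out = vst(em.values, sf)
        col = em.values.columns[0]
        raw_order = em.values[col].rank(method="average")
        vst_order = out[col].rank(method="average")
        assert (raw_order == vst_order).all()

    def test_variance_flattening_on_known_trend(self):
        """NB counts simulated across 5 mean-decades with a known trend:
        per-gene SDs of the transformed values have CV < 0.2."""
        r = np.random.default_rng(3)
        a0, a1 = 0.05, 2.0
        mus = np.repeat(10.0 ** np.arange(1, 6), 40)
        alphas = a0 + a1 / mus
        lam = r.gamma(1.0 / alphas[:, None],
                      (alphas * mus)[:, None], size=(len(mus), 60))
        counts = pd.DataFrame(r.poisson(lam).astype(float))
        sf = pd.Series(1.0, index=counts.columns)
        out = vst(counts, sf, DispersionTrend(a0, a1))
        sds = out.to_numpy().std(axis=1, ddof=1)
        assert sds.std() / sds.mean() < 0.2

    def test_trend_fit_recovers_parameters(self):
        """Moment-regression trend fit recovers (a0, a1) on data simulated
        from the parametric model."""
        r = np.random.default_rng(4)
        a0, a1 = 0.08, 3.0
        mus = np.exp(r.uniform(np.log(5), np.log(5e4), 400))
        alphas = a0 + a1 / mus
        lam = r.gamma(1.0 / alphas[:, None], (alphas * mus)[:, None],
                      size=(400, 100))
        counts = pd.DataFrame(r.poisson(lam).astype(float))
        trend = fit_dispersion_trend(counts, pd.Series(1.0, index=counts.columns))
        assert trend.a0 == pytest.approx(a0, rel=0.4)
        assert trend.a1 == pytest.approx(a1, rel=0.6)

    def test_too_few_genes_errors(self):
        counts = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError):
            fit_dispersion_trend(counts, pd.Series(1.0, index=counts.columns))


class TestStandardize:
    def test_moments_and_oracle(self):
        r = np.random.default_rng(5)
        df = pd.DataFrame(r.normal(3, 2, size=(10, 8)))
        out = standardize_rows(df)
        arr = out.to_numpy()
        assert np.all(np.abs(arr.mean(axis=1)) < 1e-12)
        assert np.allclose(arr.std(axis=1, ddof=1), 1.0)
        oracle = (df.to_numpy() - df.to_numpy().mean(1, keepdims=True)) \
            / df.to_numpy().std(1, ddof=1, keepdims=True)
        assert np.allclose(arr, oracle)

    def test_constant_row_warns_and_zeroes(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning):
            out = standardize_rows(df)
        assert (out.iloc[0] == 0.0).all()


class TestClustering:
    def test_two_separated_blobs_recovered(self):
        r = np.random.default_rng(6)
        left = r.normal(-5, 0.3, size=(10, 15))
        right = r.normal(5, 0.3, size=(10, 15))
        df = pd.DataFrame(np.hstack([left, right]),
                          columns=[f"s{i}" for i in range(30)])
        lab = hierarchical_cluster(df, k_cols=2, k_rows=2)
        groups = lab.sample_cluster.to_numpy()
        assert len(set(groups[:15])) == 1
        assert len(set(groups[15:])) == 1
        assert groups[0] != groups[-1]

    def test_duplicated_columns_co_cluster(self):
        r = np.random.default_rng(7)
        base = r.normal(size=(8, 6))
        df = pd.DataFrame(np.hstack([base, base[:, :1]]),
                          columns=[*"abcdef", "a_dup"])
        lab = hierarchical_cluster(df, k_cols=3, k_rows=2)
        assert lab.sample_cluster["a"] == lab.sample_cluster["a_dup"]

    def test_merge_sequence_matches_greedy_ward_oracle(self):
        """scipy's Ward merge sequence on <= 6 points equals exhaustive
        greedy minimisation of the Ward cost
        |A||B|/(|A|+|B|) * ||c_A - c_B||^2."""
        r = np.random.default_rng(8)
        pts = r.normal(size=(6, 3))
        df = pd.DataFrame(pts.T, columns=[f"s{i}" for i in range(6)])
        lab = hierarchical_cluster(df, k_cols=2, k_rows=1)
        link = lab.col_linkage
        # brute-force greedy Ward
        clusters = {i: [i] for i in range(6)}
        merges = []
        next_id = 6
        while len(clusters) > 1:
            best = None
            for a in sorted(clusters):
                for b in sorted(clusters):
                    if a >= b:
                        continue
                    ca = pts[clusters[a]].mean(axis=0)
                    cb = pts[clusters[b]].mean(axis=0)
                    na, nb = len(clusters[a]), len(clusters[b])
                    cost = na * nb / (na + nb) * np.sum((ca - cb) ** 2)
                    if best is None or cost < best[0]:
                        best = (cost, a, b)
            _, a, b = best
            merges.append({a, b})
            clusters[next_id] = clusters.pop(a) + clusters.pop(b)
            next_id += 1
        scipy_merges = [{int(row[0]), int(row[1])} for row in link]
        assert scipy_merges == merges

    def test_k_too_large(self):
        df = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            hierarchical_cluster(df, k_cols=5)

    def test_ward_d_option_runs(self):
        r = np.random.default_rng(9)
        df = pd.DataFrame(r.normal(size=(5, 12)))
        lab = hierarchical_cluster(df, k_cols=3, k_rows=2, method="ward_d")
        assert lab.sample_cluster.nunique() == 3


class TestLabelling:
    def _matrix_with_medians(self, medians):
        """Build a standardized-like matrix whose CD3D medians per planted
        cluster equal the requested values."""
        cols, vals, clusters = [], [], {}
        for ci, med in enumerate(medians, start=1):
            for j in range(3):
                cid = f"c{ci}_{j}"
                cols.append(cid)
                vals.append(med + (j - 1) * 0.01)
                clusters[cid] = ci
        df = pd.DataFrame([vals], index=["CD3D"], columns=cols)
        from perivasc.transcriptomics import ClusterLabeling

        lab = ClusterLabeling(
            sample_cluster=pd.Series(clusters), cluster_labels={},
            cluster_medians={},
        )
        return df, lab

    def test_threshold_rules(self):
        df, lab = self._matrix_with_medians([-0.5, 0.5, 1.5])
        lab = label_clusters(lab, df)
        assert lab.cluster_labels == {1: "Downregulated", 2: "Expressed",
                                      3: "Upregulated"}

    def test_boundary_values_are_expressed(self):
        df, lab = self._matrix_with_medians([0.0, 1.0])
        # medians exactly 0 and 1 (offsets cancel at the median)
        lab = label_clusters(lab, df)
        assert lab.cluster_labels == {1: "Expressed", 2: "Expressed"}

    def test_missing_marker_gene(self):
        df, lab = self._matrix_with_medians([0.5])
        with pytest.raises(KeyError):
            label_clusters(lab, df.rename(index={"CD3D": "OTHER"}))

    def test_degenerate_association_rejected(self):
        df, lab = self._matrix_with_medians([0.5, 0.6])
        lab = label_clusters(lab, df)
        subtypes = pd.Series("Basal", index=lab.sample_cluster.index)
        subtypes.iloc[:3] = "LumA"
        with pytest.raises(ValueError):
            cluster_subtype_association(lab, subtypes)   # single label row


class TestDifferentialExpression:
    def test_low_count_filter_exact(self):
        """Genes with < 3 total reads are excluded before testing —
        exactly those and no others."""
        counts, a, b, _ = simulate_de_counts(n_genes=50, n_per_group=5, n_de=10, seed=3)
        counts.iloc[40] = 0
        counts.iloc[41] = 0
        counts.iloc[41, 0] = 2                   # total 2 -> filtered
        counts.iloc[42] = 0
        counts.iloc[42, [0, 5]] = [1, 2]         # total 3 -> kept
        res = differential_expression(counts, a, b)
        assert res["filtered"].loc[counts.index[40]]
        assert res["filtered"].loc[counts.index[41]]
        assert not res["filtered"].loc[counts.index[42]]
        expected = counts.sum(axis=1) < 3
        assert (res["filtered"] == expected).all()
        assert res.loc[expected, "pvalue"].isna().all()

    def test_null_data_non_enriched(self):
        counts, a, b, _ = simulate_de_counts(n_de=0, seed=9)
        res = differential_expression(counts, a, b)
        kept = res[~res["filtered"]]
        assert kept["significant"].sum() == 0
        assert kept["log2FoldChange"].abs().median() < 0.25

    def test_planted_recovery_single_seed(self):
        counts, a, b, de_genes = simulate_de_counts(seed=0)
        res = differential_expression(counts, a, b)
        called = set(res.index[res["significant"]])
        assert len(called & set(de_genes)) >= 0.8 * len(de_genes)
        assert len(called - set(de_genes)) <= 1
        lfc = res.loc[de_genes, "log2FoldChange"]
        assert lfc.median() == pytest.approx(2.0, abs=0.3)

    def test_matches_statsmodels_nb_glm(self):
        """With the dispersion pinned, the vectorized NB fit agrees with
        statsmodels' NB GLM (independent IRLS) per gene."""
        sm = pytest.importorskip("statsmodels.api")
        counts, a, b, _ = simulate_de_counts(n_genes=25, n_per_group=8, n_de=8, seed=5)
        res = differential_expression(counts, a, b)
        sf = size_factors(counts)
        offset = np.log(np.concatenate([sf[a], sf[b]]))
        X = np.column_stack([np.ones(16), np.repeat([0, 1], 8)])
        y_all = counts[a + b].to_numpy(float)
        for gi in range(0, 25, 5):
            alpha = res["dispersion"].iloc[gi]
            fam = sm.families.NegativeBinomial(alpha=alpha)
            fit = sm.GLM(y_all[gi], X, family=fam, offset=offset).fit()
            assert res["log2FoldChange"].iloc[gi] == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-4)
            assert res["lfcSE"].iloc[gi] == pytest.approx(
                fit.bse[1] / np.log(2), rel=1e-3)

    def test_group_errors(self):
        counts, a, b, _ = simulate_de_counts(n_genes=20, n_per_group=5, n_de=5, seed=1)
        with pytest.raises(ValueError):
            differential_expression(counts, a[:1], b)
        with pytest.raises(ValueError):
            differential_expression(counts, a, a)


def test_pipeline_determinism(small_cohort):
    """Fixed input -> identical clusters, labels and DE calls across runs."""
    cfg, em = small_cohort
    def run():
        sf = size_factors(em.values)
        z = standardize_rows(vst(em.values, sf).loc[cfg.signature_genes])
        lab = label_clusters(hierarchical_cluster(z), z)
        return lab.sample_cluster.copy(), dict(lab.cluster_labels)
    c1, l1 = run()
    c2, l2 = run()
    pd.testing.assert_series_equal(c1, c2)
    assert l1 == l2
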