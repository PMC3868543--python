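import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score, silhouette_score

from rnadriver.errors import (
    AnnotationError,
    ConfoundingError,
    DimensionError,
    InputError,
    NormalizationError,
)
from rnadriver.matrix import CountMatrix
from rnadriver.normalize import (
    between_sample_normalize,
    cluster_subtypes,
    log_counts,
    mds_embedding,
    normalize_pipeline,
    remove_batch_effect,
    within_sample_normalize,
)
from rnadriver.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_counts,
    simulate_gene_models,
)


def toy_matrix(counts, gc=None, length=None, centers=None, subtypes=None):
    n_genes, n_samples = counts.shape
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"S{i}" for i in range(n_samples)]
    gene_meta = pd.DataFrame({
        "gc": gc if gc is not None else np.full(n_genes, 0.5),
        "length": length if length is not None else np.full(n_genes, 1000),
    }, index=genes)
    sample_meta = pd.DataFrame({
        "sample_id": samples,
        "sample_type": "patient",
        "center": centers if centers is not None else ["c1"] * n_samples,
        "subtype": subtypes if subtypes is not None else ["x"] * n_samples,
    }, index=samples)
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples),
                       gene_meta, sample_meta)


def biased_cohort(seed=0, **kw):
    cfg = SimulationConfig(n_patients=12, n_celllines=4, n_genes=500,
                           n_driver_genes=4, **kw)
    catalog = simulate_gene_models(cfg, seed=seed)
    return cfg, catalog


class TestWithinSample:
    def test_no_bias_is_near_noop(self):
        cfg = SimulationConfig(n_genes=2000, n_patients=10, n_celllines=2,
                               gc_bias_slope=0.0, length_bias_exponent=0.0)
        catalog = simulate_gene_models(cfg, seed=1)
        cm, _ = simulate_counts(cfg, catalog, seed=1)
        nm = log_counts(cm)
        out = within_sample_normalize(nm, "gc")
        assert float((out.values - nm.values).abs().max().max()) < 0.1

    def test_planted_gc_trend_removed(self):
        cfg = SimulationConfig(n_genes=2000, n_patients=10, n_celllines=2,
                               gc_bias_slope=2.0, length_bias_exponent=0.0,
                               subtype_programs={})
        catalog = simulate_gene_models(cfg, seed=2)
        cm, _ = simulate_counts(cfg, catalog, seed=2)
        nm = within_sample_normalize(log_counts(cm), "gc")
        mean_expr = nm.values.mean(axis=1)
        r = np.corrcoef(mean_expr, nm.gene_meta["gc"])[0, 1]
        assert abs(r) < 0.1

    def test_identical_columns_stay_identical(self):
        rng = np.random.default_rng(3)
        col = rng.poisson(50, size=100)
        cm = toy_matrix(np.column_stack([col, col]),
                        gc=rng.uniform(0.3, 0.7, 100))
        out = within_sample_normalize(cm, "gc")
        np.testing.assert_allclose(out.values.iloc[:, 0], out.values.iloc[:, 1])

    def test_column_mean_preserved(self):
        rng = np.random.default_rng(4)
        cm = toy_matrix(rng.poisson(40, size=(200, 3)),
                        gc=rng.uniform(0.2, 0.8, 200))
        nm = log_counts(cm)
        out = within_sample_normalize(nm, "gc")
        np.testing.assert_allclose(out.values.mean(axis=0),
                                   nm.values.mean(axis=0), atol=1e-9)

    def test_constant_covariate_warns_noop(self):
        cm = toy_matrix(np.random.default_rng(5).poisson(30, size=(50, 2)))
        nm = log_counts(cm)
        with pytest.warns(UserWarning, match="constant covariate"):
            out = within_sample_normalize(nm, "gc")
        pd.testing.assert_frame_equal(out.values, nm.values)

    def test_too_few_bins_rejected(self):
        cm = toy_matrix(np.ones((50, 2), dtype=int))
        with pytest.raises(InputError):
            within_sample_normalize(cm, "gc", n_bins=5)


class TestBetweenSample:
    def test_pure_shift_removed_by_upper_quartile(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(100, size=300).astype(float)
        cm = toy_matrix(np.column_stack([col, col * 2]).astype(int))
        out = between_sample_normalize(log_counts(cm), "upper_quartile")
        np.testing.assert_allclose(out.values.iloc[:, 0],
                                   out.values.iloc[:, 1], atol=0.02)

    def test_full_quantile_sorted_columns_identical(self):
        rng = np.random.default_rng(2)
        cm = toy_matrix(rng.poisson(50, size=(200, 5)))
        out = between_sample_normalize(log_counts(cm), "full_quantile")
        arr = np.sort(out.values.to_numpy(), axis=0)
        for j in range(1, arr.shape[1]):
            np.testing.assert_allclose(arr[:, 0], arr[:, j])

    def test_library_size_factors_equalized(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(80, size=400).astype(float)
        factors = [0.25, 0.5, 1.0, 2.0, 4.0]
        counts = np.column_stack([rng.poisson(base * f) for f in factors])
        cm = toy_matrix(counts)
        out = between_sample_normalize(log_counts(cm), "upper_quartile")
        expressed = cm.counts.to_numpy() > 0
        uqs = [np.quantile(out.values.to_numpy()[expressed[:, j], j], 0.75)
               for j in range(len(factors))]
        assert max(uqs) - min(uqs) < 1e-6

    def test_all_zero_column_rejected(self):
        counts = np.ones((50, 2), dtype=int)
        counts[:, 1] = 0
        with pytest.raises(NormalizationError):
            between_sample_normalize(log_counts(toy_matrix(counts)))

    def test_single_sample_rejected(self):
        with pytest.raises(NormalizationError):
            between_sample_normalize(log_counts(toy_matrix(
                np.ones((10, 1), dtype=int))))


class TestBatchRemoval:
    def test_no_batch_effect_near_noop(self):
        cfg = SimulationConfig(n_patients=16, n_celllines=4, n_genes=400,
                               batch_effect_sd=0.0)
        catalog = simulate_gene_models(cfg, seed=1)
        cm, _ = simulate_counts(cfg, catalog, seed=1)
        nm = log_counts(cm)
        out = remove_batch_effect(nm, batch="center", group="subtype")
        change = (out.values - nm.values).abs()
        # fitted batch coefficients are pure noise; change stays at noise level
        assert float(change.to_numpy().mean()) < 0.25
        assert float(np.quantile(change.to_numpy(), 0.99)) < 1.5

    def test_planted_shifts_recovered_within_3_se(self):
        cfg = SimulationConfig(n_patients=20, n_celllines=8, n_genes=500,
                               batch_effect_sd=0.8)
        b = simulate_cohort(cfg, seed=4)
        nm = log_counts(b.counts)
        out = remove_batch_effect(nm, batch="center", group="subtype")
        fit = out.batch_fit
        truth = b.truth.counts.batch_shift
        col = fit.coef.columns[0]
        delta = truth[col] - truth[fit.reference]
        z = (fit.coef[col] - delta) / fit.se[col]
        assert (z.abs() < 3).mean() > 0.95

    def test_batch_f_statistic_drops(self):
        cfg = SimulationConfig(n_patients=16, n_celllines=4, n_genes=300,
                               batch_effect_sd=1.0)
        b = simulate_cohort(cfg, seed=5)
        nm = log_counts(b.counts)
        out = remove_batch_effect(nm, batch="center", group="subtype")
        centers = nm.sample_meta["center"]

        def batch_f(values):
            groups = [values.loc[:, (centers == c).to_numpy()] for c in
                      centers.unique()]
            grand = values.mean(axis=1)
            between = sum(g.shape[1] * (g.mean(axis=1) - grand) ** 2
                          for g in groups)
            within = sum(((g.sub(g.mean(axis=1), axis=0)) ** 2).sum(axis=1)
                         for g in groups)
            return between / (within + 1e-12)

        assert batch_f(out.values).median() < batch_f(nm.values).median()

    def test_silhouette_flips_after_removal(self):
        cfg = SimulationConfig(n_patients=20, n_celllines=8, n_genes=500,
                               batch_effect_sd=1.0)
        b = simulate_cohort(cfg, seed=6)
        nm = normalize_pipeline(b.counts, steps=("gc", "length", "uq"))
        post = remove_batch_effect(nm, batch="center", group="subtype")
        pre_xy = mds_embedding(nm).values
        post_xy = mds_embedding(post).values
        centers = nm.sample_meta["center"]
        subtypes = nm.sample_meta["subtype"].fillna("none")
        assert silhouette_score(pre_xy, centers) > \
            silhouette_score(post_xy, centers)
        assert silhouette_score(post_xy, centers) < \
            silhouette_score(post_xy, subtypes)

    def test_confounded_design_rejected(self):
        rng = np.random.default_rng(7)
        cm = toy_matrix(rng.poisson(50, size=(60, 6)),
                        centers=["c1"] * 3 + ["c2"] * 3,
                        subtypes=["a"] * 3 + ["b"] * 3)
        with pytest.raises(ConfoundingError):
            remove_batch_effect(log_counts(cm), batch="center", group="subtype")

    def test_small_batch_rejected(self):
        rng = np.random.default_rng(8)
        cm = toy_matrix(rng.poisson(50, size=(60, 5)),
                        centers=["c1"] * 4 + ["c2"],
                        subtypes=["a", "b"] * 2 + ["a"])
        with pytest.raises(InputError):
            remove_batch_effect(log_counts(cm), batch="center", group="subtype")

    def test_provenance_recorded(self, normalized):
        steps = [p["step"] for p in normalized.provenance]
        assert steps[0] == "log2"
        assert "batch_removal" in steps
        assert normalized.shape == normalized.counts.shape


class TestMds:
    def test_equilateral_triangle(self):
        # three samples at pairwise-equal distances embed equilaterally
        x = np.array([[0.0, 1.0, 0.5],
                      [0.0, 0.0, np.sqrt(3) / 2]])
        values = pd.DataFrame(np.vstack([x, np.zeros((48, 3))]),
                              index=[f"G{i}" for i in range(50)],
                              columns=["a", "b", "c"])
        xy = mds_embedding(values, k=2, n_top=50)
        d = pdist(xy.values)
        assert np.ptp(d) < 1e-9

    def test_planar_configuration_exact(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 2))
        values = pd.DataFrame(np.vstack([pts.T, np.zeros((20, 8))]),
                              index=[f"G{i}" for i in range(22)],
                              columns=[f"S{i}" for i in range(8)])
        xy = mds_embedding(values, k=2, n_top=22)
        np.testing.assert_allclose(pdist(xy.values), pdist(pts), atol=1e-9)

    def test_deterministic(self, normalized):
        a = mds_embedding(normalized)
        b = mds_embedding(normalized)
        pd.testing.assert_frame_equal(a, b)

    def test_batches_linearly_separable(self):
        cfg = SimulationConfig(n_patients=16, n_celllines=4, n_genes=400,
                               batch_effect_sd=2.0, subtype_programs={})
        b = simulate_cohort(cfg, seed=2)
        xy = mds_embedding(log_counts(b.counts))
        centers = b.sample_meta["center"]
        from sklearn.linear_model import LogisticRegression
        clf = LogisticRegression().fit(xy.values, centers)
        assert clf.score(xy.values, centers) == 1.0

    def test_k_too_large_rejected(self, normalized):
        with pytest.raises(DimensionError):
            mds_embedding(normalized, k=normalized.shape[1])

    def test_too_few_samples_rejected(self):
        values = pd.DataFrame(np.ones((10, 2)), columns=["a", "b"])
        with pytest.raises(InputError):
            mds_embedding(values)


class TestClusterSubtypes:
    def test_planted_programs_recovered(self, bundle, normalized):
        clusters = cluster_subtypes(normalized)
        truth = bundle.truth.counts.subtype_of.fillna("none")
        assert adjusted_rand_score(truth.values, clusters.values) >= 0.9

    def test_k_one_single_cluster(self, normalized):
        clusters = cluster_subtypes(normalized, k=1)
        assert clusters.nunique() == 1

    def test_sample_order_invariance(self, bundle, normalized):
        clusters = cluster_subtypes(normalized)
        rng = np.random.default_rng(0)
        perm = rng.permutation(normalized.values.columns)
        from rnadriver.normalize import NormalizedMatrix
        shuffled = NormalizedMatrix(normalized.values[perm],
                                    normalized.gene_meta,
                                    normalized.sample_meta.loc[perm])
        reclustered = cluster_subtypes(shuffled).reindex(clusters.index)
        assert adjusted_rand_score(clusters.values, reclustered.values) == 1.0

    def test_missing_tf_rejected(self, normalized):
        with pytest.raises(AnnotationError):
            cluster_subtypes(normalized, tf_list=("NOT_A_GENE",))


class TestPipelineRecovery:
    def test_ari_over_seeds(self):
        # planted subtype recovery through the full normalization stack
        aris = []
        for seed in range(5):
            b = simulate_cohort(SimulationConfig(), seed=seed)
            nm = normalize_pipeline(b.counts)
            cl = cluster_subtypes(nm)
            truth = b.truth.counts.subtype_of.fillna("none")
            aris.append(adjusted_rand_score(truth.values, cl.values))
        assert np.median(aris) >= 0.9
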