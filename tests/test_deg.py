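import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from metabodysreg.deg import (
    bh_adjust,
    estimate_prior,
    filter_low_expression,
    moderated_t_test,
    run_deg,
    scale_normalize,
)
from metabodysreg.io import SampleSheet
from metabodysreg.synthetic import SimulationConfig, make_truth, simulate_cohort


def _sheet(n_t, n_n):
    ids = [f"T{i}" for i in range(n_t)] + [f"N{i}" for i in range(n_n)]
    return SampleSheet(pd.DataFrame(
        {"condition": ["tumor"] * n_t + ["normal"] * n_n, "cohort": "C"},
        index=pd.Index(ids, name="sample_id")))


def _matrix(values, n_t, n_n):
    n_genes = values.shape[0]
    return pd.DataFrame(values,
                        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
                        columns=_sheet(n_t, n_n).sample_ids)


class TestFilter:
    def _mat(self, zero_counts, n_samples=10):
        rows = []
        for z in zero_counts:
            row = [0.0] * z + [5.0] * (n_samples - z)
            rows.append(row)
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                            columns=[f"s{i}" for i in range(n_samples)])

    def test_boundary_strictly_greater(self):
        mat = self._mat([9, 8, 0])  # fractions 0.9, 0.8, 0.0
        out = filter_low_expression(mat, 0.8)
        assert list(out.index) == ["g1", "g2"]  # 0.9 removed, 0.8 kept

    def test_fully_expressed_matrix_unchanged(self):
        mat = self._mat([0, 0, 0])
        pd.testing.assert_frame_equal(filter_low_expression(mat), mat)

    def test_all_genes_removed_is_error(self):
        mat = self._mat([10, 10])
        with pytest.raises(ValueError):
            filter_low_expression(mat, 0.8)


class TestScaleNormalize:
    def test_identical_mads_is_pure_log_transform(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(1, 100, size=20)
        mat = pd.DataFrame({"a": col, "b": col[::-1]}, index=[f"g{i}" for i in range(20)])
        out = scale_normalize(mat)
        np.testing.assert_allclose(out.to_numpy(), np.log2(mat.to_numpy() + 1))

    def test_unequal_spreads_equalized(self):
        # column b has doubled log-scale spread around its median
        log_a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        log_b = 3.0 + 2.0 * (log_a - 3.0)
        mat = pd.DataFrame({"a": 2.0 ** log_a - 1, "b": 2.0 ** log_b - 1})
        out = scale_normalize(mat)
        mads = (out - out.median()).abs().median()
        assert mads["a"] == pytest.approx(mads["b"])
        # target is the geometric mean of the original MADs (1 and 2)
        assert mads["a"] == pytest.approx(np.sqrt(2.0))

    def test_constant_column_left_alone_with_warning(self, caplog):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [7.0, 7.0, 7.0]})
        with caplog.at_level("WARNING"):
            out = scale_normalize(mat)
        np.testing.assert_allclose(out["b"], np.log2(8.0))
        assert any("zero MAD" in r.message for r in caplog.records)

    def test_commutes_with_sample_permutation(self, tiny_expr):
        perm = ["S3", "S1", "S6", "S2", "S5", "S4"]
        out1 = scale_normalize(filter_low_expression(tiny_expr))[perm]
        out2 = scale_normalize(filter_low_expression(tiny_expr[perm]))
        pd.testing.assert_frame_equal(out1, out2)


class TestModeratedT:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(2)
        half = rng.normal(8, 1, size=(5, 4))
        mat = _matrix(np.hstack([half, half]), 4, 4)
        deg = moderated_t_test(mat, _sheet(4, 4))
        np.testing.assert_allclose(deg["log_fc"], 0, atol=1e-12)
        np.testing.assert_allclose(deg["t_stat"], 0, atol=1e-12)
        np.testing.assert_allclose(deg["p_value"], 1)

    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(3)
        mat = _matrix(rng.normal(8, 1, size=(50, 12)), 6, 6)
        deg = moderated_t_test(mat, _sheet(6, 6), prior_df=0)
        ref = stats.ttest_ind(mat.iloc[:, :6], mat.iloc[:, 6:], axis=1, equal_var=True)
        np.testing.assert_allclose(deg["t_stat"], ref.statistic, atol=1e-8)
        np.testing.assert_allclose(deg["p_value"], ref.pvalue, atol=1e-8)

    def test_posterior_variance_matches_shrinkage_formula(self):
        # heteroskedastic genes so the moment fit yields a finite prior df
        rng = np.random.default_rng(4)
        sds = rng.lognormal(0, 1, size=30)
        mat = _matrix(rng.normal(8, 1, size=(30, 10)) * sds[:, None], 5, 5)
        sheet = _sheet(5, 5)
        d = 8
        tumor, normal = mat.iloc[:, :5], mat.iloc[:, 5:]
        ss = ((tumor.sub(tumor.mean(axis=1), axis=0)) ** 2).sum(axis=1) + \
             ((normal.sub(normal.mean(axis=1), axis=0)) ** 2).sum(axis=1)
        s2 = ss / d
        d0, s02 = estimate_prior(s2.to_numpy(), d)
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        expected_t = (tumor.mean(axis=1) - normal.mean(axis=1)) / \
            np.sqrt(s2_post * (1 / 5 + 1 / 5))
        deg = moderated_t_test(mat, sheet)
        np.testing.assert_allclose(deg["t_stat"], expected_t, rtol=1e-10)

    def test_shrunken_variances_bounded_by_prior_and_sample(self):
        rng = np.random.default_rng(5)
        sds = rng.lognormal(0, 0.8, size=100)
        mat = _matrix(rng.normal(8, 1, size=(100, 10)) * sds[:, None], 5, 5)
        d = 8
        tumor, normal = mat.iloc[:, :5].to_numpy(), mat.iloc[:, 5:].to_numpy()
        ss = ((tumor - tumor.mean(1, keepdims=True)) ** 2).sum(1) + \
             ((normal - normal.mean(1, keepdims=True)) ** 2).sum(1)
        s2 = ss / d
        d0, s02 = estimate_prior(s2, d)
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        lo = np.minimum(s2, s02)
        hi = np.maximum(s2, s02)
        assert ((s2_post >= lo - 1e-12) & (s2_post <= hi + 1e-12)).all()

    def test_too_few_samples_per_group_rejected(self):
        mat = _matrix(np.ones((3, 3)) * 5, 1, 2)
        with pytest.raises(ValueError):
            moderated_t_test(mat, _sheet(1, 2))

    def test_null_pvalues_approximately_uniform(self):
        """End-to-end: null cohort gives near-uniform moderated-t p-values."""
        cfg = SimulationConfig(n_genes=2000, n_tumor=20, n_normal=20,
                               n_pathways=50, genes_per_pathway=20, seed=21)
        expr, sheet = simulate_cohort(cfg, make_truth(cfg, []))
        deg = run_deg(expr, sheet)
        ks = stats.kstest(deg["p_value"], "uniform")
        assert ks.statistic < 0.05


class TestBHAdjust:
    @staticmethod
    def brute_force(p):
        """Direct min-over-tails scan, independent of the step-up shortcut."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        for pos, idx in enumerate(order):
            tail = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
            adj[idx] = min(1.0, min(tail))
        return adj

    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_capped(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(1e-6, 1, size=500)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_na_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force(self, p):
        np.testing.assert_allclose(bh_adjust(p), self.brute_force(p), rtol=1e-12)
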