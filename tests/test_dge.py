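import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mddpipe import dge
from mddpipe.dge import DesignSpec

from conftest import two_group_counts


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(
            np.tile([[4], [10], [7]], (1, 3)),
            index=list("abc"), columns=list("xyz"),
        )
        s = dge.estimate_size_factors(counts)
        assert np.allclose(s, 1.0)

    def test_doubled_column_geomean_one(self):
        a = np.array([10, 20, 40, 5])
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        s = dge.estimate_size_factors(counts)
        assert np.allclose(s.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])

    def test_column_scaling_equivariance(self, rng):
        counts = pd.DataFrame(
            rng.poisson(50, size=(30, 4)) + 1, columns=list("abcd")
        )
        s0 = dge.estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["c"] = (scaled["c"] * 3).astype(int)
        s1 = dge.estimate_size_factors(scaled)
        # ratios to the geometric mean shift together: c gains factor 3
        # up to the geomean-1 rescaling shared by all samples
        assert np.allclose((s1 / s0) / (s1 / s0).iloc[0],
                           [1.0, 1.0, 3.0, 1.0])

    def test_no_all_positive_gene_instructs_pseudocount(self):
        counts = pd.DataFrame([[0, 5], [5, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="pseudocount"):
            dge.estimate_size_factors(counts)
        s = dge.estimate_size_factors(counts, pseudocount=0.5)
        assert np.isfinite(s).all()


class TestDispersions:
    @staticmethod
    def _simple_design(n):
        meta = pd.DataFrame({"condition": ["CTRL"] * (n // 2) + ["CASE"] * (n - n // 2)},
                            index=[f"s{i}" for i in range(n)])
        X, _ = dge.build_design_matrix(meta, DesignSpec(covariates=()))
        return X

    def test_poisson_counts_hit_floor(self, rng):
        counts = pd.DataFrame(rng.poisson(200, size=(60, 400)),
                              columns=[f"s{i}" for i in range(400)])
        s = pd.Series(1.0, index=counts.columns)
        disp = dge.estimate_dispersions(counts, s, self._simple_design(400))
        assert float(disp.median()) < 0.01

    def test_constant_gene_hits_floor(self):
        counts = pd.DataFrame([[7] * 10], columns=[f"s{i}" for i in range(10)])
        s = pd.Series(1.0, index=counts.columns)
        disp = dge.estimate_dispersions(counts, s, self._simple_design(10))
        assert disp.iloc[0] == pytest.approx(1e-8)

    def test_nb_dispersion_recovery(self, rng):
        counts, meta = two_group_counts(rng, n_genes=200, n_per_group=150,
                                        mu=200.0, alpha=0.2)
        s = dge.estimate_size_factors(counts)
        X, _ = dge.build_design_matrix(meta, DesignSpec(covariates=()))
        disp = dge.estimate_dispersions(counts, s, X)
        assert 0.16 <= float(disp.median()) <= 0.24

    def test_collinear_design_names_columns(self):
        meta = pd.DataFrame(
            {"condition": ["CTRL", "CASE"] * 4,
             "age": [1.0, 2.0] * 4,
             "age2": [2.0, 4.0] * 4},
            index=[f"s{i}" for i in range(8)],
        )
        with pytest.raises(ValueError, match="rank deficient"):
            dge.build_design_matrix(meta, DesignSpec(covariates=("age", "age2")))


class TestNbGlm:
    def test_poisson_intercept_only_closed_form(self, rng):
        y = rng.poisson(30, size=20).astype(float)
        s = np.ones(20)
        X = np.ones((20, 1))
        beta, cov, conv = dge.fit_nb_glm(y, s, X, 0.0)
        assert conv
        assert beta[0] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_two_group_poisson_group_means(self, rng):
        y = np.concatenate([rng.poisson(20, 15), rng.poisson(60, 15)]).astype(float)
        s = np.ones(30)
        X = np.column_stack([np.ones(30), np.repeat([0.0, 1.0], 15)])
        beta, _, conv = dge.fit_nb_glm(y, s, X, 0.0)
        assert conv
        assert beta[0] == pytest.approx(np.log(y[:15].mean()), abs=1e-8)
        assert beta[0] + beta[1] == pytest.approx(np.log(y[15:].mean()), abs=1e-8)

    def test_matches_statsmodels_nb_glm(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        counts, meta = two_group_counts(rng, n_genes=5, n_per_group=40,
                                        mu=80.0, alpha=0.15, log2fc=0.7)
        s = np.exp(rng.normal(0, 0.2, size=80))
        X = np.column_stack(
            [np.ones(80), (meta["condition"] == "CASE").to_numpy(float)]
        )
        for g in range(5):
            y = counts.iloc[g].to_numpy(dtype=float)
            beta, cov, conv = dge.fit_nb_glm(y, s, X, 0.15)
            assert conv
            model = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=0.15),
                offset=np.log(s),
            ).fit()
            assert np.allclose(beta, model.params, atol=1e-4)
            assert np.allclose(np.sqrt(np.diag(cov)), model.bse, rtol=1e-3)

    def test_planted_log2fc_recovery(self, rng):
        counts, meta = two_group_counts(rng, n_genes=100, n_per_group=200,
                                        mu=100.0, alpha=0.1, log2fc=1.0)
        n = 400
        X = np.column_stack(
            [np.ones(n), (meta["condition"] == "CASE").to_numpy(float)]
        )
        beta, _, conv = dge.fit_nb_glm_batch(
            counts.to_numpy(dtype=float), np.ones(n), X, np.full(100, 0.1)
        )
        assert conv.all()
        mean_lfc = float((beta[:, 1] / np.log(2)).mean())
        assert 0.9 <= mean_lfc <= 1.1


class TestWald:
    def test_zero_coefficient_gives_p_one(self):
        z, p = dge.wald_test(np.array([0.0]), np.array([[1.0]]), 0)
        assert p == pytest.approx(1.0)

    def test_critical_z_gives_p_05(self):
        z, p = dge.wald_test(np.array([1.959964]), np.array([[1.0]]), 0)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_zero_se_flagged(self):
        z, p = dge.wald_test(np.array([1.0]), np.array([[0.0]]), 0)
        assert np.isnan(z) and np.isnan(p)


def bh_oracle(p):
    """Brute-force step-up: sort, cumulative min from the right, unsort."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank_pos, i in enumerate(order, start=1):
        out[i] = min(
            min(p[j] * m / (list(order).index(j) + 1) for j in order[rank_pos - 1:]),
            1.0,
        )
    return out


class TestBH:
    def test_single_p(self):
        assert dge.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        padj = dge.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(padj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(dge.bh_adjust(np.ones(5)), 1.0)

    def test_nan_excluded_and_propagated(self):
        padj = dge.bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(padj[1])
        assert padj[0] == pytest.approx(0.02)  # m = 2 without the NaN

    def test_padj_never_below_p(self, rng):
        p = rng.uniform(size=200)
        assert (dge.bh_adjust(p) >= p - 1e-12).all()

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_matches_brute_force_oracle(self, pvals):
        p = np.array(pvals)
        assert np.allclose(dge.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(size=100)
        assert np.allclose(dge.bh_adjust(p),
                           mt.multipletests(p, method="fdr_bh")[1])


class TestRegionDge:
    def test_single_condition_region_rejected(self, rng):
        counts, meta = two_group_counts(rng, n_genes=10, n_per_group=5)
        meta = meta.assign(region="R")
        meta["condition"] = "CTRL"
        with pytest.raises(ValueError, match="single condition"):
            dge.run_region_dge(counts, meta, DesignSpec(covariates=()), region="R")

    def test_size_factor_absorbs_library_scaling(self, rng):
        """Scaling one library is absorbed by its size factor.

        The factor picks up the multiplier exactly (up to the shared
        geometric-mean-1 renormalization).  The Wald statistics stay
        numerically stable but not bit-identical: a 5x deeper library
        genuinely carries more NB-likelihood information, so no estimator
        on raw counts can be exactly invariant.
        """
        counts, meta = two_group_counts(rng, n_genes=40, n_per_group=20, mu=80.0)
        meta = meta.assign(region="R")
        spec = DesignSpec(covariates=())
        res0 = dge.run_region_dge(counts, meta, spec, region="R")
        scaled = counts.copy()
        scaled.iloc[:, 3] = (scaled.iloc[:, 3] * 5).astype(int)
        res1 = dge.run_region_dge(scaled, meta, spec, region="R",
                                  dispersions=res0.dispersions)
        assert res1.size_factors.iloc[3] / res0.size_factors.iloc[3] == (
            pytest.approx(5 * (res1.size_factors.iloc[0] / res0.size_factors.iloc[0]),
                          rel=1e-9)
        )
        common = res0.table.index.intersection(res1.table.index)
        assert np.allclose(res0.table.loc[common, "wald_z"],
                           res1.table.loc[common, "wald_z"], atol=0.1)
        res2 = dge.run_region_dge(scaled, meta, spec, region="R")
        assert np.allclose(res0.table.loc[common, "wald_z"],
                           res2.table.loc[common, "wald_z"], atol=0.15)

    def test_batch_covariate_absorbed_when_modelled(self, rng):
        """A batch effect confounded with condition inflates discoveries
        only when the dataset covariate is left out of the design."""
        n_per = 40
        counts, meta = two_group_counts(rng, n_genes=400, n_per_group=n_per,
                                        mu=100.0, alpha=0.05)
        # batch confounded with condition: 3/4 of cases come from batch b2
        batch = np.concatenate([
            np.repeat(["b1", "b2"], [30, 10]),  # controls
            np.repeat(["b1", "b2"], [10, 30]),  # cases
        ])
        meta = meta.assign(dataset=batch, region="R")
        effect = rng.normal(0, 0.5, size=400)
        mat = counts.to_numpy(dtype=float)
        mat[:, batch == "b2"] *= 2.0 ** effect[:, None]
        counts = pd.DataFrame(np.round(mat).astype(int), index=counts.index,
                              columns=counts.columns)
        with_cov = dge.run_region_dge(
            counts, meta, DesignSpec(covariates=("dataset",)), region="R"
        )
        without = dge.run_region_dge(
            counts, meta, DesignSpec(covariates=()), region="R"
        )
        assert len(with_cov.de_genes()) <= 2
        assert len(without.de_genes()) > len(with_cov.de_genes())


class TestCrossRegion:
    @staticmethod
    def _result_from_lfc(lfc: pd.Series) -> dge.DGEResult:
        table = pd.DataFrame(
            {"baseMean": 1.0, "log2fc": lfc, "se": 1.0, "wald_z": 0.0,
             "p": 1.0, "padj": 1.0}
        )
        return dge.DGEResult(table, pd.Series(dtype=float), pd.Series(dtype=float),
                             "condition[CASE]")

    def test_monotone_transform_gives_rho_one(self, rng):
        lfc = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        res = {
            "A": self._result_from_lfc(lfc),
            "B": self._result_from_lfc(np.exp(lfc) + 3.0),
        }
        mat = dge.cross_region_spearman(res)
        assert mat.loc["A", "A"] == 1.0
        assert mat.loc["A", "B"] == pytest.approx(1.0)
        assert mat.equals(mat.T)

    def test_independent_null_regions_uncorrelated(self, rng):
        idx = [f"g{i}" for i in range(3000)]
        res = {
            "A": self._result_from_lfc(pd.Series(rng.normal(size=3000), index=idx)),
            "B": self._result_from_lfc(pd.Series(rng.normal(size=3000), index=idx)),
        }
        rho = dge.cross_region_spearman(res).loc["A", "B"]
        assert abs(rho) < 0.06

    def test_insufficient_overlap_warns_nan(self, rng):
        res = {
            "A": self._result_from_lfc(pd.Series([1.0, 2.0], index=["g1", "g2"])),
            "B": self._result_from_lfc(pd.Series([1.0, 2.0], index=["g3", "g4"])),
        }
        with pytest.warns(UserWarning, match="fewer than 3"):
            mat = dge.cross_region_spearman(res)
        assert np.isnan(mat.loc["A", "B"])


class TestIntersectDeSets:
    @staticmethod
    def _result(padj: dict, lfc_sign=-1.0) -> dge.DGEResult:
        table = pd.DataFrame(
            {
                "baseMean": 1.0,
                "log2fc": lfc_sign,
                "se": 1.0,
                "wald_z": 0.0,
                "p": list(padj.values()),
                "padj": list(padj.values()),
            },
            index=list(padj),
        )
        return dge.DGEResult(table, pd.Series(dtype=float), pd.Series(dtype=float),
                             "condition[CASE]")

    def test_disjoint_signals_empty_common(self):
        res = {
            "A": self._result({"g1": 0.01, "g2": 0.9}),
            "B": self._result({"g1": 0.9, "g2": 0.01}),
        }
        venn = dge.intersect_de_sets(res)
        assert venn.common_genes == set()
        assert venn.intersection_counts[("A",)] == 1
        assert venn.intersection_counts[("A", "B")] == 0

    def test_shared_gene_with_signs(self):
        res = {
            "A": self._result({"g1": 0.001, "g2": 0.5}),
            "B": self._result({"g1": 0.002, "g2": 0.8}),
        }
        venn = dge.intersect_de_sets(res)
        assert venn.common_genes == {"g1"}
        assert venn.common_signs["g1"] == {"A": -1, "B": -1}

    def test_degenerate_threshold_gives_full_intersection(self):
        res = {
            "A": self._result({"g1": 0.4, "g2": 0.99}),
            "B": self._result({"g1": 0.7, "g2": 0.99}),
        }
        venn = dge.intersect_de_sets(res, threshold=1.01)
        assert venn.common_genes == {"g1", "g2"}
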