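import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairlim import (
    ModelSpec,
    MultiOmicsDataset,
    OmicsMatrix,
    SampleMetadata,
    adjust_fdr,
    fit_all_pairs,
    interaction_pvalue_reference,
)
from pairlim.errors import DomainError, ValidationError
from pairlim.model import FLAG_DEGENERATE, FLAG_ZERO_RESIDUAL, _build_design


def make_dataset(G, M, pheno, gene_ids=None, met_ids=None):
    ng, n = G.shape
    nm = M.shape[0]
    samples = [f"S{i}" for i in range(n)]
    gene_ids = gene_ids or [f"G{i}" for i in range(ng)]
    met_ids = met_ids or [f"M{j}" for j in range(nm)]
    meta = SampleMetadata(
        pd.DataFrame(
            {"phenotype": np.where(np.asarray(pheno) == 0, "a", "b")},
            index=pd.Index(samples, name="sample_id"),
        ),
        "phenotype",
    )
    return MultiOmicsDataset(
        OmicsMatrix(gene_ids, samples, G, "gene"),
        OmicsMatrix(met_ids, samples, M, "metabolite"),
        meta,
        {"a": 0, "b": 1},
    )


def brute_force_bh(p):
    """Quadratic-time step-up definition: adj(i) = min_{j>=i} p(j)*m/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestAdjustFdr:
    def test_hand_applied_step_up(self):
        out = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(adjust_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_missing_excluded_from_family(self):
        out = adjust_fdr([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], adjust_fdr([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            adjust_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40
        )
    )
    def test_matches_brute_force_step_up(self, pvals):
        out = adjust_fdr(pvals)
        np.testing.assert_allclose(out, brute_force_bh(pvals), atol=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_and_bounded(self, seed):
        p = np.random.default_rng(seed).uniform(size=25)
        out = adjust_fdr(p)
        assert (out >= p - 1e-15).all() and (out <= 1).all()
        order = np.argsort(p)
        assert (np.diff(out[order]) >= -1e-15).all()


class TestReferenceFit:
    def test_exact_fit_recovers_betas_and_flags_zero_residual(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=12)
        p = np.array([0] * 6 + [1] * 6)
        X = _build_design(g, p, None)
        y = X @ np.array([1.0, 2.0, 0.0, 3.0])
        fit = interaction_pvalue_reference(X, y)
        assert fit.flag == FLAG_ZERO_RESIDUAL
        np.testing.assert_allclose(fit.betas, [1, 2, 0, 3], atol=1e-8)
        assert np.isnan(fit.p_interaction)

    def test_duplicated_column_flags_degenerate(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        X = np.column_stack([X, X[:, 2]])
        fit = interaction_pvalue_reference(X, rng.normal(size=10))
        assert fit.flag == FLAG_DEGENERATE
        assert np.isnan(fit.p_interaction)

    def test_agrees_with_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        g = rng.normal(size=20)
        p = np.array([0] * 10 + [1] * 10)
        X = _build_design(g, p, None)
        y = 1 + 0.5 * g + 0.2 * p + 0.8 * g * p + rng.normal(0, 0.4, 20)
        fit = interaction_pvalue_reference(X, y)
        res = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.betas, res.params, atol=1e-10)
        assert fit.se4 == pytest.approx(res.bse[3], abs=1e-10)
        assert fit.p_interaction == pytest.approx(res.pvalues[3], abs=1e-12)


class TestFitAllPairs:
    def test_row_count_is_product(self, small_dataset):
        res = fit_all_pairs(small_dataset)
        assert len(res) == 3 * 2

    def test_batch_equals_reference_on_toy_dataset(self, small_dataset):
        res = fit_all_pairs(small_dataset).df
        p = small_dataset.phenotype_vector()
        for _, row in res.iterrows():
            g = small_dataset.genes.feature_values(str(row["gene"]))
            m = small_dataset.metabolites.feature_values(str(row["metabolite"]))
            ref = interaction_pvalue_reference(_build_design(g, p, None), m)
            np.testing.assert_allclose(
                row[["beta1", "beta2", "beta3", "beta4"]].astype(float),
                ref.betas,
                atol=1e-8,
            )
            assert row["se_interaction"] == pytest.approx(ref.se4, abs=1e-8)
            assert row["t_interaction"] == pytest.approx(ref.t4, abs=1e-8)
            assert row["p_interaction"] == pytest.approx(ref.p_interaction, abs=1e-10)

    @pytest.mark.parametrize("missing_rate", [0.0, 0.15])
    def test_batch_equals_reference_on_random_instances(self, missing_rate):
        rng = np.random.default_rng(42)
        for trial in range(10):
            n = int(rng.integers(10, 30))
            n1 = int(rng.integers(4, n - 4 + 1))
            pheno = np.zeros(n, dtype=int)
            pheno[rng.choice(n, size=n1, replace=False)] = 1
            if pheno.sum() < 4 or (1 - pheno).sum() < 4:
                continue
            ng, nm = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            G = rng.normal(8, 2, size=(ng, n))
            M = rng.normal(10, 3, size=(nm, n))
            if missing_rate:
                M[rng.random(M.shape) < missing_rate] = np.nan
            ds = make_dataset(G, M, pheno)
            res = fit_all_pairs(ds, compute_effect_sizes=False).df
            for _, row in res.iterrows():
                g = ds.genes.feature_values(str(row["gene"]))
                m = ds.metabolites.feature_values(str(row["metabolite"]))
                ok = ~np.isnan(m)
                if row["flag"] == "insufficient_samples":
                    continue
                ref = interaction_pvalue_reference(
                    _build_design(g[ok], pheno[ok], None), m[ok]
                )
                np.testing.assert_allclose(
                    row[["beta1", "beta2", "beta3", "beta4"]].astype(float),
                    ref.betas,
                    atol=1e-8,
                )
                assert row["t_interaction"] == pytest.approx(
                    ref.t4, abs=1e-8, nan_ok=True
                )
                assert row["p_interaction"] == pytest.approx(
                    ref.p_interaction, abs=1e-10, nan_ok=True
                )

    def test_label_swap_preserves_interaction_test(self, small_dataset):
        res = fit_all_pairs(small_dataset).df
        swapped_ds = MultiOmicsDataset(
            small_dataset.genes,
            small_dataset.metabolites,
            small_dataset.metadata,
            {"ctrl": 1, "case": 0},
        )
        res_sw = fit_all_pairs(swapped_ds).df
        np.testing.assert_allclose(
            np.abs(res["t_interaction"]), np.abs(res_sw["t_interaction"]), atol=1e-8
        )
        np.testing.assert_allclose(
            res["p_interaction"], res_sw["p_interaction"], atol=1e-10
        )
        # reparameterization: swapped beta4 is the negative of the original
        np.testing.assert_allclose(res["beta4"], -res_sw["beta4"], atol=1e-8)

    def test_gene_location_scale_change_preserves_test(self, small_dataset):
        res = fit_all_pairs(small_dataset).df
        G2 = small_dataset.genes.values * 3.7 + 11.0
        ds2 = MultiOmicsDataset(
            OmicsMatrix(
                small_dataset.genes.feature_ids,
                small_dataset.genes.sample_ids,
                G2,
                "gene",
            ),
            small_dataset.metabolites,
            small_dataset.metadata,
            small_dataset.phenotype_encoding,
        )
        res2 = fit_all_pairs(ds2).df
        np.testing.assert_allclose(
            res["t_interaction"], res2["t_interaction"], atol=1e-8
        )
        np.testing.assert_allclose(res["p_interaction"], res2["p_interaction"], atol=1e-10)

    def test_constant_gene_flagged_degenerate(self):
        rng = np.random.default_rng(5)
        pheno = np.array([0] * 6 + [1] * 6)
        G = np.vstack([np.full(12, 3.0), rng.normal(size=12)])
        M = rng.normal(size=(2, 12))
        res = fit_all_pairs(make_dataset(G, M, pheno), compute_effect_sizes=False).df
        g0 = res[res["gene"] == "G0"]
        assert (g0["flag"] == "degenerate").all()
        assert g0["p_interaction"].isna().all()

    def test_group_below_minimum_rejected(self):
        rng = np.random.default_rng(6)
        pheno = np.array([0] * 3 + [1] * 9)
        ds = make_dataset(rng.normal(size=(1, 12)), rng.normal(size=(1, 12)), pheno)
        with pytest.raises(ValidationError, match="minimum"):
            fit_all_pairs(ds)

    def test_fdr_at_least_raw_p(self, small_dataset):
        res = fit_all_pairs(small_dataset).df
        ok = res["p_interaction"].notna()
        assert (res.loc[ok, "fdr_p"] >= res.loc[ok, "p_interaction"] - 1e-15).all()

    def test_covariate_column_appended(self):
        rng = np.random.default_rng(7)
        pheno = np.array([0] * 8 + [1] * 8)
        G = rng.normal(size=(1, 16))
        age = rng.uniform(30, 70, 16)
        M = 5 + 0.1 * age + rng.normal(size=(1, 16))
        ds = make_dataset(G, M, pheno)
        ds.metadata.table["age"] = age
        res = fit_all_pairs(ds, ModelSpec(covariates=["age"])).df
        # 5-column design -> df = 16 - 5
        assert int(res["df"].iloc[0]) == 11
        ref = interaction_pvalue_reference(
            _build_design(G[0], pheno, age[:, None]), M[0]
        )
        assert res["p_interaction"].iloc[0] == pytest.approx(
            ref.p_interaction, abs=1e-10
        )
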