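"""QC, TMM, filtering, BH and moderated-DE behavior against hand oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import oracles
from comorbnet.datatypes import AnalysisError, ExpressionMatrix, SampleTable
from comorbnet.expression import (
    bh_fdr,
    fit_de,
    fit_fdist_moments,
    log2cpm,
    normalize,
    qc_filter,
    remove_batch,
    tmm_factors,
    trigamma_inverse,
)
from comorbnet.synthetic import CohortConfig, DiseaseSpec, simulate_cohort

from conftest import small_table


def _expr_from_counts(counts: pd.DataFrame, condition, study=None) -> ExpressionMatrix:
    n = counts.shape[1]
    md = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "disease": "d",
            "study": study if study is not None else ["st1"] * n,
            "tissue": "t",
            "condition": condition,
            "percent_aligned": 99.0,
        }
    )
    f = tmm_factors(counts)
    return ExpressionMatrix(
        values=log2cpm(counts, f),
        norm_factors=f,
        lib_sizes=counts.sum(),
        metadata=md,
    )


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([], []),
        ],
    )
    def test_known_values(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_and_invariants(self, p):
        q = bh_fdr(p)
        assert q == pytest.approx(oracles.bh_brute(p), abs=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert q == pytest.approx(q_sm, abs=1e-12)


class TestQC:
    def test_low_alignment_sample_removed(self):
        t = small_table(cases=5, controls=5, seed=1)
        md = t.metadata.copy()
        md["percent_aligned"] = 99.0
        md.loc[0, "percent_aligned"] = 65.0
        out = qc_filter(SampleTable(counts=t.counts, metadata=md))
        assert md.loc[0, "sample_id"] not in set(out.metadata["sample_id"])
        assert out.n_samples == t.n_samples - 1

    def test_study_below_min_cases_removed_entirely(self):
        t = small_table(cases=4, controls=4, seed=2)
        md = t.metadata.copy()
        md["percent_aligned"] = 99.0
        case_ids = md.index[md["condition"] == "case"][:2]
        md.loc[case_ids, "percent_aligned"] = 50.0  # leaves 2 cases
        with pytest.raises(AnalysisError):
            qc_filter(SampleTable(counts=t.counts, metadata=md))

    def test_clean_table_unchanged(self):
        t = small_table(cases=5, controls=5, seed=3)
        md = t.metadata.copy()
        md["percent_aligned"] = 100.0
        t2 = SampleTable(counts=t.counts, metadata=md)
        out = qc_filter(t2)
        pd.testing.assert_frame_equal(out.counts, t2.counts)

    def test_all_removed_is_error(self):
        t = small_table(seed=4)
        md = t.metadata.copy()
        md["percent_aligned"] = 10.0
        with pytest.raises(AnalysisError, match="no analyzable"):
            qc_filter(SampleTable(counts=t.counts, metadata=md))


class TestTMM:
    def test_identical_columns_unit_factors(self):
        col = np.array([10, 50, 200, 5, 80, 40, 33, 12, 900, 60])
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert tmm_factors(counts).to_numpy() == pytest.approx(np.ones(4))

    def test_pure_depth_difference_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.integers(5, 500, 50)
        counts = pd.DataFrame({"a": col, "b": 2 * col, "c": col})
        assert tmm_factors(counts).to_numpy() == pytest.approx(np.ones(3))

    def test_toy_matches_brute_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.integers(1, 400, size=(20, 3))
        x[0, 1] *= 25  # one inflated gene in sample 1
        counts = pd.DataFrame(x, columns=["a", "b", "c"])
        f = tmm_factors(counts)
        lib = x.sum(axis=0)
        q75 = np.quantile(x / lib, 0.75, axis=0)
        ref = int(np.argmin(np.abs(q75 - q75.mean())))
        raw = np.array([oracles.tmm_brute(x, j, ref) for j in range(3)])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert f.to_numpy() == pytest.approx(expected, abs=1e-9)

    def test_logfc_invariant_to_depth_scaling(self):
        """Depth changes are absorbed by effective library sizes.

        Scaling every sample by the same constant leaves M-values, trimming,
        weights and the CPM prior untouched, so logFC is exactly invariant.
        Scaling a single sample additionally perturbs that sample's
        precision weights (they scale by 1/s while the reference's do not),
        so its TMM factor — and hence logFC — may move by a small
        weight-reweighting term only.
        """
        t = small_table(n_genes=120, cases=5, controls=5, seed=5)
        counts = t.counts
        cond = t.metadata["condition"]
        expr1 = _expr_from_counts(counts, cond)
        p1 = fit_de(expr1, "d")

        global_scaled = counts * 3
        p_global = fit_de(_expr_from_counts(global_scaled, cond), "d")
        assert np.abs(p1.table["logFC"] - p_global.table["logFC"]).max() < 1e-9

        one_scaled = counts.copy()
        one_scaled.iloc[:, 0] = one_scaled.iloc[:, 0] * 4
        expr2 = _expr_from_counts(one_scaled, cond)
        assert expr2.lib_sizes.iloc[0] == 4 * expr1.lib_sizes.iloc[0]
        p2 = fit_de(expr2, "d")
        assert np.abs(p1.table["logFC"] - p2.table["logFC"]).max() < 5e-3


class TestNormalize:
    def _table_with_low_gene(self, frac_low: float, seed=0):
        rng = np.random.default_rng(seed)
        n = 20
        # libraries of ~1M reads so 1 log2CPM ~ 2 counts
        x = rng.integers(2000, 3000, size=(400, n))
        n_low = int(round(frac_low * n))
        # gene 0: below 1 log2CPM in n_low samples, high elsewhere
        x[0, :n_low] = 0
        x[0, n_low:] = 2500
        counts = pd.DataFrame(x, index=[f"g{i}" for i in range(400)],
                              columns=[f"s{j}" for j in range(n)])
        md = pd.DataFrame({
            "sample_id": counts.columns, "disease": "d", "study": "st1",
            "tissue": "t", "condition": ["case"] * 10 + ["control"] * 10,
            "percent_aligned": 99.0,
        })
        return SampleTable(counts=counts, metadata=md)

    def test_gene_low_in_25pct_removed(self):
        expr = normalize(self._table_with_low_gene(0.25))
        assert "g0" not in expr.values.index

    def test_gene_low_in_exactly_20pct_retained(self):
        expr = normalize(self._table_with_low_gene(0.20))
        assert "g0" in expr.values.index

    def test_constant_counts_all_equal_no_filtering(self):
        counts = pd.DataFrame(np.full((12, 6), 300),
                              index=[f"g{i}" for i in range(12)],
                              columns=[f"s{j}" for j in range(6)])
        md = pd.DataFrame({
            "sample_id": counts.columns, "disease": "d", "study": "st1",
            "tissue": "t", "condition": ["case"] * 3 + ["control"] * 3,
            "percent_aligned": 99.0,
        })
        expr = normalize(SampleTable(counts=counts, metadata=md))
        assert expr.values.shape[0] == 12
        assert np.allclose(expr.values.to_numpy(), expr.values.to_numpy()[0, 0])

    def test_norm_factors_geometric_mean_one(self):
        t = small_table(n_genes=100, cases=5, controls=5, seed=6)
        expr = normalize(t)
        assert np.exp(np.mean(np.log(expr.norm_factors))) == pytest.approx(1.0)


class TestEBayes:
    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for y in [1e-7, 0.01, 0.5, 2.0, 50.0, 1e8]:
            x = trigamma_inverse(y)
            assert float(polygamma(1, x)) == pytest.approx(y, rel=1e-4)

    def test_moment_recovery_of_prior(self):
        """s2 ~ s02 * F(d, d0): estimates recover (d0=4, s02=2)."""
        rng = np.random.default_rng(11)
        d, d0, s02 = 10, 4.0, 2.0
        d0_hats, s02_hats = [], []
        for _ in range(10):
            s2 = s02 * stats.f.rvs(d, d0, size=2000, random_state=rng)
            d0_hat, s02_hat = fit_fdist_moments(s2, d)
            d0_hats.append(d0_hat)
            s02_hats.append(s02_hat)
        assert np.mean(d0_hats) == pytest.approx(d0, abs=1.0)
        assert np.mean(s02_hats) == pytest.approx(s02, rel=0.10)

    def test_equal_variances_give_infinite_prior_df(self):
        """Observed log-variance spread below chi-square spread: d0 = inf."""
        from scipy.special import psi

        s2 = np.full(500, 3.0)
        d0, s02 = fit_fdist_moments(s2, 8)
        assert np.isinf(d0)
        assert s02 == pytest.approx(np.exp(np.log(3.0) - psi(4) + np.log(4)))

    def test_posterior_variance_limits(self):
        """Large d0 squeezes every gene to s02; d0=0 reduces to raw s2."""
        s2 = np.array([0.5, 1.0, 4.0])
        d = 6.0
        s02 = 2.0
        strong = (1e9 * s02 + d * s2) / (1e9 + d)
        assert strong == pytest.approx(np.full(3, s02), rel=1e-6)
        none = (0 * s02 + d * s2) / (0 + d)
        assert none == pytest.approx(s2)


class TestFitDE:
    def test_matches_manual_ols_and_moderation(self):
        t = small_table(n_genes=80, cases=6, controls=6, seed=8)
        expr = normalize(t)
        prof = fit_de(expr, "dx")
        # manual re-derivation gene by gene
        y = expr.values.to_numpy().T
        cond = (expr.metadata["condition"] == "case").to_numpy(float)
        X = np.column_stack([np.ones(len(cond)), cond])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        d = len(cond) - 2
        s2 = (resid**2).sum(axis=0) / d
        d0, s02 = fit_fdist_moments(s2, d)
        s2p = (d0 * s02 + d * s2) / (d0 + d)
        v = np.linalg.inv(X.T @ X)[1, 1]
        t_mod = beta[1] / np.sqrt(s2p * v)
        assert prof.table["logFC"].to_numpy() == pytest.approx(beta[1], abs=1e-10)
        assert prof.table["t"].to_numpy() == pytest.approx(t_mod, abs=1e-10)
        p_expect = 2 * stats.t.sf(np.abs(t_mod), d0 + d)
        assert prof.table["pvalue"].to_numpy() == pytest.approx(p_expect, abs=1e-12)
        assert (prof.table["sdeg"] == (prof.table["fdr"] <= 0.05)).all()

    def test_study_covariate_adjustment(self):
        """A study-confounded offset shifts unadjusted logFC but not adjusted."""
        t = small_table(n_genes=100, cases=6, controls=6, n_studies=2,
                        seed=9)
        expr = normalize(t)
        prof = fit_de(expr, "dx", covariates=("study",))
        assert prof.df_residual == len(expr.metadata) - 3

    def test_confounded_design_errors(self):
        t = small_table(n_genes=50, cases=4, controls=4, seed=10)
        md = t.metadata.copy()
        md["study"] = np.where(md["condition"] == "case", "stA", "stB")
        expr = normalize(SampleTable(counts=t.counts, metadata=md))
        with pytest.raises(AnalysisError, match="aliased"):
            fit_de(expr, "dx")

    def test_single_study_covariate_dropped(self):
        t = small_table(n_genes=50, cases=4, controls=4, seed=10)
        expr = normalize(t)
        prof = fit_de(expr, "dx")  # study has one level: silently dropped
        assert prof.df_residual == len(expr.metadata) - 2


class TestRemoveBatch:
    def test_single_batch_identity(self):
        t = small_table(n_genes=60, cases=4, controls=4, seed=11)
        expr = normalize(t)
        out = remove_batch(expr)
        pd.testing.assert_frame_equal(out.values, expr.values)

    def test_constant_offset_removed_exactly(self):
        t = small_table(n_genes=60, cases=4, controls=4, n_studies=2, seed=12)
        expr = normalize(t)
        # overwrite with a synthetic additive batch shift, no condition effect
        rng = np.random.default_rng(0)
        base = rng.normal(5, 1, size=(len(expr.values.index), 1))
        vals = np.tile(base, (1, len(expr.metadata)))
        shift = (expr.metadata["study"] == sorted(expr.metadata["study"].unique())[1]).to_numpy(float)
        vals = vals + 2.5 * shift[None, :]
        expr2 = ExpressionMatrix(
            values=pd.DataFrame(vals, index=expr.values.index, columns=expr.values.columns),
            norm_factors=expr.norm_factors, lib_sizes=expr.lib_sizes,
            metadata=expr.metadata,
        )
        out = remove_batch(expr2)
        by_batch = out.values.T.groupby(out.metadata.set_index("sample_id")["study"]).mean()
        diff = np.abs(by_batch.iloc[0] - by_batch.iloc[1])
        assert diff.max() < 1e-10

    def test_planted_batch_variance_shrinks(self):
        cfg = CohortConfig(
            n_genes=300,
            diseases=[DiseaseSpec(name="d", icd9="001", n_studies=3,
                                  cases_per_study=6, controls_per_study=6)],
            batch_sd=1.0,
            seed=13,
        )
        t = simulate_cohort(cfg)
        expr = normalize(t)
        out = remove_batch(expr)

        def between_frac(e):
            v = e.values.T
            g = v.groupby(e.metadata.set_index("sample_id")["study"]).mean()
            between = g.var(axis=0, ddof=1).mean()
            total = v.var(axis=0, ddof=1).mean()
            return between / total

        assert between_frac(out) < 0.05 * between_frac(expr)
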