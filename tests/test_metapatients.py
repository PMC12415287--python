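"""Stratification: distances, PAM, Ward2, silhouette selection, SSN."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

import oracles
from comorbnet.datatypes import AnalysisError, ExpressionMatrix
from comorbnet.dsn import build_network
from comorbnet.metapatients import (
    build_ssn,
    correlation_distance,
    meta_patient_de,
    pam_cluster,
    random_metapatient_null,
    select_k,
    ward2_cluster,
    ward2_linkage,
)
from comorbnet.expression import fit_de, normalize
from comorbnet.pipeline import disease_expression, disease_profiles, stratified_network
from comorbnet.synthetic import simulate_cohort, subtype_config

from conftest import small_table


def expr_from_values(values: pd.DataFrame, condition=None, study=None) -> ExpressionMatrix:
    n = values.shape[1]
    md = pd.DataFrame(
        {
            "sample_id": values.columns,
            "disease": "d",
            "study": study if study is not None else ["st1"] * n,
            "tissue": "t",
            "condition": condition if condition is not None else ["case"] * n,
            "percent_aligned": 99.0,
        }
    )
    ones = pd.Series(1.0, index=values.columns)
    return ExpressionMatrix(values=values, norm_factors=ones,
                            lib_sizes=ones.astype(int) * 1000, metadata=md)


def blob_distance(sizes, within=0.05, between=1.2, seed=0):
    """Synthetic distance matrix with well-separated blobs."""
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                d[i, j] = 0.0
            elif labels[i] == labels[j]:
                d[i, j] = within * (1 + 0.5 * rng.random())
            else:
                d[i, j] = between * (1 + 0.2 * rng.random())
    d = (d + d.T) / 2
    ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame(d, index=ids, columns=ids), labels


class TestCorrelationDistance:
    def test_duplicate_sample_distance_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        vals = pd.DataFrame(
            {"a": base, "b": base, "c": rng.normal(size=30), "d": rng.normal(size=30)}
        )
        d = correlation_distance(expr_from_values(vals))
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_ranks_distance_two(self):
        base = np.arange(30, dtype=float)
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(
            {"a": base, "b": -base, "c": rng.normal(size=30), "d": rng.normal(size=30)}
        )
        d = correlation_distance(expr_from_values(vals))
        assert d.loc["a", "b"] == pytest.approx(2.0)

    def test_matches_brute_force_entries(self):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("abcde"))
        d = correlation_distance(expr_from_values(vals))
        for i in "abcde":
            for j in "abcde":
                expected = 0.0 if i == j else 1 - oracles.spearman_brute(vals[i], vals[j])
                assert d.loc[i, j] == pytest.approx(expected, abs=1e-9)

    def test_constant_sample_errors_with_name(self):
        vals = pd.DataFrame(
            {"a": np.ones(20), "b": np.arange(20.0), "c": np.arange(20.0)[::-1],
             "d": np.random.default_rng(3).normal(size=20)}
        )
        with pytest.raises(AnalysisError, match="a"):
            correlation_distance(expr_from_values(vals))


class TestPAM:
    def test_two_blobs_recovered_exactly(self):
        d, truth = blob_distance([6, 6], seed=4)
        labels, _ = pam_cluster(d, 2)
        # same partition up to label swap
        assert len(set(zip(truth, labels))) == 2

    def test_two_points_k2_singletons(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        labels, medoids = pam_cluster(d, 2)
        assert sorted(labels) == [1, 2]
        assert sorted(medoids) == ["a", "b"]

    def test_objective_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 3))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        dd = pd.DataFrame(d, index=[f"p{i}" for i in range(6)],
                          columns=[f"p{i}" for i in range(6)])
        labels, medoids = pam_cluster(dd, 2)
        med_idx = [list(dd.index).index(m) for m in medoids]
        cost = d[:, med_idx].min(axis=1).sum()
        assert cost == pytest.approx(oracles.pam_exhaustive_cost(d, 2), abs=1e-9)

    def test_k_out_of_range_errors(self):
        d, _ = blob_distance([3, 3])
        with pytest.raises(AnalysisError):
            pam_cluster(d, 7)
        with pytest.raises(AnalysisError):
            pam_cluster(d, 0)


class TestWard2:
    def test_two_blobs_recovered(self):
        d, truth = blob_distance([5, 7], seed=6)
        labels = ward2_cluster(d, 2)
        assert len(set(zip(truth, labels))) == 2

    def test_k_equals_n_singletons(self):
        d, _ = blob_distance([2, 3], seed=7)
        labels = ward2_cluster(d, 5)
        assert sorted(labels) == [1, 2, 3, 4, 5]

    def test_merge_heights_match_lance_williams_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(5, 4))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        dd = pd.DataFrame(d, index=[f"p{i}" for i in range(5)],
                          columns=[f"p{i}" for i in range(5)])
        z = ward2_linkage(dd)
        expected = oracles.ward2_merge_heights(d)
        assert z[:, 2] == pytest.approx(expected, abs=1e-9)


class TestSelectK:
    def test_three_blobs_chooses_three(self):
        d, _ = blob_distance([6, 6, 6], seed=9)
        a = select_k(d, method="pam", disease="toy")
        assert a.chosen_k == 3
        assert a.silhouette_by_k[3] > 0.8
        assert not a.low_confidence

    def test_silhouette_matches_brute_definition(self):
        d, _ = blob_distance([4, 4], seed=10)
        a = select_k(d, method="pam", disease="toy", min_cluster_size=2)
        s_brute = oracles.silhouette_brute(d.to_numpy(), a.labels.to_numpy())
        assert a.silhouette_samples.to_numpy() == pytest.approx(s_brute, abs=1e-9)

    def test_equidistant_point_has_zero_silhouette(self):
        # point p4 at distance 1 from everything; two tight pairs
        ids = ["a1", "a2", "b1", "b2", "p4"]
        d = np.full((5, 5), 1.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        dd = pd.DataFrame(d, index=ids, columns=ids)
        labels = [1, 1, 2, 2, 1]
        s = oracles.silhouette_brute(d, labels)
        from sklearn.metrics import silhouette_samples

        sk = silhouette_samples(d, np.array(labels), metric="precomputed")
        assert sk == pytest.approx(s, abs=1e-12)
        assert sk[4] == pytest.approx((1 - 1) / 1, abs=1e-12)

    def test_homogeneous_cloud_flagged_low_confidence(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(10, 24))
        vals = pd.DataFrame(x, columns=[f"s{i}" for i in range(24)])
        d = correlation_distance(expr_from_values(vals))
        a = select_k(d, method="pam", disease="toy")
        assert a.chosen_k >= 2
        assert a.low_confidence

    def test_too_few_cases_unstratified(self):
        d, _ = blob_distance([2, 3], seed=12)
        a = select_k(d, method="pam", disease="toy")
        assert a.unstratified and a.chosen_k == 1

    def test_deterministic_given_distance(self):
        d, _ = blob_distance([5, 5, 5], seed=13)
        a1 = select_k(d, method="pam", disease="toy")
        a2 = select_k(d, method="pam", disease="toy")
        assert a1.chosen_k == a2.chosen_k
        pd.testing.assert_series_equal(a1.labels, a2.labels)


class TestMetaPatientDE:
    def _disease_expr(self, seed=0, n_studies=1, cases=10, controls=8):
        t = small_table(n_genes=150, cases=cases, controls=controls,
                        n_studies=n_studies, seed=seed)
        return normalize(t)

    def test_k1_identical_to_disease_profile(self):
        from comorbnet.datatypes import MetaPatientAssignment

        expr = self._disease_expr(seed=1)
        md = expr.metadata
        cases = list(md.loc[md["condition"] == "case", "sample_id"])
        a = MetaPatientAssignment(
            disease="dx", method="pam", chosen_k=1,
            labels=pd.Series(1, index=cases), unstratified=True,
        )
        mp = meta_patient_de(expr, a)
        disease = fit_de(expr, "dx", family="dx")
        assert len(mp) == 1
        pd.testing.assert_frame_equal(mp[0].table, disease.table)
        assert mp[0].d0 == disease.d0

    def test_all_cases_cluster_equals_disease(self):
        from comorbnet.datatypes import MetaPatientAssignment

        expr = self._disease_expr(seed=2)
        md = expr.metadata
        cases = list(md.loc[md["condition"] == "case", "sample_id"])
        a = MetaPatientAssignment(
            disease="dx", method="pam", chosen_k=1,
            labels=pd.Series(1, index=cases), unstratified=False,
        )
        mp = meta_patient_de(expr, a)[0]
        disease = fit_de(expr, "dx")
        assert mp.table["logFC"].to_numpy() == pytest.approx(
            disease.table["logFC"].to_numpy(), abs=0,
        )

    def test_disease_logfc_is_size_weighted_mean_of_clusters(self):
        """Single-study design: pooled logFC = sum (n_c/n) * cluster logFC."""
        from comorbnet.datatypes import MetaPatientAssignment

        expr = self._disease_expr(seed=3, cases=9)
        md = expr.metadata
        cases = list(md.loc[md["condition"] == "case", "sample_id"])
        labels = pd.Series([1] * 4 + [2] * 5, index=cases)
        a = MetaPatientAssignment(disease="dx", method="pam", chosen_k=2, labels=labels)
        mps = meta_patient_de(expr, a)
        disease = fit_de(expr, "dx")
        combo = (4 * mps[0].table["logFC"] + 5 * mps[1].table["logFC"]) / 9
        assert np.abs(disease.table["logFC"] - combo).max() < 1e-6

    def test_opposite_subtypes_have_opposite_module_logfc(self):
        cfg = subtype_config(seed=5)
        table = simulate_cohort(cfg)
        expr = disease_expression(table)
        ssn, assignments, mps = stratified_network(expr, disease_profiles(expr))
        fam = [p for p in mps if p.family == "D00"]
        assert len(fam) == 2
        module_genes = [g for g in table.truth["modules"]["Mshared"]
                        if g in fam[0].table.index]
        lf0 = fam[0].table.loc[module_genes, "logFC"]
        lf1 = fam[1].table.loc[module_genes, "logFC"]
        # the two meta-patients disagree in sign on nearly all module genes
        assert (np.sign(lf0) != np.sign(lf1)).mean() > 0.9


class TestSSN:
    def test_no_stratification_equals_dsn(self, null_cohort_small):
        _, table = null_cohort_small
        expr = disease_expression(table)
        profiles = disease_profiles(expr)
        dsn = build_network(profiles)
        ssn = build_ssn(profiles, [])
        pd.testing.assert_frame_equal(dsn.edges, ssn.edges)

    def test_node_count_conservation(self):
        cfg = subtype_config(seed=6)
        table = simulate_cohort(cfg)
        expr = disease_expression(table)
        profiles = disease_profiles(expr)
        ssn, assignments, mps = stratified_network(expr, profiles)
        expected = len(profiles) + sum(
            a.chosen_k for a in assignments.values() if not a.unstratified
        )
        assert len(ssn.nodes) == expected

    def test_self_family_pairs_never_linked(self):
        cfg = subtype_config(seed=7)
        table = simulate_cohort(cfg)
        expr = disease_expression(table)
        profiles = disease_profiles(expr)
        ssn, assignments, mps = stratified_network(expr, profiles)
        fams = {
            r.id: (r.family if r.family is not None else r.id)
            for r in ssn.nodes.itertuples()
        }
        for row in ssn.edges.itertuples():
            assert fams[row.node_a] != fams[row.node_b]

    def test_random_null_preserves_cluster_sizes_and_floor(self):
        cfg = subtype_config(seed=8)
        table = simulate_cohort(cfg)
        expr = disease_expression(table)
        profiles = disease_profiles(expr)
        ssn, assignments, mps = stratified_network(expr, profiles)
        res = random_metapatient_null(
            expr, assignments, profiles, n_reps=20, seed=3, observed_ssn=ssn,
        )
        assert res["p_positive"] >= 1.0 / 21
        assert res["replicate_positive"].shape == (20,)
        with pytest.raises(AnalysisError):
            random_metapatient_null(expr, assignments, profiles, n_reps=0, seed=1)
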