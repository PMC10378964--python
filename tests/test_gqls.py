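"""Quasi-likelihood score test and chromosome-wise q-values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from spastigen.gqls import (CohortError, assign_tiers, chromosome_pfdr,
                            gqls_test, manhattan_table, qvalues, run_gwas,
                            storey_pi0)
from spastigen.io import GenotypeMatrix, MarkerMap, MISSING
from spastigen.kinship import AdditiveRelationship


def gls_score_oracle(y, x, K):
    """Dense generalized-least-squares score statistic, from first principles."""
    n = len(y)
    one = np.ones(n)
    Ki = np.linalg.inv(K)
    mu0 = (one @ Ki @ y) / (one @ Ki @ one)
    v = mu0 * (1 - mu0) / 2.0
    U = x @ Ki @ (y - mu0 * one)
    varU = v * (x @ Ki @ x - (x @ Ki @ one) ** 2 / (one @ Ki @ one))
    return U * U / varU


def make_matrix(dosage, chrom=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    chrom = chrom if chrom is not None else [1] * m
    pos = (np.concatenate(
        [np.arange(1, (np.array(chrom) == c).sum() + 1) * 1000
         for c in pd.unique(pd.Series(chrom))])
        if m else np.array([], dtype=int))
    mm = MarkerMap(pd.DataFrame({
        "snp_id": [f"S{j}" for j in range(m)], "chromosome": chrom,
        "position_bp": pos,
        "allele_a": ["A"] * m, "allele_b": ["G"] * m}))
    return GenotypeMatrix([f"A{i}" for i in range(n)], mm, dosage)


class TestScoreTest:
    def test_worked_example_t_equals_12(self):
        y = np.array([1.0, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1, 1, 0, 0, 0])
        T, p = gqls_test(y, x)
        assert T == pytest.approx(12.0)

    def test_monomorphic_snp_flagged(self):
        T, p = gqls_test(np.full(6, 0.5), np.array([1, 1, 1, 0, 0, 0]))
        assert np.isnan(T) and p == 1.0

    def test_single_phenotype_class_rejected(self):
        with pytest.raises(CohortError):
            gqls_test(np.array([0.0, 0.5, 1.0]), np.array([1, 1, 1]))

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.binomial(2, 0.3, 40) / 2.0
            x = (rng.random(40) < 0.5).astype(float)
            if len(np.unique(y)) < 2 or len(np.unique(x)) < 2:
                continue
            T1, _ = gqls_test(y, x)
            T2, _ = gqls_test(1.0 - y, x)
            assert T1 == pytest.approx(T2, abs=1e-10)

    def test_matches_gls_oracle_identity_and_random_psd_kinship(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 50:
            n = int(rng.integers(10, 40))
            y = rng.binomial(2, rng.uniform(0.2, 0.8), n) / 2.0
            x = (rng.random(n) < 0.5).astype(float)
            if len(np.unique(y)) < 2 or len(np.unique(x)) < 2:
                continue
            B = rng.normal(size=(n, n))
            for K in (np.eye(n), B @ B.T / n + np.eye(n)):
                T, _ = gqls_test(y, x, K)
                assert T == pytest.approx(gls_score_oracle(y, x, K),
                                          abs=1e-10)
            checked += 1

    def test_missing_dropped_pairwise(self):
        y = np.array([1.0, 1, 1, np.nan, 0, 0, 0])
        x = np.array([1.0, 1, 1, 1, 0, 0, 0])
        T, _ = gqls_test(y, x)
        assert T == pytest.approx(12.0)


class TestRunGwas:
    def test_planted_signal_detected(self):
        rng = np.random.default_rng(10)
        n, m = 120, 60
        d = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m))
        x = rng.integers(0, 2, n)
        d[:, 7] = np.clip(x * 2 + rng.integers(0, 2, n) - 0, 0, 2)
        g = make_matrix(d)
        status = pd.DataFrame({"animal": g.animal_ids, "status": x})
        res = run_gwas(g, status)
        assert res.loc[7, "p_value"] == res["p_value"].min()
        assert res.loc[7, "p_value"] < 1e-4

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(0)
        n, m = 200, 800
        d = rng.binomial(2, rng.uniform(0.15, 0.85, m),
                         size=(n, m)).astype(np.int8)
        g = make_matrix(d)
        status = pd.DataFrame({"animal": g.animal_ids,
                               "status": rng.permutation([0, 1] * 100)})
        res = run_gwas(g, status)
        p = res.loc[~res["monomorphic"], "p_value"]
        assert kstest(p, "uniform").pvalue > 0.01

    def test_kinship_matrix_used(self, small_cohort):
        from spastigen.kinship import build_A
        ids = small_cohort.phenotypes.animal_ids[:80]
        g = small_cohort.genotypes.subset(animal_ids=ids,
                                          snp_mask=np.arange(30))
        status = pd.DataFrame(
            {"animal": ids,
             "status": small_cohort.phenotypes.status[:80]})
        K = build_A(small_cohort.pedigree).submatrix(ids)
        res_k = run_gwas(g, status, K)
        res_i = run_gwas(g, status)
        assert not np.allclose(res_k["T"].to_numpy(dtype=float),
                               res_i["T"].to_numpy(dtype=float),
                               equal_nan=True)

    def test_id_mismatch_raises(self):
        g = make_matrix([[0, 1], [1, 2]])
        status = pd.DataFrame({"animal": ["A0", "ZZ"], "status": [0, 1]})
        with pytest.raises(CohortError, match="ZZ"):
            run_gwas(g, status)

    def test_no_snps_warns_and_returns_empty(self):
        g = make_matrix(np.zeros((4, 0), dtype=np.int8))
        status = pd.DataFrame({"animal": [f"A{i}" for i in range(4)],
                               "status": [0, 1, 0, 1]})
        with pytest.warns(UserWarning, match="no SNPs"):
            res = run_gwas(g, status)
        assert res.empty


class TestQValues:
    def test_bh_hand_example_with_pi0_one(self):
        q = qvalues(np.array([0.001, 0.02, 0.03, 0.8]), pi0=1.0)
        np.testing.assert_allclose(q, [0.004, 0.04, 0.04, 0.8])

    def test_all_ones_stay_ones(self):
        rec = pd.DataFrame({"chromosome": [1] * 4, "p_value": [1.0] * 4})
        out = chromosome_pfdr(rec)
        assert (out["q_value"] == 1.0).all()
        assert (out["pfdr_tier"] == "ns").all()

    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_p(self, ps):
        p = np.array(ps)
        q = qvalues(p, pi0=1.0)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_q_equals_bh_when_pi0_one_and_below_max_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        q = qvalues(p, pi0=1.0)
        assert (q <= p.max() + 1e-12).all()
        # BH reference via statsmodels
        from statsmodels.stats.multitest import multipletests
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_small_chromosome_falls_back_to_pi0_one(self):
        p = np.array([0.2, 0.5, 0.9])
        assert storey_pi0(p) == 1.0

    def test_tiers_match_cutoffs(self):
        q = np.array([0.005, 0.03, 0.08, 0.5])
        assert assign_tiers(q).tolist() == ["0.01", "0.05", "0.1", "ns"]

    def test_chromosome_wise_independence(self):
        rec = pd.DataFrame({
            "chromosome": [1] * 3 + [2] * 3,
            "p_value": [0.001, 0.5, 0.9, 0.001, 0.5, 0.9]})
        out = chromosome_pfdr(rec)
        q1 = out.loc[out["chromosome"] == 1, "q_value"].to_numpy()
        q2 = out.loc[out["chromosome"] == 2, "q_value"].to_numpy()
        np.testing.assert_allclose(q1, q2)


class TestManhattan:
    def test_neglog_q_truncated_at_six(self):
        rec = pd.DataFrame({"chromosome": [1, 1], "position_bp": [1, 2],
                            "snp_id": ["a", "b"],
                            "q_value": [1e-9, 0.5]})
        t = manhattan_table(rec)
        assert t["neg_log10_q"].iloc[0] == 6.0
        assert bool(t["exceeds_cap"].iloc[0])
        assert not bool(t["exceeds_cap"].iloc[1])
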