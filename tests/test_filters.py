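"""Post-GWAS cascade: MAF, genotype chi-square, homozygotic polarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from spastigen.filters import (apply_cascade, chisq_genotype_test,
                               compute_maf, polarity_score)
from spastigen.gqls import CohortError
from spastigen.io import MISSING
from test_gqls import make_matrix


def chi2_oracle(table):
    """Expected-count chi-square computed from scratch."""
    table = np.asarray(table, dtype=float)
    exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
    return float(((table - exp) ** 2 / exp).sum())


class TestMaf:
    @pytest.mark.parametrize("dosages,expected", [
        ([0, 0, 1, 2], 0.375), ([1, 1, 1, 1], 0.5), ([2, 2, 2], 0.0)])
    def test_hand_values(self, dosages, expected):
        assert compute_maf(np.array(dosages, dtype=np.int8)) == expected

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            compute_maf(np.array([MISSING, MISSING], dtype=np.int8))


class TestChiSquare:
    def test_identical_distributions_give_p_one(self):
        col = np.concatenate([np.repeat([0, 1, 2], [25, 50, 25])] * 2
                             ).astype(np.int8)
        status = np.array([1] * 100 + [0] * 100)
        stat, p, dof = chisq_genotype_test(col, status)
        assert stat == 0.0 and p == 1.0

    def test_polarised_2x3_table(self):
        col = np.concatenate([np.repeat([0, 1, 2], [30, 10, 0]),
                              np.repeat([0, 1, 2], [0, 10, 30])]
                             ).astype(np.int8)
        status = np.array([1] * 40 + [0] * 40)
        stat, p, dof = chisq_genotype_test(col, status)
        assert stat == pytest.approx(60.0)
        assert dof == 2

    def test_single_phenotype_class_rejected(self):
        with pytest.raises(CohortError):
            chisq_genotype_test(np.array([0, 1, 2], dtype=np.int8),
                                np.array([1, 1, 1]))

    def test_single_genotype_class_gives_p_one(self):
        stat, p, dof = chisq_genotype_test(
            np.ones(20, dtype=np.int8), np.array([0, 1] * 10))
        assert p == 1.0 and dof == 0

    def test_matches_from_scratch_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            counts = rng.integers(5, 40, size=(2, 3))
            col = np.concatenate([
                np.repeat([0, 1, 2], counts[0]),
                np.repeat([0, 1, 2], counts[1])]).astype(np.int8)
            status = np.array([1] * counts[0].sum()
                              + [0] * counts[1].sum())
            stat, p, dof = chisq_genotype_test(col, status)
            assert stat == pytest.approx(chi2_oracle(counts), abs=1e-10)
            assert p == pytest.approx(chi2.sf(stat, dof), abs=1e-12)


class TestPolarity:
    def test_worked_example_score_one(self):
        col = np.concatenate([np.repeat([0, 1, 2], [40, 10, 0]),
                              np.repeat([0, 1, 2], [10, 20, 20])]
                             ).astype(np.int8)
        status = np.array([1] * 50 + [0] * 50)
        assert polarity_score(col, status) == pytest.approx(1.0)

    def test_identical_distributions_score_zero(self):
        col = np.concatenate([np.repeat([0, 1, 2], [10, 20, 10])] * 2
                             ).astype(np.int8)
        status = np.array([1] * 40 + [0] * 40)
        assert polarity_score(col, status) == 0.0

    def test_missing_homozygote_class_is_na(self):
        # no dosage-2 genotype anywhere in the cohort
        col = np.array([0, 0, 1, 1, 0, 1, 1, 0], dtype=np.int8)
        status = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        assert np.isnan(polarity_score(col, status))

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(1, 30),
           st.integers(0, 30), st.integers(0, 30), st.integers(1, 30))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_swap_symmetric(self, a0, a1, a2, b0, b1, b2):
        col = np.concatenate([np.repeat([0, 1, 2], [a0, a1, a2]),
                              np.repeat([0, 1, 2], [b0, b1, b2])]
                             ).astype(np.int8)
        status = np.array([1] * (a0 + a1 + a2) + [0] * (b0 + b1 + b2))
        s = polarity_score(col, status)
        if not np.isnan(s):
            assert 0.0 <= s <= 2.0
            flipped = (2 - col).astype(np.int8)
            assert polarity_score(flipped, status) == pytest.approx(s)


class TestCascade:
    def _records(self, g):
        df = g.marker_map.df
        return pd.DataFrame({"snp_id": df["snp_id"],
                             "chromosome": df["chromosome"],
                             "pfdr_tier": "0.1"})

    def test_empty_input_gives_zero_report(self):
        g = make_matrix([[0, 1], [1, 2]])
        status = pd.DataFrame({"animal": g.animal_ids, "status": [0, 1]})
        rep = apply_cascade(pd.DataFrame(columns=["snp_id", "chromosome",
                                                  "pfdr_tier"]),
                            g, status)
        assert rep.survivors == [0, 0, 0, 0]

    def test_survivors_non_increasing(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(80, 40)).astype(np.int8)
        g = make_matrix(d)
        status = pd.DataFrame({"animal": g.animal_ids,
                               "status": rng.integers(0, 2, 80)})
        rep = apply_cascade(self._records(g), g, status)
        assert all(a >= b for a, b in zip(rep.survivors, rep.survivors[1:]))
        per_chrom = rep.per_chromosome
        for _, row in per_chrom.iterrows():
            assert row["pfdr_10pct"] >= row["maf"] >= row["chi_square"] \
                >= row["polarity"]

    def test_noop_thresholds_pass_all_defined_scores(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(60, 25)).astype(np.int8)
        g = make_matrix(d)
        status = pd.DataFrame({"animal": g.animal_ids,
                               "status": rng.integers(0, 2, 60)})
        rep = apply_cascade(self._records(g), g, status, maf_min=0.0,
                            chi2_alpha=1.0, polarity_min=0.0)
        defined = ~rep.per_snp["polarity"].isna()
        assert rep.per_snp.loc[defined, "pass_polarity"].all()

    def test_na_polarity_never_passes(self):
        d = np.array([[0, 0], [1, 0], [1, 1], [0, 1]] * 10,
                     dtype=np.int8)  # SNP0 lacks dosage-2 entirely
        g = make_matrix(d)
        status = pd.DataFrame({"animal": g.animal_ids,
                               "status": [0, 1] * 20})
        rep = apply_cascade(self._records(g), g, status, maf_min=0.0,
                            chi2_alpha=1.0, polarity_min=0.0)
        row = rep.per_snp.set_index("snp_id").loc["S0"]
        assert np.isnan(row["polarity"]) and not row["pass_polarity"]

    def test_planted_polarised_qtl_survives(self):
        rng = np.random.default_rng(3)
        wins = 0
        for rep_i in range(10):
            n = 100
            x = np.array([1] * 50 + [0] * 50)
            d = rng.integers(0, 3, size=(n, 20)).astype(np.int8)
            # strong homozygote differentiation at SNP 4
            d[:, 4] = np.where(x == 1,
                               rng.choice([0, 1], n, p=[0.8, 0.2]),
                               rng.choice([2, 1], n, p=[0.8, 0.2]))
            g = make_matrix(d)
            status = pd.DataFrame({"animal": g.animal_ids, "status": x})
            rep = apply_cascade(self._records(g), g, status)
            row = rep.per_snp.set_index("snp_id").loc["S4"]
            wins += bool(row["pass_polarity"])
        assert wins >= 8

    def test_bad_threshold_rejected(self):
        g = make_matrix([[0, 1], [1, 2]])
        status = pd.DataFrame({"animal": g.animal_ids, "status": [0, 1]})
        with pytest.raises(ValueError, match="maf_min"):
            apply_cascade(self._records(g), g, status, maf_min=0.9)
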