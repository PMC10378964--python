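"""Two-locus EM LD, solid-spine blocks, gene mapping, syntenic screen."""

import numpy as np
import pandas as pd
import pytest

from spastigen.io import GenotypeMatrix, MarkerMap, MISSING
from spastigen.ld import (LDError, estimate_ld, haplotype_frequencies_em,
                          ld_matrix, map_snps_to_genes,
                          read_gene_annotation, solid_spine_blocks,
                          syntenic_ld_screen)
from test_gqls import make_matrix


def sample_pair(rng, pA, pB, D, n=200):
    """Phased two-locus sample; returns dosages and truth r2 from the
    realized haplotype counts (the phased-truth oracle)."""
    f = np.array([pA * pB + D, pA * (1 - pB) - D,
                  (1 - pA) * pB - D, (1 - pA) * (1 - pB) + D])
    assert (f > 0).all()
    haps = rng.choice(4, size=(n, 2), p=f)  # 0=AB 1=Ab 2=aB 3=ab
    a_dose = (haps < 2).sum(axis=1)
    b_dose = ((haps == 0) | (haps == 2)).sum(axis=1)
    hc = np.bincount(haps.ravel(), minlength=4) / (2.0 * n)
    pa, pb = hc[0] + hc[1], hc[0] + hc[2]
    Dt = hc[0] - pa * pb
    den = pa * (1 - pa) * pb * (1 - pb)
    return a_dose, b_dose, (Dt * Dt / den if den > 0 else 0.0)


def oracle_blocks(L, threshold):
    """Exhaustive enumeration: all valid [i..j] by definition, then maximal
    non-overlapping blocks in positional order."""
    m = L.shape[0]
    blocks, i = [], 0
    while i < m - 1:
        best = -1
        for j in range(i + 1, m):
            ok = L[i, j] >= threshold and all(
                L[i, k] >= threshold and L[k, j] >= threshold
                for k in range(i + 1, j))
            if ok:
                best = j
        if best > i:
            blocks.append((i, best))
            i = best + 1
        else:
            i += 1
    return blocks


class TestEstimateLD:
    def test_complete_ld_r2_one(self):
        gi = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        gj = gi.copy()
        pair = estimate_ld(gi, gj)
        assert pair.r2 == pytest.approx(1.0)
        assert pair.d_prime == pytest.approx(1.0)

    def test_exact_independence_r2_zero(self):
        # genotype counts matching independence products exactly
        gi, gj = [], []
        for a, pa in [(0, 1), (1, 2), (2, 1)]:
            for b, pb in [(0, 1), (1, 2), (2, 1)]:
                gi += [a] * (pa * pb)
                gj += [b] * (pa * pb)
        pair = estimate_ld(np.array(gi, dtype=np.int8),
                           np.array(gj, dtype=np.int8))
        assert pair.r2 == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_rejected(self):
        with pytest.raises(LDError):
            estimate_ld(np.zeros(10, dtype=np.int8),
                        np.array([0, 1, 2, 1, 0, 1, 2, 0, 1, 2],
                                 dtype=np.int8))

    def test_em_close_to_phased_truth(self):
        rng = np.random.default_rng(2024)
        errs = []
        for _ in range(40):
            pA, pB = rng.uniform(0.25, 0.75, 2)
            Dmax = min(pA * (1 - pB), (1 - pA) * pB)
            a, b, r2_true = sample_pair(rng, pA, pB,
                                        rng.uniform(0.3, 0.95) * Dmax)
            errs.append(abs(estimate_ld(a, b).r2 - r2_true))
        assert float(np.median(errs)) < 0.02

    def test_allele_swap_invariance(self):
        rng = np.random.default_rng(3)
        a, b, _ = sample_pair(rng, 0.4, 0.6, 0.1)
        r = estimate_ld(a, b).r2
        assert estimate_ld(2 - a, b).r2 == pytest.approx(r, abs=1e-9)
        assert estimate_ld(a, 2 - b).r2 == pytest.approx(r, abs=1e-9)

    def test_dprime_bounds_r(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            pA, pB = rng.uniform(0.2, 0.8, 2)
            Dmax = min(pA * (1 - pB), (1 - pA) * pB)
            a, b, _ = sample_pair(rng, pA, pB, rng.uniform(0, 1) * Dmax)
            pair = estimate_ld(a, b)
            assert pair.d_prime >= np.sqrt(pair.r2) - 0.05
            assert 0.0 <= pair.d_prime <= 1.0

    def test_missing_calls_dropped_pairwise(self):
        gi = np.array([0, 0, 1, 1, 2, 2, MISSING], dtype=np.int8)
        gj = np.array([0, 0, 1, 1, 2, 2, 0], dtype=np.int8)
        pair = estimate_ld(gi, gj)
        assert pair.n_used == 6 and pair.r2 == pytest.approx(1.0)


class TestSolidSpine:
    def test_perfect_ld_single_block(self):
        base = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 1], dtype=np.int8)
        g = make_matrix(np.stack([base, base, base], axis=1))
        blocks = solid_spine_blocks(g, 0.2)
        assert len(blocks) == 1 and blocks[0].n_snps == 3

    def test_independent_snps_no_blocks(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.5, size=(300, 4)).astype(np.int8)
        g = make_matrix(d)
        assert solid_spine_blocks(g, 0.9) == []

    def test_fewer_than_two_snps_empty(self):
        g = make_matrix(np.array([[0], [1], [2]], dtype=np.int8))
        assert solid_spine_blocks(g, 0.2) == []

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            m = int(rng.integers(2, 9))
            d = rng.binomial(2, rng.uniform(0.25, 0.75, m),
                             size=(80, m)).astype(np.int8)
            # induce some correlation by copying columns with noise
            for j in range(1, m):
                if rng.random() < 0.5:
                    flip = rng.random(80) < 0.15
                    d[:, j] = np.where(flip, d[:, j], d[:, j - 1])
            try:
                g = make_matrix(d)
            except Exception:
                continue
            L = np.nan_to_num(ld_matrix(g), nan=-1.0)
            got = [(b.first_index, b.last_index)
                   for b in solid_spine_blocks(g, 0.2)]
            assert got == oracle_blocks(L, 0.2)

    def test_weak_flank_excluded(self):
        # SNP2 tracks SNP1, SNP3 nearly independent of SNP1
        rng = np.random.default_rng(5)
        s1 = rng.binomial(2, 0.5, 400).astype(np.int8)
        flip = rng.random(400) < 0.05
        s2 = np.where(flip, rng.binomial(2, 0.5, 400), s1).astype(np.int8)
        s3 = rng.binomial(2, 0.5, 400).astype(np.int8)
        g = make_matrix(np.stack([s1, s2, s3], axis=1))
        blocks = solid_spine_blocks(g, 0.2)
        assert [(b.first_index, b.last_index) for b in blocks] == [(0, 1)]


class TestGeneMapping:
    GENES = pd.DataFrame({
        "gene_id": ["CACNA1A"], "chromosome": [7],
        "start_bp": [13_249_309], "end_bp": [13_506_224]})

    def _snps(self, pos):
        return pd.DataFrame({"snp_id": ["s"], "chromosome": [7],
                             "position_bp": [pos]})

    def test_snp_within_gene_distance_zero(self):
        out = map_snps_to_genes(self._snps(13_282_230), self.GENES)
        assert len(out) == 1
        assert out["distance_bp"].iloc[0] == 0
        assert out["relation"].iloc[0] == "within gene"

    def test_boundary_inclusive_at_window(self):
        out = map_snps_to_genes(self._snps(13_506_224 + 2_000_000),
                                self.GENES)
        assert len(out) == 1
        assert out["distance_bp"].iloc[0] == -2_000_000

    def test_one_base_past_window_not_mapped(self):
        out = map_snps_to_genes(self._snps(13_506_224 + 2_000_001),
                                self.GENES)
        assert out.empty

    def test_bed_halfopen_converted(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("7\t99\t200\tGENE1\nnot\ta\tvalid\trow\n")
        with pytest.warns(UserWarning, match="malformed"):
            genes = read_gene_annotation(bed)
        assert genes.loc[0, "start_bp"] == 100
        assert genes.loc[0, "end_bp"] == 200

    def test_gff3_gene_rows(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "7\tsrc\tgene\t100\t200\t.\t+\t.\tID=G1;gene_id=GENE1\n"
            "7\tsrc\texon\t100\t150\t.\t+\t.\tID=E1\n")
        genes = read_gene_annotation(gff)
        assert len(genes) == 1
        assert genes.loc[0, "gene_id"] == "GENE1"
        assert genes.loc[0, "start_bp"] == 100


class TestSyntenicScreen:
    def test_threshold_zero_returns_all_pairs(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.5, size=(100, 4)).astype(np.int8)
        g = make_matrix(d)
        out = syntenic_ld_screen(["S0", "S1"], ["S2", "S3"], g, r2_min=0.0)
        assert len(out) == 4

    def test_cross_chromosome_pair_rejected(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.5, size=(50, 2)).astype(np.int8)
        g = make_matrix(d, chrom=[1, 2])
        with pytest.raises(LDError, match="syntenic"):
            syntenic_ld_screen(["S0"], ["S1"], g)

    def test_linked_pair_detected_above_threshold(self):
        rng = np.random.default_rng(8)
        s1 = rng.binomial(2, 0.5, 300).astype(np.int8)
        flip = rng.random(300) < 0.1
        s2 = np.where(flip, rng.binomial(2, 0.5, 300), s1).astype(np.int8)
        g = make_matrix(np.stack([s1, s2], axis=1))
        out = syntenic_ld_screen(["S0"], ["S1"], g, r2_min=0.2)
        assert len(out) == 1 and out["r2"].iloc[0] >= 0.2


class TestEMInternals:
    def test_loglik_monotone_checked_internally(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b, _ = sample_pair(rng, *rng.uniform(0.3, 0.7, 2), 0.05)
            haplotype_frequencies_em(a, b)  # raises if likelihood dips
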