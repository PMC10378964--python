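"""Pre-GWAS quality control screens.

Fixed filter order: (1) animals by call rate, (2) SNPs by call rate,
(3) SNPs by heterozygosity excess (observed het frequency minus the
Hardy-Weinberg expectation on non-missing calls), (4) SNPs by minor
allele frequency.  Each removed record is attributed to exactly one
filter so the report reconciles with the matrix dimensions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, MISSING


@dataclass
class QCReport:
    n_animals_in: int
    n_animals_out: int
    n_snps_in: int
    n_snps_out: int
    removals: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def summary(self) -> str:
        lines = [
            f"animals: {self.n_animals_in} -> {self.n_animals_out}",
            f"SNPs:    {self.n_snps_in} -> {self.n_snps_out}",
        ]
        for k, v in self.removals.items():
            lines.append(f"  removed by {k}: {v}")
        return "\n".join(lines)


def heterozygosity_excess(g: GenotypeMatrix) -> np.ndarray:
    """Observed het frequency minus HWE-expected 2p(1-p), per SNP."""
    d = g.dosage
    nonmiss = d != MISSING
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n = nonmiss.sum(axis=0).astype(float)
        het = ((d == 1) & nonmiss).sum(axis=0) / n
        p = np.where(nonmiss, d, 0).sum(axis=0) / (2.0 * n)
    return het - 2.0 * p * (1.0 - p)


def qc_filter(g: GenotypeMatrix, ind_call_rate: float = 0.90,
              snp_call_rate: float = 0.90, het_excess_max: float = 0.499,
              maf_min: float = 0.00001) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the four QC screens in fixed order; idempotent.

    Thresholds: animals and SNPs with call rate < 0.90 drop; SNPs with
    het excess >= 0.499 drop; SNPs with MAF <= 1e-5 drop (this keeps
    virtually all informative SNPs, removing only monomorphic and
    near-monomorphic markers).
    """
    for name, t in [("ind_call_rate", ind_call_rate),
                    ("snp_call_rate", snp_call_rate),
                    ("het_excess_max", het_excess_max),
                    ("maf_min", maf_min)]:
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {t}")
    if g.n_animals == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")

    removals: dict[str, int] = {}

    nonmiss = g.dosage != MISSING
    ind_cr = nonmiss.mean(axis=1)
    keep_animals = ind_cr >= ind_call_rate
    removals["individual_call_rate"] = int((~keep_animals).sum())
    g1 = g.subset(animal_ids=[a for a, k in zip(g.animal_ids, keep_animals)
                              if k])

    nonmiss = g1.dosage != MISSING
    snp_cr = nonmiss.mean(axis=0) if g1.n_animals else np.zeros(g1.n_snps)
    keep_cr = snp_cr >= snp_call_rate
    removals["snp_call_rate"] = int((~keep_cr).sum())
    g2 = g1.subset(snp_mask=keep_cr)

    hexc = heterozygosity_excess(g2)
    keep_het = ~(np.nan_to_num(hexc, nan=0.0) >= het_excess_max)
    removals["heterozygosity_excess"] = int((~keep_het).sum())
    g3 = g2.subset(snp_mask=keep_het)

    maf = g3.maf()
    keep_maf = np.nan_to_num(maf, nan=0.0) > maf_min
    removals["maf"] = int((~keep_maf).sum())
    g4 = g3.subset(snp_mask=keep_maf)

    report = QCReport(
        n_animals_in=g.n_animals, n_animals_out=g4.n_animals,
        n_snps_in=g.n_snps, n_snps_out=g4.n_snps,
        removals=removals,
        thresholds={"ind_call_rate": ind_call_rate,
                    "snp_call_rate": snp_call_rate,
                    "het_excess_max": het_excess_max,
                    "maf_min": maf_min})
    return g4, report
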