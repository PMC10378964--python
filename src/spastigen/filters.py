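"""Post-GWAS filter cascade: MAF, genotype chi-square, homozygotic polarity.

Applied cumulatively, in fixed order, to the SNPs significant at the 10%
chromosome-wise pFDR tier:

1. MAF >= 0.2 — with a case prevalence near 60%, truly associated
   alleles should be common;
2. Pearson chi-square of the 2 (status) x k (genotype) table at 0.05;
3. homozygotic polarity score >= 0.3, where the score is the absolute
   difference between cases and controls of (freq hom_0 - freq hom_2),
   each frequency taken over all non-missing animals of that class.
   Large scores flag SNPs whose opposite homozygotes are enriched in
   opposite disease classes.  If one homozygote class is absent in the
   whole cohort the score is undefined (N/A) and the SNP cannot pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .io import GenotypeMatrix, MISSING
from .gqls import CohortError

STAGES = ["pfdr_10pct", "maf", "chi_square", "polarity"]


@dataclass
class FilterCascadeReport:
    stages: list[str]
    survivors: list[int]
    per_snp: pd.DataFrame
    per_chromosome: pd.DataFrame = field(default_factory=pd.DataFrame)
    thresholds: dict = field(default_factory=dict)

    def summary(self) -> str:
        return " -> ".join(f"{s}:{n}" for s, n in
                           zip(self.stages, self.survivors))


def compute_maf(column: np.ndarray) -> float:
    """Minor allele frequency of one dosage column (missing = MISSING)."""
    d = np.asarray(column)
    d = d[d != MISSING].astype(float)
    if d.size == 0:
        raise ValueError("all calls missing: MAF undefined")
    p = d.mean() / 2.0
    return float(min(p, 1.0 - p))


def chisq_genotype_test(column: np.ndarray, status: np.ndarray
                        ) -> tuple[float, float, int]:
    """Pearson chi-square of genotype class counts by disease status.

    Genotype classes absent from the whole cohort are dropped; df = k - 1
    for k observed classes.  Returns (chi2, p, df); a single observed
    class gives (0, 1, 0).  No continuity correction is applied; small
    expected counts produce a warning rather than an error.
    """
    d = np.asarray(column)
    status = np.asarray(status)
    keep = d != MISSING
    d, s = d[keep], status[keep]
    if len(np.unique(s)) < 2:
        raise CohortError("both phenotype classes required")
    classes = np.unique(d)
    if len(classes) < 2:
        return 0.0, 1.0, 0
    table = np.array([[np.sum((s == grp) & (d == c)) for c in classes]
                      for grp in (1, 0)])
    nz = table.sum(axis=0) > 0
    table = table[:, nz]
    if table.shape[1] < 2:
        return 0.0, 1.0, 0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        warnings.warn("chi-square table has expected counts < 5")
    stat, p, dof, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p), int(dof)


def polarity_score(column: np.ndarray, status: np.ndarray) -> float:
    """Homozygotic polarity: |(p_hom0 - p_hom2)_cases - (..)_controls|.

    Homozygote proportions are computed over all non-missing animals in
    each phenotype class.  Returns NaN (N/A) when only one homozygotic
    state exists across all tested animals.
    """
    d = np.asarray(column)
    status = np.asarray(status)
    keep = d != MISSING
    d, s = d[keep], status[keep]
    if len(np.unique(s)) < 2:
        raise CohortError("both phenotype classes required")
    if not ((d == 0).any() and (d == 2).any()):
        return float("nan")

    def class_diff(cls: int) -> float:
        dc = d[s == cls]
        if dc.size == 0:
            return 0.0
        return float(np.mean(dc == 0) - np.mean(dc == 2))

    return float(abs(class_diff(1) - class_diff(0)))


def apply_cascade(records: pd.DataFrame, g: GenotypeMatrix,
                  status: pd.DataFrame, maf_min: float = 0.2,
                  chi2_alpha: float = 0.05, polarity_min: float = 0.3
                  ) -> FilterCascadeReport:
    """Run the cumulative cascade over tier-annotated association records.

    ``records`` should contain the SNPs significant at pFDR <= 10%
    (rows with other tiers are ignored if a ``pfdr_tier`` column is
    present).  Survivor counts per stage are reported overall and per
    chromosome (the classic cumulative-columns layout).
    """
    for name, t, lo, hi in [("maf_min", maf_min, 0.0, 0.5),
                            ("chi2_alpha", chi2_alpha, 0.0, 1.0),
                            ("polarity_min", polarity_min, 0.0, 2.0)]:
        if not (lo <= t <= hi):
            raise ValueError(f"{name} must lie in [{lo}, {hi}], got {t}")

    records = records.copy()
    if "pfdr_tier" in records.columns:
        records = records[records["pfdr_tier"] != "ns"]
    if records.empty:
        empty = pd.DataFrame(columns=["snp_id", "chromosome", "maf",
                                      "chi2", "chi2_p", "polarity",
                                      "pass_maf", "pass_chi2",
                                      "pass_polarity"])
        return FilterCascadeReport(STAGES, [0, 0, 0, 0], empty,
                                   thresholds={"maf_min": maf_min,
                                               "chi2_alpha": chi2_alpha,
                                               "polarity_min": polarity_min})

    snp_pos = {s: j for j, s in enumerate(g.marker_map.df["snp_id"])}
    absent = [s for s in records["snp_id"] if s not in snp_pos]
    if absent:
        raise KeyError(f"association records reference SNPs not in the "
                       f"genotype matrix: {absent[:5]}")
    gpos = {a: i for i, a in enumerate(g.animal_ids)}
    status = status.copy()
    status["animal"] = status["animal"].astype(str)
    rows = np.array([gpos[a] for a in status["animal"]])
    x = status["status"].to_numpy(dtype=int)

    out = []
    for _, rec in records.iterrows():
        j = snp_pos[rec["snp_id"]]
        col = g.dosage[rows, j]
        maf = compute_maf(col)
        chi, chip, _ = chisq_genotype_test(col, x)
        pol = polarity_score(col, x)
        pass_maf = maf >= maf_min
        pass_chi = pass_maf and (chip <= chi2_alpha)
        pass_pol = pass_chi and (not np.isnan(pol)) and pol >= polarity_min
        out.append({"snp_id": rec["snp_id"],
                    "chromosome": rec["chromosome"], "maf": maf,
                    "chi2": chi, "chi2_p": chip, "polarity": pol,
                    "pass_maf": pass_maf, "pass_chi2": pass_chi,
                    "pass_polarity": pass_pol})
    per_snp = pd.DataFrame(out)
    survivors = [len(per_snp), int(per_snp["pass_maf"].sum()),
                 int(per_snp["pass_chi2"].sum()),
                 int(per_snp["pass_polarity"].sum())]
    per_chrom = (per_snp.assign(total=1)
                 .groupby("chromosome")
                 .agg(pfdr_10pct=("total", "sum"),
                      maf=("pass_maf", "sum"),
                      chi_square=("pass_chi2", "sum"),
                      polarity=("pass_polarity", "sum"))
                 .reset_index())
    return FilterCascadeReport(STAGES, survivors, per_snp, per_chrom,
                               thresholds={"maf_min": maf_min,
                                           "chi2_alpha": chi2_alpha,
                                           "polarity_min": polarity_min})
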