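"""Genotype containers and text-format I/O (PLINK .ped/.map, VCF, CSV).

Genotypes are held as an animals x SNPs dosage matrix coded 0/1/2 (count of
the B allele), with -9 marking a missing call.  Dosage/2 is the "allelic
proportion" response used by the quasi-likelihood score test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = np.int8(-9)

MAP_COLUMNS = ["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]


class FormatError(ValueError):
    pass


@dataclass
class MarkerMap:
    """SNP metadata: id, autosome (1-29), 1-based bp position, alleles."""

    df: pd.DataFrame
    max_chromosome: int = 29

    def __post_init__(self) -> None:
        missing = [c for c in MAP_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"marker map lacks columns {missing}")
        self.df = self.df.reset_index(drop=True)
        chrom = self.df["chromosome"].to_numpy()
        if np.any((chrom < 1) | (chrom > self.max_chromosome)):
            bad = self.df.loc[(chrom < 1) | (chrom > self.max_chromosome),
                              "snp_id"].tolist()[:5]
            raise FormatError(
                f"non-autosomal chromosome for SNPs {bad} "
                f"(autosomes 1..{self.max_chromosome} only)")
        for c in np.unique(chrom):
            pos = self.df.loc[chrom == c, "position_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise FormatError(
                    f"positions not strictly increasing on chromosome {c}")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosages in {0, 1, 2, MISSING}."""

    animal_ids: list[str]
    marker_map: MarkerMap
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.animal_ids), len(self.marker_map)):
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.marker_map)} SNPs")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.marker_map)

    def allelic_proportions(self) -> np.ndarray:
        """Dosage/2 with missing as NaN: the Y response of the score test."""
        y = self.dosage.astype(float) / 2.0
        y[self.dosage == MISSING] = np.nan
        return y

    def subset(self, animal_ids=None, snp_mask=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_animals)
        ids = list(self.animal_ids)
        if animal_ids is not None:
            pos = {a: i for i, a in enumerate(self.animal_ids)}
            absent = [a for a in animal_ids if a not in pos]
            if absent:
                raise KeyError(f"animals not genotyped: {absent[:5]}")
            rows = np.array([pos[a] for a in animal_ids])
            ids = list(animal_ids)
        cols = np.arange(self.n_snps)
        mm = self.marker_map
        if snp_mask is not None:
            snp_mask = np.asarray(snp_mask)
            cols = np.flatnonzero(snp_mask) if snp_mask.dtype == bool else snp_mask
            mm = MarkerMap(self.marker_map.df.iloc[cols].reset_index(drop=True))
        return GenotypeMatrix(ids, mm, self.dosage[np.ix_(rows, cols)])

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(d, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


def read_plink_text(ped_path, map_path, max_chromosome: int = 29
                    ) -> GenotypeMatrix:
    """Read PLINK text .ped/.map into a dosage matrix.

    The counted (B) allele at each SNP is the second distinct allele
    observed in file order; "0 0" allele pairs become missing calls.  The
    .ped phenotype column is ignored (statuses come from the phenotype CSV).
    """
    mdf = pd.read_csv(map_path, sep=r"\s+", header=None,
                      names=["chromosome", "snp_id", "cm", "position_bp"])
    m = len(mdf)
    animal_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path} line {ln}: expected {6 + 2 * m} fields "
                    f"(6 + 2 x {m} SNPs), found {len(fields)}")
            animal_ids.append(fields[1])
            allele_rows.append(np.array(fields[6:], dtype="U2"))
    alleles = (np.stack(allele_rows).reshape(len(animal_ids), m, 2)
               if animal_ids else np.empty((0, m, 2), dtype="U2"))

    dosage = np.zeros((len(animal_ids), m), dtype=np.int8)
    allele_a = np.empty(m, dtype="U2")
    allele_b = np.empty(m, dtype="U2")
    for j in range(m):
        col = alleles[:, j, :]
        seen = [a for a in pd.unique(col.ravel()) if a != "0"]
        if len(seen) > 2:
            raise FormatError(
                f"SNP {mdf['snp_id'].iloc[j]} has {len(seen)} alleles "
                f"({seen}); only biallelic SNPs supported")
        a = seen[0] if seen else "A"
        b = seen[1] if len(seen) > 1 else a
        allele_a[j], allele_b[j] = a, b
        miss = (col == "0").any(axis=1)
        dosage[:, j] = (col == b).sum(axis=1).astype(np.int8)
        dosage[miss, j] = MISSING
    mm = MarkerMap(pd.DataFrame({
        "snp_id": mdf["snp_id"].astype(str),
        "chromosome": mdf["chromosome"].astype(int),
        "position_bp": mdf["position_bp"].astype(int),
        "allele_a": allele_a, "allele_b": allele_b}),
        max_chromosome=max_chromosome)
    return GenotypeMatrix(animal_ids, mm, dosage)


def write_plink_text(g: GenotypeMatrix, ped_path, map_path) -> None:
    mdf = g.marker_map.df
    with open(map_path, "w") as fh:
        for _, r in mdf.iterrows():
            fh.write(f"{r['chromosome']}\t{r['snp_id']}\t0\t{r['position_bp']}\n")
    aa = mdf["allele_a"].to_numpy()
    bb = mdf["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(g.animal_ids):
            d = g.dosage[i]
            # het written "a b" so allele_a is observed first where possible
            first = np.where(d == 2, bb, aa)
            second = np.where(d >= 1, bb, aa)
            first = np.where(d == MISSING, "0", first)
            second = np.where(d == MISSING, "0", second)
            pairs = " ".join(f"{x} {y}" for x, y in zip(first, second))
            fh.write(f"FAM {aid} 0 0 0 -9 {pairs}\n")


def read_vcf(path, max_chromosome: int = 29) -> GenotypeMatrix:
    """Minimal VCF reader: biallelic sites, GT field only (unphased ok)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animal_ids = list(vcf.samples)
    rows = []
    recs = []
    for var in vcf:
        if var.ALT and len(var.ALT) > 1:
            raise FormatError(f"SNP {var.ID or var.POS} is not biallelic")
        gts = np.array([[g[0], g[1]] for g in var.genotypes], dtype=np.int16)
        d = gts[:, 0] + gts[:, 1]
        d[(gts[:, 0] < 0) | (gts[:, 1] < 0)] = MISSING
        rows.append(d.astype(np.int8))
        recs.append((var.ID or f"{var.CHROM}_{var.POS}",
                     int(str(var.CHROM).lstrip("chr")), var.POS,
                     var.REF, var.ALT[0] if var.ALT else var.REF))
    mm = MarkerMap(pd.DataFrame(recs, columns=MAP_COLUMNS),
                   max_chromosome=max_chromosome)
    dosage = (np.stack(rows, axis=1) if rows
              else np.empty((len(animal_ids), 0), dtype=np.int8))
    return GenotypeMatrix(animal_ids, mm, dosage)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype CSV (animal, status) with status in {0,1}.

    PLINK-style 1/2 coding (1 = unaffected, 2 = affected) is auto-detected
    and remapped to 0/1 with a warning.
    """
    df = pd.read_csv(path, dtype={0: str})
    df.columns = [c.lower() for c in df.columns]
    if "animal" not in df.columns or "status" not in df.columns:
        df.columns = ["animal", "status"] + list(df.columns[2:])
    df["status"] = df["status"].astype(int)
    vals = set(df["status"].unique())
    if vals <= {1, 2} and 2 in vals:
        warnings.warn("phenotypes use PLINK 1/2 coding; remapped to 0/1")
        df["status"] = df["status"] - 1
    if not set(df["status"].unique()) <= {0, 1}:
        raise FormatError(f"statuses must be 0/1, found {sorted(vals)}")
    return df[["animal", "status"]]


def read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]
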