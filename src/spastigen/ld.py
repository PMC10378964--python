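"""Two-locus LD from unphased genotypes, solid-spine blocks, gene mapping.

Haplotype frequencies for a pair of biallelic SNPs are estimated from
unphased dosage pairs by EM (the double heterozygote is the only
ambiguous class); r^2 = D^2 / (pA(1-pA) pB(1-pB)) and D' = |D|/Dmax
follow.  Haplotype blocks use the "solid spine of LD" rule: the first
and last markers of a block must be in strong LD with every marker in
between (and with each other).  SNP-to-gene mapping attaches genes whose
bodies fall within a +/-2 Mb window of the SNP; the syntenic screen
keeps (significant SNP, within-gene SNP) pairs with r^2 above threshold
regardless of distance, same chromosome only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MISSING


class LDError(ValueError):
    pass


@dataclass
class LDPair:
    snp_i: str
    snp_j: str
    r2: float
    d_prime: float
    n_used: int
    em_iterations: int


@dataclass
class HaploBlock:
    chromosome: int
    first_index: int
    last_index: int
    start_bp: int
    end_bp: int
    snp_ids: list[str]

    @property
    def n_snps(self) -> int:
        return self.last_index - self.first_index + 1


def haplotype_frequencies_em(gi: np.ndarray, gj: np.ndarray,
                             tol: float = 1e-10, max_iter: int = 1000
                             ) -> tuple[np.ndarray, int, int]:
    """EM haplotype frequencies (pAB, pAb, paB, pab) for one SNP pair.

    The likelihood is monotone non-decreasing across iterations (checked);
    alleles 'A'/'a' at locus i are the 0- and 2-dosage alleles, likewise
    'B'/'b' at locus j.  Returns (freqs, n pairwise-complete animals,
    iterations used).
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    keep = (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[keep].astype(int), gj[keep].astype(int)
    n = len(gi)
    if n == 0 or len(np.unique(gi)) < 2 or len(np.unique(gj)) < 2:
        raise LDError("monomorphic or empty SNP column: LD undefined")

    counts = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            counts[a, b] = np.sum((gi == a) & (gj == b))

    # haplotypes: 0 = ab, 1 = aB, 2 = Ab, 3 = AB  (capital = dosage allele)
    f = np.full(4, 0.25)
    n_dh = counts[1, 1]
    # fixed haplotype counts from the 8 unambiguous genotype classes
    base = np.zeros(4)
    base[3] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    base[2] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base[1] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[0] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    total = 2.0 * n

    def loglik(f: np.ndarray) -> float:
        ll = float(base @ np.log(np.maximum(f, 1e-300)))
        if n_dh:
            ll += n_dh * np.log(max(2 * f[3] * f[0] + 2 * f[2] * f[1],
                                    1e-300))
        return ll

    prev_ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        denom = f[3] * f[0] + f[2] * f[1]
        share_cis = f[3] * f[0] / denom if denom > 0 else 0.5
        new = base.copy()
        new[3] += n_dh * share_cis
        new[0] += n_dh * share_cis
        new[2] += n_dh * (1 - share_cis)
        new[1] += n_dh * (1 - share_cis)
        f_new = new / total
        ll = loglik(f_new)
        if ll + 1e-9 < prev_ll:
            raise AssertionError("EM log-likelihood decreased")
        if abs(ll - prev_ll) < tol:
            f = f_new
            break
        f, prev_ll = f_new, ll
    return f, n, it


def estimate_ld(gi: np.ndarray, gj: np.ndarray, snp_i: str = "i",
                snp_j: str = "j") -> LDPair:
    """r^2 and D' between two dosage columns (pairwise-complete animals)."""
    f, n, it = haplotype_frequencies_em(gi, gj)
    pA = f[3] + f[2]
    pB = f[3] + f[1]
    D = f[3] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = float(D * D / denom) if denom > 0 else 0.0
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = float(abs(D) / dmax) if dmax > 0 else 0.0
    return LDPair(snp_i, snp_j, min(r2, 1.0), min(d_prime, 1.0), n, it)


def ld_matrix(g: GenotypeMatrix, statistic: str = "r2") -> np.ndarray:
    """Pairwise LD for all SNPs of a (small) region matrix."""
    m = g.n_snps
    ids = g.marker_map.df["snp_id"].tolist()
    out = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            try:
                pair = estimate_ld(g.dosage[:, i], g.dosage[:, j],
                                   ids[i], ids[j])
                val = pair.r2 if statistic == "r2" else pair.d_prime
            except LDError:
                val = np.nan
            out[i, j] = out[j, i] = val
    return out


def solid_spine_blocks(g: GenotypeMatrix, strong_ld_min: float = 0.2,
                       statistic: str = "r2") -> list[HaploBlock]:
    """Maximal non-overlapping solid-spine blocks in positional order.

    A candidate block [i..j] is valid when LD(i, k) >= threshold and
    LD(k, j) >= threshold for every k strictly between i and j, and
    LD(i, j) >= threshold.  Scanning left to right, each block start
    takes the largest valid end; blocks have at least 2 SNPs.  The
    statistic defaults to r^2 (threshold 0.2); D' (classic threshold 0.8)
    is available via ``statistic="dprime"``.
    """
    m = g.n_snps
    if m < 2:
        return []
    L = ld_matrix(g, "r2" if statistic == "r2" else "dprime")
    mm = g.marker_map.df

    def valid(i: int, j: int) -> bool:
        if not (L[i, j] >= strong_ld_min):
            return False
        for k in range(i + 1, j):
            if not (L[i, k] >= strong_ld_min and L[k, j] >= strong_ld_min):
                return False
        return True

    blocks: list[HaploBlock] = []
    i = 0
    while i < m - 1:
        best = -1
        for j in range(i + 1, m):
            if int(mm["chromosome"].iloc[j]) != int(mm["chromosome"].iloc[i]):
                break
            if valid(i, j):
                best = j
        if best > i:
            blocks.append(HaploBlock(
                chromosome=int(mm["chromosome"].iloc[i]),
                first_index=i, last_index=best,
                start_bp=int(mm["position_bp"].iloc[i]),
                end_bp=int(mm["position_bp"].iloc[best]),
                snp_ids=mm["snp_id"].iloc[i:best + 1].tolist()))
            i = best + 1
        else:
            i += 1
    return blocks


# ---------------------------------------------------------------------------
# Gene annotation and mapping
# ---------------------------------------------------------------------------

def read_gene_annotation(path, fmt: str | None = None) -> pd.DataFrame:
    """Gene records (gene_id, chromosome, start_bp, end_bp), 1-based inclusive.

    BED input (0-based half-open) is converted to 1-based inclusive;
    GFF3 keeps its native 1-based inclusive coordinates (gene-type rows
    only; the ID/gene_id attribute names the gene).  Malformed rows are
    skipped with a warning count.
    """
    path = str(path)
    if fmt is None:
        fmt = "gff3" if path.endswith((".gff", ".gff3")) else "bed"
    rows = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if fmt == "bed":
                    chrom = int(str(parts[0]).lstrip("chr"))
                    start0, end = int(parts[1]), int(parts[2])
                    gene = parts[3] if len(parts) > 3 else \
                        f"{chrom}:{start0 + 1}-{end}"
                    rows.append((gene, chrom, start0 + 1, end))
                else:
                    if len(parts) < 9 or parts[2].lower() != "gene":
                        continue
                    chrom = int(str(parts[0]).lstrip("chr"))
                    start, end = int(parts[3]), int(parts[4])
                    attrs = dict(kv.split("=", 1) for kv in
                                 parts[8].split(";") if "=" in kv)
                    gene = attrs.get("gene_id", attrs.get("ID",
                                                          f"{chrom}:{start}"))
                    rows.append((gene, chrom, start, end))
            except (ValueError, IndexError):
                skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} malformed annotation rows")
    df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start_bp",
                                     "end_bp"])
    if ((df["start_bp"] > df["end_bp"]).any()):
        bad = df.loc[df["start_bp"] > df["end_bp"], "gene_id"].tolist()[:5]
        raise LDError(f"gene start > end for {bad}")
    return df


def map_snps_to_genes(snps: pd.DataFrame, genes: pd.DataFrame,
                      window_bp: int = 2_000_000) -> pd.DataFrame:
    """Map each SNP to genes whose body overlaps [pos-window, pos+window].

    Coordinates are 1-based inclusive at both ends.  The signed distance
    is 0 when the SNP lies inside the gene, negative when the gene is to
    the left (SNP downstream of gene end), positive to the right.
    """
    out = []
    for _, s in snps.iterrows():
        chrom = int(s["chromosome"])
        pos = int(s["position_bp"])
        sub = genes[genes["chromosome"] == chrom]
        for _, gn in sub.iterrows():
            if gn["end_bp"] < pos - window_bp or \
               gn["start_bp"] > pos + window_bp:
                continue
            if gn["start_bp"] <= pos <= gn["end_bp"]:
                dist = 0
                rel = "within gene"
            elif pos > gn["end_bp"]:
                dist = -(pos - int(gn["end_bp"]))
                rel = f"{-dist} bases left"      # gene left of the SNP
            else:
                dist = int(gn["start_bp"]) - pos
                rel = f"{dist} bases right"
            row = {"snp_id": s["snp_id"], "chromosome": chrom,
                   "position_bp": pos, "gene_id": gn["gene_id"],
                   "gene_start_bp": int(gn["start_bp"]),
                   "gene_end_bp": int(gn["end_bp"]),
                   "distance_bp": dist, "relation": rel}
            for extra in ("maf", "polarity", "q_value"):
                if extra in s.index:
                    row[extra] = s[extra]
            out.append(row)
    return pd.DataFrame(out, columns=["snp_id", "chromosome", "position_bp",
                                      "gene_id", "gene_start_bp",
                                      "gene_end_bp", "distance_bp",
                                      "relation"]
                        + [c for c in ("maf", "polarity", "q_value")
                           if c in snps.columns])


def syntenic_ld_screen(sig_snps: list[str], gene_snps: list[str],
                       g: GenotypeMatrix, r2_min: float = 0.2
                       ) -> pd.DataFrame:
    """All (significant SNP, gene SNP) pairs with r^2 >= threshold.

    Pairs must be syntenic (same chromosome); distance is unrestricted —
    a useful linkage can reach beyond the gene-mapping window.
    """
    mm = g.marker_map.df
    pos = {s: j for j, s in enumerate(mm["snp_id"])}
    rows = []
    for a in sig_snps:
        for b in gene_snps:
            if a == b:
                continue
            ja, jb = pos.get(a), pos.get(b)
            if ja is None or jb is None:
                raise KeyError(f"SNP missing from genotype matrix: "
                               f"{a if ja is None else b}")
            ca = int(mm['chromosome'].iloc[ja])
            cb = int(mm['chromosome'].iloc[jb])
            if ca != cb:
                raise LDError(
                    f"cross-chromosome pair requested: {a} (chr {ca}) vs "
                    f"{b} (chr {cb}); syntenic LD only")
            try:
                pair = estimate_ld(g.dosage[:, ja], g.dosage[:, jb], a, b)
            except LDError:
                continue
            if pair.r2 >= r2_min:
                rows.append({"snp_i": a, "snp_j": b, "chromosome": ca,
                             "r2": pair.r2, "d_prime": pair.d_prime,
                             "n_used": pair.n_used})
    return pd.DataFrame(rows, columns=["snp_i", "snp_j", "chromosome",
                                       "r2", "d_prime", "n_used"])
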