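"""Kinship-aware quasi-likelihood score test and chromosome-wise pFDR.

The association model treats the per-animal allelic proportion
Y in {0, 1/2, 1} as the response and disease status X in {0, 1} as the
covariate, with mean mu = exp(b0 + b1 X) / (1 + exp(b0 + b1 X)) and a
working covariance v(mu) * K, where v(mu) = mu(1-mu)/2 (binomial variance
of a two-allele count divided by 4) and K is the additive relationship
matrix of the tested animals.  The score test of H0: b1 = 0 is

    mu0 = (1' K^-1 y) / (1' K^-1 1)
    T   = [x' K^-1 (y - mu0)]^2
          / ( v(mu0) * [x' K^-1 x - (x' K^-1 1)^2 / (1' K^-1 1)] )

with p = P(chi2_1 > T).  With K = I this is the classical score test for
the logistic-type mean model.  Chromosome-wise positive-FDR control uses
Storey q-values (smoother pi0 estimate, pi0 = 1 fallback on chromosomes
with few SNPs) at 1/5/10% tiers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .io import GenotypeMatrix
from .kinship import AdditiveRelationship

TIER_CUTOFFS = (0.01, 0.05, 0.10)

ASSOC_COLUMNS = ["snp_id", "chromosome", "position_bp", "sign", "T",
                 "p_value", "maf", "n_used", "monomorphic"]


class CohortError(ValueError):
    pass


def _variance_function(mu: float) -> float:
    return mu * (1.0 - mu) / 2.0


def gqls_test(y: np.ndarray, x: np.ndarray,
              K: np.ndarray | None = None,
              estimate_dispersion: bool = False) -> tuple[float, float]:
    """Score statistic and p-value for one SNP.

    y : allelic proportions in {0, 0.5, 1} with NaN for missing calls.
    x : 0/1 disease statuses, same length.
    K : kinship (additive relationship) matrix; identity if None.
    estimate_dispersion : divide T by a moment overdispersion estimate.

    Monomorphic SNPs return (nan, 1.0).  A single phenotype class raises
    ``CohortError``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = ~np.isnan(y)
    y, x = y[keep], x[keep]
    if len(np.unique(x)) < 2:
        raise CohortError("only one phenotype class present")
    if np.all(y == y[0]):
        return float("nan"), 1.0
    if K is None:
        Kin = None
    else:
        Kin = np.asarray(K, dtype=float)[np.ix_(keep.nonzero()[0],
                                                keep.nonzero()[0])]
    return _gqls_core(y, x, Kin, estimate_dispersion)


def _gqls_core(y, x, K, estimate_dispersion=False):
    one = np.ones_like(y)
    if K is None:
        Ki_y, Ki_x, Ki_1 = y, x, one
    else:
        c = cho_factor(K)
        Ki_y = cho_solve(c, y)
        Ki_x = cho_solve(c, x)
        Ki_1 = cho_solve(c, one)
    s11 = float(one @ Ki_1)
    mu0 = float(one @ Ki_y) / s11
    if not (0.0 < mu0 < 1.0):
        return float("nan"), 1.0
    U = float(x @ Ki_y) - mu0 * float(x @ Ki_1)
    varU = _variance_function(mu0) * (float(x @ Ki_x)
                                      - float(x @ Ki_1) ** 2 / s11)
    if varU <= 0:
        return float("nan"), 1.0
    T = U * U / varU
    if estimate_dispersion:
        resid = y - mu0
        Ki_r = Ki_y - mu0 * Ki_1
        phi = float(resid @ Ki_r) / (_variance_function(mu0) * (len(y) - 1))
        if phi > 0:
            T = T / phi
    p = float(chi2.sf(T, df=1))
    return float(T), max(p, np.finfo(float).tiny)


def run_gwas(g: GenotypeMatrix, status: pd.DataFrame,
             K: AdditiveRelationship | np.ndarray | None = None,
             estimate_dispersion: bool = False) -> pd.DataFrame:
    """One score test per SNP; returns the association table.

    Animals are aligned on ids between genotypes and phenotypes;
    K^-1-dependent quantities are factorised once and reused for every
    SNP without missing calls (SNPs with missing calls fall back to a
    per-SNP sub-factorisation, pairwise complete).
    """
    status = status.copy()
    status["animal"] = status["animal"].astype(str)
    gpos = {a: i for i, a in enumerate(g.animal_ids)}
    missing_ids = [a for a in status["animal"] if a not in gpos]
    if missing_ids:
        raise CohortError(f"phenotyped animals not genotyped: "
                          f"{missing_ids[:5]}")
    ids = status["animal"].tolist()
    x = status["status"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise CohortError("only one phenotype class present")
    gsub = g.subset(animal_ids=ids)
    if gsub.n_snps == 0:
        warnings.warn("no SNPs to test (all removed by QC?)")
        return pd.DataFrame(columns=ASSOC_COLUMNS)

    if K is None:
        Kmat = None
    elif isinstance(K, AdditiveRelationship):
        Kmat = K.submatrix(ids).A
    else:
        Kmat = np.asarray(K, dtype=float)
        if Kmat.shape != (len(ids), len(ids)):
            raise CohortError("kinship matrix shape does not match cohort")

    Y = gsub.allelic_proportions()        # n x m, NaN = missing
    n, m = Y.shape
    maf = gsub.maf()
    complete = ~np.isnan(Y).any(axis=0)
    mono = np.array([len(np.unique(Y[~np.isnan(Y[:, j]), j])) < 2
                     for j in range(m)])

    T = np.full(m, np.nan)
    p = np.ones(m)
    sign = np.zeros(m)
    n_used = (~np.isnan(Y)).sum(axis=0)

    one = np.ones(n)
    do_vec = complete & ~mono
    if do_vec.any():
        Yv = Y[:, do_vec]
        if Kmat is None:
            KiY, Ki_x, Ki_1 = Yv, x, one
        else:
            c = cho_factor(Kmat)
            KiY = cho_solve(c, Yv)
            Ki_x = cho_solve(c, x)
            Ki_1 = cho_solve(c, one)
        s11 = float(one @ Ki_1)
        sx1 = float(x @ Ki_1)
        sxx = float(x @ Ki_x)
        mu0 = (one @ KiY) / s11
        U = x @ KiY - mu0 * sx1
        v = mu0 * (1.0 - mu0) / 2.0
        varU = v * (sxx - sx1 * sx1 / s11)
        ok = (mu0 > 0) & (mu0 < 1) & (varU > 0)
        Tv = np.where(ok, U * U / np.where(varU > 0, varU, 1.0), np.nan)
        if estimate_dispersion:
            R = Yv - one[:, None] * mu0
            KiR = KiY - Ki_1[:, None] * mu0
            phi = np.einsum("ij,ij->j", R, KiR) / (v * (n - 1))
            Tv = np.where(phi > 0, Tv / phi, Tv)
        T[do_vec] = Tv
        pv = chi2.sf(Tv, df=1)
        p[do_vec] = np.where(np.isnan(pv), 1.0,
                             np.maximum(pv, np.finfo(float).tiny))
        sign[do_vec] = np.sign(U)

    for j in np.flatnonzero(~complete & ~mono):
        keep = ~np.isnan(Y[:, j])
        if len(np.unique(x[keep])) < 2:
            continue
        Kj = Kmat[np.ix_(keep.nonzero()[0], keep.nonzero()[0])] \
            if Kmat is not None else None
        T[j], p[j] = _gqls_core(Y[keep, j], x[keep], Kj, estimate_dispersion)

    df = gsub.marker_map.df
    return pd.DataFrame({
        "snp_id": df["snp_id"], "chromosome": df["chromosome"],
        "position_bp": df["position_bp"], "sign": sign, "T": T,
        "p_value": p, "maf": maf, "n_used": n_used, "monomorphic": mono})


# ---------------------------------------------------------------------------
# Chromosome-wise positive FDR (Storey q-values)
# ---------------------------------------------------------------------------

def storey_pi0(p: np.ndarray, min_snps_for_smoother: int = 100) -> float:
    """Smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over
    lambda = 0.05..0.95; a cubic fit evaluated at lambda = 0.95 gives the
    estimate, clipped to (0, 1].  Small sets fall back to pi0 = 1
    (the conservative Benjamini-Hochberg limit).
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m < min_snps_for_smoother:
        return 1.0
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0s = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0s, 3)
    pi0 = float(np.polyval(coef, lambdas[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def qvalues(p: np.ndarray, pi0: float | None = None,
            min_snps_for_smoother: int = 100) -> np.ndarray:
    """Storey q-values: q_(i) = min_{j >= i} pi0 * m * p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    if pi0 is None:
        pi0 = storey_pi0(p, min_snps_for_smoother)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def assign_tiers(q: np.ndarray,
                 cutoffs: tuple[float, ...] = TIER_CUTOFFS) -> np.ndarray:
    tiers = np.full(len(q), "ns", dtype=object)
    for cut in sorted(cutoffs, reverse=True):
        tiers[q <= cut] = f"{cut:g}"
    return tiers


def chromosome_pfdr(records: pd.DataFrame,
                    cutoffs: tuple[float, ...] = TIER_CUTOFFS,
                    min_snps_for_smoother: int = 100) -> pd.DataFrame:
    """Add chromosome-wise q-values and pFDR tiers to an association table."""
    records = records.copy()
    records["q_value"] = 1.0
    records["pi0"] = 1.0
    for chrom, idx in records.groupby("chromosome").groups.items():
        p = records.loc[idx, "p_value"].to_numpy()
        pi0 = storey_pi0(p, min_snps_for_smoother)
        records.loc[idx, "q_value"] = qvalues(p, pi0=pi0)
        records.loc[idx, "pi0"] = pi0
    records["pfdr_tier"] = assign_tiers(records["q_value"].to_numpy(),
                                        cutoffs)
    return records


def manhattan_table(records: pd.DataFrame, cap: float = 6.0) -> pd.DataFrame:
    """Plot-ready table with -log10(q) truncated at ``cap``.

    SNPs whose significance exceeds the truncation are flagged so a plot
    can mark them (classically drawn as triangles).
    """
    neglog = -np.log10(np.clip(records["q_value"].to_numpy(), 1e-300, None))
    return pd.DataFrame({
        "chromosome": records["chromosome"],
        "position_bp": records["position_bp"],
        "snp_id": records["snp_id"],
        "neg_log10_q": np.minimum(neglog, cap),
        "exceeds_cap": neglog > cap})
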