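"""Liability-threshold heritability: scale transformation and PQL probit fit.

A binary trait is modelled as an underlying standard-normal liability
exceeding a threshold set by the prevalence alpha.  Heritability on the
underlying (liability) scale relates to heritability computed on the
observed 0/1 scale through

    h2_obs = h2_und * w**2 / (alpha * (1 - alpha)),

where z is the standard normal deviate with upper-tail probability alpha
and w = exp(-z**2 / 2) / sqrt(2*pi) is the normal density at z
(Dempster-Lerner / Robertson).  The transformation factor is at most
2/pi and is maximised at alpha = 0.5.

``estimate_h2_pql_probit`` fits the threshold model directly to 0/1
records with an animal model (overall mean + additive genetic effect with
pedigree covariance A * sigma2_u, probit link, unit residual liability
variance) by penalised quasi-likelihood: iteratively reweighted working
responses with the variance component re-estimated by REML at each step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize_scalar
from scipy.sparse.linalg import splu
from scipy.stats import norm

from .kinship import AdditiveRelationship, Pedigree, a_inverse


class DomainError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, trace: list[float]):
        super().__init__(msg)
        self.trace = trace


@dataclass
class LiabilityEstimate:
    h2_underlying: float
    h2_observed: float
    prevalence_alpha: float
    z: float
    w: float
    se_underlying: float = float("nan")
    sigma2_u: float = float("nan")
    n_iterations: int = 0

    def to_dict(self) -> dict:
        return {k: (v if not isinstance(v, float) or np.isfinite(v) else None)
                for k, v in self.__dict__.items()}


def _zw(alpha: float) -> tuple[float, float]:
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"prevalence must lie in (0, 1), got {alpha}")
    z = norm.isf(alpha)  # threshold exceeded with probability alpha
    w = norm.pdf(z)
    return float(z), float(w)


def transformation_factor(alpha: float) -> float:
    """w^2 / (alpha (1 - alpha)); <= 2/pi, symmetric about alpha = 0.5."""
    z, w = _zw(alpha)
    return w * w / (alpha * (1.0 - alpha))


def underlying_to_observed(h2_u: float, alpha: float) -> LiabilityEstimate:
    """Transform an underlying-scale heritability to the observed 0/1 scale."""
    if not (0.0 <= h2_u <= 1.0):
        raise DomainError(f"h2_underlying must lie in [0, 1], got {h2_u}")
    z, w = _zw(alpha)
    h2_o = h2_u * w * w / (alpha * (1.0 - alpha))
    return LiabilityEstimate(h2_underlying=float(h2_u), h2_observed=float(h2_o),
                             prevalence_alpha=float(alpha), z=z, w=w)


def observed_to_underlying(h2_o: float, alpha: float) -> LiabilityEstimate:
    """Algebraic inverse of ``underlying_to_observed``."""
    if h2_o < 0.0:
        raise DomainError(f"h2_observed must be >= 0, got {h2_o}")
    z, w = _zw(alpha)
    h2_u = h2_o * alpha * (1.0 - alpha) / (w * w)
    if h2_u > 1.0 + 1e-12:
        raise DomainError(
            f"inconsistent inputs: inverting h2_obs={h2_o} at alpha={alpha} "
            f"gives h2_underlying={h2_u:.4f} > 1")
    return LiabilityEstimate(h2_underlying=float(min(h2_u, 1.0)),
                             h2_observed=float(h2_o),
                             prevalence_alpha=float(alpha), z=z, w=w)


# ---------------------------------------------------------------------------
# PQL probit animal model
# ---------------------------------------------------------------------------

def estimate_h2_pql_probit(status: pd.DataFrame,
                           kinship: Pedigree | AdditiveRelationship,
                           tol: float = 1e-6, max_iter: int = 200,
                           sigma2_init: float = 0.5,
                           sigma2_max: float = 50.0) -> LiabilityEstimate:
    """Underlying-scale heritability of a 0/1 trait by PQL with probit link.

    Parameters
    ----------
    status : DataFrame with columns (animal, status in {0,1}).
    kinship : the pedigree (preferred; the sparse A-inverse makes large
        problems fast) or a dense AdditiveRelationship covering at least
        the phenotyped animals.
    tol : convergence tolerance on successive sigma2_u values.

    The working linear mixed model at each PQL step is
    t = 1*mu + u + e with Var(u) = A sigma2_u, Var(e) = W^-1, where
    t_i = eta_i + (y_i - Phi(eta_i))/phi(eta_i) and
    w_i = phi(eta_i)^2 / (Phi(eta_i)(1 - Phi(eta_i))).  sigma2_u is
    re-estimated by 1-d REML on Henderson's mixed-model equations.
    Residual liability variance is fixed at 1 (probit identification), so
    h2 = sigma2_u / (sigma2_u + 1).

    Returns the estimate with an approximate SE (curvature of the REML
    profile, delta method) and the observed-scale value auto-filled at
    the sample prevalence.
    """
    status = status.copy()
    status["animal"] = status["animal"].astype(str)
    y = status["status"].to_numpy(dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise DomainError("both phenotype classes must be present")
    ids = status["animal"].tolist()

    if isinstance(kinship, Pedigree):
        missing = set(ids) - set(kinship.animal)
        if missing:
            raise KeyError(f"phenotyped animals absent from pedigree: "
                           f"{sorted(missing)[:5]}")
        Ainv, logdetA = a_inverse(kinship)
        all_ids = kinship.animal
    else:
        unique_ids = list(dict.fromkeys(ids))  # repeated records share one u
        sub = kinship.submatrix(unique_ids)
        Ainv = sparse.csc_matrix(np.linalg.inv(sub.A))
        logdetA = float(np.linalg.slogdet(sub.A)[1])
        all_ids = unique_ids
    q = len(all_ids)
    pos = {a: i for i, a in enumerate(all_ids)}
    zidx = np.array([pos[a] for a in ids])  # observation -> animal level
    n = len(ids)
    Z = sparse.csc_matrix((np.ones(n), (np.arange(n), zidx)), shape=(n, q))

    eta = np.full(n, norm.ppf(np.clip(y.mean(), 1e-6, 1 - 1e-6)))
    sigma2 = float(sigma2_init)
    trace: list[float] = []
    boundary_warned = False
    for it in range(1, max_iter + 1):
        eta_c = np.clip(eta, -5.0, 5.0)
        mu = np.clip(norm.cdf(eta_c), 1e-10, 1 - 1e-10)
        phi = np.maximum(norm.pdf(eta_c), 1e-10)
        w = phi * phi / (mu * (1.0 - mu))
        t = eta_c + (y - mu) / phi

        sigma2_new, sol, curv = _reml_1d(t, w, Z, Ainv, logdetA, q,
                                         sigma2_max)
        beta, u = sol
        eta = beta + u[zidx]
        trace.append(sigma2_new)
        if sigma2_new >= sigma2_max - 1e-6 and not boundary_warned:
            warnings.warn("variance estimate at upper boundary (possible "
                          "separation: cases confined to few families)")
            boundary_warned = True
        if abs(sigma2_new - sigma2) < tol:
            sigma2 = sigma2_new
            break
        sigma2 = sigma2_new
    else:
        raise ConvergenceError(
            f"PQL did not converge in {max_iter} iterations "
            f"(last sigma2 values {trace[-5:]})", trace)

    h2 = sigma2 / (sigma2 + 1.0)
    se = float("nan")
    if curv is not None and curv > 0:
        var_s2 = 1.0 / curv
        se = np.sqrt(var_s2) / (1.0 + sigma2) ** 2  # delta method
    alpha = float(y.mean())
    est = underlying_to_observed(h2, alpha)
    est.se_underlying = float(se)
    est.sigma2_u = float(sigma2)
    est.n_iterations = len(trace)
    return est


def estimate_h2_observed_reml(status: pd.DataFrame,
                              kinship: Pedigree | AdditiveRelationship,
                              ) -> LiabilityEstimate:
    """Observed-scale animal-model REML on 0/1 records, then the threshold
    transformation to the underlying scale (the classical two-step route).

    Fits y = 1*mu + u + e with Var(u) = A sigma2_u, Var(e) = sigma2_e I by
    REML (1-d profile over the variance ratio), takes
    h2_obs = sigma2_u / (sigma2_u + sigma2_e), and divides by the
    transformation factor w^2/(alpha(1-alpha)) at the sample prevalence.
    Unlike penalised quasi-likelihood this is nearly unbiased for the
    liability-scale heritability under the threshold model, because the
    0/1 analysis is a plain linear model (no link linearisation).
    """
    status = status.copy()
    status["animal"] = status["animal"].astype(str)
    y = status["status"].to_numpy(dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise DomainError("both phenotype classes must be present")
    ids = status["animal"].tolist()
    if isinstance(kinship, Pedigree):
        Ainv, logdetA = a_inverse(kinship)
        all_ids = kinship.animal
    else:
        unique_ids = list(dict.fromkeys(ids))
        sub = kinship.submatrix(unique_ids)
        Ainv = sparse.csc_matrix(np.linalg.inv(sub.A))
        logdetA = float(np.linalg.slogdet(sub.A)[1])
        all_ids = unique_ids
    q = len(all_ids)
    pos = {a: i for i, a in enumerate(all_ids)}
    zidx = np.array([pos[a] for a in ids])
    n = len(ids)
    Z = sparse.csc_matrix((np.ones(n), (np.arange(n), zidx)), shape=(n, q))
    w = np.ones(n)
    sum_y2 = float(y @ y)
    c1u = np.asarray(Z.T @ y * 0 + Z.T @ np.ones(n)).ravel()
    Cuu0 = (Z.T @ Z).tocsc()
    rhs = np.concatenate(([float(y.sum())], np.asarray(Z.T @ y).ravel()))

    def neg2profile(log_lam: float) -> float:
        lam = float(np.exp(log_lam))
        C = sparse.bmat(
            [[sparse.csc_matrix(([float(n)], ([0], [0])), shape=(1, 1)),
              sparse.csc_matrix(c1u[None, :])],
             [sparse.csc_matrix(c1u[:, None]), Cuu0 + Ainv / lam]]).tocsc()
        lu = splu(C, permc_spec="MMD_AT_PLUS_A",
                  options={"SymmetricMode": True})
        logdetC = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        sol = lu.solve(rhs)
        yPy = sum_y2 - float(rhs @ sol)
        s2e = yPy / (n - 1)
        return ((n - 1) * np.log(s2e) + q * np.log(lam) + logdetA
                + logdetC)

    res = minimize_scalar(neg2profile, bounds=(np.log(1e-6), np.log(50.0)),
                          method="bounded", options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    h2_obs = lam / (1.0 + lam)
    alpha = float(y.mean())
    # clamp at the theoretical ceiling (h2_underlying <= 1)
    h2_obs_c = min(h2_obs, transformation_factor(alpha))
    est = observed_to_underlying(h2_obs_c, alpha)
    est.sigma2_u = lam
    return est


def _reml_1d(t: np.ndarray, w: np.ndarray, Z: sparse.csc_matrix,
             Ainv: sparse.csc_matrix, logdetA: float, q: int,
             sigma2_max: float):
    """Profile REML over sigma2_u for t = 1 mu + Zu + e, Var(e) = diag(1/w).

    Uses Henderson's MME:  C = [[1'W1, 1'WZ], [Z'W1, Z'WZ + Ainv/s2]];
    -2 loglik_REML = log|D| + log|A s2| + log|C| + t' P t, with the P
    quadratic form evaluated from the MME solution.  All factorisations
    are sparse LU (no row pivoting; C is positive definite).
    """
    n = len(t)
    W = sparse.diags(w)
    ZtW = Z.T @ W
    c11 = float(w.sum())
    c1u = np.asarray(ZtW @ np.ones(n)).ravel()
    Cuu0 = (ZtW @ Z).tocsc()
    r1 = float(w @ t)
    ru = np.asarray(ZtW @ t).ravel()
    rhs = np.concatenate(([r1], ru))
    tWt = float(w @ (t * t))
    log_detD = float(-np.log(w).sum())

    cache: dict[float, tuple] = {}

    def factor(s2: float):
        key = round(s2, 12)
        if key in cache:
            return cache[key]
        C = sparse.bmat([[sparse.csc_matrix(([c11], ([0], [0])), shape=(1, 1)),
                          sparse.csc_matrix(c1u[None, :])],
                         [sparse.csc_matrix(c1u[:, None]),
                          Cuu0 + Ainv / s2]]).tocsc()
        lu = splu(C, permc_spec="MMD_AT_PLUS_A",
                  options={"SymmetricMode": True})
        logdetC = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        sol = lu.solve(rhs)
        cache[key] = (sol, logdetC)
        return cache[key]

    def neg2loglik(log_s2: float) -> float:
        s2 = float(np.exp(log_s2))
        sol, logdetC = factor(s2)
        yPy = tWt - float(rhs @ sol)
        return (log_detD + q * np.log(s2) + logdetA + logdetC + yPy)

    res = minimize_scalar(neg2loglik,
                          bounds=(np.log(1e-6), np.log(sigma2_max)),
                          method="bounded",
                          options={"xatol": 1e-8})
    s2_hat = float(np.exp(res.x))
    sol, _ = factor(s2_hat)
    beta, u = float(sol[0]), sol[1:]

    # curvature of -2 loglik / 2 wrt sigma2 (central difference on log scale)
    h = 0.05
    try:
        f0 = res.fun
        fp = neg2loglik(res.x + h)
        fm = neg2loglik(res.x - h)
        d2_log = (fp - 2.0 * f0 + fm) / (h * h) / 2.0  # loglik curvature
        # convert d2/d(log s2)^2 -> d2/d(s2)^2 at optimum (gradient ~ 0)
        curv = d2_log / (s2_hat * s2_hat) if d2_log > 0 else None
    except Exception:
        curv = None
    return s2_hat, (beta, u), curv
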