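"""One-factor confirmatory factor analysis by maximum likelihood.

Model: ``Sigma(theta) = lambda lambda' + diag(psi)`` with the factor variance
fixed at 1.  The ML discrepancy

    F_ML = log|Sigma| + tr(S Sigma^-1) - log|S| - p

is minimized by an EM iteration (closed-form updates, batched over many
covariance matrices for bootstrap work) followed by a quasi-Newton polish
with analytic gradients.  ``chi2 = (n - 1) F_ML`` at the optimum.

Fit indices (CFI against the independence baseline, RMSEA with a 90%
noncentral-chi-square confidence interval, SRMR including the diagonal) and
coefficient omega ``(sum lambda)^2 / ((sum lambda)^2 + sum psi)`` with a BCa
bootstrap interval are provided on the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bootstrap import _bca_endpoints

__all__ = [
    "OneFactorCFA",
    "CFAResults",
    "FitIndices",
    "fit_one_factor_cfa",
    "compute_fit_indices",
    "omega_from_fit",
]

_PSI_FLOOR = 1e-6


def _fml_batch(S, lam, psi, logdet_S):
    """ML discrepancy for batches, via the Woodbury/determinant identities."""
    w = lam / psi
    alpha = 1.0 + (lam * w).sum(axis=-1)
    logdet_sigma = np.log(psi).sum(axis=-1) + np.log(alpha)
    diag_S = np.diagonal(S, axis1=-2, axis2=-1)
    Sw = np.einsum("...ij,...j->...i", S, w)
    tr = (diag_S / psi).sum(axis=-1) - (w * Sw).sum(axis=-1) / alpha
    p = S.shape[-1]
    return logdet_sigma + tr - logdet_S - p


def _em_batch(S, lam, psi, logdet_S, tol=1e-10, max_iter=5000):
    """Batched EM for the one-factor model. Arrays: S (..., p, p);
    lam, psi (..., p). Returns (lam, psi, fml, converged)."""
    S = np.asarray(S, dtype=float)
    lam = np.array(lam, dtype=float, copy=True)
    psi = np.array(psi, dtype=float, copy=True)
    f = _fml_batch(S, lam, psi, logdet_S)
    diag_S = np.diagonal(S, axis1=-2, axis2=-1)
    converged = np.zeros(f.shape, dtype=bool)
    for _ in range(max_iter):
        w = lam / psi
        alpha = 1.0 + (lam * w).sum(axis=-1, keepdims=True)
        beta = w / alpha
        g = np.einsum("...ij,...j->...i", S, beta)        # S beta'
        delta = (1.0 - (beta * lam).sum(axis=-1, keepdims=True)
                 + (beta * g).sum(axis=-1, keepdims=True))
        lam_new = g / delta
        psi_new = np.maximum(diag_S - lam_new * g, _PSI_FLOOR)
        f_new = _fml_batch(S, lam_new, psi_new, logdet_S)
        # EM is monotone; only accept improving updates (guards the psi floor)
        improve = f_new <= f
        lam = np.where(improve[..., None], lam_new, lam)
        psi = np.where(improve[..., None], psi_new, psi)
        newly = improve & (f - f_new < tol)
        converged |= newly | ~improve
        f = np.where(improve, f_new, f)
        if converged.all():
            break
    return lam, psi, f, converged


def _polish(S, lam, psi, logdet_S):
    """Quasi-Newton refinement of a single fit with analytic gradients."""
    p = S.shape[0]

    def fun(x):
        lam_, psi_ = x[:p], x[p:]
        Sigma = np.outer(lam_, lam_) + np.diag(psi_)
        try:
            Sinv = np.linalg.inv(Sigma)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(2 * p)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return np.inf, np.zeros(2 * p)
        f = logdet + np.trace(S @ Sinv) - logdet_S - p
        A = Sinv @ (Sigma - S) @ Sinv
        grad = np.concatenate([2.0 * A @ lam_, np.diag(A)])
        return f, grad

    x0 = np.concatenate([lam, psi])
    bounds = [(None, None)] * p + [(_PSI_FLOOR, None)] * p
    res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"ftol": 1e-14, "gtol": 1e-10,
                                     "maxiter": 500})
    return res.x[:p], res.x[p:], float(res.fun)


@dataclass
class FitIndices:
    """Covariance-structure fit indices."""
    cfi: float
    rmsea: float
    rmsea_ci: tuple
    srmr: float
    chi2: float
    df: int
    pvalue: float
    chi2_baseline: float
    df_baseline: int
    rmsea_undefined: bool = False


class CFAResults:
    """Fitted one-factor model.

    Attributes
    ----------
    loadings, uniquenesses : ndarray
        ML estimates on the input covariance scale.
    std_loadings : ndarray
        Loadings standardized by the model-implied item variances.
    fml, chi2, df, n, converged : solution diagnostics.
    """

    def __init__(self, model, lam, psi, fml, converged, n_starts_used):
        self.model = model
        self.loadings = lam
        self.uniquenesses = psi
        self.fml = fml
        self.converged = converged
        self.n_starts_used = n_starts_used
        self.S = model.S
        self.n = model.n
        self.p = model.p
        self.Sigma = np.outer(lam, lam) + np.diag(psi)
        self.df = self.p * (self.p + 1) // 2 - 2 * self.p
        self.chi2 = max((self.n - 1) * fml, 0.0)
        self.std_loadings = lam / np.sqrt(np.diag(self.Sigma))

    @property
    def omega(self) -> float:
        return omega_from_fit(self)

    def fit_indices(self, ci_level: float = 0.90) -> FitIndices:
        return compute_fit_indices(self, ci_level=ci_level)

    def omega_ci(self, B: int = 1000, level: float = 0.95, seed=None):
        """BCa bootstrap confidence interval for omega (resampling
        respondents; requires the model to hold raw data)."""
        X = self.model.data
        if X is None:
            raise ValueError("omega_ci requires raw item responses; the "
                             "model was built from a covariance matrix")
        lo, hi, _, _ = _omega_bca(X, self.loadings, self.uniquenesses,
                                  B=B, level=level, seed=seed)
        return lo, hi

    def summary(self) -> str:
        fi = self.fit_indices()
        lines = [
            "One-factor CFA (ML)",
            f"  items: {self.p}   n: {self.n}   converged: {self.converged}",
            f"  chi2({self.df}) = {self.chi2:.2f}, p = {fi.pvalue:.4f}",
            f"  CFI = {fi.cfi:.3f}   RMSEA = {fi.rmsea:.3f} "
            f"[{fi.rmsea_ci[0]:.3f}, {fi.rmsea_ci[1]:.3f}]   "
            f"SRMR = {fi.srmr:.3f}",
            f"  omega = {self.omega:.3f}",
            "  standardized loadings: "
            + ", ".join(f"{x:.3f}" for x in self.std_loadings),
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        fi = self.fit_indices()
        return pd.DataFrame([{
            "chi2": self.chi2, "df": self.df, "pvalue": fi.pvalue,
            "cfi": fi.cfi, "rmsea": fi.rmsea,
            "rmsea_lo": fi.rmsea_ci[0], "rmsea_hi": fi.rmsea_ci[1],
            "srmr": fi.srmr, "omega": self.omega, "n": self.n,
        }])


class OneFactorCFA:
    """One-factor covariance-structure model for an item battery.

    Parameters
    ----------
    item_matrix : (n, p) array or DataFrame
        Raw item responses, ``p >= 3`` and ``n > p``.
    """

    def __init__(self, item_matrix):
        X = np.asarray(item_matrix, dtype=float)
        if X.ndim != 2:
            raise ValueError("item_matrix must be 2-dimensional")
        n, p = X.shape
        if p < 3:
            raise ValueError("need at least 3 items")
        if n <= p:
            raise ValueError("need more respondents than items")
        if np.isnan(X).any():
            raise ValueError("item matrix contains missing values")
        self.data = X
        self.n = n
        self.p = p
        self.S = np.cov(X, rowvar=False, ddof=1)
        self._check_S()

    @classmethod
    def from_covariance(cls, S, n):
        """Build the model from a covariance matrix (no raw data)."""
        obj = cls.__new__(cls)
        S = np.asarray(S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        obj.data = None
        obj.S = S
        obj.n = int(n)
        obj.p = S.shape[0]
        obj._check_S()
        return obj

    def _check_S(self):
        sign, _ = np.linalg.slogdet(self.S)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "sample covariance matrix is singular")

    def _starts(self, seed):
        S = self.S
        d = np.sqrt(np.diag(S))
        rng = np.random.default_rng(seed)
        starts = []
        # Principal-axis start from squared-multiple-correlation communality
        Sinv = np.linalg.inv(S)
        smc = np.clip(1.0 - 1.0 / (np.diag(Sinv) * np.diag(S)), 0.05, 0.95)
        psi0 = np.diag(S) * (1.0 - smc)
        evals, evecs = np.linalg.eigh(S - np.diag(psi0))
        lam0 = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-3))
        starts.append((lam0, psi0))
        # Null start: lambda = 0 is a stationary point; it can only win when
        # the independence structure genuinely fits best, and then prevents
        # an arbitrary point on the unidentified loading ridge being kept.
        starts.append((np.zeros(self.p), np.diag(S).copy()))
        for _ in range(3):
            lam_r = rng.uniform(0.2, 0.9, self.p) * d
            psi_r = np.diag(S) * rng.uniform(0.3, 0.8, self.p)
            starts.append((lam_r, psi_r))
        return starts

    def fit(self, tol: float = 1e-8, max_iter: int = 5000,
            seed: int = 0) -> CFAResults:
        """Fit by ML from a principal-axis start plus three random starts;
        the solution with the lowest discrepancy is kept (ties within
        1e-10)."""
        _, logdet_S = np.linalg.slogdet(self.S)
        candidates = []
        for lam0, psi0 in self._starts(seed):
            lam, psi, f, conv = _em_batch(self.S, lam0, psi0, logdet_S,
                                          tol=min(tol, 1e-10) * 0.1,
                                          max_iter=max_iter)
            if np.any(np.abs(lam) > 1e-12):
                lam, psi, f = _polish(self.S, lam, psi, logdet_S)
            candidates.append((lam, psi, f, bool(conv)))
        n_used = len(candidates)
        f_min = min(c[2] for c in candidates)
        # ties (within 1e-10) broken toward the most parsimonious solution
        tied = [c for c in candidates if c[2] <= f_min + 1e-10]
        lam, psi, f, conv = min(tied, key=lambda c: (c[0] ** 2).sum())
        if lam.sum() < 0:
            lam = -lam
        f = max(f, 0.0)
        return CFAResults(self, lam, psi, f, conv, n_used)


def fit_one_factor_cfa(item_matrix, **kwargs) -> CFAResults:
    """Convenience wrapper: ``OneFactorCFA(item_matrix).fit()``."""
    return OneFactorCFA(item_matrix).fit(**kwargs)


def _baseline_chi2(S, n):
    """Independence model: free variances, zero covariances."""
    _, logdet_S = np.linalg.slogdet(S)
    f_b = np.log(np.diag(S)).sum() - logdet_S
    p = S.shape[0]
    return max((n - 1) * f_b, 0.0), p * (p - 1) // 2


def _ncp_ci(chi2, df, level=0.90):
    """Invert the noncentral chi-square CDF for the RMSEA interval."""
    lo_q, hi_q = (1.0 + level) / 2.0, (1.0 - level) / 2.0
    upper_cap = max(10.0 * chi2 + 100.0, 1e3)

    def solve(target):
        f = lambda nc: stats.ncx2.cdf(chi2, df, nc) - target
        if f(0.0) < 0:      # even ncp=0 puts chi2 below the target quantile
            return 0.0
        if f(upper_cap) > 0:
            return upper_cap
        return optimize.brentq(f, 0.0, upper_cap, xtol=1e-10)

    return solve(lo_q), solve(hi_q)


def compute_fit_indices(fit: CFAResults, ci_level: float = 0.90
                        ) -> FitIndices:
    """CFI, RMSEA (with noncentral-chi-square CI) and SRMR for a fit."""
    chi2, df, n = fit.chi2, fit.df, fit.n
    chi2_b, df_b = _baseline_chi2(fit.S, n)
    num = max(chi2 - df, 0.0)
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - num / denom if denom > 0 else 1.0
    undefined = df == 0
    if undefined:
        rmsea, ci = float("nan"), (float("nan"), float("nan"))
    else:
        rmsea = np.sqrt(num / (df * (n - 1)))
        nc_lo, nc_hi = _ncp_ci(chi2, df, ci_level)
        ci = (np.sqrt(nc_lo / (df * (n - 1))),
              np.sqrt(nc_hi / (df * (n - 1))))
    d = np.sqrt(np.diag(fit.S))
    resid = (fit.S - fit.Sigma) / np.outer(d, d)
    iu = np.triu_indices(fit.p)
    srmr = np.sqrt((resid[iu] ** 2).mean())
    pvalue = stats.chi2.sf(chi2, df) if df > 0 else float("nan")
    return FitIndices(float(cfi), float(rmsea), ci, float(srmr),
                      float(chi2), int(df), float(pvalue),
                      float(chi2_b), int(df_b), undefined)


def omega_from_fit(fit) -> float:
    """Coefficient omega: ``(sum lam)^2 / ((sum lam)^2 + sum psi)``."""
    s = fit.loadings.sum()
    if np.allclose(fit.loadings, 0.0):
        warnings.warn("all loadings are zero; omega = 0", stacklevel=2)
        return 0.0
    return float(s ** 2 / (s ** 2 + fit.uniquenesses.sum()))


def _omega_of(lam, psi):
    s = lam.sum(axis=-1)
    return s ** 2 / (s ** 2 + psi.sum(axis=-1))


def _batch_cov(X, idx):
    """Covariance matrices of X[idx_b] for each row of idx. idx: (B, n)."""
    Xb = X[idx]                                # (B, n, p)
    Xb = Xb - Xb.mean(axis=1, keepdims=True)
    n = idx.shape[1]
    return np.einsum("bij,bik->bjk", Xb, Xb) / (n - 1)


def _jackknife_cov(X):
    """Leave-one-out covariance matrices, vectorized by downdating."""
    n, p = X.shape
    m = X.mean(axis=0)
    T = X.T @ X
    m_i = (n * m[None, :] - X) / (n - 1)       # (n, p)
    outer_x = np.einsum("ij,ik->ijk", X, X)
    outer_m = np.einsum("ij,ik->ijk", m_i, m_i)
    return (T[None] - outer_x - (n - 1) * outer_m) / (n - 2)


def _omega_bca(X, lam_hat, psi_hat, B=1000, level=0.95, seed=None):
    """BCa interval for omega with all CFA refits run through the batched
    EM solver, warm-started at the full-sample solution."""
    n, p = X.shape
    rng = np.random.default_rng(seed)
    theta_hat = _omega_of(lam_hat, psi_hat)

    idx = rng.integers(0, n, size=(B, n))
    S_boot = _batch_cov(X, idx)
    S_all = np.concatenate([S_boot, _jackknife_cov(X)], axis=0)
    sign, logdet = np.linalg.slogdet(S_all)
    ok = sign > 0
    lam0 = np.broadcast_to(lam_hat, (S_all.shape[0], p))
    psi0 = np.broadcast_to(psi_hat, (S_all.shape[0], p))
    lam, psi, f, conv = _em_batch(S_all[ok], lam0[ok], psi0[ok],
                                  logdet[ok], tol=1e-11, max_iter=3000)
    omegas = np.full(S_all.shape[0], theta_hat)
    omegas[ok] = _omega_of(lam, psi)
    boot, jack = omegas[:B], omegas[B:]
    return _bca_endpoints(theta_hat, boot, jack, level)
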