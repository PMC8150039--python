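"""Decomposed-variance analysis of a specification curve.

Fits the crossed random-effects *null model*

    beta_i = mu + u_outcome(i) + u_predictor(i) + u_covset(i) + u_subset(i)
             + e_i

to the curve's effect sizes, with independent zero-mean random effects per
analytic-decision class, by restricted maximum likelihood (EM iterations
warm-started at a method-of-moments estimate, then a bounded quasi-Newton
polish of the REML objective; tolerance 1e-8 on the log-likelihood).
Negative components are truncated at zero.

Outputs are the raw intraclass correlation coefficients
``ICC_k = sigma2_k / (sum_j sigma2_j + sigma2_e)`` and the class-normalized
shares ``sigma2_k / sum_j sigma2_j`` (summing to 100% over the decision
classes, residual excluded), which are the headline quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "VarianceComponentsResults",
    "CurveVarianceDecomposition",
    "decompose_variance",
    "rerun_without_predictor",
    "DEFAULT_CLASSES",
]

DEFAULT_CLASSES = {
    "outcome": "outcome",
    "predictor": "predictor",
    "covariates": "covariates",
    "outliers": "outliers",
}


class _Design:
    """Indicator matrices per decision class."""

    def __init__(self, y, labels):
        self.y = np.asarray(y, dtype=float)
        self.n = self.y.size
        self.classes = list(labels)
        self.Z = {}
        self.levels = {}
        for k, lab in labels.items():
            lab = np.asarray(lab)
            levs, idx = np.unique(lab, return_inverse=True)
            Z = np.zeros((self.n, levs.size))
            Z[np.arange(self.n), idx] = 1.0
            self.Z[k] = Z
            self.levels[k] = levs
        self.estimable = [k for k in self.classes
                          if self.levels[k].size >= 2]


def _mom_start(d: _Design):
    """Method-of-moments warm start for a (near-)balanced crossed grid:
    equate observed level-mean variances and the total variance to their
    expectations and solve the linear system (clipped at zero)."""
    ks = d.estimable
    K = len(ks)
    A = np.zeros((K + 1, K + 1))
    b = np.zeros(K + 1)
    y = d.y
    for i, k in enumerate(ks):
        Z = d.Z[k]
        counts = Z.sum(axis=0)
        means = (Z.T @ y) / counts
        b[i] = means.var(ddof=1) if means.size > 1 else 0.0
        for j, kj in enumerate(ks):
            if j == i:
                A[i, j] = 1.0
            else:
                A[i, j] = 1.0 / d.levels[kj].size
        A[i, K] = 1.0 / counts.mean()
    A[K, :K] = 1.0
    A[K, K] = 1.0
    b[K] = y.var(ddof=1)
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        sol = np.full(K + 1, y.var(ddof=1) / (K + 1))
    floor = max(y.var(ddof=1), 1e-12)
    return {k: float(max(sol[i], 1e-4 * floor)) for i, k in enumerate(ks)}, \
        float(max(sol[K], 1e-4 * floor))


def _reml_pieces(d: _Design, sig, sig_e):
    """REML log-likelihood, P-projected quantities via Woodbury on the
    stacked indicator matrix."""
    ks = d.estimable
    W = np.concatenate([d.Z[k] for k in ks], axis=1)
    q_sizes = [d.levels[k].size for k in ks]
    g = np.concatenate([np.full(q, sig[k]) for k, q in zip(ks, q_sizes)])
    n = d.n
    WtW = W.T @ W
    M = np.diag(sig_e / g) + WtW
    Mi = np.linalg.inv(M)
    # V^-1 x = (x - W Mi W' x) / sig_e
    y = d.y
    ones = np.ones(n)

    def vinv(x):
        return (x - W @ (Mi @ (W.T @ x))) / sig_e

    Vy = vinv(y)
    V1 = vinv(ones)
    s11 = ones @ V1
    Py = Vy - V1 * (ones @ Vy) / s11
    sign, logdet_M = np.linalg.slogdet(M)
    with np.errstate(invalid="ignore", divide="ignore"):
        logdet_V = n * np.log(sig_e) + logdet_M + np.log(g).sum() \
            - g.size * np.log(sig_e)
        ll = -0.5 * (logdet_V + np.log(s11) + y @ Py)
    if not np.isfinite(ll):
        ll = -1e30
    # P W for traces
    VW = (W - W @ (Mi @ WtW)) / sig_e
    PW = VW - np.outer(V1, (ones @ VW)) / s11
    return ll, Py, PW, W, ks, q_sizes


def _reml_grad(d, sig, sig_e):
    ll, Py, PW, W, ks, q_sizes = _reml_pieces(d, sig, sig_e)
    grads = {}
    offset = 0
    for k, q in zip(ks, q_sizes):
        Zk = d.Z[k]
        tr = float((Zk * PW[:, offset:offset + q]).sum())
        quad = float(((Zk.T @ Py) ** 2).sum())
        grads[k] = -0.5 * (tr - quad)
        offset += q
    return ll, grads, Py


def _trace_P(d, sig, sig_e):
    ks = d.estimable
    W = np.concatenate([d.Z[k] for k in ks], axis=1)
    q_sizes = [d.levels[k].size for k in ks]
    g = np.concatenate([np.full(q, sig[k]) for k, q in zip(ks, q_sizes)])
    M = np.diag(sig_e / g) + W.T @ W
    Mi = np.linalg.inv(M)
    n = d.n
    ones = np.ones(n)
    trV = (n - float((W @ Mi * W).sum())) / sig_e
    V1 = (ones - W @ (Mi @ W.sum(axis=0))) / sig_e
    s11 = ones @ V1
    return trV - float(V1 @ V1) / s11


@dataclass
class VarianceComponentsResults:
    """REML variance components of curve effect sizes by decision class."""
    components: dict
    residual: float
    icc: dict
    shares: dict
    loglik: float
    converged: bool
    method: str
    n: int
    degenerate: bool = False
    levels: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": k, "sigma2": v, "icc": self.icc[k],
                 "share": self.shares[k], "n_levels": self.levels.get(k)}
                for k, v in self.components.items()]
        rows.append({"class": "residual", "sigma2": self.residual,
                     "icc": self.residual / self._total()
                     if self._total() > 0 else 0.0,
                     "share": float("nan"), "n_levels": None})
        return pd.DataFrame(rows)

    def _total(self):
        return sum(self.components.values()) + self.residual

    def summary(self) -> str:
        lines = ["Decomposed variance (crossed random-effects null model, "
                 f"REML; n = {self.n} effect sizes)"]
        for k, v in self.components.items():
            lines.append(f"  {k:<12} sigma2 = {v:.6f}   ICC = "
                         f"{self.icc[k]:.3f}   share = "
                         f"{100 * self.shares[k]:.1f}%")
        lines.append(f"  residual     sigma2 = {self.residual:.6f}")
        if self.degenerate:
            lines.append("  note: all effect sizes identical; shares "
                         "defined as 0")
        return "\n".join(lines)

    def plot(self, **kwargs):
        from .plots import plot_variance_shares
        return plot_variance_shares(self, **kwargs)


class CurveVarianceDecomposition:
    """Random-effects decomposition model for a curve's effect sizes.

    Parameters
    ----------
    results : DataFrame or SpecificationCurveResults
        Must contain a ``beta`` column and one label column per decision
        class.
    classes : dict, optional
        ``{class name: label column}``; defaults to the four SCA decision
        classes (outcome, predictor, covariate set, outlier subset).
    """

    def __init__(self, results, classes: dict | None = None):
        if hasattr(results, "results"):
            results = results.results
        self.frame = results
        self.classes = dict(classes) if classes is not None \
            else dict(DEFAULT_CLASSES)
        if "beta" not in results.columns:
            raise KeyError("results need a 'beta' column")
        labels = {}
        for k, col in self.classes.items():
            if col not in results.columns:
                raise KeyError(f"label column {col!r} missing")
            labels[k] = results[col].to_numpy()
        self.design = _Design(results["beta"].to_numpy(), labels)

    def fit(self, tol: float = 1e-8, max_em: int = 200,
            ) -> VarianceComponentsResults:
        d = self.design
        y = d.y
        var_y = y.var(ddof=1) if d.n > 1 else 0.0
        levels = {k: int(d.levels[k].size) for k in d.classes}
        if var_y <= 1e-14 or not d.estimable:
            comps = {k: 0.0 for k in d.classes}
            return VarianceComponentsResults(
                comps, 0.0, {k: 0.0 for k in d.classes},
                {k: 0.0 for k in d.classes}, 0.0, True, "degenerate",
                d.n, degenerate=True, levels=levels)

        sig, sig_e = _mom_start(d)
        method = "reml-em+qn"
        converged = True
        # EM-REML: sigma2_k <- sigma2_k + (sigma2_k^2/q_k)(y'PQ_kPy - tr(PQ_k))
        # where the bracket equals twice the REML gradient.
        ll_old = -np.inf
        for _ in range(max_em):
            ll, grads, Py = _reml_grad(d, sig, sig_e)
            trP = _trace_P(d, sig, sig_e)
            ge = -0.5 * (trP - float(Py @ Py))
            for k in d.estimable:
                q = d.levels[k].size
                sig[k] = max(sig[k] + (sig[k] ** 2 / q) * 2.0 * grads[k],
                             1e-12 * var_y)
            sig_e = max(sig_e + (sig_e ** 2 / d.n) * 2.0 * ge,
                        1e-12 * var_y)
            if abs(ll - ll_old) < tol:
                break
            ll_old = ll

        # Quasi-Newton polish on the REML objective
        ks = d.estimable
        x0 = np.array([sig[k] for k in ks] + [sig_e])
        lb = 1e-12 * var_y

        def negll(x):
            s = {k: max(v, lb) for k, v in zip(ks, x[:-1])}
            se = max(x[-1], lb)
            ll, grads, Py = _reml_grad(d, s, se)
            trP = _trace_P(d, s, se)
            ge = -0.5 * (trP - float(Py @ Py))
            grad = np.array([grads[k] for k in ks] + [ge])
            return -ll, -grad

        try:
            res = optimize.minimize(
                negll, x0, jac=True, method="L-BFGS-B",
                bounds=[(lb, None)] * (len(ks) + 1),
                options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500})
            x = res.x
            loglik = -float(res.fun)
        except Exception:
            warnings.warn("REML optimization failed; falling back to "
                          "method-of-moments estimates", stacklevel=2)
            sig, sig_e = _mom_start(d)
            x = np.array([sig[k] for k in ks] + [sig_e])
            loglik = float("nan")
            method = "method-of-moments"
            converged = False

        comps = {k: 0.0 for k in d.classes}
        for k, v in zip(ks, x[:-1]):
            comps[k] = float(v) if v > 2.0 * lb else 0.0
        resid = float(x[-1]) if x[-1] > 2.0 * lb else 0.0
        total = sum(comps.values()) + resid
        icc = {k: (v / total if total > 0 else 0.0)
               for k, v in comps.items()}
        class_total = sum(comps.values())
        shares = {k: (v / class_total if class_total > 0 else 0.0)
                  for k, v in comps.items()}
        return VarianceComponentsResults(
            comps, resid, icc, shares, loglik, converged, method,
            d.n, degenerate=False, levels=levels)


def decompose_variance(results, classes: dict | None = None,
                       **fit_kwargs) -> VarianceComponentsResults:
    """Functional wrapper: fit the crossed random-effects null model."""
    return CurveVarianceDecomposition(results, classes).fit(**fit_kwargs)


def rerun_without_predictor(results, excluded: str,
                            classes: dict | None = None
                            ) -> VarianceComponentsResults:
    """Decompose the curve again with one predictor operationalization
    removed (anomaly diagnostics)."""
    if hasattr(results, "results"):
        results = results.results
    if excluded not in set(results["predictor"]):
        raise KeyError(f"predictor {excluded!r} not present")
    kept = results.loc[results["predictor"] != excluded]
    if kept["predictor"].nunique() < 1 or len(kept) == 0:
        raise ValueError("filter removed every specification")
    return CurveVarianceDecomposition(kept, classes).fit()
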