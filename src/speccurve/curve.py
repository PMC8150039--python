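"""Specification-curve engine.

Enumerates every justifiable analysis specification for the dysregulated
gaming / well-being relationship -- outcome operationalization (3) x
predictor operationalization (9) x covariate set (18: none, each single
covariate, all 16) x outlier handling (include/exclude) = 972 ordinary
least-squares models -- fits them all, and summarizes the resulting curve
of standardized coefficients.

Per model, the outcome and all continuous variables are z-scored within the
model's analysis subset; categorical covariates (gender, education) enter as
indicator contrasts and are left unstandardized.  The focal effect size is
the standardized coefficient of the dysregulation measure, with its 95%
t-interval, two-sided p, multiple R^2 and semipartial Delta R^2 (computed by
a full refit without the focal predictor).

The curve summary reports the median/min/max effect and the *median-model*
confidence interval: the CI of the individual model holding the central-most
estimate, or, for an even model count, the interval built from the mean of
the two central estimates and the mean of their standard errors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import scales as scl

__all__ = [
    "Specification",
    "SpecificationSpace",
    "CurveSummary",
    "SpecificationCurve",
    "SpecificationCurveResults",
    "build_default_space",
    "fit_specification",
    "run_curve",
    "summarize_curve",
    "power_bivariate",
    "correlation_matrix",
]

# Design-matrix blocks for categorical covariates (reference levels female /
# tertiary education).
_CATEGORICAL_BLOCKS = {
    "gender": ("gender_male", "gender_other"),
    "education": ("education_secondary",),
}
# Only the male contrast is summarized; the sparse third category stays in
# the model but is not reported in the covariate table.
_REPORTED_DUMMY = {"gender": "gender_male", "education": "education_secondary"}


@dataclass(frozen=True)
class Specification:
    """One analytic choice tuple."""
    outcome: str
    predictor: str
    covariates: tuple
    outliers: str  # "include" | "exclude"

    def __post_init__(self):
        if self.predictor in self.covariates:
            raise ValueError("focal predictor cannot also be a covariate")
        if self.outliers not in ("include", "exclude"):
            raise ValueError("outliers must be 'include' or 'exclude'")


@dataclass
class SpecificationSpace:
    """The four decision axes of the curve."""
    outcomes: list
    predictors: list
    covariate_sets: list
    outlier_choices: list = field(
        default_factory=lambda: ["include", "exclude"])

    def __post_init__(self):
        for name in ("outcomes", "predictors", "covariate_sets",
                     "outlier_choices"):
            if not getattr(self, name):
                raise ValueError(f"specification axis {name!r} is empty")
        self.covariate_sets = [tuple(c) for c in self.covariate_sets]
        if len(set(self.covariate_sets)) != len(self.covariate_sets):
            raise ValueError("covariate sets must be distinct")

    def __len__(self):
        return (len(self.outcomes) * len(self.predictors)
                * len(self.covariate_sets) * len(self.outlier_choices))

    def enumerate(self) -> list:
        """Deterministic lexicographic Cartesian product."""
        return [Specification(o, p, c, s)
                for o, p, c, s in itertools.product(
                    self.outcomes, self.predictors,
                    self.covariate_sets, self.outlier_choices)]


def enumerate_specifications(space: SpecificationSpace) -> list:
    return space.enumerate()


def build_default_space(scored: pd.DataFrame,
                        item_level: bool = False) -> SpecificationSpace:
    """The study's default space: 3 outcomes x 9 predictors x 18 covariate
    sets x 2 outlier choices.  In ``item_level`` mode the predictors are the
    15 single items of the 11-item CVAT-2 plus the ICD-11."""
    outcomes = scl.outcome_names()
    if item_level:
        battery = scl.default_scales()
        predictors = (list(battery["cvat2_11"].items)
                      + list(battery["icd11"].items))
    else:
        predictors = scl.predictor_scale_names()
    covs = scl.covariate_names()
    covariate_sets = [()] + [(c,) for c in covs] + [tuple(covs)]
    for col in outcomes + predictors:
        if col not in scored.columns:
            raise KeyError(f"column {col!r} missing from scored dataset")
    return SpecificationSpace(outcomes, predictors, covariate_sets)


# --------------------------------------------------------------------------
# Fitting machinery.

class _Subset:
    """Pre-standardized analysis subset (include or exclude outliers)."""

    def __init__(self, scored: pd.DataFrame, exclude_outliers: bool):
        df = scored
        if exclude_outliers:
            df = scored.loc[~scored["playtime_outlier"].astype(bool)]
        self.n = len(df)
        self.columns = {}
        self.zero_variance = set()
        for col in df.columns:
            if col in ("respondent_id", "playtime_outlier"):
                continue
            if col == "gender":
                g = df["gender"].astype(str).to_numpy()
                self.columns["gender_male"] = (g == "male").astype(float)
                self.columns["gender_other"] = (g == "other").astype(float)
                for dummy in ("gender_male", "gender_other"):
                    if self.columns[dummy].std() == 0:
                        self.zero_variance.add(dummy)
            elif col == "education":
                e = df["education"].astype(str).to_numpy()
                self.columns["education_secondary"] = \
                    (e == "secondary").astype(float)
                if self.columns["education_secondary"].std() == 0:
                    self.zero_variance.add("education_secondary")
            else:
                x = df[col].to_numpy(dtype=float)
                sd = x.std(ddof=1)
                if sd == 0:
                    self.zero_variance.add(col)
                    self.columns[col] = np.zeros_like(x)
                else:
                    self.columns[col] = (x - x.mean()) / sd

    def design(self, names):
        return np.column_stack([np.ones(self.n)]
                               + [self.columns[c] for c in names])


def _cov_block(name):
    return list(_CATEGORICAL_BLOCKS.get(name, (name,)))


def _ols(X, y):
    """Least squares with coefficient covariance; returns (beta, se, rss)."""
    n, k = X.shape
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < k:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - k)
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
    return beta, se, rss


@dataclass
class SpecResult:
    """A fitted specification."""
    specification: Specification
    beta: float
    se: float
    ci: tuple
    pvalue: float
    df_resid: int
    r2: float
    delta_r2: float
    n: int
    covariate_stats: list = field(default_factory=list)
    # covariate_stats rows: (variable, coef, se, df_resid, delta_r2,
    #                        standardized)


def _fit_from_subset(sub: _Subset, spec: Specification,
                     covariate_detail: bool = True) -> SpecResult:
    if spec.predictor in sub.zero_variance:
        raise ZeroDivisionError(
            f"focal predictor {spec.predictor!r} has zero variance in the "
            f"{spec.outliers} subset")
    y = sub.columns[spec.outcome]
    # covariate columns that are empty/constant within this subset (e.g. an
    # unobserved sparse gender level) are dropped from the design
    cov_cols = []
    for c in spec.covariates:
        cov_cols.extend(x for x in _cov_block(c)
                        if x not in sub.zero_variance)
    names = [spec.predictor] + cov_cols
    X = sub.design(names)
    try:
        beta, se, rss = _ols(X, y)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"rank-deficient design for {spec}; columns: {names}")
    n, k = X.shape
    dof = n - k
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    tcrit = stats.t.ppf(0.975, dof)
    b, s = float(beta[1]), float(se[1])
    pval = 2.0 * stats.t.sf(abs(b / s), dof)
    # semipartial Delta R^2 by full refit without the focal predictor
    X0 = sub.design(cov_cols)
    _, _, rss0 = _ols(X0, y)
    delta = (rss0 - rss) / tss
    cov_stats = []
    if covariate_detail and spec.covariates:
        col_index = {name: i + 1 for i, name in enumerate(names)}
        for c in spec.covariates:
            block = [x for x in _cov_block(c) if x in col_index]
            reported = _REPORTED_DUMMY.get(c, c)
            if not block or reported not in col_index:
                continue
            keep = [spec.predictor] + [x for x in cov_cols
                                       if x not in block]
            _, _, rss_c = _ols(sub.design(keep), y)
            d_c = (rss_c - rss) / tss
            j = col_index[reported]
            cov_stats.append((c, float(beta[j]), float(se[j]), dof,
                              float(d_c), c not in _CATEGORICAL_BLOCKS))
    return SpecResult(
        specification=spec, beta=b, se=s,
        ci=(b - tcrit * s, b + tcrit * s), pvalue=float(pval),
        df_resid=dof, r2=float(r2), delta_r2=float(delta), n=n,
        covariate_stats=cov_stats)


def fit_specification(scored: pd.DataFrame, spec: Specification,
                      covariate_detail: bool = True) -> SpecResult:
    """Fit a single specification on the scored dataset."""
    sub = _Subset(scored, exclude_outliers=(spec.outliers == "exclude"))
    return _fit_from_subset(sub, spec, covariate_detail)


# --------------------------------------------------------------------------
# Model / Results objects.

class SpecificationCurve:
    """Specification-curve model over a scored dataset.

    Parameters
    ----------
    scored : DataFrame
        Output of :func:`speccurve.cleaning.score_dataset` (must contain a
        boolean ``playtime_outlier`` column).
    space : SpecificationSpace, optional
        Defaults to the study's 972-model space.
    covariate_detail : bool
        Also compute per-covariate coefficients and semipartial Delta R^2
        (needed for the covariate summary table; adds refits).
    """

    def __init__(self, scored: pd.DataFrame,
                 space: SpecificationSpace | None = None,
                 covariate_detail: bool = True):
        if "playtime_outlier" not in scored.columns:
            raise KeyError("scored dataset lacks 'playtime_outlier'")
        self.data = scored
        self.space = space if space is not None else \
            build_default_space(scored)
        self.covariate_detail = covariate_detail

    def fit(self) -> "SpecificationCurveResults":
        subsets = {
            "include": _Subset(self.data, exclude_outliers=False),
            "exclude": _Subset(self.data, exclude_outliers=True),
        }
        results, skipped = [], []
        for idx, spec in enumerate(self.space.enumerate()):
            try:
                res = _fit_from_subset(subsets[spec.outliers], spec,
                                       self.covariate_detail)
            except ZeroDivisionError as err:
                skipped.append((idx, spec, str(err)))
                continue
            results.append((idx, res))
        return SpecificationCurveResults(self, results, skipped)


class SpecificationCurveResults:
    """Fitted curve: one row per specification, in enumeration order."""

    def __init__(self, model, indexed_results, skipped):
        self.model = model
        self.space = model.space
        self.skipped = skipped
        rows, cov_rows = [], []
        for idx, r in indexed_results:
            s = r.specification
            rows.append({
                "spec_index": idx, "outcome": s.outcome,
                "predictor": s.predictor,
                "covariates": "+".join(s.covariates) if s.covariates
                              else "none",
                "n_covariates": len(s.covariates),
                "outliers": s.outliers,
                "beta": r.beta, "se": r.se,
                "ci_low": r.ci[0], "ci_high": r.ci[1],
                "pvalue": r.pvalue, "df_resid": r.df_resid,
                "r2": r.r2, "delta_r2": r.delta_r2, "n": r.n,
            })
            for (var, coef, se, dof, dr2, std) in r.covariate_stats:
                cov_rows.append({
                    "spec_index": idx, "variable": var, "coef": coef,
                    "se": se, "df_resid": dof, "delta_r2": dr2,
                    "standardized": std,
                })
        self.results = pd.DataFrame(rows)
        self.covariate_results = pd.DataFrame(
            cov_rows, columns=["spec_index", "variable", "coef", "se",
                               "df_resid", "delta_r2", "standardized"])

    def __len__(self):
        return len(self.results)

    @property
    def median_beta(self) -> float:
        return float(self.results["beta"].median())

    @property
    def frac_significant(self) -> float:
        return float((self.results["pvalue"] < 0.05).mean())

    def summarize(self, variable: str) -> "CurveSummary":
        return summarize_curve(self, variable)

    def summary_table(self, level: str = "predictor") -> pd.DataFrame:
        """Per-level curve summaries (Table-3 style).  ``level`` is one of
        'predictor', 'outcome', 'outliers', 'covariate'."""
        if level == "covariate":
            names = list(dict.fromkeys(self.covariate_results["variable"]))
        else:
            names = list(dict.fromkeys(self.results[level]))
        rows = [summarize_curve(self, name).as_dict() for name in names]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        s = self.summarize("all")
        lines = [
            "Specification curve",
            f"  models fitted: {len(self)} of {len(self.space)} "
            f"(skipped: {len(self.skipped)})",
            f"  median beta = {s.median:.3f}  "
            f"[{s.ci[0]:.3f}, {s.ci[1]:.3f}] (median-model 95% CI)",
            f"  range: [{s.min:.3f}, {s.max:.3f}]   "
            f"median dR2 = {s.median_delta_r2:.3f}",
            f"  share of models significant at 0.05: "
            f"{100 * self.frac_significant:.1f}%",
        ]
        return "\n".join(lines)

    def ordered(self) -> pd.DataFrame:
        """Results sorted ascending by beta (ties by enumeration index)."""
        return self.results.sort_values(
            ["beta", "spec_index"], kind="mergesort").reset_index(drop=True)

    def filter(self, **conditions) -> "SpecificationCurveResults":
        """Sub-curve with rows matching all conditions removed/kept;
        e.g. ``filter(predictor_not='odba')``."""
        mask = pd.Series(True, index=self.results.index)
        for key, val in conditions.items():
            if key.endswith("_not"):
                mask &= self.results[key[:-4]] != val
            else:
                mask &= self.results[key] == val
        out = SpecificationCurveResults.__new__(SpecificationCurveResults)
        out.model = self.model
        out.space = self.space
        out.skipped = self.skipped
        out.results = self.results.loc[mask].reset_index(drop=True)
        keep = set(out.results["spec_index"])
        out.covariate_results = self.covariate_results.loc[
            self.covariate_results["spec_index"].isin(keep)
        ].reset_index(drop=True)
        return out

    def decompose_variance(self, **kwargs):
        from .decompose import CurveVarianceDecomposition
        return CurveVarianceDecomposition(self.results, **kwargs).fit()

    def plot(self, **kwargs):
        from .plots import plot_specification_curve
        return plot_specification_curve(self, **kwargs)

    def plot_boxplots(self, **kwargs):
        from .plots import plot_choice_boxplots
        return plot_choice_boxplots(self, **kwargs)


@dataclass
class CurveSummary:
    """Distribution summary of one variable's coefficients across models."""
    variable: str
    median: float
    min: float
    max: float
    ci: tuple
    median_delta_r2: float
    n_models: int
    frac_significant: float

    def __post_init__(self):
        if not (self.min <= self.median <= self.max):
            raise ValueError("median outside [min, max]")

    def as_dict(self) -> dict:
        return {"variable": self.variable, "median_beta": self.median,
                "ci_low": self.ci[0], "ci_high": self.ci[1],
                "min_beta": self.min, "max_beta": self.max,
                "median_delta_r2": self.median_delta_r2,
                "n_models": self.n_models,
                "frac_significant": self.frac_significant}


def _median_model_ci(betas, ses, dfs, level=0.95):
    order = np.argsort(betas, kind="mergesort")
    m = len(order)
    if m % 2 == 1:
        mid = order[m // 2]
        b, s, dof = betas[mid], ses[mid], dfs[mid]
    else:
        two = order[m // 2 - 1: m // 2 + 1]
        b = betas[two].mean()
        s = ses[two].mean()
        dof = dfs[two].mean()
    t = stats.t.ppf((1 + level) / 2.0, dof)
    return float(b), (float(b - t * s), float(b + t * s))


def summarize_curve(results, variable: str) -> CurveSummary:
    """Summarize one variable's coefficient distribution across all models
    containing it.

    ``variable`` may be 'all' (the whole curve), a predictor or outcome
    operationalization, an outlier choice, or a covariate name.
    """
    if isinstance(results, SpecificationCurveResults):
        df, cov = results.results, results.covariate_results
    else:
        df, cov = results, None
    if variable == "all":
        sel = df
    elif variable in set(df["predictor"]):
        sel = df[df["predictor"] == variable]
    elif variable in set(df["outcome"]):
        sel = df[df["outcome"] == variable]
    elif variable in set(df["outliers"]):
        sel = df[df["outliers"] == variable]
    elif cov is not None and variable in set(cov["variable"]):
        c = cov[cov["variable"] == variable]
        betas = c["coef"].to_numpy()
        ses = c["se"].to_numpy()
        dfs = c["df_resid"].to_numpy(dtype=float)
        med, ci = _median_model_ci(betas, ses, dfs)
        tcrit = stats.t.ppf(0.975, dfs)
        pvals = 2 * stats.t.sf(np.abs(betas / ses), dfs)
        return CurveSummary(variable, med, float(betas.min()),
                            float(betas.max()), ci,
                            float(np.median(c["delta_r2"])), len(c),
                            float((pvals < 0.05).mean()))
    else:
        raise KeyError(f"variable {variable!r} appears in no fitted model")
    if len(sel) == 0:
        raise KeyError(f"variable {variable!r} appears in no fitted model")
    betas = sel["beta"].to_numpy()
    med, ci = _median_model_ci(betas, sel["se"].to_numpy(),
                               sel["df_resid"].to_numpy(dtype=float))
    return CurveSummary(variable, med, float(betas.min()),
                        float(betas.max()), ci,
                        float(sel["delta_r2"].median()), len(sel),
                        float((sel["pvalue"] < 0.05).mean()))


def run_curve(scored: pd.DataFrame, space: SpecificationSpace,
              covariate_detail: bool = True) -> SpecificationCurveResults:
    """Fit every specification; results follow enumeration order."""
    return SpecificationCurve(scored, space, covariate_detail).fit()


def power_bivariate(n: int, beta: float, alpha: float = 0.05) -> float:
    """Power of the two-sided t-test for a standardized bivariate slope.

    Uses the noncentral t with ``df = n - 2`` and noncentrality
    ``beta * sqrt(n) / sqrt(1 - beta^2)``.
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    if not -1.0 < beta < 1.0:
        raise ValueError("beta must lie in (-1, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    dof = n - 2
    ncp = beta * np.sqrt(n) / np.sqrt(1.0 - beta ** 2)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    return float(stats.nct.sf(tcrit, dof, ncp)
                 + stats.nct.cdf(-tcrit, dof, ncp))


def correlation_matrix(scored: pd.DataFrame) -> pd.DataFrame:
    """Zero-order Pearson correlations between all numeric study variables."""
    drop = ["respondent_id", "playtime_outlier"]
    num = scored.drop(columns=[c for c in drop if c in scored.columns])
    num = num.select_dtypes(include=[np.number])
    return num.corr()
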