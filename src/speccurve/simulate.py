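"""Synthetic Likert-survey generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a dysregulation factor ``D`` and three well-being factors
(``general_mental_health``, ``absence_depressive_mood``, ``life_satisfaction``)
with configurable standardized associations; Likert items produced from the
one-factor mechanism ``y* = lambda_j * F + sqrt(1 - lambda_j^2) * eps`` and
discretized at standard-normal thresholds; demographic and gaming covariates
with weak associations to the focal constructs; plus the survey-quality
pathologies the cleaning stage must handle (page-level dropout, careless
patterned responders who fail attention checks, and extreme-playtime
outliers).

Because item discretization and finite reliability attenuate observed
scale-score correlations below the latent factor correlation, the generator
*compensates*: the ``D``-to-well-being entries of the latent correlation
matrix are inflated by the analytically computed score-factor attenuation of
the scales involved, so that the Pearson correlation of the *observed* scale
scores targets the configured value.  Both the configured targets and the
inflated latent matrix actually used are recorded in :class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import scales as scl

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "likert_discretize",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

FACTORS = ("D", "general_mental_health", "absence_depressive_mood",
           "life_satisfaction")

# Default latent targets: observed-score standardized associations near the
# per-outcome curve medians the design aims to recover.
_DEFAULT_LATENT_CORR = np.array([
    [1.00, -0.40, -0.47, -0.33],
    [-0.40, 1.00, 0.55, 0.55],
    [-0.47, 0.55, 1.00, 0.55],
    [-0.33, 0.55, 0.55, 1.00],
])

# Threshold conventions (standard-normal cut points) per item family.  The
# source study does not report item-level distributions; these are stated
# conventions that reproduce the published scale means (dysregulation ~2.1,
# well-being ~3.6, depressive symptoms ~2.4, motivations/needs ~3.7).
_TAU_DYS = (-0.6, 0.4, 1.2, 2.0)
_TAU_WB = (-2.0, -1.2, -0.3, 0.6)
_TAU_DEP = (-0.9, 0.1, 0.9, 1.7)
_TAU_MOT = (-2.2, -1.3, -0.5, 0.5)

_LOADING_CYCLE = (0.70, 0.62, 0.55, 0.74, 0.66, 0.58)
_ODBA_LOADINGS = (0.58, 0.62, 0.50, 0.45)

_MOT_FACTORS = tuple(f"{m}_motivation" for m in
                     ("habit", "narrative", "pastime", "performance",
                      "reactivity", "social", "escapism", "agency"))
_NEED_FACTORS = tuple(f"{n}_satisfaction" for n in
                      ("autonomy", "competence", "relatedness"))
_COV_FACTORS = _MOT_FACTORS + _NEED_FACTORS
_CONT_LATENTS = ("z_age", "z_weekday", "z_weekend", "z_session", "z_educ")

# Weak covariate-construct correlations (latent scale, not compensated).
_COV_WITH_D = {
    "habit_motivation": 0.30, "narrative_motivation": 0.05,
    "pastime_motivation": 0.20, "performance_motivation": 0.15,
    "reactivity_motivation": 0.05, "social_motivation": 0.10,
    "escapism_motivation": 0.25, "agency_motivation": 0.05,
    "autonomy_satisfaction": -0.05, "competence_satisfaction": -0.10,
    "relatedness_satisfaction": 0.10,
    "z_age": -0.20, "z_weekday": 0.35, "z_weekend": 0.30, "z_session": 0.30,
    "z_educ": -0.10,
}
_COV_WITH_W = {
    "habit_motivation": -0.05, "narrative_motivation": 0.0,
    "pastime_motivation": -0.10, "performance_motivation": 0.08,
    "reactivity_motivation": 0.05, "social_motivation": 0.08,
    "escapism_motivation": -0.10, "agency_motivation": 0.0,
    "autonomy_satisfaction": 0.10, "competence_satisfaction": 0.15,
    "relatedness_satisfaction": 0.10,
    "z_age": 0.05, "z_weekday": -0.05, "z_weekend": -0.05, "z_session": -0.05,
    "z_educ": 0.05,
}


@dataclass(frozen=True)
class ItemSpec:
    """Generating parameters of one Likert item.

    ``sign`` is -1 for reverse-keyed items (generated from ``-F``); their
    thresholds are given on the raw response scale.
    """
    factor: str
    loading: float
    thresholds: tuple
    sign: int = 1

    def recoded(self):
        """(loading, thresholds) after the 6 - y recode that aligns the item
        with its factor; identity for positively keyed items."""
        if self.sign == 1:
            return self.loading, self.thresholds
        return self.loading, tuple(-t for t in reversed(self.thresholds))


def _default_item_specs() -> dict:
    specs = {}

    def add_items(items, factor, tau, loadings=None, reverse=()):
        for j, col in enumerate(items):
            lam = (loadings[j] if loadings is not None
                   else _LOADING_CYCLE[j % len(_LOADING_CYCLE)])
            if col in reverse:
                mirrored = tuple(-t for t in reversed(tau))
                specs[col] = ItemSpec(factor, lam, mirrored, sign=-1)
            else:
                specs[col] = ItemSpec(factor, lam, tau)

    base = scl.default_scales()
    for name in ("vat", "cvat2_11", "icd11", "gko"):
        add_items(base[name].items, "D", _TAU_DYS)
    add_items(base["odba"].items, "D", _TAU_DYS, loadings=_ODBA_LOADINGS,
              reverse=base["odba"].reverse)
    add_items(base["general_mental_health"].items, "general_mental_health",
              _TAU_WB, reverse=base["general_mental_health"].reverse)
    add_items(base["life_satisfaction"].items, "life_satisfaction", _TAU_WB)
    # Depressive symptom items load negatively on the "absence of depressive
    # mood" factor; the raw responses keep the symptom-scale marginals.
    for j, col in enumerate(base["depressive_mood"].items):
        specs[col] = ItemSpec("absence_depressive_mood",
                              _LOADING_CYCLE[j % 6], _TAU_DEP, sign=-1)
    for fac in _COV_FACTORS:
        add_items(base[fac].items, fac, _TAU_MOT)
    return specs


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic survey.

    Defaults reproduce the reference study's sample structure: 743 starters,
    a 38.9% page-level dropout rate, a 6.6% careless rate among completers
    and ~5% extreme-playtime outliers; observed-score effect targets are the
    per-outcome curve medians (-0.40, -0.47, -0.33).
    """
    n_respondents: int = 743
    latent_corr: np.ndarray = field(
        default_factory=lambda: _DEFAULT_LATENT_CORR.copy())
    item_specs: dict = field(default_factory=_default_item_specs)
    dropout_rate: float = 289.0 / 743.0
    careless_rate: float = 30.0 / 454.0
    outlier_rate: float = 0.05
    gender_probs: tuple = (307 / 424, 113 / 424, 4 / 424)  # male/female/other
    tertiary_prob: float = 0.55
    compensate_attenuation: bool = True
    seed: int = 0

    def validate(self) -> None:
        lc = np.asarray(self.latent_corr, dtype=float)
        if lc.shape != (4, 4):
            raise ValueError("latent_corr must be 4x4 over "
                             "(D, W_gmh, W_adm, W_ls)")
        if not np.allclose(lc, lc.T):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(lc), 1.0):
            raise ValueError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(lc).min() < -1e-10:
            raise ValueError("latent_corr is not positive semi-definite")
        for name in ("dropout_rate", "careless_rate", "outlier_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for col, spec in self.item_specs.items():
            tau = np.asarray(spec.thresholds, float)
            if tau.size != 4 or np.any(np.diff(tau) <= 0):
                raise ValueError(
                    f"item {col!r}: thresholds must be 4 strictly "
                    "increasing values")
            if not 0.0 < spec.loading < 1.0:
                raise ValueError(f"item {col!r}: loading must be in (0,1)")


@dataclass
class GroundTruth:
    """Record of generating parameters and membership labels."""
    target_latent_corr: np.ndarray
    adjusted_latent_corr: np.ndarray
    attenuation: dict          # scale name -> corr(score, own factor)
    expected_score_corr: dict  # (predictor, outcome) -> expected Pearson r
    loadings: dict
    thresholds: dict
    careless_ids: list
    dropout_ids: list
    outlier_ids: list
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "target_latent_corr": np.asarray(self.target_latent_corr).tolist(),
            "adjusted_latent_corr":
                np.asarray(self.adjusted_latent_corr).tolist(),
            "attenuation": self.attenuation,
            "expected_score_corr":
                {f"{k[0]}|{k[1]}": v for k, v in
                 self.expected_score_corr.items()},
            "loadings": self.loadings,
            "thresholds": {k: list(v) for k, v in self.thresholds.items()},
            "careless_ids": list(map(int, self.careless_ids)),
            "dropout_ids": list(map(int, self.dropout_ids)),
            "outlier_ids": list(map(int, self.outlier_ids)),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def likert_discretize(latent_value, thresholds):
    """Map latent values to 1-5 responses: ``1 + #{tau_k < x}``.

    Parameters
    ----------
    latent_value : float or array
    thresholds : sequence of 4 strictly increasing cut points
    """
    tau = np.asarray(thresholds, dtype=float)
    if tau.ndim != 1 or tau.size != 4 or np.any(np.diff(tau) <= 0):
        raise ValueError("thresholds must be 4 strictly increasing values")
    x = np.asarray(latent_value, dtype=float)
    out = 1 + np.searchsorted(tau, x, side="left").astype(np.int64)
    # searchsorted(left) counts tau < x except at exact ties, where it counts
    # tau >= x; correct ties to the strict rule.
    if np.any(np.isin(x, tau)):
        out = 1 + (tau[None, :] < np.atleast_1d(x)[:, None]).sum(axis=1)
        out = out.reshape(np.shape(x)) if np.shape(x) else out[0]
    if np.ndim(latent_value) == 0:
        return int(out)
    return out


# --------------------------------------------------------------------------
# Analytic moments of discretized items (for attenuation compensation).

_moment_cache: dict = {}


def _phi2(a, b, rho):
    """Bivariate standard-normal CDF at points (a_i, b_i), correlation rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    pts = np.column_stack([a, b])
    return stats.multivariate_normal(mean=[0.0, 0.0], cov=cov,
                                     allow_singular=True).cdf(pts)


def _item_mean_var(tau):
    tau = np.asarray(tau, float)
    p_gt = stats.norm.sf(tau)          # P(y* > tau_k)
    mean = 1.0 + p_gt.sum()
    mx = np.maximum.outer(tau, tau)
    var = (stats.norm.sf(mx) - np.outer(p_gt, p_gt)).sum()
    return mean, var


def _pair_cov(tau_i, tau_j, rho):
    """Covariance of two discretized items whose latents correlate at rho."""
    tau_i = np.asarray(tau_i, float)
    tau_j = np.asarray(tau_j, float)
    a = np.repeat(tau_i, tau_j.size)
    b = np.tile(tau_j, tau_i.size)
    surv = 1.0 - stats.norm.cdf(a) - stats.norm.cdf(b) + _phi2(a, b, rho)
    prod = stats.norm.sf(a) * stats.norm.sf(b)
    return (surv - prod).sum()


def scale_attenuation(item_params):
    """corr(mean item score, factor) for a unidimensional Likert scale.

    ``item_params`` is a sequence of (loading, thresholds) pairs on the
    recoded (factor-aligned) basis.  Uses exact single/bivariate normal
    orthant probabilities.
    """
    key = tuple((round(l, 10), tuple(np.round(t, 10))) for l, t in item_params)
    if key in _moment_cache:
        return _moment_cache[key]
    lams = np.array([l for l, _ in item_params])
    taus = [np.asarray(t, float) for _, t in item_params]
    p = len(lams)
    cs = np.array([stats.norm.pdf(t).sum() for t in taus])
    variances = np.array([_item_mean_var(t)[1] for t in taus])
    total = variances.sum()
    for i in range(p):
        for j in range(i + 1, p):
            total += 2.0 * _pair_cov(taus[i], taus[j], lams[i] * lams[j])
    # Cov(score, F) = (1/p) sum lam_j c_j ; sd(score) = sqrt(total)/p
    alpha = (lams * cs).sum() / np.sqrt(total)
    _moment_cache[key] = float(alpha)
    return float(alpha)


def _scale_alpha(config, scale: scl.ScaleDefinition) -> float:
    params = [config.item_specs[c].recoded() for c in scale.items]
    return scale_attenuation(params)


def _attenuations(config) -> dict:
    """Score-factor attenuation for the nine predictor operationalizations
    and the three outcome scales."""
    battery = scl.default_scales()
    out = {}
    for name in scl.predictor_scale_names():
        out[name] = _scale_alpha(config, battery[name])
    out["general_mental_health"] = _scale_alpha(
        config, battery["general_mental_health"])
    out["absence_depressive_mood"] = _scale_alpha(
        config, battery["depressive_mood"])
    out["life_satisfaction"] = _scale_alpha(
        config, battery["life_satisfaction"])
    return out


def _adjusted_latent_corr(config, alphas):
    """Inflate D-W entries so observed scale-score correlations hit the
    configured targets (mean attenuation over the nine operationalizations
    on the predictor side)."""
    lc = np.asarray(config.latent_corr, float).copy()
    if not config.compensate_attenuation:
        return lc
    alpha_d = np.mean([alphas[s] for s in scl.predictor_scale_names()])
    for k, outcome in enumerate(FACTORS[1:], start=1):
        r = lc[0, k] / (alpha_d * alphas[outcome])
        lc[0, k] = lc[k, 0] = np.clip(r, -0.97, 0.97)
    if np.linalg.eigvalsh(lc).min() < -1e-10:
        raise ValueError(
            "attenuation-compensated latent correlation matrix is not "
            "positive semi-definite; lower the configured associations")
    return lc


# --------------------------------------------------------------------------
# Full latent correlation over factors + covariate latents.

def _full_latent_corr(adjusted_lc):
    names = list(FACTORS) + list(_COV_FACTORS) + list(_CONT_LATENTS)
    k = len(names)
    C = np.eye(k)
    C[:4, :4] = adjusted_lc
    idx = {n: i for i, n in enumerate(names)}
    covs = list(_COV_FACTORS) + list(_CONT_LATENTS)
    for c in covs:
        C[idx[c], 0] = C[0, idx[c]] = _COV_WITH_D[c]
        for w in FACTORS[1:]:
            C[idx[c], idx[w]] = C[idx[w], idx[c]] = _COV_WITH_W[c]
    for i, a in enumerate(_MOT_FACTORS):
        for b in _MOT_FACTORS[i + 1:]:
            C[idx[a], idx[b]] = C[idx[b], idx[a]] = 0.25
    for i, a in enumerate(_NEED_FACTORS):
        for b in _NEED_FACTORS[i + 1:]:
            C[idx[a], idx[b]] = C[idx[b], idx[a]] = 0.30
    for a in _MOT_FACTORS:
        for b in _NEED_FACTORS:
            C[idx[a], idx[b]] = C[idx[b], idx[a]] = 0.15
    C[idx["z_weekday"], idx["z_weekend"]] = 0.45
    C[idx["z_weekend"], idx["z_weekday"]] = 0.45
    C[idx["z_weekday"], idx["z_session"]] = 0.30
    C[idx["z_session"], idx["z_weekday"]] = 0.30
    C[idx["z_weekend"], idx["z_session"]] = 0.30
    C[idx["z_session"], idx["z_weekend"]] = 0.30
    C[idx["z_age"], idx["z_educ"]] = C[idx["z_educ"], idx["z_age"]] = 0.15
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ValueError("full latent correlation matrix is not PSD")
    return names, C


def _lognormal_params(mean, sd):
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


def generate_dataset(config: GeneratorConfig):
    """Generate one survey dataset.

    Returns
    -------
    (pandas.DataFrame, GroundTruth)
        The respondent table (one row per starter; dropouts carry missing
        items from their abandonment page onward) and the ground-truth
        record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    alphas = _attenuations(config)
    adjusted = _adjusted_latent_corr(config, alphas)
    names, C = _full_latent_corr(adjusted)
    n = config.n_respondents

    L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    Z = rng.standard_normal((n, C.shape[0])) @ L.T
    fac = {name: Z[:, i] for i, name in enumerate(names)}

    # Likert items.
    data = {}
    item_cols = scl.all_item_columns()
    for col in item_cols:
        spec = config.item_specs[col]
        f = fac[spec.factor] * spec.sign
        ystar = spec.loading * f + np.sqrt(1.0 - spec.loading ** 2) \
            * rng.standard_normal(n)
        tau = np.asarray(spec.thresholds, float)
        data[col] = (1 + np.searchsorted(tau, ystar, side="left")).astype(
            np.int64)

    # Demographics and playtime (marginals chosen to match the published
    # descriptives: age ~24 (sd 8), weekly time ~21 h, sessions ~150 min).
    mu, sg = _lognormal_params(8.2, 7.7)
    age = np.round(16.0 + np.exp(mu + sg * fac["z_age"])).astype(np.int64)
    mu, sg = _lognormal_params(2.4, 1.6)
    weekday = np.round(np.exp(mu + sg * fac["z_weekday"]) * 2.0) / 2.0
    mu, sg = _lognormal_params(4.0, 2.4)
    weekend = np.round(np.exp(mu + sg * fac["z_weekend"]) * 2.0) / 2.0
    mu, sg = _lognormal_params(150.0, 130.0)
    session = np.round(np.exp(mu + sg * fac["z_session"]) / 5.0) * 5.0
    gender = rng.choice(np.array(["male", "female", "other"]), size=n,
                        p=np.asarray(config.gender_probs) /
                        np.sum(config.gender_probs))
    education = np.where(
        fac["z_educ"] < stats.norm.ppf(config.tertiary_prob),
        "tertiary", "secondary")

    df = pd.DataFrame({"respondent_id": np.arange(1, n + 1),
                       "age": age, "gender": gender, "education": education,
                       "weekday_hours": weekday, "weekend_hours": weekend,
                       "session_minutes": session})
    for col in item_cols:
        df[col] = data[col]
    df["check_1"] = "pass"
    df["check_2"] = "pass"

    # Membership labels.
    ids = df["respondent_id"].to_numpy()
    n_drop = int(round(config.dropout_rate * n))
    perm = rng.permutation(n)
    drop_idx = np.sort(perm[:n_drop])
    completer_idx = np.sort(perm[n_drop:])
    n_careless = int(round(config.careless_rate * completer_idx.size))
    perm2 = rng.permutation(completer_idx.size)
    careless_idx = np.sort(completer_idx[perm2[:n_careless]])
    clean_completers = completer_idx[perm2[n_careless:]]
    n_out = int(round(config.outlier_rate * completer_idx.size))
    outlier_idx = np.sort(clean_completers[
        rng.permutation(clean_completers.size)[:n_out]])

    # Careless responders: patterned answers, >=1 failed check.
    pattern_123 = np.tile([1, 2, 3], len(item_cols) // 3 + 1)[:len(item_cols)]
    for i in careless_idx:
        if rng.random() < 0.5:
            df.loc[i, item_cols] = int(rng.integers(1, 6))
        else:
            df.loc[i, item_cols] = pattern_123
        which = rng.integers(0, 3)
        if which in (0, 2):
            df.loc[i, "check_1"] = "fail"
        if which in (1, 2):
            df.loc[i, "check_2"] = "fail"

    # Extreme-playtime outliers: weekly hours far above 3 SD of the bulk.
    for i in outlier_idx:
        df.loc[i, "weekday_hours"] = np.round(rng.uniform(13, 16) * 2) / 2
        df.loc[i, "weekend_hours"] = np.round(rng.uniform(14, 20) * 2) / 2
        if rng.random() < 0.5:
            df.loc[i, "session_minutes"] = np.round(
                rng.uniform(700, 1200) / 5) * 5

    # Page-level dropout: missing everything from the abandonment page on.
    pages = scl.survey_pages()
    page_cols = [set(p) for p in pages]
    if n_drop:
        # Early abandonment dominates, as in self-selected online surveys.
        w = np.array([0.45, 0.25, 0.12] + [0.18 / (len(pages) - 4)]
                     * (len(pages) - 4))
        abandon_pages = rng.choice(np.arange(1, len(pages)), size=n_drop,
                                   p=w / w.sum())
        item_like = item_cols + ["check_1", "check_2"]
        for i, pg in zip(drop_idx, abandon_pages):
            missing = set().union(*page_cols[pg:])
            cols = [c for c in item_like if c in missing]
            df.loc[i, cols] = np.nan

    for col in item_cols:
        df[col] = df[col].astype("Float64")

    expected = {}
    for s in scl.predictor_scale_names():
        for k, w in enumerate(FACTORS[1:], start=1):
            expected[(s, w)] = float(adjusted[0, k] * alphas[s] * alphas[w])
    truth = GroundTruth(
        target_latent_corr=np.asarray(config.latent_corr, float).copy(),
        adjusted_latent_corr=adjusted,
        attenuation=alphas,
        expected_score_corr=expected,
        loadings={c: config.item_specs[c].loading for c in item_cols},
        thresholds={c: tuple(config.item_specs[c].thresholds)
                    for c in item_cols},
        careless_ids=ids[careless_idx].tolist(),
        dropout_ids=ids[drop_idx].tolist(),
        outlier_ids=ids[outlier_idx].tolist(),
        seed=config.seed,
    )
    return df, truth


def write_dataset(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in scl.all_item_columns():
        if col in df.columns:
            df[col] = df[col].astype("Float64")
    return df
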