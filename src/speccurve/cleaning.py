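"""Survey cleaning cascade and score construction.

Cleaning follows the fixed cascade *incomplete -> careless*: respondents with
any missing item are removed first, then respondents who failed at least one
of the two attention checks.  A sensitivity mode retains everyone (both
incomplete and careless responses) for robustness re-analysis.  Scale scores
are item means after reverse coding; weekly game time is ``5 * weekday +
2 * weekend``; playtime outliers are flagged at three sample standard
deviations above the mean (weekly hours or session minutes), together with
any respondent reporting zero weekly game time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import scales as scl
from .scales import ScaleDefinition

__all__ = [
    "CleaningReport",
    "clean_dataset",
    "score_scale",
    "weekly_game_time",
    "reverse_wellbeing",
    "flag_outliers",
    "score_dataset",
]

CHECK_COLUMNS = ("check_1", "check_2")


@dataclass
class CleaningReport:
    """Counts for each stage of the cleaning cascade."""
    n_initial: int
    n_incomplete_removed: int
    n_careless_removed: int
    n_retained: int
    sensitivity_mode: bool = False

    def __post_init__(self):
        total = (self.n_incomplete_removed + self.n_careless_removed
                 + self.n_retained)
        if total != self.n_initial:
            raise ValueError("cleaning counts do not conserve respondents")

    @property
    def pct_incomplete(self) -> float:
        return 100.0 * self.n_incomplete_removed / self.n_initial

    @property
    def pct_careless_among_completers(self) -> float:
        completers = self.n_initial - self.n_incomplete_removed
        return 100.0 * self.n_careless_removed / completers

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def clean_dataset(raw: pd.DataFrame, sensitivity_mode: bool = False,
                  item_columns=None):
    """Apply the cleaning cascade.

    Parameters
    ----------
    raw : DataFrame
        Respondent table with item columns and the two attention-check
        columns (values ``"pass"``/``"fail"``, missing if unreached).
    sensitivity_mode : bool
        If True, no respondents are removed (incomplete and careless
        responses retained); downstream scoring handles missingness.
    item_columns : list of str, optional
        Item columns defining completeness; defaults to the full battery.

    Returns
    -------
    (DataFrame, CleaningReport)
    """
    for col in CHECK_COLUMNS:
        if col not in raw.columns:
            raise KeyError(f"attention-check column {col!r} missing")
    if item_columns is None:
        item_columns = [c for c in scl.all_item_columns() if c in raw.columns]
    n_initial = len(raw)
    if sensitivity_mode:
        report = CleaningReport(n_initial, 0, 0, n_initial,
                                sensitivity_mode=True)
        return raw.copy(), report

    complete = raw[item_columns].notna().all(axis=1)
    completers = raw.loc[complete]
    failed = (completers[list(CHECK_COLUMNS)] == "fail").any(axis=1)
    retained = completers.loc[~failed].copy()
    report = CleaningReport(
        n_initial=n_initial,
        n_incomplete_removed=int((~complete).sum()),
        n_careless_removed=int(failed.sum()),
        n_retained=len(retained),
    )
    return retained, report


def score_scale(dataset: pd.DataFrame, scale: ScaleDefinition,
                core_only: bool = False, on_missing: str = "raise"):
    """Mean item score after reverse coding.

    Reverse-coded item responses ``r`` contribute ``6 - r``.  With
    ``core_only`` the mean runs over the scale's core-criterion items.
    ``on_missing`` is ``"raise"`` (cleaned data must be complete) or
    ``"nan"`` (score only complete responders, e.g. in sensitivity mode).
    """
    items = list(scale.selected_items(core_only))
    block = dataset[items].astype(float)
    if block.isna().any().any():
        if on_missing == "raise":
            bad = block.isna().any(axis=1).sum()
            raise ValueError(
                f"scale {scale.name!r}: {bad} respondents have missing "
                "items; clean the data or pass on_missing='nan'")
        elif on_missing != "nan":
            raise ValueError("on_missing must be 'raise' or 'nan'")
    rev = [c for c in scale.reverse if c in items]
    if rev:
        block[rev] = 6.0 - block[rev]
    return block.mean(axis=1, skipna=False)


def weekly_game_time(weekday_hours, weekend_hours):
    """Weekly play estimate in hours: ``5 * weekday + 2 * weekend``."""
    wd = np.asarray(weekday_hours, dtype=float)
    we = np.asarray(weekend_hours, dtype=float)
    if np.nanmin(wd, initial=0.0) < 0 or np.nanmin(we, initial=0.0) < 0:
        raise ValueError("daily play hours must be non-negative")
    out = 5.0 * wd + 2.0 * we
    if np.ndim(weekday_hours) == 0 and np.ndim(weekend_hours) == 0:
        return float(out)
    return out


def reverse_wellbeing(score):
    """Reverse a 1-5 scale score (depressive mood -> absence thereof)."""
    s = np.asarray(score, dtype=float)
    if np.nanmin(s, initial=1.0) < 1.0 or np.nanmax(s, initial=5.0) > 5.0:
        raise ValueError("scale scores must lie in [1, 5]")
    out = 6.0 - s
    if np.ndim(score) == 0:
        return float(out)
    return out


def flag_outliers(dataset: pd.DataFrame) -> set:
    """Ids with weekly game time or session minutes >= mean + 3 SD, plus
    ids reporting zero weekly game time.

    The mean/SD are computed over the given (cleaned) sample; with zero
    variance no SD-based flags are produced.
    """
    weekly = weekly_game_time(dataset["weekday_hours"].to_numpy(),
                              dataset["weekend_hours"].to_numpy())
    session = dataset["session_minutes"].to_numpy(dtype=float)
    ids = dataset["respondent_id"].to_numpy()
    flagged = np.zeros(len(dataset), dtype=bool)
    for values in (weekly, session):
        sd = np.std(values, ddof=1) if len(values) > 1 else 0.0
        if sd > 0:
            flagged |= values >= values.mean() + 3.0 * sd
    flagged |= weekly == 0.0
    return set(ids[flagged].tolist())


def score_dataset(cleaned: pd.DataFrame, battery: dict | None = None,
                  on_missing: str = "raise") -> pd.DataFrame:
    """Build the analysis table: scale scores, derived variables, covariates
    and the playtime-outlier flag.

    Returns one row per respondent with the nine dysregulated-gaming
    operationalizations, the three well-being outcomes (depressive mood
    reversed into ``absence_depressive_mood``), the 16 candidate covariates
    and a boolean ``playtime_outlier`` column.
    """
    if battery is None:
        battery = scl.default_scales()
    out = pd.DataFrame({"respondent_id": cleaned["respondent_id"].to_numpy()},
                       index=cleaned.index)
    for name in scl.predictor_scale_names():
        out[name] = score_scale(cleaned, battery[name],
                                on_missing=on_missing)
    out["general_mental_health"] = score_scale(
        cleaned, battery["general_mental_health"], on_missing=on_missing)
    out["life_satisfaction"] = score_scale(
        cleaned, battery["life_satisfaction"], on_missing=on_missing)
    dep = score_scale(cleaned, battery["depressive_mood"],
                      on_missing=on_missing)
    out["absence_depressive_mood"] = reverse_wellbeing(dep.to_numpy())
    for fac in ([f"{m}_motivation" for m in
                 ("habit", "narrative", "pastime", "performance",
                  "reactivity", "social", "escapism", "agency")]
                + [f"{n}_satisfaction" for n in
                   ("autonomy", "competence", "relatedness")]):
        out[fac] = score_scale(cleaned, battery[fac], on_missing=on_missing)
    out["age"] = cleaned["age"].to_numpy(dtype=float)
    out["gender"] = pd.Categorical(cleaned["gender"],
                                   categories=["female", "male", "other"])
    out["education"] = pd.Categorical(cleaned["education"],
                                      categories=["tertiary", "secondary"])
    out["weekly_game_time"] = weekly_game_time(
        cleaned["weekday_hours"].to_numpy(),
        cleaned["weekend_hours"].to_numpy())
    out["session_minutes"] = cleaned["session_minutes"].to_numpy(dtype=float)
    outliers = flag_outliers(cleaned)
    out["playtime_outlier"] = out["respondent_id"].isin(outliers)
    # Item columns for item-level curves.
    for col in (list(scl.default_scales()["cvat2_11"].items)
                + list(scl.default_scales()["icd11"].items)):
        out[col] = cleaned[col].astype(float).to_numpy()
    return out
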