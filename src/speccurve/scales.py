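"""Scale definitions for the survey battery.

Each instrument is described by a :class:`ScaleDefinition`: an ordered list of
item column names, the subset that is reverse-coded (answered on the same 1-5
Likert format but keyed in the opposite direction), and the subset classified
as *core* criteria (items directly assessing negative consequences and
conflict, as opposed to peripheral high-engagement indicators such as
preoccupation, tolerance or mood modification).

The default battery mirrors a Dutch/Flemish gamer survey: five dysregulated
gaming instruments (plus derived core-only and composite operationalizations),
three well-being scales, eight gaming-motivation subscales and three in-game
need-satisfaction subscales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "ScaleDefinition",
    "default_scales",
    "predictor_scale_names",
    "outcome_names",
    "covariate_names",
    "survey_pages",
    "scales_to_yaml",
    "scales_from_yaml",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """A named scale: ordered item ids, reverse-coded ids, core-criterion ids.

    Parameters
    ----------
    name : str
        Scale identifier (used as the scored column name).
    items : tuple of str
        Ordered item column names; at least one.
    reverse : tuple of str
        Items scored as ``6 - response``. Must be a subset of ``items``.
    core : tuple of str
        Core-criterion items. Must be a subset of ``items``.
    """

    name: str
    items: tuple
    reverse: tuple = field(default=())
    core: tuple = field(default=())

    def __post_init__(self):
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        object.__setattr__(self, "reverse", tuple(self.reverse))
        object.__setattr__(self, "core", tuple(self.core))
        if len(items) == 0:
            raise ValueError(f"scale {self.name!r} has no items")
        if len(set(items)) != len(items):
            raise ValueError(f"scale {self.name!r} has duplicate items")
        for label, subset in (("reverse", self.reverse), ("core", self.core)):
            missing = set(subset) - set(items)
            if missing:
                raise ValueError(
                    f"scale {self.name!r}: {label} ids {sorted(missing)} "
                    "are not scale items"
                )

    @property
    def n_items(self) -> int:
        return len(self.items)

    def selected_items(self, core_only: bool = False) -> tuple:
        if core_only:
            if not self.core:
                raise ValueError(f"scale {self.name!r} has no core subset")
            return self.core
        return self.items


def _ids(prefix: str, n: int) -> tuple:
    return tuple(f"{prefix}_{i}" for i in range(1, n + 1))


# Dysregulated-gaming instruments.
#
# VAT (Video Game Addiction Test, 14 items): loss of control (1-4),
# conflict (5-8), preoccupation/salience (9-11), coping/mood modification
# (12-13), withdrawal (14).  Core = loss of control + conflict (8 items).
_VAT_ITEMS = _ids("vat", 14)
_VAT_CORE = _VAT_ITEMS[:8]

# CVAT-2 (Clinical Video Game Addiction Test 2.0).  Items keyed to DSM-5
# criteria: 1 tolerance, 2 withdrawal, 3 loss of control, 4 preoccupation,
# 5 mood modification/escapism, 6 loss of interests, 7 lying/deception,
# 8 continuation despite problems, 9 problems (work/social); the 11-item
# version adds 10 craving and 11 problems (health).  Peripheral indicators
# are tolerance, withdrawal, preoccupation and mood modification.
_CVAT_ITEMS = _ids("cvat", 11)
_CVAT_PERIPHERAL = ("cvat_1", "cvat_2", "cvat_4", "cvat_5")
_CVAT_CORE = tuple(i for i in _CVAT_ITEMS if i not in _CVAT_PERIPHERAL)

_ICD_ITEMS = _ids("icd", 4)
_GKO_ITEMS = _ids("gko", 5)
# ODBA: items 3 ("gaming does not lead to problems") and 4 ("time spent is a
# conscious choice") are negatively keyed.
_ODBA_ITEMS = _ids("odba", 4)
_ODBA_REVERSE = ("odba_3", "odba_4")

# Well-being.  MHI item 3 ("calm and peaceful") is positively keyed against
# the other four symptom items, coded here as the reverse-scored one once the
# scale is keyed toward good mental health.
_MHI_ITEMS = _ids("mhi", 5)
_SWLS_ITEMS = _ids("swls", 5)
_ADM_ITEMS = _ids("adm", 6)

_MOTIVATIONS = (
    "habit",
    "narrative",
    "pastime",
    "performance",
    "reactivity",
    "social",
    "escapism",
    "agency",
)
_NEEDS = ("autonomy", "competence", "relatedness")


def default_scales() -> dict:
    """Return the default battery as ``{name: ScaleDefinition}``.

    Includes the nine dysregulated-gaming operationalizations used as curve
    predictors (the two ``*_core`` entries are views of their parent
    instruments restricted to core criteria; ``cvat3`` is the 15-item
    composite of the 11-item CVAT-2 and the four ICD-11 items), the three
    well-being scales, and the eleven covariate subscales.
    """
    scales = {}

    def add(s: ScaleDefinition):
        scales[s.name] = s

    add(ScaleDefinition("vat", _VAT_ITEMS, core=_VAT_CORE))
    add(ScaleDefinition("vat_core", _VAT_CORE, core=_VAT_CORE))
    add(ScaleDefinition("cvat2_9", _CVAT_ITEMS[:9],
                        core=tuple(i for i in _CVAT_CORE if i in _CVAT_ITEMS[:9])))
    add(ScaleDefinition("cvat2_11", _CVAT_ITEMS, core=_CVAT_CORE))
    add(ScaleDefinition("cvat2_core", _CVAT_CORE, core=_CVAT_CORE))
    add(ScaleDefinition("icd11", _ICD_ITEMS, core=_ICD_ITEMS))
    add(ScaleDefinition("odba", _ODBA_ITEMS, reverse=_ODBA_REVERSE,
                        core=("odba_1", "odba_2", "odba_3")))
    add(ScaleDefinition("gko", _GKO_ITEMS, core=_GKO_ITEMS))
    add(ScaleDefinition("cvat3", _CVAT_ITEMS + _ICD_ITEMS,
                        core=_CVAT_CORE + _ICD_ITEMS))

    add(ScaleDefinition("general_mental_health", _MHI_ITEMS, reverse=("mhi_3",)))
    add(ScaleDefinition("life_satisfaction", _SWLS_ITEMS))
    # Depressive mood is scored normally here; the scale-level score is
    # reversed downstream to yield "absence of depressive mood".
    add(ScaleDefinition("depressive_mood", _ADM_ITEMS))

    for m in _MOTIVATIONS:
        add(ScaleDefinition(f"{m}_motivation", _ids(f"mot_{m}", 3)))
    for need in _NEEDS:
        add(ScaleDefinition(f"{need}_satisfaction", _ids(f"need_{need}", 4)))
    return scales


def predictor_scale_names() -> list:
    """The nine dysregulated-gaming operationalizations, in curve order."""
    return ["vat", "vat_core", "cvat2_9", "cvat2_11", "cvat2_core",
            "icd11", "odba", "gko", "cvat3"]


def outcome_names() -> list:
    """The three well-being outcomes (all keyed toward higher well-being)."""
    return ["general_mental_health", "absence_depressive_mood",
            "life_satisfaction"]


def covariate_names() -> list:
    """The 16 candidate control variables."""
    return (["age", "gender", "education", "weekly_game_time",
             "session_minutes"]
            + [f"{need}_satisfaction" for need in _NEEDS]
            + [f"{m}_motivation" for m in _MOTIVATIONS])


def survey_pages() -> list:
    """Ordered survey pages (lists of item columns) used for page-level
    dropout.  Demographics and playtime are collected on the first page;
    the second attention check sits near the end of the battery."""
    return [
        ["age", "gender", "education", "weekday_hours", "weekend_hours",
         "session_minutes"],
        list(_VAT_ITEMS),
        list(_MHI_ITEMS),
        list(_ids("mot_habit", 3) + _ids("mot_narrative", 3)
             + _ids("mot_pastime", 3) + _ids("mot_performance", 3)),
        list(_CVAT_ITEMS) + ["check_1"],
        list(_SWLS_ITEMS),
        list(_ids("mot_reactivity", 3) + _ids("mot_social", 3)
             + _ids("mot_escapism", 3) + _ids("mot_agency", 3)),
        list(_ICD_ITEMS),
        list(_ADM_ITEMS),
        list(_GKO_ITEMS),
        list(_ids("need_autonomy", 4) + _ids("need_competence", 4)
             + _ids("need_relatedness", 4)) + ["check_2"],
        list(_ODBA_ITEMS),
    ]


def all_item_columns() -> list:
    """Every Likert item column, in survey order."""
    cols = []
    for page in survey_pages():
        cols.extend(c for c in page
                    if c not in ("age", "gender", "education", "weekday_hours",
                                 "weekend_hours", "session_minutes",
                                 "check_1", "check_2"))
    return cols


def scales_to_yaml(scales: dict, path) -> None:
    payload = {
        name: {"items": list(s.items), "reverse": list(s.reverse),
               "core": list(s.core)}
        for name, s in scales.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def scales_from_yaml(path) -> dict:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {
        name: ScaleDefinition(name, tuple(d["items"]),
                              tuple(d.get("reverse", ())),
                              tuple(d.get("core", ())))
        for name, d in payload.items()
    }
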