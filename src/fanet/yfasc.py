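"""Yale Food Addiction Scale for Children (YFAS-C) scoring.

The 25-item child-adapted scale maps onto seven DSM-IV-style substance
dependence symptoms plus a clinical impairment/distress criterion:

* larger amounts / longer than intended — items 1, 2, 3
* persistent desire or unsuccessful attempts to cut down — items 4, 17, 18, 25
* much time spent obtaining, using, recovering — items 5, 6, 7
* important activities given up or reduced — items 8, 9, 10, 11
* continued use despite adverse consequences — item 21
* tolerance — items 22, 23
* use to relieve withdrawal — items 12, 13, 14
* impairment/distress — items 15, 16

Items 19, 20 and 24 are never scored.  A symptom counts as present when at
least one of its items is endorsed; the food-addiction diagnosis requires at
least three symptoms together with the impairment/distress criterion.

Most items are answered on a 0-4 Likert scale and a handful are yes/no; the
per-item endorsement cut points of the child scale are instrument
configuration, not results, so they live in :class:`EndorsementMap` with a
documented default, and scoring is otherwise invariant to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "SYMPTOMS",
    "IMPAIRMENT_ITEMS",
    "UNSCORED_ITEMS",
    "EndorsementMap",
    "SymptomProfile",
    "score_symptoms",
    "diagnose",
    "score_table",
]

SYMPTOMS: dict[str, frozenset[int]] = {
    "larger_amount_longer": frozenset({1, 2, 3}),
    "persistent_desire": frozenset({4, 17, 18, 25}),
    "much_time_spent": frozenset({5, 6, 7}),
    "activities_given_up": frozenset({8, 9, 10, 11}),
    "use_despite_consequences": frozenset({21}),
    "tolerance": frozenset({22, 23}),
    "withdrawal": frozenset({12, 13, 14}),
}

IMPAIRMENT_ITEMS: frozenset[int] = frozenset({15, 16})
UNSCORED_ITEMS: frozenset[int] = frozenset({19, 20, 24})
ALL_ITEMS: frozenset[int] = frozenset(range(1, 26))
SCORED_ITEMS: frozenset[int] = ALL_ITEMS - UNSCORED_ITEMS

_YES = {"yes", "y", "1", "true"}
_NO = {"no", "n", "0", "false"}


@dataclass(frozen=True)
class EndorsementMap:
    """Per-item rule turning a raw response into endorsed / not endorsed.

    Likert items (0-4) are endorsed at or above their cut point; dichotomous
    items are endorsed on "yes".  The default uses a cut point of 3
    ("very often" or more) for every Likert item and treats items 15, 16,
    19, 20 and 24 as dichotomous — a documented fixture, since the child
    scale's per-item thresholds are part of the instrument manual rather
    than of any analysis output.
    """

    likert_cutpoints: Mapping[int, int] = field(default_factory=dict)
    dichotomous_items: frozenset[int] = frozenset({15, 16, 19, 20, 24})
    default_cutpoint: int = 3

    def cutpoint(self, item: int) -> int:
        return int(self.likert_cutpoints.get(item, self.default_cutpoint))

    def is_endorsed(self, item: int, response) -> bool:
        if item in self.dichotomous_items:
            s = str(response).strip().lower()
            if s in _YES:
                return True
            if s in _NO:
                return False
            raise ValueError(f"item {item}: expected yes/no, got {response!r}")
        r = int(response)
        if not 0 <= r <= 4:
            raise ValueError(f"item {item}: Likert response must be 0..4, got {response!r}")
        return r >= self.cutpoint(item)


@dataclass(frozen=True)
class SymptomProfile:
    """Seven symptom indicators plus the impairment/distress criterion."""

    symptoms: dict[str, bool]
    impairment: bool
    zero_filled: frozenset[int] = frozenset()

    @property
    def symptom_count(self) -> int:
        return sum(self.symptoms.values())


def score_symptoms(
    responses: Mapping[int, object],
    endorsement: EndorsementMap | None = None,
    zero_fill_missing: bool = False,
) -> SymptomProfile:
    """Collapse 25 item responses into the seven-symptom profile.

    A symptom is present iff at least one of its items is endorsed;
    impairment/distress is present iff item 15 or item 16 is endorsed.
    Items 19, 20 and 24 are ignored.  A missing scored item raises unless
    ``zero_fill_missing`` is set, in which case it is treated as not
    endorsed and flagged in the output.
    """
    endorsement = endorsement or EndorsementMap()
    missing = {
        i
        for i in SCORED_ITEMS
        if i not in responses or responses[i] is None or (pd.isna(responses[i]) is True)
    }
    if missing and not zero_fill_missing:
        raise ValueError(f"missing scored items: {sorted(missing)}")

    def endorsed(item: int) -> bool:
        if item in missing:
            return False
        return endorsement.is_endorsed(item, responses[item])

    symptoms = {
        name: any(endorsed(i) for i in items) for name, items in SYMPTOMS.items()
    }
    impairment = any(endorsed(i) for i in IMPAIRMENT_ITEMS)
    return SymptomProfile(symptoms, impairment, frozenset(missing))


def diagnose(profile: SymptomProfile) -> bool:
    """Food addiction: at least 3 symptoms plus impairment/distress."""
    return profile.symptom_count >= 3 and profile.impairment


def score_table(
    items: pd.DataFrame,
    endorsement: EndorsementMap | None = None,
    zero_fill_missing: bool = False,
) -> pd.DataFrame:
    """Score a wide response table (columns ``item_1`` .. ``item_25``).

    Returns one row per subject with the seven symptom indicators,
    ``symptom_count``, ``impairment``, the ``food_addiction`` diagnosis and
    the number of zero-filled items.
    """
    cols = {f"item_{i}": i for i in range(1, 26)}
    missing_cols = set(cols) - set(items.columns)
    if missing_cols:
        raise ValueError(f"missing item columns: {sorted(missing_cols)}")
    rows = []
    for _, row in items.iterrows():
        profile = score_symptoms(
            {i: row[c] for c, i in cols.items()}, endorsement, zero_fill_missing
        )
        rec = dict(profile.symptoms)
        rec["symptom_count"] = profile.symptom_count
        rec["impairment"] = profile.impairment
        rec["food_addiction"] = diagnose(profile)
        rec["n_zero_filled"] = len(profile.zero_filled)
        rows.append(rec)
    return pd.DataFrame(rows, index=items.index)
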