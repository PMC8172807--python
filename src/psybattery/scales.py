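"""Survey data model and declarative instrument scoring.

Eight scored instruments are built in: CPSS (post-traumatic stress), PHQ-A
(depression), HADS anxiety subscale, CRAFFT (alcohol/substance use), the
Tobacco Use questionnaire, the Rosenberg self-esteem scale, Kidscreen-10
(quality of life, 11 scored items here) and CYRM-12 (resilience).

Answers are encoded as the 0-based position of the chosen option in the
printed answer list for that item (``schema.json`` carries the verbatim
texts).  Per-item scores run ``score_base + 0 .. score_base + levels-1`` in
printed answer order; reverse-coded items flip that so every item's score
increases with the construct the scale total measures (symptom severity, or
self-esteem / quality of life / resilience for the positively-oriented
scales).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping, Optional

logger = logging.getLogger(__name__)

YES = 0  # printed order of binary items is "Yes, No"
NO = 1

GENDERS = ("female", "male", "other", "prefer_not_say")
YEARS = (2017, 2018, 2019)

AGE_LOW_TEXT = "10 years or less"
AGE_HIGH_TEXT = "20 years or more"


class TriState(Enum):
    """Outcome of a screening assessment."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_EVALUABLE = "not_evaluable"

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError("TriState is not a boolean; compare explicitly")


@dataclass(frozen=True)
class SkipRule:
    """Items shown only when the condition items warrant it.

    ``dependent_items`` are skipped when every condition item's answer is in
    ``skip_answers`` (e.g. CRAFFT part B is skipped when questions 1-3 are
    all "no").  Condition items always precede dependent items.
    """

    condition_items: tuple[int, ...]
    dependent_items: tuple[int, ...]
    skip_answers: frozenset[int]

    def __post_init__(self) -> None:
        if max(self.condition_items) >= min(self.dependent_items):
            raise ValueError("skip-rule condition items must precede dependents")

    def status(self, answers: Mapping[int, int]) -> Optional[bool]:
        """True if dependents are skipped, False if required, None if unknown."""
        got = [answers.get(i) for i in self.condition_items]
        if any(a is None for a in got):
            return None
        return all(a in self.skip_answers for a in got)


@dataclass(frozen=True)
class ScaleDefinition:
    scale_id: str
    levels: Mapping[int, int]  # item index (1-based) -> number of answer choices
    scored_items: tuple[int, ...]
    reverse_items: frozenset[int] = frozenset()
    score_base: int = 0
    skip_rules: tuple[SkipRule, ...] = ()
    total_range: tuple[int, int] = (0, 0)

    @property
    def items(self) -> tuple[int, ...]:
        return tuple(sorted(self.levels))

    def item_score(self, item: int, answer_index: int) -> int:
        n = self.levels[item]
        if not 0 <= answer_index < n:
            raise ValueError(
                f"{self.scale_id} item {item}: answer index {answer_index} "
                f"outside 0..{n - 1}"
            )
        raw = (n - 1 - answer_index) if item in self.reverse_items else answer_index
        return self.score_base + raw

    def item_max(self, item: int) -> int:
        return self.score_base + self.levels[item] - 1

    def item_min(self, item: int) -> int:
        return self.score_base

    def validate(self) -> None:
        lo = sum(self.item_min(i) for i in self.scored_items)
        hi = sum(self.item_max(i) for i in self.scored_items)
        if (lo, hi) != self.total_range:
            raise ValueError(
                f"{self.scale_id}: scored items span {(lo, hi)}, "
                f"declared {self.total_range}"
            )


def _same(n_items: int, levels: int, start: int = 1) -> dict[int, int]:
    return {i: levels for i in range(start, start + n_items)}


SCALES: dict[str, ScaleDefinition] = {
    # Items 1-2 are context questions (index event, time since); the 17
    # symptom items 3-19 are scored 0-3 in printed order.
    "cpss": ScaleDefinition(
        "cpss",
        levels={1: 6, 2: 8, **_same(17, 4, start=3)},
        scored_items=tuple(range(3, 20)),
        total_range=(0, 51),
    ),
    # Items 1-9 are the depression items (0-3); items 10-11 probe suicidal
    # thinking behind skip logic and never enter the total.
    "phqa": ScaleDefinition(
        "phqa",
        levels={**_same(9, 4), 10: 2, 11: 2},
        scored_items=tuple(range(1, 10)),
        skip_rules=(SkipRule((9,), (10, 11), frozenset({0})),),
        total_range=(0, 27),
    ),
    # Items 4 and 5 are printed mild-first and score ascending; the other
    # five are printed severe-first and are reverse-coded so every item's
    # score rises with anxiety.
    "hads": ScaleDefinition(
        "hads",
        levels=_same(7, 4),
        scored_items=tuple(range(1, 8)),
        reverse_items=frozenset({1, 2, 3, 6, 7}),
        total_range=(0, 21),
    ),
    # Yes/no items; total is the yes-count over items 4-9 ("yes" is printed
    # first, so scoring is the 2-level reverse map).  Part B (5-9) is shown
    # only if any of 1-3 is "yes".
    "crafft": ScaleDefinition(
        "crafft",
        levels=_same(9, 2),
        scored_items=tuple(range(4, 10)),
        reverse_items=frozenset(range(4, 10)),
        skip_rules=(SkipRule((1, 2, 3), (5, 6, 7, 8, 9), frozenset({NO})),),
        total_range=(0, 6),
    ),
    "tobacco": ScaleDefinition(
        "tobacco",
        levels=_same(2, 2),
        scored_items=(),
        total_range=(0, 0),
    ),
    # All items printed "Strongly agree .. Strongly disagree".  Positive
    # self-statements (1,3,4,7,10) are reverse-coded so agreement scores 3;
    # negative self-statements score in printed order.  Higher = higher
    # self-esteem.
    "rosenberg": ScaleDefinition(
        "rosenberg",
        levels=_same(10, 4),
        scored_items=tuple(range(1, 11)),
        reverse_items=frozenset({1, 3, 4, 7, 10}),
        total_range=(0, 30),
    ),
    # Items 3 ("felt sad"), 4 ("felt lonely") and 11 (general health,
    # printed best-first) are reverse-coded; higher total = better quality
    # of life.
    "kidscreen": ScaleDefinition(
        "kidscreen",
        levels=_same(11, 5),
        scored_items=tuple(range(1, 12)),
        reverse_items=frozenset({3, 4, 11}),
        total_range=(0, 44),
    ),
    # Items score 1..5 ("Not at all".."A lot"), total 12-60.
    "cyrm": ScaleDefinition(
        "cyrm",
        levels=_same(12, 5),
        scored_items=tuple(range(1, 13)),
        score_base=1,
        total_range=(12, 60),
    ),
}

for _d in SCALES.values():
    _d.validate()

# Positive-self-image item sets used by the consistency screens.
ROSENBERG_POSITIVE = (1, 3, 4, 7, 10)
ROSENBERG_NEGATIVE = (2, 5, 6, 8, 9)
KIDSCREEN_POSITIVE = (1, 2, 5, 6, 7, 8, 9, 10, 11)


@dataclass
class SurveyResponse:
    """One anonymous survey row.

    ``age`` holds the parsed integer when the participant gave a numeric
    age, or the verbatim categorical extreme ("10 years or less" /
    "20 years or more").  ``answers`` maps ``(scale_id, item)`` to the
    0-based printed answer index; absent keys are unanswered items.
    """

    year: int
    age: int | str
    gender: str
    answers: dict[tuple[str, int], int] = field(default_factory=dict)

    def answer(self, scale_id: str, item: int) -> Optional[int]:
        return self.answers.get((scale_id, item))

    def scale_answers(self, scale_id: str) -> dict[int, int]:
        return {
            item: idx
            for (sid, item), idx in self.answers.items()
            if sid == scale_id
        }

    def validate(self) -> None:
        if self.year not in YEARS:
            raise ValueError(f"year {self.year!r} not in {YEARS}")
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        for (sid, item), idx in self.answers.items():
            d = SCALES.get(sid)
            if d is None or item not in d.levels:
                raise ValueError(f"unknown item {sid}_q{item}")
            if not 0 <= idx < d.levels[item]:
                raise ValueError(
                    f"{sid}_q{item}: answer index {idx} outside "
                    f"0..{d.levels[item] - 1}"
                )


@dataclass(frozen=True)
class ScaleScore:
    scale_id: str
    total: Optional[int]
    complete: bool

    def __post_init__(self) -> None:
        if (self.total is not None) != self.complete:
            raise ValueError("total must be present iff the scale is complete")


def score_scale(response: SurveyResponse, definition: ScaleDefinition) -> ScaleScore:
    """Sum per-item scores over the scored items of one instrument.

    Items legitimately skipped by a skip rule contribute 0 and do not break
    completeness.  A skipped item that was answered anyway is counted, with
    a warning.  The score is missing if any required item is unanswered.
    """
    if definition.scale_id not in SCALES:
        raise KeyError(f"unknown scale {definition.scale_id!r}")
    answers = response.scale_answers(definition.scale_id)

    skipped: set[int] = set()
    for rule in definition.skip_rules:
        status = rule.status(answers)
        if status is True:
            for item in rule.dependent_items:
                if item in answers:
                    logger.warning(
                        "%s item %d answered despite skip condition; counted",
                        definition.scale_id,
                        item,
                    )
                else:
                    skipped.add(item)
        # status None (condition unanswered): dependents stay required, so a
        # total is still computable when they were answered directly.

    total = 0
    for item in definition.scored_items:
        idx = answers.get(item)
        if idx is None:
            if item in skipped:
                continue
            return ScaleScore(definition.scale_id, None, False)
        total += definition.item_score(item, idx)
    return ScaleScore(definition.scale_id, total, True)


def score_crafft(response: SurveyResponse) -> ScaleScore:
    """Yes-count over CRAFFT questions 4-9, honouring the part-B skip."""
    return score_scale(response, SCALES["crafft"])


def assess_tobacco_use(response: SurveyResponse) -> TriState:
    """Positive if either tobacco question is "yes"."""
    a1 = response.answer("tobacco", 1)
    a2 = response.answer("tobacco", 2)
    if a1 == YES or a2 == YES:
        return TriState.POSITIVE
    if a1 == NO and a2 == NO:
        return TriState.NEGATIVE
    return TriState.NOT_EVALUABLE


def assess_suicidal_thinking(response: SurveyResponse) -> TriState:
    """Elevated PHQ-A question 9 combined with "yes" to question 10.

    "Not at all" on question 9 skips question 10 and is negative outright;
    an elevated question 9 with "no" to question 10 is negative.  Question
    11 is ignored.
    """
    q9 = response.answer("phqa", 9)
    q10 = response.answer("phqa", 10)
    if q9 is None:
        return TriState.NOT_EVALUABLE
    if q9 == 0:
        if q10 is not None:
            logger.warning("phqa q10 answered despite q9 'Not at all'; ignored")
        return TriState.NEGATIVE
    if q10 is None:
        return TriState.NOT_EVALUABLE
    return TriState.POSITIVE if q10 == YES else TriState.NEGATIVE


def item_columns() -> list[str]:
    """Flat CSV column names for every instrument item, in schema order."""
    return [
        f"{sid}_q{item}"
        for sid, d in SCALES.items()
        for item in d.items
    ]


def score_frame(df) -> "pd.DataFrame":
    """Vectorized scoring of a survey frame.

    Returns a frame with the meta columns plus, per instrument,
    ``<scale>_total`` (float, NaN when incomplete) and ``<scale>_complete``,
    and the two tri-state assessments ``suicidal`` and ``tobacco_use``
    coded 1.0 / 0.0 / NaN.
    """
    import numpy as np
    import pandas as pd

    out = df[["year", "age", "gender"]].copy()
    n = len(df)

    def answers(sid: str, items) -> "np.ndarray":
        cols = [f"{sid}_q{i}" for i in items]
        block = np.full((n, len(items)), np.nan)
        for j, c in enumerate(cols):
            if c in df.columns:
                block[:, j] = df[c].to_numpy(dtype=float)
        return block

    for sid, d in SCALES.items():
        if not d.scored_items:
            continue
        A = answers(sid, d.scored_items)
        S = np.empty_like(A)
        for j, item in enumerate(d.scored_items):
            col = A[:, j]
            if item in d.reverse_items:
                S[:, j] = d.levels[item] - 1 - col
            else:
                S[:, j] = col
        S += d.score_base
        present = ~np.isnan(A)

        if sid == "crafft":
            part_a = answers(sid, (1, 2, 3))
            all_no = np.all(part_a == NO, axis=1)
            q4_ok = present[:, 0]
            part_b_ok = present[:, 1:].all(axis=1)
            complete = q4_ok & (part_b_ok | all_no)
            total = np.nansum(np.where(present, S, 0.0), axis=1)
        else:
            complete = present.all(axis=1)
            total = S.sum(axis=1)

        out[f"{sid}_total"] = np.where(complete, total, np.nan)
        out[f"{sid}_complete"] = complete

    t1 = answers("tobacco", (1,))[:, 0]
    t2 = answers("tobacco", (2,))[:, 0]
    pos = (t1 == YES) | (t2 == YES)
    neg = (t1 == NO) & (t2 == NO)
    out["tobacco_use"] = np.where(pos, 1.0, np.where(neg, 0.0, np.nan))

    q9 = answers("phqa", (9,))[:, 0]
    q10 = answers("phqa", (10,))[:, 0]
    s_neg = (q9 == 0) | ((q9 > 0) & (q10 == NO))
    s_pos = (q9 > 0) & (q10 == YES)
    out["suicidal"] = np.where(s_pos, 1.0, np.where(s_neg, 0.0, np.nan))

    return out


def load_schema() -> dict:
    """Machine-readable questionnaire schema (items and answer texts)."""
    with resources.files("psybattery").joinpath("schema.json").open() as fh:
        return json.load(fh)


def answer_text(scale_id: str, item: int, answer_index: int) -> str:
    """Verbatim printed text of one answer choice."""
    schema = load_schema()
    choices = schema["questionnaires"][scale_id]["items"][str(item)]["answers"]
    return choices[answer_index]
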