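"""Exclusion criteria and cut-off based probable diagnoses.

Five exclusion criteria are applied, in order: the two categorical age
extremes, then three consistency screens (Rosenberg internal contradiction,
Rosenberg-vs-Kidscreen contradiction, HADS straight-lining across the two
reversed-order probe items).  The consistency screens are configurable
instantiations of "gave inconsistent answers"; the original rule details are
not public.

Diagnoses are tri-state: positive / negative / not-evaluable (incomplete
scale), so per-measure complete-case analysis falls out of the coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .scales import (
    AGE_HIGH_TEXT,
    AGE_LOW_TEXT,
    KIDSCREEN_POSITIVE,
    ROSENBERG_NEGATIVE,
    ROSENBERG_POSITIVE,
    SCALES,
    ScaleScore,
    SurveyResponse,
    TriState,
)

CRITERIA = (
    "age_low",
    "age_high",
    "rosenberg_inconsistent",
    "rosenberg_kidscreen_inconsistent",
    "hads_inconsistent",
)

INCLUDED = "included"


@dataclass(frozen=True)
class ConsistencyRules:
    """Tunable parameters of the three consistency screens.

    ``endorse_max_index``: largest answer index still counting as agreement
    on a 4-level agree..disagree item (1 = "Strongly agree"/"Agree").
    ``quartile``: width of the top/bottom band of the item-score range used
    by the Rosenberg-vs-Kidscreen cross-check.
    ``hads_gap``: scored-severity gap between reversed-order and
    normal-order HADS items that, combined with straight-lining, flags a
    respondent (3 = the maximum possible on 0-3 items).
    """

    endorse_max_index: int = 1
    quartile: float = 0.25
    hads_gap: int = 3


@dataclass
class ExclusionReport:
    """Per-survey decisions plus the aggregate ledger."""

    decisions: pd.Series  # "included" or the first matching criterion id
    counts: dict = field(default_factory=dict)

    @property
    def n_collected(self) -> int:
        return int(len(self.decisions))

    @property
    def n_excluded(self) -> int:
        return int((self.decisions != INCLUDED).sum())

    @property
    def n_included(self) -> int:
        return int((self.decisions == INCLUDED).sum())

    def to_frame(self) -> pd.DataFrame:
        rows = [("collected", self.n_collected)]
        rows += [(c, self.counts.get(c, 0)) for c in CRITERIA]
        rows += [("excluded", self.n_excluded), ("included", self.n_included)]
        return pd.DataFrame(rows, columns=["criterion", "count"])


def _block(df: pd.DataFrame, sid: str, items) -> np.ndarray:
    out = np.full((len(df), len(items)), np.nan)
    for j, i in enumerate(items):
        col = f"{sid}_q{i}"
        if col in df.columns:
            out[:, j] = df[col].to_numpy(dtype=float)
    return out


def _criterion_masks(df: pd.DataFrame, rules: ConsistencyRules) -> dict:
    age = df["age"]
    masks = {
        "age_low": (age == AGE_LOW_TEXT).to_numpy(),
        "age_high": (age == AGE_HIGH_TEXT).to_numpy(),
    }

    # (a) Rosenberg internal contradiction: endorsing (or rejecting) both
    # the positive and the negative item sets wholesale.
    pos = _block(df, "rosenberg", ROSENBERG_POSITIVE)
    neg = _block(df, "rosenberg", ROSENBERG_NEGATIVE)
    k = rules.endorse_max_index
    endorse_all = ((pos <= k).all(axis=1)) & ((neg <= k).all(axis=1))
    reject_all = ((pos > k).all(axis=1)) & ((neg > k).all(axis=1))
    masks["rosenberg_inconsistent"] = endorse_all | reject_all

    # (b) Rosenberg-vs-Kidscreen cross-check on positively phrased items:
    # self-esteem in the top band while quality of life is in the bottom
    # band, or vice versa.  Triggers only on fully answered item sets.
    ros_def = SCALES["rosenberg"]
    kid_def = SCALES["kidscreen"]
    ros_scores = np.stack(
        [3 - pos[:, j] if it in ros_def.reverse_items else pos[:, j]
         for j, it in enumerate(ROSENBERG_POSITIVE)],
        axis=1,
    )
    kid = _block(df, "kidscreen", KIDSCREEN_POSITIVE)
    kid_scores = np.stack(
        [4 - kid[:, j] if it in kid_def.reverse_items else kid[:, j]
         for j, it in enumerate(KIDSCREEN_POSITIVE)],
        axis=1,
    )
    q = rules.quartile
    with np.errstate(invalid="ignore"):
        ros_mean = ros_scores.mean(axis=1)
        kid_mean = kid_scores.mean(axis=1)
    ros_hi, ros_lo = ros_mean >= 3 * (1 - q), ros_mean <= 3 * q
    kid_hi, kid_lo = kid_mean >= 4 * (1 - q), kid_mean <= 4 * q
    rk = (ros_hi & kid_lo) | (ros_lo & kid_hi)
    masks["rosenberg_kidscreen_inconsistent"] = np.where(np.isnan(ros_mean + kid_mean), False, rk)

    # (c) HADS straight-lining: every answer at the same printed position
    # while reversed-order and normal-order items disagree maximally.
    hads_def = SCALES["hads"]
    hads = _block(df, "hads", hads_def.scored_items)
    same = (hads == hads[:, [0]]).all(axis=1)
    sev = np.stack(
        [3 - hads[:, j] if it in hads_def.reverse_items else hads[:, j]
         for j, it in enumerate(hads_def.scored_items)],
        axis=1,
    )
    rev_idx = [j for j, it in enumerate(hads_def.scored_items) if it in hads_def.reverse_items]
    fwd_idx = [j for j, it in enumerate(hads_def.scored_items) if it not in hads_def.reverse_items]
    gap = np.abs(sev[:, rev_idx].mean(axis=1) - sev[:, fwd_idx].mean(axis=1))
    masks["hads_inconsistent"] = np.where(np.isnan(gap), False, same & (gap >= rules.hads_gap))

    return masks


def apply_exclusions(
    surveys, rules: Optional[ConsistencyRules] = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the five exclusion criteria; first matching criterion wins.

    ``surveys`` is a validated survey frame (or a list of
    :class:`SurveyResponse`, converted internally).  Returns the included
    subset (with integer ages) and the exclusion ledger.
    """
    if isinstance(surveys, list):
        from .io import responses_to_frame

        surveys = responses_to_frame(surveys)
    rules = rules or ConsistencyRules()

    masks = _criterion_masks(surveys, rules)
    decisions = pd.Series(INCLUDED, index=surveys.index, dtype=object)
    for crit in CRITERIA:
        hit = masks[crit] & (decisions == INCLUDED).to_numpy()
        decisions[hit] = crit

    counts = {c: int((decisions == c).sum()) for c in CRITERIA}
    report = ExclusionReport(decisions=decisions, counts=counts)

    included = surveys.loc[decisions == INCLUDED].copy()
    included["age"] = included["age"].astype(int)
    bad_age = ~included["age"].between(11, 19)
    if bad_age.any():
        raise ValueError("retained survey with age outside 11-19")
    assert report.n_included + report.n_excluded == report.n_collected
    return included, report


@dataclass(frozen=True)
class DiagnosisThresholds:
    cpss_ptsd: int = 15
    phqa_depression: int = 11
    phqa_moderately_severe: int = 15
    hads_anxiety: int = 11
    crafft_disorder: int = 2

    def __post_init__(self) -> None:
        for scale, value in [
            ("cpss", self.cpss_ptsd),
            ("phqa", self.phqa_depression),
            ("phqa", self.phqa_moderately_severe),
            ("hads", self.hads_anxiety),
            ("crafft", self.crafft_disorder),
        ]:
            lo, hi = SCALES[scale].total_range
            if not lo < value <= hi:
                raise ValueError(
                    f"threshold {value} outside {scale} range ({lo}, {hi}]"
                )


ANY4_COMPONENTS = ("ptsd", "depression", "anxiety", "substance")


@dataclass(frozen=True)
class DiagnosisProfile:
    ptsd: TriState
    depression: TriState
    mod_severe_depression: TriState
    suicidal: TriState
    anxiety: TriState
    substance: TriState
    tobacco: TriState
    any4: TriState


def _threshold_state(score: ScaleScore, threshold: int) -> TriState:
    if not score.complete:
        return TriState.NOT_EVALUABLE
    return TriState.POSITIVE if score.total >= threshold else TriState.NEGATIVE


def derive_diagnoses(
    scores: dict[str, ScaleScore],
    suicidal: TriState,
    tobacco: TriState,
    thresholds: Optional[DiagnosisThresholds] = None,
) -> DiagnosisProfile:
    """Tri-state diagnosis flags for one survey from its scale scores.

    The any-of-4 composite is positive as soon as one component is
    positive, negative only when all four components are evaluable and
    negative, and not-evaluable otherwise.
    """
    t = thresholds or DiagnosisThresholds()
    flags = {
        "ptsd": _threshold_state(scores["cpss"], t.cpss_ptsd),
        "depression": _threshold_state(scores["phqa"], t.phqa_depression),
        "mod_severe_depression": _threshold_state(
            scores["phqa"], t.phqa_moderately_severe
        ),
        "anxiety": _threshold_state(scores["hads"], t.hads_anxiety),
        "substance": _threshold_state(scores["crafft"], t.crafft_disorder),
    }
    comp = [flags[c] for c in ANY4_COMPONENTS]
    if any(f is TriState.POSITIVE for f in comp):
        any4 = TriState.POSITIVE
    elif all(f is TriState.NEGATIVE for f in comp):
        any4 = TriState.NEGATIVE
    else:
        any4 = TriState.NOT_EVALUABLE
    return DiagnosisProfile(
        ptsd=flags["ptsd"],
        depression=flags["depression"],
        mod_severe_depression=flags["mod_severe_depression"],
        suicidal=suicidal,
        anxiety=flags["anxiety"],
        substance=flags["substance"],
        tobacco=tobacco,
        any4=any4,
    )


def diagnose_frame(
    scored: pd.DataFrame, thresholds: Optional[DiagnosisThresholds] = None
) -> pd.DataFrame:
    """Vectorized tri-state diagnosis columns (1.0 / 0.0 / NaN)."""
    t = thresholds or DiagnosisThresholds()
    out = scored.copy()

    def flag(total_col: str, threshold: int) -> np.ndarray:
        total = scored[total_col].to_numpy(dtype=float)
        return np.where(np.isnan(total), np.nan, (total >= threshold) * 1.0)

    out["ptsd"] = flag("cpss_total", t.cpss_ptsd)
    out["depression"] = flag("phqa_total", t.phqa_depression)
    out["mod_severe_depression"] = flag("phqa_total", t.phqa_moderately_severe)
    out["anxiety"] = flag("hads_total", t.hads_anxiety)
    out["substance"] = flag("crafft_total", t.crafft_disorder)
    out["tobacco"] = scored["tobacco_use"]

    comp = out[list(ANY4_COMPONENTS)].to_numpy(dtype=float)
    any_pos = np.nansum(comp == 1.0, axis=1) > 0
    all_neg = (comp == 0.0).all(axis=1)
    out["any4"] = np.where(any_pos, 1.0, np.where(all_neg, 0.0, np.nan))
    return out
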