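"""Full analysis battery: 15 measures x 5 effects, joint FDR, summaries.

The battery takes an analysis frame (screened surveys with scale totals and
tri-state diagnosis flags), runs one permutation test per (measure, effect)
cell with per-measure complete-case filtering, and applies a single step-up
FDR correction across every test that ran.  Binary measures enter the
linear machinery coded 0/100 so slopes read as percentage points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .inference import (
    EFFECTS,
    DegenerateDesignError,
    FdrResult,
    PermutationConfig,
    TestResult,
    bh_fdr,
    build_design,
    derive_rng,
    fit_slope,
    permutation_test,
)
from .scales import GENDERS, score_frame
from .screening import ConsistencyRules, DiagnosisThresholds, apply_exclusions, diagnose_frame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeasureSpec:
    measure_id: str
    kind: str  # "score" | "rate"
    column: str
    label: str

    def values(self, frame: pd.DataFrame) -> np.ndarray:
        v = frame[self.column].to_numpy(dtype=float)
        return v * 100.0 if self.kind == "rate" else v


MEASURES: dict[str, MeasureSpec] = {
    m.measure_id: m
    for m in [
        MeasureSpec("cpss", "score", "cpss_total", "CPSS score (PTSD)"),
        MeasureSpec("phqa", "score", "phqa_total", "PHQ-A score (depression)"),
        MeasureSpec("hads", "score", "hads_total", "HADS score (anxiety)"),
        MeasureSpec("crafft", "score", "crafft_total", "CRAFFT score (alcohol/drugs)"),
        MeasureSpec("rosenberg", "score", "rosenberg_total", "Rosenberg score (self-esteem)"),
        MeasureSpec("kidscreen", "score", "kidscreen_total", "Kidscreen score (quality of life)"),
        MeasureSpec("cyrm", "score", "cyrm_total", "CYRM-12 score (resilience)"),
        MeasureSpec("ptsd", "rate", "ptsd", "Probable PTSD"),
        MeasureSpec("depression", "rate", "depression", "Probable depression"),
        MeasureSpec(
            "mod_severe_depression", "rate", "mod_severe_depression",
            "Probable moderately severe depression",
        ),
        MeasureSpec("suicidal", "rate", "suicidal", "Suicidal thinking"),
        MeasureSpec("anxiety", "rate", "anxiety", "Probable anxiety"),
        MeasureSpec(
            "substance", "rate", "substance",
            "Probable alcohol/substance use disorder",
        ),
        MeasureSpec("tobacco", "rate", "tobacco", "Tobacco use"),
        MeasureSpec("any4", "rate", "any4", "Any of 4 probable diagnoses"),
    ]
}


@dataclass(frozen=True)
class BatteryConfig:
    permutations: int = 100_000
    seed: int = 0
    alpha: float = 0.05
    scheme: str = "effect"
    n_floor: int = 10
    age_min: int = 11
    age_max: int = 19
    measures: tuple[str, ...] = tuple(MEASURES)
    effects: tuple[str, ...] = tuple(EFFECTS)


@dataclass
class BatteryReport:
    results: list[TestResult]
    fdr: Optional[FdrResult]
    skipped: list[tuple[str, str, str]]  # (measure, effect, reason)
    config: BatteryConfig
    n_surveys: int

    def rejected(self, measure_id: str, effect_id: str) -> Optional[bool]:
        for i, r in enumerate(self.results):
            if r.measure_id == measure_id and r.effect_id == effect_id:
                return bool(self.fdr.rejected[i]) if self.fdr else None
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.results):
            rows.append(
                {
                    "measure": r.measure_id,
                    "effect": r.effect_id,
                    "n": r.n,
                    "slope": round(r.slope, 2),
                    "p_value": round(r.p_value, 5),
                    "fdr_significant": bool(self.fdr.rejected[i]) if self.fdr else None,
                    **{
                        f"group_{k}": v
                        for k, v in sorted(r.descriptives.items())
                    },
                }
            )
        return pd.DataFrame(rows)


def prepare_frame(
    surveys: pd.DataFrame,
    rules: Optional[ConsistencyRules] = None,
    thresholds: Optional[DiagnosisThresholds] = None,
):
    """Screen, score and diagnose a raw survey frame.

    Returns the analysis frame (one row per retained survey, with totals
    and tri-state flags) and the exclusion ledger.
    """
    included, report = apply_exclusions(surveys, rules)
    scored = score_frame(included)
    analysis = diagnose_frame(scored, thresholds)
    return analysis, report


def _group_descriptives(
    frame: pd.DataFrame, spec: MeasureSpec, effect_id: str
) -> dict:
    """Per-group mean +/- SD (scores) or rate % (binary), battery-style."""
    values = spec.values(frame)
    mask = ~np.isnan(values)
    if effect_id == "time":
        keys = frame["year"].to_numpy()
    elif effect_id == "age":
        keys = frame["age"].to_numpy()
    else:
        keys = frame["gender"].to_numpy()
    out = {}
    for key in pd.unique(keys[mask]):
        sub = values[mask & (keys == key)]
        if spec.kind == "rate":
            out[str(key)] = f"{sub.mean():.0f}%"
        else:
            out[str(key)] = f"{sub.mean():.2f} ± {sub.std(ddof=1):.2f}"
    return out


def run_single_test(
    frame: pd.DataFrame,
    measure_id: str,
    effect_id: str,
    config: BatteryConfig,
) -> TestResult:
    """One (measure, effect) permutation test on an analysis frame."""
    spec = MEASURES[measure_id]
    effect = EFFECTS[effect_id]
    sub = frame.loc[effect.inclusion_mask(frame)]
    values = spec.values(sub)
    mask = ~np.isnan(values)
    sub = sub.loc[mask]
    values = values[mask]
    design = build_design(sub, effect, values)
    result = permutation_test(
        design,
        PermutationConfig(
            iterations=config.permutations, seed=config.seed, scheme=config.scheme
        ),
        rng=derive_rng(config.seed, measure_id, effect_id),
    )
    result.measure_id = measure_id
    result.descriptives = _group_descriptives(sub, spec, effect_id)
    return result


def run_battery(frame: pd.DataFrame, config: Optional[BatteryConfig] = None) -> BatteryReport:
    """Run every configured (measure, effect) cell and one joint FDR.

    Cells whose usable N falls below the configured floor, or whose design
    cannot be built (empty comparison group), are skipped with a logged
    reason and excluded from the FDR family.
    """
    config = config or BatteryConfig()
    frame = frame.loc[frame["age"].between(config.age_min, config.age_max)]

    results: list[TestResult] = []
    skipped: list[tuple[str, str, str]] = []
    for measure_id in config.measures:
        spec = MEASURES[measure_id]
        for effect_id in config.effects:
            effect = EFFECTS[effect_id]
            sub = frame.loc[effect.inclusion_mask(frame)]
            values = spec.values(sub)
            n = int((~np.isnan(values)).sum())
            if n < config.n_floor:
                reason = f"N={n} below floor {config.n_floor}"
                logger.warning("skipping %s x %s: %s", measure_id, effect_id, reason)
                skipped.append((measure_id, effect_id, reason))
                continue
            try:
                results.append(run_single_test(frame, measure_id, effect_id, config))
            except (ValueError, DegenerateDesignError) as exc:
                logger.warning("skipping %s x %s: %s", measure_id, effect_id, exc)
                skipped.append((measure_id, effect_id, str(exc)))

    fdr = bh_fdr([r.p_value for r in results], config.alpha) if results else None
    return BatteryReport(
        results=results,
        fdr=fdr,
        skipped=skipped,
        config=config,
        n_surveys=int(len(frame)),
    )


def run_age_restricted(
    frame: pd.DataFrame,
    config: Optional[BatteryConfig] = None,
    age_min: int = 12,
    age_max: int = 17,
    baseline: Optional[BatteryReport] = None,
) -> tuple[BatteryReport, list[str]]:
    """Re-run the age-effect tests on an age-restricted subset.

    Returns the restricted report (its own FDR family over the age tests)
    and, when a full-range baseline report is given, the measures whose
    FDR conclusion flips.
    """
    config = config or BatteryConfig()
    restricted = replace(config, age_min=age_min, age_max=age_max, effects=("age",))
    report = run_battery(frame, restricted)
    changed = []
    if baseline is not None:
        for r in report.results:
            before = baseline.rejected(r.measure_id, "age")
            after = report.rejected(r.measure_id, "age")
            if before is not None and after is not None and before != after:
                changed.append(r.measure_id)
    return report, changed


def distribution_moments(shares: Sequence[float], values: Sequence[float]) -> tuple[float, float]:
    """Weighted mean and population SD of a categorical distribution.

    Shares are renormalized, so percentage rows that sum to 100 +/- rounding
    are accepted as-is.
    """
    w = np.asarray(shares, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("shares must be non-negative and sum > 0")
    w = w / w.sum()
    v = np.asarray(values, dtype=float)
    mean = float(w @ v)
    sd = float(np.sqrt(w @ (v - mean) ** 2))
    return mean, sd


def summarize(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Demographic summary tables (percent per year, gender, age)."""
    years = sorted(frame["year"].unique())
    ages = list(range(11, 20))

    def pct(series: pd.Series, categories) -> list[float]:
        n = len(series)
        return [round(100.0 * (series == c).sum() / n, 1) if n else 0.0 for c in categories]

    gender_rows = {"all": pct(frame["gender"], GENDERS)}
    age_rows = {"all": pct(frame["age"], ages)}
    counts = {"all": len(frame)}
    for y in years:
        sub = frame.loc[frame["year"] == y]
        gender_rows[y] = pct(sub["gender"], GENDERS)
        age_rows[y] = pct(sub["age"], ages)
        counts[y] = len(sub)

    age_by_gender = {"all": pct(frame["age"], ages)}
    for g in GENDERS:
        sub = frame.loc[frame["gender"] == g]
        age_by_gender[g] = pct(sub["age"], ages)

    return {
        "counts": pd.DataFrame(
            {"group": list(counts), "n": list(counts.values())}
        ),
        "gender": pd.DataFrame.from_dict(
            gender_rows, orient="index", columns=list(GENDERS)
        ),
        "age": pd.DataFrame.from_dict(age_rows, orient="index", columns=ages),
        "age_by_gender": pd.DataFrame.from_dict(
            age_by_gender, orient="index", columns=ages
        ),
    }
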