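"""Synthetic survey cohort generator with planted linear effects.

Every respondent gets, per instrument, a Gaussian latent severity on the
total-score axis:

    latent = baseline + b_time * t + b_age * (age - age_center)
             + gender offset (+ optional senior offset for ages >= 18)
             + Normal(0, sd)

The latent is clamped to the scale range, rounded to the nearest integer
total, and distributed over items (largest-remainder allocation with seeded
jitter) honouring skip rules and reverse-coded answer orders, so re-scoring
the emitted items recovers the intended total exactly.  Binary outcome
measures arise from the same latents crossing the screening thresholds;
tobacco use and suicidal thinking use dedicated latent propensities.

Item missingness, inconsistent responders (which trip the consistency
screens) and out-of-range age answers are injected at configurable rates.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import reference
from .scales import (
    AGE_HIGH_TEXT,
    AGE_LOW_TEXT,
    GENDERS,
    NO,
    SCALES,
    ScaleDefinition,
    YEARS,
    YES,
    item_columns,
)

logger = logging.getLogger(__name__)

CONTINUOUS_SCALES = ("cpss", "phqa", "hads", "crafft", "rosenberg", "kidscreen", "cyrm")


def _default_plants() -> dict:
    return copy.deepcopy(reference.DEFAULT_PLANTS)


def _default_ages() -> dict:
    return {y: list(reference.AGE_SHARES[y]) for y in YEARS}


def _default_genders() -> dict:
    return {y: dict(reference.GENDER_SHARES[y]) for y in YEARS}


@dataclass
class CohortConfig:
    """Generator calibration; defaults mirror the reference cohort."""

    n_per_year: Mapping[int, int] = field(
        default_factory=lambda: {
            y: reference.SURVEY_COUNTS[y]["included"] for y in YEARS
        }
    )
    age_shares: Mapping[int, list] = field(default_factory=_default_ages)
    gender_shares: Mapping[int, dict] = field(default_factory=_default_genders)
    plants: dict = field(default_factory=_default_plants)
    age_center: float = 14.3
    missing_rate: float = 0.0  # per-item missingness probability
    inconsistent_rate: float = 0.0  # straight-lining responders
    oor_age_rate: float = 0.0  # "10 years or less" / "20 years or more"
    tobacco_threshold: float = reference.TOBACCO_LATENT_THRESHOLD
    suicidal_threshold: float = reference.SUICIDAL_LATENT_THRESHOLD
    # extra latent offset for respondents aged >= 18, per measure id
    senior_offsets: dict = field(default_factory=dict)

    def validate(self) -> None:
        for y in YEARS:
            if self.n_per_year[y] < 0:
                raise ValueError("n per year must be >= 0")
            shares = np.asarray(self.age_shares[y], dtype=float)
            if (shares < 0).any() or shares.sum() <= 0:
                raise ValueError("age shares must be non-negative, sum > 0")
            g = self.gender_shares[y]
            if any(g[k] < 0 for k in GENDERS) or sum(g[k] for k in GENDERS) <= 0:
                raise ValueError("gender shares must be non-negative, sum > 0")
        for m, p in self.plants.items():
            if p["sd"] < 0:
                raise ValueError(f"{m}: residual sd must be >= 0")

    def null(self) -> "CohortConfig":
        """Copy with every planted slope/offset zeroed (type-I studies)."""
        cfg = copy.deepcopy(self)
        for p in cfg.plants.values():
            for k in ("time", "age", "female", "other", "pnts"):
                p[k] = 0.0
        cfg.senior_offsets = {}
        return cfg


def latent_mean(
    config: CohortConfig,
    measure: str,
    t: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
) -> np.ndarray:
    """Noise-free latent severity for given demographics (vectorized)."""
    p = config.plants[measure]
    mu = (
        p["baseline"]
        + p["time"] * np.asarray(t, dtype=float)
        + p["age"] * (np.asarray(age, dtype=float) - config.age_center)
    )
    gender = np.asarray(gender)
    # female offset relative to male; minority-identity offsets relative to
    # the female/male mixture (approximated by its midpoint)
    mu = mu + np.where(gender == "female", p["female"], 0.0)
    half = p["female"] / 2.0
    mu = mu + np.where(gender == "other", half + p["other"], 0.0)
    mu = mu + np.where(gender == "prefer_not_say", half + p["pnts"], 0.0)
    senior = config.senior_offsets.get(measure, 0.0)
    if senior:
        mu = mu + np.where(np.asarray(age, dtype=float) >= 18, senior, 0.0)
    return mu


def allocate_totals(
    totals: np.ndarray, definition: ScaleDefinition, rng: np.random.Generator
) -> np.ndarray:
    """Distribute integer totals over scored items (rows x items).

    Largest-remainder allocation of the points above the per-item minima,
    with seeded jitter breaking ties, capped at each item's maximum.
    Row sums equal ``totals`` exactly.
    """
    items = definition.scored_items
    caps = np.array([definition.levels[i] - 1 for i in items], dtype=float)
    lo = definition.score_base * len(items)
    extra = np.asarray(totals, dtype=float) - lo
    if (extra < 0).any() or (extra > caps.sum()).any():
        raise ValueError("total outside the scale range")

    quota = np.outer(extra, caps) / caps.sum()
    base = np.floor(quota)
    remainder = (extra - base.sum(axis=1)).astype(int)
    frac = quota - base
    key = frac + rng.random(frac.shape) * 1e-9  # jitter breaks exact ties
    order = np.argsort(-key, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(len(items))[None, :], axis=1)
    add = ranks < remainder[:, None]
    scores = definition.score_base + base + add
    assert np.array_equal(scores.sum(axis=1), np.asarray(totals))
    return scores.astype(int)


def items_from_severity(
    severity: float, definition: ScaleDefinition, rng: np.random.Generator
) -> dict[int, int]:
    """Single-row item answers whose re-score equals clamp(round(severity))."""
    lo, hi = definition.total_range
    total = int(np.clip(np.rint(severity), lo, hi))
    scores = allocate_totals(np.array([total]), definition, rng)[0]
    answers = {}
    for j, item in enumerate(definition.scored_items):
        raw = scores[j] - definition.score_base
        n = definition.levels[item]
        answers[item] = (n - 1 - raw) if item in definition.reverse_items else raw
    return answers


def _discretize(latent: np.ndarray, definition: ScaleDefinition) -> tuple[np.ndarray, int]:
    lo, hi = definition.total_range
    clamped = np.clip(np.rint(latent), lo, hi)
    n_clamped = int(((latent < lo - 0.5) | (latent > hi + 0.5)).sum())
    return clamped.astype(int), n_clamped


def generate_cohort(config: Optional[CohortConfig] = None, seed: int = 0) -> pd.DataFrame:
    """Generate a raw item-level survey frame (CSV schema) deterministically."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))

    years = np.concatenate(
        [np.full(config.n_per_year[y], y, dtype=int) for y in YEARS]
    )
    n = len(years)
    ages = np.empty(n, dtype=int)
    genders = np.empty(n, dtype=object)
    offset = 0
    for y in YEARS:
        ny = config.n_per_year[y]
        a = np.asarray(config.age_shares[y], dtype=float)
        ages[offset : offset + ny] = rng.choice(
            reference.AGES, size=ny, p=a / a.sum()
        )
        g = np.array([config.gender_shares[y][k] for k in GENDERS], dtype=float)
        genders[offset : offset + ny] = rng.choice(
            list(GENDERS), size=ny, p=g / g.sum()
        )
        offset += ny
    t = years - YEARS[0]

    data: dict[str, np.ndarray] = {}
    clamp_log: dict[str, int] = {}
    latents: dict[str, np.ndarray] = {}
    for sid in CONTINUOUS_SCALES:
        d = SCALES[sid]
        mu = latent_mean(config, sid, t, ages, genders)
        latent = mu + rng.normal(0.0, config.plants[sid]["sd"], size=n)
        latents[sid] = latent
        totals, n_clamped = _discretize(latent, d)
        if n_clamped:
            clamp_log[sid] = n_clamped
        scores = allocate_totals(totals, d, rng)
        for j, item in enumerate(d.scored_items):
            raw = scores[:, j] - d.score_base
            levels = d.levels[item]
            idx = (levels - 1 - raw) if item in d.reverse_items else raw
            data[f"{sid}_q{item}"] = idx.astype(float)

    # CPSS context items (unscored): random plausible answers
    data["cpss_q1"] = rng.integers(0, SCALES["cpss"].levels[1], size=n).astype(float)
    data["cpss_q2"] = rng.integers(0, SCALES["cpss"].levels[2], size=n).astype(float)

    # CRAFFT part A consistent with the allocated part-B yeses
    part_b_yes = np.zeros(n, dtype=bool)
    for item in (5, 6, 7, 8, 9):
        part_b_yes |= data[f"crafft_q{item}"] == YES
    data["crafft_q1"] = np.where(part_b_yes, YES, NO).astype(float)
    data["crafft_q2"] = np.full(n, NO, dtype=float)
    data["crafft_q3"] = np.full(n, NO, dtype=float)
    for item in (5, 6, 7, 8, 9):  # part B hidden when part A is all "no"
        col = data[f"crafft_q{item}"]
        data[f"crafft_q{item}"] = np.where(part_b_yes, col, np.nan)

    # suicidal thinking: gated question 10 driven by the depression latent
    q9 = data["phqa_q9"]
    suicidal = latents["phqa"] >= config.suicidal_threshold
    q10 = np.where(q9 > 0, np.where(suicidal, YES, NO).astype(float), np.nan)
    q11 = np.where(
        q9 > 0, rng.integers(0, 2, size=n).astype(float), np.nan
    )
    data["phqa_q10"] = q10
    data["phqa_q11"] = q11

    # tobacco: positive when the 0-100 propensity crosses its threshold
    tob_mu = latent_mean(config, "tobacco", t, ages, genders)
    tob_latent = tob_mu + rng.normal(0.0, config.plants["tobacco"]["sd"], size=n)
    tob_pos = tob_latent >= config.tobacco_threshold
    smokeless = rng.random(n) < 0.3
    data["tobacco_q1"] = np.where(tob_pos, YES, NO).astype(float)
    data["tobacco_q2"] = np.where(tob_pos & smokeless, YES, NO).astype(float)

    # item missingness (demographics never go missing)
    if config.missing_rate > 0:
        for col in list(data):
            drop = rng.random(n) < config.missing_rate
            data[col] = np.where(drop, np.nan, data[col])

    # inconsistent responders: straight-line full agreement on Rosenberg,
    # which contradicts itself across the positive and negative item sets
    inconsistent = (
        rng.random(n) < config.inconsistent_rate
        if config.inconsistent_rate > 0
        else np.zeros(n, dtype=bool)
    )
    for item in SCALES["rosenberg"].scored_items:
        col = data[f"rosenberg_q{item}"]
        data[f"rosenberg_q{item}"] = np.where(inconsistent, 0.0, col)

    age_answers = ages.astype(object)
    if config.oor_age_rate > 0:
        oor = rng.random(n) < config.oor_age_rate
        extremes = rng.choice([AGE_LOW_TEXT, AGE_HIGH_TEXT], size=n)
        age_answers = np.where(oor, extremes, age_answers)

    if clamp_log:
        logger.info(
            "clamped latent severities: %s",
            ", ".join(f"{k}={v}" for k, v in sorted(clamp_log.items())),
        )

    frame = pd.DataFrame({"year": years, "age": age_answers, "gender": genders})
    for col in item_columns():
        frame[col] = data[col]
    return frame


def expected_cell_means(config: CohortConfig, measure: str) -> pd.DataFrame:
    """Analytic expected outcome per (year, age, gender) cell.

    Independent oracle for planted-effect recovery: for continuous measures
    the expectation of the clamped, rounded Gaussian latent; for binary
    measures 100 x the probability that the relevant latent crosses its
    screening threshold (any-of-4 by independence of the four latents).
    Returns cell weights (population probabilities) alongside the means.
    """
    from scipy.stats import norm

    from .screening import DiagnosisThresholds

    rows = []
    for y in YEARS:
        n_y = config.n_per_year[y]
        a = np.asarray(config.age_shares[y], dtype=float)
        a = a / a.sum()
        g = np.array([config.gender_shares[y][k] for k in GENDERS], dtype=float)
        g = g / g.sum()
        total_n = sum(config.n_per_year[yy] for yy in YEARS)
        for ai, age in enumerate(reference.AGES):
            for gi, gender in enumerate(GENDERS):
                rows.append(
                    {
                        "year": y,
                        "age": age,
                        "gender": gender,
                        "weight": (n_y / total_n) * a[ai] * g[gi],
                    }
                )
    cells = pd.DataFrame(rows)
    t = cells["year"].to_numpy() - YEARS[0]
    age = cells["age"].to_numpy()
    gender = cells["gender"].to_numpy()

    def cross_prob(scale: str, threshold: float) -> np.ndarray:
        mu = latent_mean(config, scale, t, age, gender)
        sd = config.plants[scale]["sd"]
        if sd == 0:
            return (mu >= threshold - 0.5).astype(float)
        return 1.0 - norm.cdf((threshold - 0.5 - mu) / sd)

    th = DiagnosisThresholds()
    if measure in CONTINUOUS_SCALES:
        d = SCALES[measure]
        lo, hi = d.total_range
        mu = latent_mean(config, measure, t, age, gender)
        sd = config.plants[measure]["sd"]
        ks = np.arange(lo, hi + 1)
        if sd == 0:
            mean = np.clip(np.rint(mu), lo, hi)
        else:
            edges = np.concatenate(([-np.inf], ks[:-1] + 0.5, [np.inf]))
            cdf = norm.cdf((edges[None, :] - mu[:, None]) / sd)
            probs = np.diff(cdf, axis=1)
            mean = probs @ ks
        cells["mean"] = mean
    elif measure == "tobacco":
        mu = latent_mean(config, "tobacco", t, age, gender)
        sd = config.plants["tobacco"]["sd"]
        z = (config.tobacco_threshold - mu) / sd
        cells["mean"] = 100.0 * (1.0 - norm.cdf(z))
    elif measure == "any4":
        miss = np.ones(len(cells))
        for scale, threshold in [
            ("cpss", th.cpss_ptsd),
            ("phqa", th.phqa_depression),
            ("hads", th.hads_anxiety),
            ("crafft", th.crafft_disorder),
        ]:
            miss *= 1.0 - cross_prob(scale, threshold)
        cells["mean"] = 100.0 * (1.0 - miss)
    else:
        scale, threshold = {
            "ptsd": ("cpss", th.cpss_ptsd),
            "depression": ("phqa", th.phqa_depression),
            "mod_severe_depression": ("phqa", th.phqa_moderately_severe),
            "anxiety": ("hads", th.hads_anxiety),
            "substance": ("crafft", th.crafft_disorder),
        }[measure]
        cells["mean"] = 100.0 * cross_prob(scale, threshold)
    return cells


def population_slope(config: CohortConfig, measure: str, effect_id: str) -> float:
    """Population-level OLS slope implied by the planted parameters.

    Solves the weighted normal equations over demographic cells using the
    analytic cell means — an oracle independent of the sampling, item
    allocation and permutation machinery.
    """
    from .inference import EFFECTS

    cells = expected_cell_means(config, measure)
    spec = EFFECTS[effect_id]
    cells = cells.loc[spec.inclusion_mask(cells)].reset_index(drop=True)
    w = cells["weight"].to_numpy()
    w = w / w.sum()

    # weighted centring/normal equations via sqrt-weight row scaling of an
    # uncentred design, then partitioned regression for the slope
    x = spec.encode(cells).astype(float)
    cols = [x]
    if not spec.categorical:
        cols[0] = x - w @ x
    if spec.intercept:
        cols.append(np.ones(len(cells)))
    for name in spec.covariates:
        v = (cells["year"] - YEARS[0]).to_numpy(dtype=float) if name == "time" else cells["age"].to_numpy(dtype=float)
        cols.append(v - w @ v)
    if spec.gender_indicators:
        for g in GENDERS:
            cols.append((cells["gender"] == g).to_numpy(dtype=float))
    X = np.column_stack(cols)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = cells["mean"].to_numpy() * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    return float(beta[0])
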