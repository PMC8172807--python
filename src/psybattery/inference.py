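"""Design matrices, OLS slopes, permutation tests and step-up FDR.

Every test fits an ordinary-least-squares linear model whose first column
is the tested effect variable and whose remaining columns are nuisance
terms, then compares the absolute fitted slope against absolute slopes
refitted under random relabellings.

Design conventions: the time and age effects are mean-centred covariates
accompanied by four gender indicator columns and no intercept (the
indicators span the constant); the three gender contrasts are 0/1 coded,
not centred, with an intercept plus centred time and age covariates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .scales import GENDERS

BASE_YEAR = 2017


class DegenerateDesignError(np.linalg.LinAlgError):
    """Model matrix with linearly dependent columns."""


@dataclass(frozen=True)
class EffectSpec:
    """How one tested effect selects rows and builds its model matrix."""

    effect_id: str
    categorical: bool
    covariates: tuple[str, ...]  # mean-centred nuisance covariates
    gender_indicators: bool  # four 0/1 nuisance columns, one per identity
    intercept: bool
    include_genders: Optional[tuple[str, ...]]  # None = all rows
    encode: Callable[[pd.DataFrame], np.ndarray]

    def inclusion_mask(self, df: pd.DataFrame) -> np.ndarray:
        if self.include_genders is None:
            return np.ones(len(df), dtype=bool)
        return df["gender"].isin(self.include_genders).to_numpy()


def _covariate(df: pd.DataFrame, name: str) -> np.ndarray:
    if name == "time":
        return df["year"].to_numpy(dtype=float) - BASE_YEAR
    if name == "age":
        return df["age"].to_numpy(dtype=float)
    raise KeyError(name)


def _gender_contrast(group: str) -> Callable[[pd.DataFrame], np.ndarray]:
    def encode(df: pd.DataFrame) -> np.ndarray:
        return (df["gender"] == group).to_numpy(dtype=float)

    return encode


EFFECTS: dict[str, EffectSpec] = {
    "time": EffectSpec(
        "time",
        categorical=False,
        covariates=("age",),
        gender_indicators=True,
        intercept=False,
        include_genders=None,
        encode=lambda df: _covariate(df, "time"),
    ),
    "age": EffectSpec(
        "age",
        categorical=False,
        covariates=("time",),
        gender_indicators=True,
        intercept=False,
        include_genders=None,
        encode=lambda df: _covariate(df, "age"),
    ),
    "female_vs_male": EffectSpec(
        "female_vs_male",
        categorical=True,
        covariates=("time", "age"),
        gender_indicators=False,
        intercept=True,
        include_genders=("female", "male"),
        encode=_gender_contrast("female"),
    ),
    "other_vs_fm": EffectSpec(
        "other_vs_fm",
        categorical=True,
        covariates=("time", "age"),
        gender_indicators=False,
        intercept=True,
        include_genders=("female", "male", "other"),
        encode=_gender_contrast("other"),
    ),
    "pnts_vs_fm": EffectSpec(
        "pnts_vs_fm",
        categorical=True,
        covariates=("time", "age"),
        gender_indicators=False,
        intercept=True,
        include_genders=("female", "male", "prefer_not_say"),
        encode=_gender_contrast("prefer_not_say"),
    ),
}


@dataclass
class DesignMatrix:
    """Model matrix with the effect in column 0, plus the response."""

    X: np.ndarray
    y: np.ndarray
    columns: tuple[str, ...]
    effect_id: str
    centred_columns: tuple[int, ...] = ()

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def validate(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("design contains missing values")
        for j in self.centred_columns:
            if abs(self.X[:, j].sum()) > 1e-8 * max(1, self.n):
                raise ValueError(f"column {self.columns[j]} not centred")
        _check_full_rank(self.X, self.columns)


def _check_full_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via rank-revealing QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(columns[j] for j in piv[rank:])
        raise DegenerateDesignError(
            f"model matrix is rank deficient; collinear columns: {bad}"
        )


def build_design(
    df: pd.DataFrame, effect: str | EffectSpec, y: np.ndarray
) -> DesignMatrix:
    """Assemble the model matrix for one effect over pre-filtered rows.

    ``df`` must already be restricted to the effect's included gender
    identities and to rows with a complete value for the measure; ``y`` is
    the aligned response vector.
    """
    spec = EFFECTS[effect] if isinstance(effect, str) else effect
    y = np.asarray(y, dtype=float)
    if len(df) == 0:
        raise ValueError(f"empty design for effect {spec.effect_id!r}")
    if spec.include_genders is not None:
        if not df["gender"].isin(spec.include_genders).all():
            raise ValueError("rows outside the effect's gender inclusion filter")

    x = spec.encode(df).astype(float)
    if spec.categorical and (x.min() == x.max()):
        raise ValueError(
            f"effect {spec.effect_id!r}: a comparison group is empty"
        )
    cols: list[np.ndarray] = [x]
    names = [spec.effect_id]
    centred: list[int] = []
    if not spec.categorical:
        cols[0] = x - x.mean()
        centred.append(0)

    if spec.intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")

    for name in spec.covariates:
        v = _covariate(df, name)
        cols.append(v - v.mean())
        centred.append(len(cols) - 1)
        names.append(name)

    if spec.gender_indicators:
        # only identities actually present: an all-zero indicator would
        # make the matrix rank deficient without informing the fit
        present = set(df["gender"].unique())
        for g in GENDERS:
            if g in present:
                cols.append((df["gender"] == g).to_numpy(dtype=float))
                names.append(f"gender[{g}]")

    design = DesignMatrix(
        X=np.column_stack(cols),
        y=y,
        columns=tuple(names),
        effect_id=spec.effect_id,
        centred_columns=tuple(centred),
    )
    design.validate()
    return design


def fit_slope(design: DesignMatrix) -> float:
    """First element of the normal-equations solution (X'X)^-1 X'y."""
    X, y = design.X, design.y
    xtx = X.T @ X
    try:
        beta = np.linalg.solve(xtx, X.T @ y)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError(str(exc)) from exc
    return float(beta[0])


@dataclass(frozen=True)
class PermutationConfig:
    iterations: int = 100_000
    seed: int = 0
    scheme: str = "effect"  # or "freedman_lane"
    chunk: int = 256

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.scheme not in ("effect", "freedman_lane"):
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")


@dataclass
class TestResult:
    measure_id: Optional[str]
    effect_id: str
    n: int
    slope: float
    p_value: float
    iterations: int
    perm_sd: float
    descriptives: dict = field(default_factory=dict)


def derive_rng(seed: int, *keys: str) -> np.random.Generator:
    """Deterministic per-test stream, independent of battery order."""
    entropy = [int(seed)] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def permutation_test(
    design: DesignMatrix,
    config: Optional[PermutationConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> TestResult:
    """Two-tailed permutation p-value for the effect-column slope.

    Under the ``effect`` scheme the effect column is shuffled across rows,
    leaving response and nuisance rows intact; under ``freedman_lane`` the
    nuisance-model residuals of the response are shuffled instead.  The
    p-value is (r + 1) / (B + 1) with r the number of permuted absolute
    slopes at least as large as the observed one, so it can never be 0.
    """
    config = config or PermutationConfig()
    if rng is None:
        rng = derive_rng(config.seed, design.effect_id)

    beta1 = fit_slope(design)

    x = design.X[:, 0].copy()
    Z = design.X[:, 1:]
    y = design.y
    n, b = design.n, config.iterations

    # Partialled quantities: slope = x~'y / x~'x~ with x~ = x off Z
    # (partitioned-regression identity; exact for any full-rank design).
    if Z.shape[1] > 0:
        chol = cholesky(Z.T @ Z, lower=True)
        x_res = x - Z @ cho_solve((chol, True), Z.T @ x)
        y_res = y - Z @ cho_solve((chol, True), Z.T @ y)
    else:
        chol = None
        x_res = x.copy()
        y_res = y.copy()
    denom0 = x_res @ x_res
    if denom0 <= 1e-12 * max(1.0, x @ x):
        raise DegenerateDesignError("effect column is collinear with nuisance")
    assert np.isclose(x_res @ y / denom0, beta1, rtol=1e-8, atol=1e-10)

    xx = x @ x
    perm_slopes = np.empty(b)
    degenerate = 0
    done = 0
    while done < b:
        c = min(config.chunk, b - done)
        if config.scheme == "effect":
            # c independent permutations of the effect column, one per row
            Xp = rng.permuted(np.broadcast_to(x, (c, n)), axis=1, out=np.empty((c, n))).T
            if chol is not None:
                u = solve_triangular(chol, Z.T @ Xp, lower=True)
                denom = xx - (u * u).sum(axis=0)
            else:
                denom = np.full(c, xx)
            numer = y_res @ Xp
            ok = denom > 1e-12 * max(1.0, xx)
            degenerate += int((~ok).sum())
            slopes = np.where(ok, numer / np.where(ok, denom, 1.0), np.inf)
        else:  # freedman_lane: y* = Z g + P(e); slope* = x~'e* / x~'x~
            Ep = rng.permuted(
                np.broadcast_to(y_res, (c, n)), axis=1, out=np.empty((c, n))
            ).T
            slopes = (x_res @ Ep) / denom0
        perm_slopes[done : done + c] = slopes
        done += c

    if degenerate > 0.01 * b:
        raise DegenerateDesignError(
            f"{degenerate}/{b} permutations produced singular designs"
        )
    finite = np.isfinite(perm_slopes)
    # slopes numerically indistinguishable from zero (relative to the
    # largest slope the data could support) are treated as exact zeros, so
    # a constant response yields p = 1 rather than float-noise ordering
    tol = 1e-12 * np.sqrt(max(y @ y, 1e-300) / max(denom0, 1e-300))
    threshold = abs(beta1) if abs(beta1) >= tol else 0.0
    # ties (permutations reproducing |slope| exactly) must count toward r;
    # a hair of relative slack absorbs float noise between the direct and
    # the projection-based slope formulas, erring conservatively
    r = int((np.abs(perm_slopes[finite]) >= threshold * (1 - 1e-9)).sum()) + int(
        (~finite).sum()
    )
    p = (r + 1) / (b + 1)
    return TestResult(
        measure_id=None,
        effect_id=design.effect_id,
        n=n,
        slope=beta1,
        p_value=p,
        iterations=b,
        perm_sd=float(np.std(perm_slopes[finite])) if finite.any() else float("nan"),
    )


@dataclass
class FdrResult:
    p_values: np.ndarray
    rejected: np.ndarray
    threshold: float
    alpha: float

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05) -> FdrResult:
    """Step-up false-discovery-rate control.

    Rejects every test with p <= p_(k*), where k* is the largest k such
    that p_(k) <= (k/m) * alpha; tied p-values share a fate.  The realized
    threshold is p_(k*), or 0.0 when nothing is rejected.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")

    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = (np.arange(1, m + 1) / m) * alpha
    passing = np.nonzero(sorted_p <= crit)[0]
    if passing.size == 0:
        return FdrResult(p, np.zeros(m, dtype=bool), 0.0, alpha)
    threshold = float(sorted_p[passing.max()])
    return FdrResult(p, p <= threshold, threshold, alpha)
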