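import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psybattery.inference import (
    EFFECTS,
    DegenerateDesignError,
    DesignMatrix,
    PermutationConfig,
    bh_fdr,
    build_design,
    derive_rng,
    fit_slope,
    permutation_test,
)
from psybattery.reference import REFERENCE_NONSIGNIFICANT, REFERENCE_PVALUES


def demo_frame(n, rng, genders=("female", "male", "other", "prefer_not_say")):
    return pd.DataFrame(
        {
            "year": rng.choice([2017, 2018, 2019], size=n),
            "age": rng.integers(11, 20, size=n),
            "gender": rng.choice(list(genders), size=n),
        }
    )


class TestBuildDesign:
    def test_time_design_shape_and_columns(self, rng):
        df = demo_frame(40, rng)
        design = build_design(df, "time", rng.normal(size=40))
        assert design.X.shape == (40, 6)
        assert design.columns[0] == "time"
        assert "intercept" not in design.columns
        # centred effect and age columns
        assert abs(design.X[:, 0].sum()) < 1e-8
        assert abs(design.X[:, 1].sum()) < 1e-8
        # gender indicators partition the rows
        assert np.array_equal(design.X[:, 2:].sum(axis=1), np.ones(40))

    def test_gender_design_coding(self, rng):
        df = demo_frame(60, rng, genders=("female", "male", "other"))
        design = build_design(df, "other_vs_fm", np.zeros(60))
        assert design.X.shape == (60, 4)
        assert design.columns == ("other_vs_fm", "intercept", "time", "age")
        x = design.X[:, 0]
        assert set(np.unique(x)) <= {0.0, 1.0}
        assert np.array_equal(x == 1.0, (df["gender"] == "other").to_numpy())
        # categorical effect not centred; covariates centred
        assert abs(design.X[:, 2].sum()) < 1e-8
        assert abs(design.X[:, 3].sum()) < 1e-8

    def test_rows_outside_filter_rejected(self, rng):
        df = demo_frame(30, rng)
        with pytest.raises(ValueError):
            build_design(df, "female_vs_male", np.zeros(30))

    def test_empty_comparison_group(self, rng):
        df = demo_frame(30, rng, genders=("female", "male"))
        with pytest.raises(ValueError, match="empty"):
            build_design(df, "other_vs_fm", np.zeros(30))

    def test_degenerate_design_names_columns(self):
        X = np.column_stack([np.arange(5.0), np.ones(5), np.ones(5)])
        d = DesignMatrix(X, np.zeros(5), ("x", "a", "b"), "custom")
        with pytest.raises(DegenerateDesignError, match="collinear"):
            d.validate()


class TestFitSlope:
    def test_exact_simple_regression(self):
        X = np.column_stack([[-1.0, 0.0, 1.0], np.ones(3)])
        d = DesignMatrix(X, np.array([2.0, 4.0, 6.0]), ("x", "intercept"), "x")
        assert fit_slope(d) == pytest.approx(2.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_matches_lstsq_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        d = DesignMatrix(X, y, ("x", "a", "b"), "x")
        oracle = np.linalg.lstsq(X, y, rcond=None)[0][0]
        assert fit_slope(d) == pytest.approx(oracle, abs=1e-10)

    def test_orthogonal_nuisance_leaves_slope(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        z -= z @ x / (x @ x) * x  # orthogonalize
        y = rng.normal(size=50)
        with_z = DesignMatrix(np.column_stack([x, z]), y, ("x", "z"), "x")
        without = DesignMatrix(x[:, None], y, ("x",), "x")
        assert fit_slope(with_z) == pytest.approx(fit_slope(without), abs=1e-10)

    def test_frisch_waugh_identity(self, rng):
        """Full-design slope equals simple regression on residualized parts."""
        df = demo_frame(120, rng)
        y = rng.normal(size=120)
        design = build_design(df, "age", y)
        x, Z = design.X[:, 0], design.X[:, 1:]
        px = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        py = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        assert fit_slope(design) == pytest.approx(px @ py / (px @ px), rel=1e-9)

    def test_nuisance_order_invariance(self, rng):
        df = demo_frame(80, rng, genders=("female", "male"))
        y = rng.normal(size=80)
        d1 = build_design(df, "female_vs_male", y)
        # same columns, covariates swapped
        X2 = d1.X[:, [0, 1, 3, 2]]
        d2 = DesignMatrix(X2, y, ("female_vs_male", "intercept", "age", "time"), "female_vs_male")
        assert fit_slope(d1) == pytest.approx(fit_slope(d2), rel=1e-10)


def enumeration_pvalue(x, y, Z=None):
    """Exact permutation p-value by enumerating all n! relabellings."""
    n = len(x)
    cols = [np.asarray(x, dtype=float)]
    if Z is not None:
        cols.extend(np.asarray(Z, dtype=float).T)
    X = np.column_stack(cols)
    obs = abs(np.linalg.lstsq(X, y, rcond=None)[0][0])
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        Xp = X.copy()
        Xp[:, 0] = X[list(perm), 0]
        b = abs(np.linalg.lstsq(Xp, y, rcond=None)[0][0])
        count += b >= obs - 1e-12
        total += 1
    return count / total


class TestPermutationTest:
    def test_constant_response_p_one(self, rng):
        x = rng.normal(size=30)
        d = DesignMatrix(
            np.column_stack([x - x.mean(), np.ones(30)]),
            np.full(30, 3.0),
            ("x", "intercept"),
            "x",
        )
        res = permutation_test(d, PermutationConfig(iterations=500, seed=1))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_perfect_fit_attains_minimum(self, rng):
        x = rng.normal(size=50)
        d = DesignMatrix(
            np.column_stack([x, np.ones(50)]), x.copy(), ("x", "intercept"), "x"
        )
        res = permutation_test(d, PermutationConfig(iterations=999, seed=2))
        assert res.p_value == pytest.approx(1 / 1000)

    @pytest.mark.parametrize("with_nuisance", [False, True])
    def test_enumeration_oracle_n5(self, rng, with_nuisance):
        """Monte-Carlo p within 3 binomial SEs of the exact enumeration."""
        x = np.array([0.3, -1.2, 0.7, 1.9, -0.5])
        y = np.array([0.2, -0.9, 1.3, 1.1, -0.2])
        Z = np.column_stack([np.ones(5), [0.1, 0.4, -0.2, 0.3, 0.0]]) if with_nuisance else np.ones((5, 1))
        exact = enumeration_pvalue(x, y, Z)
        d = DesignMatrix(
            np.column_stack([x, Z]),
            y,
            ("x",) + tuple(f"z{i}" for i in range(Z.shape[1])),
            "x",
        )
        B = 100_000
        res = permutation_test(d, PermutationConfig(iterations=B, seed=3))
        se = np.sqrt(exact * (1 - exact) / B)
        assert abs(res.p_value - exact) <= 3 * se + 2 / B

    def test_deterministic_given_seed(self, rng):
        df = demo_frame(60, rng)
        y = rng.normal(size=60)
        d = build_design(df, "time", y)
        r1 = permutation_test(d, PermutationConfig(iterations=300, seed=42))
        r2 = permutation_test(d, PermutationConfig(iterations=300, seed=42))
        assert r1.p_value == r2.p_value and r1.slope == r2.slope

    def test_minimum_p_is_never_zero(self, rng):
        df = demo_frame(40, rng)
        y = df["age"].to_numpy(dtype=float)  # y == effect for the age test
        d = build_design(df, "age", y)
        res = permutation_test(d, PermutationConfig(iterations=99, seed=5))
        assert res.p_value >= 1 / 100

    def test_schemes_agree_under_null(self, rng):
        df = demo_frame(150, rng)
        y = rng.normal(size=150)
        d = build_design(df, "time", y)
        pe = permutation_test(d, PermutationConfig(iterations=2000, seed=6, scheme="effect"))
        pf = permutation_test(d, PermutationConfig(iterations=2000, seed=6, scheme="freedman_lane"))
        assert abs(pe.p_value - pf.p_value) < 0.1

    def test_type_one_error_calibration(self):
        """Null p-values are uniform: rejection rate at 0.05 within 3 SEs."""
        reps = 500
        B = 999
        n = 200
        hits = 0
        rng = np.random.default_rng(2024)
        for i in range(reps):
            df = demo_frame(n, rng)
            y = rng.normal(size=n)
            d = build_design(df, "time", y)
            res = permutation_test(
                d, PermutationConfig(iterations=B), rng=derive_rng(777, str(i))
            )
            hits += res.p_value < 0.05
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 3 * se


def bh_oracle(p, alpha):
    """Brute-force step-up: largest k with p_(k) <= k/m*alpha, reject below."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    kstar = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k / m * alpha:
            kstar = k
    reject = np.zeros(m, dtype=bool)
    if kstar:
        reject = p <= p[order[kstar - 1]]
    return reject


class TestBhFdr:
    def test_reference_battery_fixture(self):
        keys = list(REFERENCE_PVALUES)
        res = bh_fdr([REFERENCE_PVALUES[k] for k in keys], alpha=0.05)
        rejected = {k for k, r in zip(keys, res.rejected) if r}
        assert len(rejected) == 73
        assert set(keys) - rejected == set(REFERENCE_NONSIGNIFICANT)

    def test_all_ones_rejects_nothing(self):
        res = bh_fdr([1.0] * 10)
        assert res.n_rejected == 0 and res.threshold == 0.0

    def test_hand_computed_step_up(self):
        res = bh_fdr([0.01, 0.02, 0.04], alpha=0.05)
        assert res.rejected.all()

    def test_ties_share_a_fate(self):
        res = bh_fdr([0.01, 0.01, 0.8, 0.9], alpha=0.05)
        assert res.rejected[:2].all() and not res.rejected[2:].any()

    @settings(max_examples=200, deadline=None)
    @given(
        seed=st.integers(0, 10**6),
        m=st.integers(1, 40),
        alpha=st.floats(0.01, 0.2),
    )
    def test_matches_bruteforce_and_statsmodels(self, seed, m, alpha):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=m)
        res = bh_fdr(p, alpha)
        assert np.array_equal(res.rejected, bh_oracle(p, alpha))
        from statsmodels.stats.multitest import multipletests

        sm_reject = multipletests(p, alpha=alpha, method="fdr_bh")[0]
        assert np.array_equal(res.rejected, sm_reject)

    def test_rejection_set_is_lower_set(self, rng):
        p = rng.uniform(size=30)
        res = bh_fdr(p)
        if res.n_rejected:
            assert p[res.rejected].max() <= p[~res.rejected].min() + 1e-15

    def test_validation(self):
        with pytest.raises(ValueError):
            bh_fdr([])
        with pytest.raises(ValueError):
            bh_fdr([0.5], alpha=1.5)
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
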