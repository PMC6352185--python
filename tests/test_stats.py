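"""Correlation, normalisation, screening and group-comparison statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from mocapskill import (
    DegenerateInputError,
    IndicatorSet,
    InsufficientDataError,
    compare_groups,
    describe,
    normalize_scores,
    pearson,
    select_indicators,
    trials_to_frame,
)
import pandas as pd


def textbook_pearson(x, y):
    """Independent oracle: covariance formula + exact t transform."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    r = ((x - x.mean()) * (y - y.mean())).sum() / (
        np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
    )
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return r, p


def welch_oracle(a, b):
    """Independent Welch t-test: hand-coded t, Welch-Satterthwaite df, p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df=df)
    return t, df, p


def indicator_sets(time_values, eom_values=None):
    """Minimal per-trial indicator sets with controlled time/eom columns."""
    n = len(time_values)
    eom_values = eom_values if eom_values is not None else [500.0] * n
    return [
        IndicatorSet(
            time_s=float(tv), collisions=0, high_accel_events=0,
            eom_left_mm=float(ev), eom_right_mm=float(ev), eom_mean_mm=float(ev),
            workspace_mm3=1e5,
        )
        for tv, ev in zip(time_values, eom_values)
    ]


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-6

    def test_perfect_anticorrelation(self):
        res = pearson([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = pearson(x, y)
        r_ref, p_ref = textbook_pearson(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_degenerate_and_shape_errors(self):
        with pytest.raises(DegenerateInputError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])
        with pytest.raises(InsufficientDataError):
            pearson([1, 2], [3, 4])

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=20, unique=True),
        st.floats(0.1, 50),
        st.floats(-50, 50),
    )
    def test_symmetry_and_affine_invariance(self, xs, scale, shift):
        x = np.array(xs)
        y = np.sin(x) + 0.1 * x  # arbitrary non-degenerate partner
        if np.ptp(y) == 0:
            return
        base = pearson(x, y).r
        assert pearson(y, x).r == pytest.approx(base, abs=1e-12)
        assert pearson(scale * x + shift, y).r == pytest.approx(base, abs=1e-9)


class TestNormalizeScores:
    def test_basic_scaling(self):
        np.testing.assert_allclose(normalize_scores([0, 5, 10]), [0, 0.5, 1])

    def test_output_range(self, rng):
        out = normalize_scores(rng.normal(size=50))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_sequence_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_scores([3, 3, 3])

    def test_pearson_invariant_under_normalisation(self, study_trials):
        df = trials_to_frame(study_trials)
        raw = pearson(df["baba"], df["mc"])
        norm = pearson(normalize_scores(df["baba"]), normalize_scores(df["mc"]))
        assert norm.r == pytest.approx(raw.r, abs=1e-12)
        assert norm.p == pytest.approx(raw.p, rel=1e-9)


class TestDescribe:
    # printed per-cycle mean +/- SD pairs of the published cohort
    EXPECTED = {
        ("baba", 1): (18.1, 4.4), ("baba", 2): (27.5, 5.6),
        ("mc", 1): (44.0, 16.4), ("mc", 2): (62.7, 21.8),
        ("dvss", 1): (59.2, 22.1), ("dvss", 2): (80.1, 11.1),
    }

    def test_reproduces_all_printed_values(self, study_trials):
        desc = describe(study_trials)
        for (score, cycle), (mean, sd) in self.EXPECTED.items():
            assert round(desc.loc[cycle, (score, "mean")], 1) == mean
            assert round(desc.loc[cycle, (score, "std")], 1) == sd

    def test_empty_and_single_trial_errors(self, study_trials):
        with pytest.raises(DegenerateInputError):
            describe([])
        with pytest.raises(DegenerateInputError):
            describe(study_trials[:1])


class TestSelectIndicators:
    def test_too_few_trials_rejected(self):
        sets = indicator_sets([10.0, 20.0])
        scores = pd.DataFrame({"dvss": [1.0, 2.0], "baba": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            select_indicators(sets, scores)

    def test_reports_cover_all_pairs(self, rng):
        n = 10
        sets = indicator_sets(rng.uniform(50, 200, n), rng.uniform(200, 800, n))
        scores = pd.DataFrame({"dvss": rng.uniform(0, 100, n), "baba": rng.uniform(0, 40, n)})
        reports = select_indicators(sets, scores)
        assert len(reports) == 18  # 9 indicators x 2 targets
        constant = [r for r in reports if r.result is None]
        assert all(not r.selected for r in constant)

    def test_power_at_strong_negative_correlation(self, rng):
        # time built to correlate rho = -0.8 with dVSS at n = 20
        rho, n, hits = -0.8, 20, 0
        for _ in range(100):
            z = rng.normal(size=n)
            time = 120.0 + 30.0 * z
            dvss = 50.0 + 20.0 * (rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n))
            sets = indicator_sets(time)
            reports = select_indicators(sets, pd.DataFrame({"dvss": dvss, "baba": rng.normal(20, 5, n)}))
            rep = next(r for r in reports if r.indicator == "time_s" and r.target == "dvss")
            hits += rep.selected and rep.result.r < 0
        assert hits >= 90

    def test_holm_is_more_conservative(self, rng):
        n = 20
        sets = indicator_sets(rng.uniform(50, 200, n), rng.uniform(200, 800, n))
        scores = pd.DataFrame({"dvss": rng.uniform(0, 100, n), "baba": rng.uniform(0, 40, n)})
        raw = select_indicators(sets, scores, holm=False)
        adj = select_indicators(sets, scores, holm=True)
        assert sum(r.selected for r in adj) <= sum(r.selected for r in raw)


class TestCompareGroups:
    def test_identical_groups(self):
        gc = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert gc.t == pytest.approx(0.0)
        assert gc.p == pytest.approx(1.0)

    def test_small_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            compare_groups([1.0], [1.0, 2.0])

    def test_welch_matches_independent_formula(self, rng):
        a = rng.normal(675, 200, size=6)
        b = rng.normal(369, 120, size=6)
        gc = compare_groups(a, b, variant="welch")
        t_ref, df_ref, p_ref = welch_oracle(a, b)
        assert gc.t == pytest.approx(t_ref, abs=1e-9)
        assert gc.df == pytest.approx(df_ref, abs=1e-9)
        assert gc.p == pytest.approx(p_ref, abs=1e-9)

    def test_power_near_published_group_contrast(self, rng):
        # low/high economy-of-motion contrast: means 675 vs 369 mm, SD 200, n=6
        rejections = 0
        for _ in range(200):
            a = rng.normal(675.2, 200, size=6)
            b = rng.normal(369.4, 200, size=6)
            rejections += compare_groups(a, b).p < 0.05
        assert rejections > 100  # rejected in the majority of replicates

    def test_student_variant(self, rng):
        a = rng.normal(0, 1, size=8)
        b = rng.normal(1, 1, size=8)
        gc = compare_groups(a, b, variant="student")
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert gc.t == pytest.approx(float(ref.statistic), abs=1e-12)
        assert gc.df == pytest.approx(14.0)
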