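"""Correlation, selection and group-comparison statistics for trial cohorts.

This layer implements the study-style analysis: Pearson product-moment
correlation with a two-sided p-value from the exact t transform
(t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom), min-max score
normalisation, correlation-based screening of kinematic indicators against
the external scores, per-cycle descriptive statistics, and a two-tailed
t-test comparing low- and high-proficiency groups (Welch by default;
Student's pooled-variance variant selectable).

Indicator screening tests each of the five base indicators and four ratio
derivatives against each external score (dVSS and BABA), 18 tests in all,
and flags those with p below alpha.  No multiplicity correction is applied
by default — the selection is a screening heuristic, not a confirmatory
family — but Holm step-down adjustment can be switched on.

Because Pearson's r is invariant under positive affine maps, min-max
normalising the scores before correlating (as done for plotting on a common
0–1 axis) leaves every r and p unchanged; the normalisation is therefore
exposed for presentation and applied nowhere in the inference path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, InsufficientDataError
from .io import TrialRecord, trials_to_frame
from .kinematics import IndicatorSet


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided significance.

    ``r`` in [−1, 1], ``p`` in [0, 1], ``n`` the paired sample size (≥ 3).
    """

    r: float
    p: float
    n: int


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of screening one indicator against one external score.

    ``result`` is None when the indicator was constant across trials (its
    correlation is undefined) — such indicators are never selected.
    """

    indicator: str
    target: str
    result: CorrelationResult | None
    alpha: float
    selected: bool


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test summary for a low- vs high-proficiency contrast."""

    mean_low: float
    mean_high: float
    sd_low: float
    sd_high: float
    n_low: int
    n_high: int
    t: float
    df: float
    p: float
    variant: Literal["welch", "student"]


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided p-value.

    Raises
    ------
    ValueError
        If the sequences differ in length.
    InsufficientDataError
        If fewer than 3 pairs are supplied.
    DegenerateInputError
        If either sequence has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"shape mismatch: x {x.shape}, y {y.shape}")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 pairs for correlation, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance input: correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(n))


def normalize_scores(values: Sequence[float]) -> np.ndarray:
    """Min-max scale a sequence to [0, 1]: (v − min) / (max − min).

    Raises
    ------
    DegenerateInputError
        If all values are equal (zero range).
    """
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateInputError("constant sequence cannot be min-max normalised")
    return (v - lo) / (hi - lo)


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def select_indicators(
    indicators: Sequence[IndicatorSet],
    scores: Sequence[TrialRecord] | pd.DataFrame,
    *,
    alpha: float = 0.05,
    holm: bool = False,
) -> list[SelectionReport]:
    """Screen every indicator against dVSS and BABA by Pearson correlation.

    Correlates each of the 5 base indicators and 4 ratio derivatives of
    ``indicators`` (one IndicatorSet per trial, in the same order as
    ``scores``) against each external score, 18 tests, and marks those with
    p < alpha as selected.  ``holm=True`` applies Holm step-down adjustment
    across the 18 tests before thresholding (off by default).

    Raises
    ------
    InsufficientDataError
        With fewer than 3 complete trials.
    ValueError
        If indicator and score counts differ.
    """
    if isinstance(scores, pd.DataFrame):
        score_df = scores
    else:
        score_df = trials_to_frame(scores)
    if len(indicators) != len(score_df):
        raise ValueError(
            f"{len(indicators)} indicator sets vs {len(score_df)} score rows"
        )
    if len(indicators) < 3:
        raise InsufficientDataError("need >= 3 complete trials for indicator screening")

    ind_df = pd.DataFrame([ind.as_dict() for ind in indicators])
    names = list(IndicatorSet.BASE_NAMES) + list(IndicatorSet.DERIVATIVE_NAMES)
    pairs = [(name, target) for name in names for target in ("dvss", "baba")]
    results: list[CorrelationResult | None] = []
    for name, target in pairs:
        try:
            results.append(pearson(ind_df[name], score_df[target]))
        except DegenerateInputError:
            # constant indicator across trials: correlation undefined
            results.append(None)

    pvals = np.array([res.p if res is not None else 1.0 for res in results])
    if holm:
        defined = np.array([res is not None for res in results])
        effective = pvals.copy()
        if defined.any():
            effective[defined] = _holm(pvals[defined])
    else:
        effective = pvals
    return [
        SelectionReport(
            indicator=name,
            target=target,
            result=res,
            alpha=alpha,
            selected=bool(res is not None and p_eff < alpha),
        )
        for (name, target), res, p_eff in zip(pairs, results, effective)
    ]


def describe(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Per-cycle mean ± SD of the BABA, MC and dVSS scores.

    Returns a DataFrame indexed by cycle with a two-level column index
    (score, statistic).  The SD uses the sample (n − 1) denominator.

    Raises
    ------
    DegenerateInputError
        If the cohort is empty or any cycle has a single trial (SD
        undefined).
    """
    if not trials:
        raise DegenerateInputError("cannot describe an empty cohort")
    df = trials_to_frame(trials)
    counts = df.groupby("cycle").size()
    if (counts < 2).any():
        raise DegenerateInputError("sample SD undefined for cycles with a single trial")
    agg = df.groupby("cycle")[["baba", "mc", "dvss"]].agg(["mean", "std"])
    return agg


def compare_groups(
    values_low: Sequence[float],
    values_high: Sequence[float],
    variant: Literal["welch", "student"] = "welch",
) -> GroupComparison:
    """Two-tailed two-sample t-test between low and high proficiency groups.

    Welch's unequal-variance test is the default; ``variant="student"``
    selects the pooled-variance test.

    Raises
    ------
    DegenerateInputError
        If either group has fewer than 2 values.
    """
    a = np.asarray(values_low, dtype=float)
    b = np.asarray(values_high, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs n >= 2 for a t-test")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "student"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    df = float(res.df)
    return GroupComparison(
        mean_low=float(a.mean()),
        mean_high=float(b.mean()),
        sd_low=float(a.std(ddof=1)),
        sd_high=float(b.std(ddof=1)),
        n_low=int(a.size),
        n_high=int(b.size),
        t=t,
        df=df,
        p=p,
        variant=variant,
    )
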