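"""The composite motion-capture (MC) proficiency score and cohort classification.

The MC score condenses a trial's kinematic indicators into points:

    MC = 5000 / time  +  6000 / eom  +  (workspace / time) / 60
         −  4000 · (time / workspace)

with time in seconds, economy-of-motion (eom, mean of the two hands' path
lengths) in mm and used workspace in mm³.  The anchor profile of a highly
proficient trial — completion under 83 s, mean economy-of-motion under
300 mm, workspace usage above 1200 mm³/s — contributes 60 + 20 + 20 points,
and a trial slow relative to its workspace (time/workspace at 0.0025 s/mm³)
is penalised by 10 points.  The nominal maximum of 100 points is *not*
enforced: the formula is unbounded and scores are never clamped or rounded
internally.

A trial's overall score is BABA + dVSS + MC; overall scores band into
low (≤ 130), moderate (131–170] and high (> 170) proficiency classes.  The
integer band edges are extended to non-integer scores half-open:
low iff overall ≤ 130, moderate iff 130 < overall ≤ 170, high iff > 170.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import IncompleteTrialError
from .io import TrialRecord
from .kinematics import IndicatorSet

PROFICIENCY_LABELS = ("low", "moderate", "high")


@dataclass(frozen=True)
class MCScoreParams:
    """Coefficients of the four MC-score terms.

    Attributes
    ----------
    time_coeff : float
        Numerator of the time term, points·s (default 5000: 60 points at the
        83 s anchor).
    eom_coeff : float
        Numerator of the economy-of-motion term, points·mm (default 6000:
        20 points at the 300 mm anchor).
    workspace_rate_divisor : float
        Workspace-usage rate per point, mm³·s⁻¹ (default 60: 20 points at
        1200 mm³/s).
    penalty_coeff : float
        Slowness penalty coefficient, points·mm³·s⁻¹ (default 4000:
        10 points at 0.0025 s/mm³).
    """

    time_coeff: float = 5000.0
    eom_coeff: float = 6000.0
    workspace_rate_divisor: float = 60.0
    penalty_coeff: float = 4000.0

    def __post_init__(self) -> None:
        for name in ("time_coeff", "eom_coeff", "workspace_rate_divisor", "penalty_coeff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class MCScoreBreakdown:
    """The four MC-score terms (points) and their total.

    ``total == time_term + eom_term + workspace_term - penalty_term`` exactly.
    """

    time_term: float
    eom_term: float
    workspace_term: float
    penalty_term: float
    total: float


@dataclass(frozen=True)
class ClassBounds:
    """Upper edges of the proficiency bands, points.

    ``low_max`` closes the low band, ``moderate_max`` the moderate band;
    ``high_max`` is the nominal ceiling of the overall scale and is not
    enforced on inputs.
    """

    low_max: float = 130.0
    moderate_max: float = 170.0
    high_max: float = 240.0

    def __post_init__(self) -> None:
        if not self.low_max < self.moderate_max < self.high_max:
            raise ValueError("bounds must satisfy low_max < moderate_max < high_max")


def mc_score(ind: IndicatorSet, params: MCScoreParams | None = None) -> MCScoreBreakdown:
    """Evaluate the MC score for one trial's indicators.

    Raises
    ------
    ValueError
        If time, mean economy-of-motion or workspace volume is not strictly
        positive — the score is undefined there, never clamped.
    """
    params = params or MCScoreParams()
    if ind.time_s <= 0:
        raise ValueError(f"MC score undefined for time_s={ind.time_s} (must be > 0)")
    if ind.eom_mean_mm <= 0:
        raise ValueError(f"MC score undefined for eom_mean_mm={ind.eom_mean_mm} (must be > 0)")
    if ind.workspace_mm3 <= 0:
        raise ValueError(f"MC score undefined for workspace_mm3={ind.workspace_mm3} (must be > 0)")
    time_term = params.time_coeff / ind.time_s
    eom_term = params.eom_coeff / ind.eom_mean_mm
    workspace_term = ind.workspace_mm3 / ind.time_s / params.workspace_rate_divisor
    penalty_term = params.penalty_coeff * ind.time_s / ind.workspace_mm3
    return MCScoreBreakdown(
        time_term=time_term,
        eom_term=eom_term,
        workspace_term=workspace_term,
        penalty_term=penalty_term,
        total=time_term + eom_term + workspace_term - penalty_term,
    )


def overall_score(trial: TrialRecord) -> float:
    """Overall proficiency score of a trial: BABA + dVSS + MC.

    Raises
    ------
    IncompleteTrialError
        If the trial's MC score has not been computed.
    """
    return trial.overall


def classify(overall: float, bounds: ClassBounds | None = None) -> str:
    """Band an overall score into 'low', 'moderate' or 'high'.

    Monotone in ``overall``; negative scores are a domain error.
    """
    bounds = bounds or ClassBounds()
    if overall < 0:
        raise ValueError(f"overall score must be >= 0, got {overall}")
    if overall <= bounds.low_max:
        return "low"
    if overall <= bounds.moderate_max:
        return "moderate"
    return "high"


def classify_cohort(
    trials: list[TrialRecord], bounds: ClassBounds | None = None
) -> tuple[dict[str, int], list[str]]:
    """Classify every trial of a cohort by its overall score.

    Returns ``(counts, labels)``: counts per proficiency class (all three
    keys always present) and the per-trial labels in input order.

    Raises
    ------
    IncompleteTrialError
        If any trial lacks an MC score.
    """
    bounds = bounds or ClassBounds()
    labels = [classify(overall_score(t), bounds) for t in trials]
    counts = Counter(labels)
    return {label: counts.get(label, 0) for label in PROFICIENCY_LABELS}, labels
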