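"""Synthetic dual-hand recordings and score cohorts with known ground truth.

No raw motion recordings are publicly available for this kind of
console-training study, so every pipeline stage is exercised against a
generator whose statistical structure mirrors what the analysis assumes:

* each hand traverses **minimum-jerk** segments between via-points drawn
  uniformly inside a per-hand workspace box (the standard smooth model for
  point-to-point reaching movements, giving the high-acceleration detector
  a controllable null);
* a latent **proficiency** in [0, 1] drives the kinematics through affine
  links — higher proficiency means faster cruise speed, a smaller detour
  factor (path inflation through intermediate bumps), lower band-limited
  tremor and a wider separation between the hands (novices bump their
  hands together, experts keep them apart); rare ballistic "twitches"
  occur at a small proficiency-independent rate, so the high-acceleration
  count is a deliberately weak indicator, mirroring its failure to
  correlate with external scores in console-training cohorts;
* external BABA and dVSS scores are affine in the same latent proficiency
  plus Gaussian noise, so score–indicator correlations have known signs:
  completion time and economy-of-motion fall with proficiency while the
  workspace-usage rate rises.

Everything is deterministic given the ``SyntheticSpec`` seed (NumPy PCG64 via
``numpy.random.default_rng``).  Default magnitudes target the published
orders for this kind of fine-motor console task: trial times of 10¹–10² s,
hand path lengths of 10²–10³ mm, workspace-usage rates of ~10³ mm³/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import HandTrack, MotionRecording, TrialRecord

#: Affine proficiency links applied by ``SyntheticSpec.for_proficiency``:
#: parameter = AT_ZERO + (AT_ONE - AT_ZERO) * proficiency.
SPEED_AT_ZERO, SPEED_AT_ONE = 2.5, 5.2  # cruise speed, mm/s
DETOUR_AT_ZERO, DETOUR_AT_ONE = 2.6, 1.1  # path-inflation multiplier
TREMOR_AT_ZERO, TREMOR_AT_ONE = 0.30, 0.05  # tremor SD, mm
TWITCH_RATE_DEFAULT = 0.002  # ballistic twitch rate, 1/s (not proficiency-linked)
SEPARATION_AT_ZERO, SEPARATION_AT_ONE = 40.0, 160.0  # inter-hand gap, mm

#: Default affine score links: score = intercept + slope * proficiency + noise.
BABA_LINK = (2.0, 38.0)  # spans ~2-40 points over proficiency 0-1
DVSS_LINK = (15.0, 90.0)  # spans ~15-105, clipped to [0, 100]

#: Window (frames) of the moving average that band-limits the tremor noise.
_TREMOR_SMOOTH_FRAMES = 25


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic trial recording.

    Use :meth:`for_proficiency` to derive speed/detour/tremor/twitch/
    separation values from a latent skill level; direct construction fixes
    them explicitly.

    Attributes
    ----------
    proficiency : float
        Latent skill in [0, 1]; metadata unless set via
        :meth:`for_proficiency`.
    n_viapoints : int
        Number of task waypoints per hand (>= 2).
    workspace_extent : float
        Edge length of each hand's cubic workspace, mm.
    base_speed : float
        Cruise speed along the path, mm/s.
    tremor_sd : float
        SD of the additive band-limited Gaussian positional tremor, mm.
    detour_factor : float
        Path-inflation multiplier >= 1; each segment is routed through a
        perpendicular intermediate point so its length is multiplied by
        roughly this factor.
    twitch_rate : float
        Expected ballistic twitches per second (short out-and-back flicks
        fast enough to trip the high-acceleration detector).
    twitch_amp_mm : float
        Displacement amplitude of one twitch, mm.  A genuine supra-10 m/s²
        event sampled at 25 fps necessarily spans >100 mm (a = 10⁴ mm/s²
        sustained over ~0.2 s), so the default is a 140 mm flick.
    hand_separation : float
        Gap between the two hands' workspace boxes along x, mm; small gaps
        let the inter-hand distance cross the collision threshold.
    fps : float
        Sampling rate, frames per second.
    seed : int
        RNG seed; identical specs produce bit-identical recordings.
    """

    proficiency: float = 0.5
    n_viapoints: int = 12
    workspace_extent: float = 40.0
    base_speed: float = 3.5
    tremor_sd: float = 0.15
    detour_factor: float = 1.4
    twitch_rate: float = TWITCH_RATE_DEFAULT
    twitch_amp_mm: float = 140.0
    hand_separation: float = 100.0
    fps: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.proficiency <= 1.0:
            raise ValueError("proficiency must be in [0, 1]")
        if self.n_viapoints < 2:
            raise ValueError("n_viapoints must be >= 2")
        if self.workspace_extent <= 0 or self.base_speed <= 0 or self.fps <= 0:
            raise ValueError("workspace_extent, base_speed and fps must be > 0")
        if min(self.tremor_sd, self.twitch_rate, self.twitch_amp_mm, self.hand_separation) < 0:
            raise ValueError("tremor_sd, twitch_rate, twitch_amp_mm, hand_separation must be >= 0")
        if self.detour_factor < 1.0:
            raise ValueError("detour_factor must be >= 1")

    @classmethod
    def for_proficiency(cls, proficiency: float, *, seed: int = 0, **overrides) -> "SyntheticSpec":
        """Build a spec whose kinematic parameters follow the affine links."""
        p = float(proficiency)

        def link(lo: float, hi: float) -> float:
            return lo + (hi - lo) * p

        params = dict(
            proficiency=p,
            base_speed=link(SPEED_AT_ZERO, SPEED_AT_ONE),
            detour_factor=link(DETOUR_AT_ZERO, DETOUR_AT_ONE),
            tremor_sd=link(TREMOR_AT_ZERO, TREMOR_AT_ONE),
            hand_separation=link(SEPARATION_AT_ZERO, SEPARATION_AT_ONE),
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class ScoreLink:
    """Affine map from latent proficiency to an external score scale."""

    intercept: float
    slope: float

    def __call__(self, proficiency: float) -> float:
        return self.intercept + self.slope * proficiency


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic training cohort.

    Each participant draws one latent proficiency (uniform on
    ``proficiency_range``), incremented by ``cycle2_proficiency_gain`` in
    the second cycle; BABA and dVSS scores are the affine ``score_link``
    images of that proficiency plus Gaussian noise, clipped to the score
    ranges (BABA >= 0, dVSS in [0, 100]).
    """

    n_participants: int = 10
    cycles: int = 2
    proficiency_range: tuple[float, float] = (0.2, 0.65)
    cycle2_proficiency_gain: float = 0.2
    score_noise_sd: float = 5.0
    baba_link: ScoreLink = ScoreLink(*BABA_LINK)
    dvss_link: ScoreLink = ScoreLink(*DVSS_LINK)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.cycles not in (1, 2):
            raise ValueError("cycles must be 1 or 2")
        lo, hi = self.proficiency_range
        if not 0 <= lo < hi <= 1:
            raise ValueError("proficiency_range must satisfy 0 <= lo < hi <= 1")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Trajectory construction
# ---------------------------------------------------------------------------

def _minimum_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile s(tau) = 10t^3 - 15t^4 + 6t^5."""
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def _detour_points(
    waypoints: np.ndarray,
    detour_factor: float,
    rng: np.random.Generator,
    box_lo: np.ndarray,
    box_hi: np.ndarray,
) -> np.ndarray:
    """Route each segment through a perpendicular midpoint bump.

    The bump height h = (L/2)·sqrt(d² − 1) makes the two straight halves sum
    to d·L, inflating the path length by the detour factor.  Bump points are
    clipped into the hand's workspace box so detours lengthen the path
    without growing the covered volume.
    """
    if detour_factor <= 1.0:
        return waypoints
    out = [waypoints[0]]
    for p0, p1 in zip(waypoints[:-1], waypoints[1:]):
        seg = p1 - p0
        length = np.linalg.norm(seg)
        if length > 0:
            # random unit vector perpendicular to the segment
            v = rng.normal(size=3)
            v -= v.dot(seg) / length**2 * seg
            norm = np.linalg.norm(v)
            if norm > 1e-12:
                h = 0.5 * length * np.sqrt(detour_factor**2 - 1.0)
                bump = np.clip((p0 + p1) / 2.0 + v / norm * h, box_lo, box_hi)
                out.append(bump)
        out.append(p1)
    return np.asarray(out)


def _sample_viapoint_path(
    waypoints: np.ndarray, speed: float, t: np.ndarray, total_duration: float
) -> np.ndarray:
    """Sample a piecewise minimum-jerk path through ``waypoints`` at times t.

    Segment durations are proportional to segment lengths (constant cruise
    speed), rescaled so the whole path spans ``total_duration`` seconds.
    """
    lengths = np.linalg.norm(np.diff(waypoints, axis=0), axis=1)
    lengths = np.maximum(lengths, 1e-9)
    durations = lengths / speed
    durations *= total_duration / durations.sum()
    bounds = np.concatenate(([0.0], np.cumsum(durations)))
    bounds[-1] = total_duration  # guard rounding
    seg = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(durations) - 1)
    tau = np.clip((t - bounds[seg]) / durations[seg], 0.0, 1.0)
    s = _minimum_jerk_profile(tau)[:, None]
    return waypoints[seg] + (waypoints[seg + 1] - waypoints[seg]) * s


def _add_twitches(
    pos: np.ndarray, t: np.ndarray, rate: float, amp: float, fps: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Superimpose ballistic out-and-back flicks (Poisson-timed)."""
    duration = t[-1] - t[0]
    n_twitch = rng.poisson(rate * duration)
    if n_twitch == 0:
        return pos
    half = max(int(round(0.2 * fps)), 2)  # ~0.2 s out, ~0.2 s back
    window = 2 * half
    bump = np.concatenate(
        [_minimum_jerk_profile(np.linspace(0, 1, half)),
         _minimum_jerk_profile(np.linspace(1, 0, half))]
    )
    pos = pos.copy()
    for _ in range(n_twitch):
        start = rng.integers(0, max(len(t) - window, 1))
        direction = rng.normal(size=3)
        direction /= max(np.linalg.norm(direction), 1e-12)
        seg = slice(start, min(start + window, len(t)))
        pos[seg] += amp * bump[: seg.stop - seg.start, None] * direction
    return pos


def _tremor(shape: tuple[int, int], sd: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited positional tremor: moving-averaged Gaussian noise.

    Raw per-frame white noise would dominate the path length at 25 fps; a
    short moving average keeps the tremor's displacement scale at ``sd``
    while bounding its frame-to-frame increments.
    """
    noise = rng.normal(0.0, sd, size=shape)
    return uniform_filter1d(noise, _TREMOR_SMOOTH_FRAMES, axis=0, mode="nearest")


def _orientation_drift(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Slow sinusoidal roll/pitch/yaw drift (degrees), carried but unused."""
    phases = rng.uniform(0, 2 * np.pi, size=3)
    freqs = rng.uniform(0.02, 0.1, size=3)
    amps = rng.uniform(5.0, 40.0, size=3)
    return amps * np.sin(2 * np.pi * freqs * t[:, None] + phases)


def generate_recording(spec: SyntheticSpec, *, trial_id: str = "synthetic") -> MotionRecording:
    """Generate one dual-hand recording from a synthetic spec.

    The right (dominant) hand's via-point path sets the trial duration; the
    left hand follows its own via-point path, time-warped onto the same
    frame grid.  The hands work in boxes separated by
    ``spec.hand_separation`` along x, so small separations let the
    inter-hand distance cross the collision threshold.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    extent = spec.workspace_extent

    # Right hand owns [0, extent]^3; the left box sits at lower x with a
    # gap of hand_separation between the facing box edges.
    right_lo = np.zeros(3)
    left_lo = np.array([-(spec.hand_separation + extent), 0.0, 0.0])

    def _waypoints(lo: np.ndarray) -> np.ndarray:
        return lo + rng.uniform(0, extent, size=(spec.n_viapoints, 3))

    right_wp = _detour_points(
        _waypoints(right_lo), spec.detour_factor, rng, right_lo, right_lo + extent
    )
    left_wp = _detour_points(
        _waypoints(left_lo), spec.detour_factor, rng, left_lo, left_lo + extent
    )

    right_len = np.linalg.norm(np.diff(right_wp, axis=0), axis=1).sum()
    duration = max(right_len / spec.base_speed, 3.0 / spec.fps)
    n_frames = max(int(np.floor(duration * spec.fps)) + 1, 3)
    t = np.arange(n_frames) / spec.fps
    duration = float(t[-1])

    right_pos = _sample_viapoint_path(right_wp, spec.base_speed, t, duration)
    left_pos = _sample_viapoint_path(left_wp, spec.base_speed, t, duration)

    right_pos = _add_twitches(right_pos, t, spec.twitch_rate, spec.twitch_amp_mm, spec.fps, rng)
    left_pos = _add_twitches(left_pos, t, 0.6 * spec.twitch_rate, spec.twitch_amp_mm, spec.fps, rng)

    if spec.tremor_sd > 0:
        right_pos = right_pos + _tremor(right_pos.shape, spec.tremor_sd, rng)
        left_pos = left_pos + _tremor(left_pos.shape, spec.tremor_sd, rng)

    left = HandTrack(t=t, pos=left_pos, orient=_orientation_drift(t, rng))
    right = HandTrack(t=t, pos=right_pos, orient=_orientation_drift(t, rng))
    return MotionRecording(trial_id=trial_id, left=left, right=right, nominal_fps=spec.fps)


def trial_key(participant: int, cycle: int) -> str:
    """Canonical trial identifier, e.g. ``p03c1``."""
    return f"p{participant:02d}c{cycle}"


def generate_cohort(
    cspec: CohortSpec,
) -> tuple[dict[str, MotionRecording], list[TrialRecord]]:
    """Generate a full training cohort: recordings plus external scores.

    Returns ``(recordings, trials)`` where recordings are keyed by
    :func:`trial_key` and trials carry the noisy BABA/dVSS scores (MC is
    left unset for the scoring pipeline to fill).  Deterministic given
    ``cspec.seed``.
    """
    rng = np.random.default_rng(cspec.seed)
    lo, hi = cspec.proficiency_range
    base_prof = rng.uniform(lo, hi, size=cspec.n_participants)
    recordings: dict[str, MotionRecording] = {}
    trials: list[TrialRecord] = []
    for i in range(cspec.n_participants):
        participant = i + 1
        for cycle in range(1, cspec.cycles + 1):
            prof = float(
                np.clip(base_prof[i] + (cycle - 1) * cspec.cycle2_proficiency_gain, 0.0, 1.0)
            )
            rec_seed = int(rng.integers(0, 2**31 - 1))
            spec = SyntheticSpec.for_proficiency(prof, seed=rec_seed)
            key = trial_key(participant, cycle)
            recordings[key] = generate_recording(spec, trial_id=key)
            baba = cspec.baba_link(prof) + rng.normal(0, cspec.score_noise_sd)
            dvss = cspec.dvss_link(prof) + rng.normal(0, cspec.score_noise_sd)
            trials.append(
                TrialRecord(
                    participant_id=participant,
                    cycle=cycle,
                    baba=float(np.clip(baba, 0.0, None)),
                    dvss=float(np.clip(dvss, 0.0, 100.0)),
                )
            )
    return recordings, trials
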