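"""Reading, writing and validation of dual-hand motion recordings.

The canonical trajectory dialect is delimited UTF-8 text with one header line

    t,lx,ly,lz,lroll,lpitch,lyaw,rx,ry,rz,rroll,rpitch,ryaw

and one row per frame: time in seconds, positions in mm, orientations in
degrees, left hand then right hand.  Comma and tab delimiters are both
accepted on read.  The ``t`` column may be omitted, in which case timestamps
are synthesised from the frame index at the recording's nominal frame rate
(25 fps by default, matching inertial motion-capture exports).

Frames containing any non-finite channel are dropped *pairwise* — the same
frame index is removed from both hands — so that every downstream inter-hand
computation operates on index-aligned tracks.

This module also ships the packaged per-trial score table (10 participants
x 2 training cycles with BABA, MC and dVSS scores) used by the statistics
layer and the worked examples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import IncompleteTrialError, MalformedRecordingError, SchemaError

logger = logging.getLogger(__name__)

#: Column order of the canonical trajectory dialect (without the time column).
CHANNEL_COLUMNS = [
    "lx", "ly", "lz", "lroll", "lpitch", "lyaw",
    "rx", "ry", "rz", "rroll", "rpitch", "ryaw",
]

_POSITION = slice(0, 3)
_ORIENTATION = slice(3, 6)


@dataclass(frozen=True)
class HandFrame:
    """A single sampled pose of one hand.

    Attributes
    ----------
    t : float
        Time since recording start, seconds.
    x, y, z : float
        Cartesian position, mm.
    roll, pitch, yaw : float
        Orientation, degrees, normalised into [-360, 360].
    """

    t: float
    x: float
    y: float
    z: float
    roll: float
    pitch: float
    yaw: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t) and self.t >= 0):
            raise MalformedRecordingError(f"frame time must be finite and >= 0, got {self.t}")
        for name in ("x", "y", "z"):
            if not math.isfinite(getattr(self, name)):
                raise MalformedRecordingError(f"non-finite position channel {name}")
        for name in ("roll", "pitch", "yaw"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise MalformedRecordingError(f"non-finite orientation channel {name}")
            object.__setattr__(self, name, math.fmod(v, 360.0))


@dataclass(frozen=True)
class HandTrack:
    """One hand's sampled trajectory, stored as arrays for vectorised work.

    ``t`` is shape (n,) seconds; ``pos`` is (n, 3) mm; ``orient`` is (n, 3)
    degrees in roll/pitch/yaw order.
    """

    t: np.ndarray
    pos: np.ndarray
    orient: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        pos = np.asarray(self.pos, dtype=float)
        orient = np.asarray(self.orient, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "pos", pos)
        object.__setattr__(self, "orient", orient)
        n = t.shape[0]
        if pos.shape != (n, 3) or orient.shape != (n, 3):
            raise MalformedRecordingError(
                f"track shape mismatch: t {t.shape}, pos {pos.shape}, orient {orient.shape}"
            )

    def __len__(self) -> int:
        return int(self.t.shape[0])

    def frames(self) -> Iterator[HandFrame]:
        for i in range(len(self)):
            yield HandFrame(
                float(self.t[i]), *map(float, self.pos[i]), *map(float, self.orient[i])
            )


@dataclass(frozen=True)
class MotionRecording:
    """A validated dual-hand recording of one training trial.

    Invariants enforced at construction: both hands have the same frame
    count (>= 2), timestamps are strictly increasing, and all channels are
    finite.
    """

    trial_id: str
    left: HandTrack
    right: HandTrack
    nominal_fps: float = 25.0

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise MalformedRecordingError(
                f"{self.trial_id}: left has {len(self.left)} frames, right {len(self.right)}"
            )
        if len(self.left) < 2:
            raise MalformedRecordingError(
                f"{self.trial_id}: need >= 2 frames, got {len(self.left)}"
            )
        for name, track in (("left", self.left), ("right", self.right)):
            for arr, what in ((track.t, "t"), (track.pos, "pos"), (track.orient, "orient")):
                if not np.all(np.isfinite(arr)):
                    raise MalformedRecordingError(f"{self.trial_id}: non-finite {what} in {name}")
            if np.any(np.diff(track.t) <= 0):
                raise MalformedRecordingError(
                    f"{self.trial_id}: timestamps not strictly increasing in {name}"
                )
            if np.any(track.t < 0):
                raise MalformedRecordingError(f"{self.trial_id}: negative timestamp in {name}")
        if not np.allclose(self.left.t, self.right.t):
            raise MalformedRecordingError(f"{self.trial_id}: left/right timestamps differ")
        if self.nominal_fps <= 0:
            raise MalformedRecordingError(f"{self.trial_id}: nominal_fps must be > 0")

    @property
    def n_frames(self) -> int:
        return len(self.left)

    @property
    def duration(self) -> float:
        """Recording duration in seconds (last minus first timestamp)."""
        return float(self.left.t[-1] - self.left.t[0])

    def with_trial_id(self, trial_id: str) -> "MotionRecording":
        return replace(self, trial_id=trial_id)


@dataclass
class TrialRecord:
    """Per-trial external and computed scores for one participant and cycle.

    ``baba`` is the physical-model rubric score (points, >= 0), ``dvss`` the
    simulator score (points, 0-100), ``mc`` the motion-capture composite
    score, absent (None) until scoring has run.
    """

    participant_id: int
    cycle: int
    baba: float
    dvss: float
    mc: float | None = None

    def __post_init__(self) -> None:
        if self.cycle not in (1, 2):
            raise SchemaError(f"cycle must be 1 or 2, got {self.cycle}")
        if self.baba < 0:
            raise SchemaError(f"baba score must be >= 0, got {self.baba}")
        if not 0 <= self.dvss <= 100:
            raise SchemaError(f"dvss score must be in [0, 100], got {self.dvss}")

    @property
    def overall(self) -> float:
        """Sum of the three scores; raises if MC has not been computed."""
        if self.mc is None:
            raise IncompleteTrialError(
                f"participant {self.participant_id} cycle {self.cycle} has no MC score"
            )
        return self.baba + self.dvss + self.mc


# ---------------------------------------------------------------------------
# Trajectory file I/O
# ---------------------------------------------------------------------------

def read_recording(
    path: str | Path,
    *,
    delimiter: str | None = None,
    nominal_fps: float = 25.0,
    trial_id: str | None = None,
) -> MotionRecording:
    """Read a trajectory file in the canonical dialect.

    Parameters
    ----------
    path
        File to read.  Must exist and carry the header line declaring the
        channel order (``t`` optional).
    delimiter
        ``','`` or ``'\\t'``; sniffed from the header when None.
    nominal_fps
        Frame rate used to synthesise timestamps when the file has no ``t``
        column.
    trial_id
        Identifier for the recording; defaults to the file stem.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    MalformedRecordingError
        If fewer than 2 valid frames remain after dropping non-finite rows,
        or validation fails.
    SchemaError
        If required channel columns are missing.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in CHANNEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing channel columns {missing}")

    for c in df.columns:
        df[c] = pd.to_numeric(df[c], errors="coerce")

    if "t" in df.columns:
        t = df["t"].to_numpy(dtype=float)
    else:
        t = np.arange(len(df), dtype=float) / nominal_fps

    channels = df[CHANNEL_COLUMNS].to_numpy(dtype=float)
    finite = np.isfinite(channels).all(axis=1) & np.isfinite(t)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("%s: dropped %d frame(s) with non-finite channels", path, n_dropped)
    t = t[finite]
    channels = channels[finite]
    if len(t) < 2:
        raise MalformedRecordingError(f"{path}: fewer than 2 valid frames after cleaning")

    left = HandTrack(t=t, pos=channels[:, 0:3], orient=channels[:, 3:6])
    right = HandTrack(t=t, pos=channels[:, 6:9], orient=channels[:, 9:12])
    return MotionRecording(
        trial_id=trial_id if trial_id is not None else path.stem,
        left=left,
        right=right,
        nominal_fps=nominal_fps,
    )


def write_recording(
    rec: MotionRecording, path: str | Path, *, delimiter: str = ","
) -> None:
    """Write a recording in the canonical dialect (10 significant digits).

    The recording is validated (by construction) before any file is created;
    an invalid object never produces a partial file.
    """
    if not isinstance(rec, MotionRecording):
        raise MalformedRecordingError("write_recording expects a MotionRecording")
    path = Path(path)
    header = delimiter.join(["t", *CHANNEL_COLUMNS])
    data = np.column_stack(
        [rec.left.t, rec.left.pos, rec.left.orient, rec.right.pos, rec.right.orient]
    )
    lines = [header]
    for row in data:
        lines.append(delimiter.join(f"{v:.10g}" for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Score table
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = ("participant", "cycle", "baba", "dvss")


def load_score_table(path: str | Path | None = None) -> list[TrialRecord]:
    """Load a per-trial score table; None loads the packaged study table.

    The CSV must have columns ``participant,cycle,baba,dvss`` and may have
    ``mc``.  The packaged table holds the published scores of the ten
    participants over two training cycles (20 trials).

    Raises
    ------
    SchemaError
        On missing columns or duplicate (participant, cycle) pairs.
    """
    if path is None:
        source = resources.files("mocapskill.data").joinpath("study_scores.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"score table missing column(s) {missing}")
    dup = df.duplicated(subset=["participant", "cycle"])
    if dup.any():
        offenders = df.loc[dup, ["participant", "cycle"]].to_records(index=False).tolist()
        raise SchemaError(f"duplicate (participant, cycle) rows: {offenders}")
    has_mc = "mc" in df.columns
    trials = []
    for row in df.itertuples(index=False):
        mc = getattr(row, "mc") if has_mc else None
        if mc is not None and (isinstance(mc, float) and math.isnan(mc)):
            mc = None
        trials.append(
            TrialRecord(
                participant_id=int(row.participant),
                cycle=int(row.cycle),
                baba=float(row.baba),
                dvss=float(row.dvss),
                mc=None if mc is None else float(mc),
            )
        )
    return trials


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tabulate trial records as a DataFrame (one row per trial)."""
    return pd.DataFrame(
        {
            "participant": [t.participant_id for t in trials],
            "cycle": [t.cycle for t in trials],
            "baba": [t.baba for t in trials],
            "dvss": [t.dvss for t in trials],
            "mc": [t.mc for t in trials],
        }
    )
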