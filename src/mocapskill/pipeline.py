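"""End-to-end analysis pipeline: indicators → MC scores → classes → statistics.

`run_pipeline` ties the stages together for a cohort: it loads the score
table, reads one trajectory file per trial (named ``<trial_key>.csv`` in the
recordings directory, e.g. ``p03c1.csv``), computes the kinematic indicators
and the composite MC score, classifies each trial's overall proficiency,
and runs the correlation / screening / group-comparison statistics.  All
numeric outputs are written as CSV with fixed formatting so a rerun with the
same configuration and seed is byte-identical; the run log records a
configuration hash and library versions, never timestamps.

In ``scores_only`` mode no recordings are read and the MC scores must
already be present in the score table — useful for re-analysing published
score tables without raw motion data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import IncompleteTrialError, ReconciliationError
from .io import MotionRecording, TrialRecord, load_score_table, read_recording, trials_to_frame
from .kinematics import IndicatorSet, KinematicsConfig, compute_indicators
from .scoring import ClassBounds, MCScoreParams, classify_cohort, mc_score
from .stats import compare_groups, describe, pearson, select_indicators
from .synthetic import trial_key

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run (YAML-serialisable)."""

    output_dir: Path = Path("mocapskill_run")
    recordings_dir: Path | None = None
    scores_csv: Path | None = None  # None loads the packaged study table
    scores_only: bool = False
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    mc_params: MCScoreParams = field(default_factory=MCScoreParams)
    bounds: ClassBounds = field(default_factory=ClassBounds)
    alpha: float = 0.05
    t_variant: str = "welch"
    holm: bool = False
    log_level: str = "INFO"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["output_dir"] = str(self.output_dir)
        d["recordings_dir"] = None if self.recordings_dir is None else str(self.recordings_dir)
        d["scores_csv"] = None if self.scores_csv is None else str(self.scores_csv)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("output_dir", "recordings_dir", "scores_csv"):
            if d.get(key) is not None:
                d[key] = Path(d[key])
        if "kinematics" in d and isinstance(d["kinematics"], dict):
            d["kinematics"] = KinematicsConfig(**d["kinematics"])
        if "mc_params" in d and isinstance(d["mc_params"], dict):
            d["mc_params"] = MCScoreParams(**d["mc_params"])
        if "bounds" in d and isinstance(d["bounds"], dict):
            d["bounds"] = ClassBounds(**d["bounds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunArtifacts:
    """In-memory results and output paths of one pipeline run."""

    config: PipelineConfig
    trials: list[TrialRecord]
    labels: list[str]
    counts: dict[str, int]
    indicators: dict[str, IndicatorSet] | None
    recordings: dict[str, MotionRecording] | None
    paths: dict[str, Path]


def _write_csv(df: pd.DataFrame, path: Path, expected_columns: Sequence[str]) -> None:
    """Schema-check the frame against its documented header, then write."""
    if list(df.columns) != list(expected_columns):
        raise ValueError(f"{path.name}: columns {list(df.columns)} != {list(expected_columns)}")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _load_recordings(
    trials: Sequence[TrialRecord], recordings_dir: Path
) -> dict[str, MotionRecording]:
    keys = [trial_key(t.participant_id, t.cycle) for t in trials]
    missing = [k for k in keys if not (recordings_dir / f"{k}.csv").is_file()]
    extra = sorted(
        p.stem
        for p in recordings_dir.glob("*.csv")
        if p.stem not in set(keys) and p.name != "scores.csv"  # colocated score table
    )
    if missing or extra:
        raise ReconciliationError(
            f"recordings/scores mismatch: missing recordings {missing}, "
            f"unmatched recording files {extra}"
        )
    return {k: read_recording(recordings_dir / f"{k}.csv", trial_id=k) for k in keys}


def summarize(trials: Sequence[TrialRecord], counts: dict[str, int] | None = None) -> str:
    """Human-readable per-cycle mean ± SD table plus class counts."""
    desc = describe(trials)
    lines = ["Per-cycle scores (mean ± SD)", ""]
    lines.append(f"{'cycle':>5}  {'BABA':>12}  {'MC':>12}  {'dVSS':>12}")
    for cycle in desc.index:
        cells = []
        for score in ("baba", "mc", "dvss"):
            m = desc.loc[cycle, (score, "mean")]
            s = desc.loc[cycle, (score, "std")]
            cells.append(f"{m:.1f} ± {s:.1f}")
        lines.append(f"{cycle:>5}  " + "  ".join(f"{c:>12}" for c in cells))
    if counts is not None:
        lines += ["", "Overall-proficiency classes: "
                  + ", ".join(f"{k}={v}" for k, v in counts.items())]
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: PipelineConfig) -> RunArtifacts:
    """Execute the full analysis and write all run artifacts.

    Raises
    ------
    ReconciliationError
        If trial identifiers in the recordings directory and the score
        table do not match (offenders are listed).
    IncompleteTrialError
        In ``scores_only`` mode, if the score table lacks MC values.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    trials = load_score_table(cfg.scores_csv)
    keys = [trial_key(t.participant_id, t.cycle) for t in trials]

    indicators: dict[str, IndicatorSet] | None = None
    recordings: dict[str, MotionRecording] | None = None
    if cfg.scores_only:
        missing_mc = [k for k, t in zip(keys, trials) if t.mc is None]
        if missing_mc:
            raise IncompleteTrialError(
                f"scores_only run requires MC in the score table; missing for {missing_mc}"
            )
        logger.info("scores-only run: %d trials, no recordings read", len(trials))
    else:
        if cfg.recordings_dir is None:
            raise ReconciliationError("recordings_dir is required unless scores_only=True")
        recordings = _load_recordings(trials, Path(cfg.recordings_dir))
        indicators = {k: compute_indicators(recordings[k], cfg.kinematics) for k in keys}

        ind_rows = []
        for k in keys:
            row = {"trial": k}
            row.update(indicators[k].as_dict())
            ind_rows.append(row)
        ind_df = pd.DataFrame(ind_rows)
        paths["indicators"] = out / "indicators.csv"
        _write_csv(ind_df, paths["indicators"], ind_df.columns)

        mc_rows = []
        for k, t in zip(keys, trials):
            bd = mc_score(indicators[k], cfg.mc_params)
            t.mc = bd.total
            mc_rows.append(
                {
                    "trial": k,
                    "time_term": bd.time_term,
                    "eom_term": bd.eom_term,
                    "workspace_term": bd.workspace_term,
                    "penalty_term": bd.penalty_term,
                    "mc_score": bd.total,
                }
            )
        paths["mc_scores"] = out / "mc_scores.csv"
        _write_csv(
            pd.DataFrame(mc_rows),
            paths["mc_scores"],
            ["trial", "time_term", "eom_term", "workspace_term", "penalty_term", "mc_score"],
        )

    counts, labels = classify_cohort(trials, cfg.bounds)
    cls_df = trials_to_frame(trials)
    cls_df["overall"] = [t.overall for t in trials]
    cls_df["label"] = labels
    paths["classification"] = out / "classification.csv"
    _write_csv(
        cls_df,
        paths["classification"],
        ["participant", "cycle", "baba", "dvss", "mc", "overall", "label"],
    )

    # Correlations: the three inter-score pairs, plus indicator screening
    # against dVSS and BABA when recordings were analysed.
    score_df = trials_to_frame(trials)
    corr_rows = []
    for a, b in (("baba", "mc"), ("mc", "dvss"), ("dvss", "baba")):
        res = pearson(score_df[a], score_df[b])
        corr_rows.append(
            {"kind": "score_pair", "x": a, "y": b, "r": res.r, "p": res.p,
             "n": res.n, "selected": res.p < cfg.alpha}
        )
    if indicators is not None:
        reports = select_indicators(
            [indicators[k] for k in keys], trials, alpha=cfg.alpha, holm=cfg.holm
        )
        for rep in reports:
            corr_rows.append(
                {
                    "kind": "indicator_screen",
                    "x": rep.indicator,
                    "y": rep.target,
                    "r": np.nan if rep.result is None else rep.result.r,
                    "p": np.nan if rep.result is None else rep.result.p,
                    "n": len(keys) if rep.result is None else rep.result.n,
                    "selected": rep.selected,
                }
            )
    paths["correlations"] = out / "correlations.csv"
    _write_csv(
        pd.DataFrame(corr_rows),
        paths["correlations"],
        ["kind", "x", "y", "r", "p", "n", "selected"],
    )

    # Low- vs high-proficiency contrast on per-hand economy-of-motion.
    if indicators is not None:
        low_keys = [k for k, lab in zip(keys, labels) if lab == "low"]
        high_keys = [k for k, lab in zip(keys, labels) if lab == "high"]
        if len(low_keys) >= 2 and len(high_keys) >= 2:
            cmp_rows = []
            for attr in ("eom_left_mm", "eom_right_mm"):
                gc = compare_groups(
                    [getattr(indicators[k], attr) for k in low_keys],
                    [getattr(indicators[k], attr) for k in high_keys],
                    variant=cfg.t_variant,  # type: ignore[arg-type]
                )
                cmp_rows.append(
                    {
                        "indicator": attr,
                        "mean_low": gc.mean_low, "sd_low": gc.sd_low, "n_low": gc.n_low,
                        "mean_high": gc.mean_high, "sd_high": gc.sd_high, "n_high": gc.n_high,
                        "t": gc.t, "df": gc.df, "p": gc.p, "variant": gc.variant,
                    }
                )
            paths["group_comparison"] = out / "group_comparison.csv"
            _write_csv(
                pd.DataFrame(cmp_rows),
                paths["group_comparison"],
                ["indicator", "mean_low", "sd_low", "n_low", "mean_high", "sd_high",
                 "n_high", "t", "df", "p", "variant"],
            )
        else:
            logger.info(
                "group comparison skipped: need >= 2 trials per extreme class "
                "(low=%d, high=%d)", len(low_keys), len(high_keys),
            )
    else:
        logger.info("group comparison skipped: no recordings analysed")

    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text(summarize(trials, counts), encoding="utf-8")

    import matplotlib
    import scipy
    from importlib.metadata import version as _pkg_version

    paths["run_log"] = out / "run_log.json"
    paths["run_log"].write_text(
        json.dumps(
            {
                "config_hash": cfg.config_hash(),
                "config": cfg.to_dict(),
                "n_trials": len(trials),
                "versions": {
                    "numpy": np.__version__,
                    "scipy": scipy.__version__,
                    "pandas": pd.__version__,
                    "matplotlib": matplotlib.__version__,
                    "click": _pkg_version("click"),
                },
            },
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )

    return RunArtifacts(
        config=cfg,
        trials=trials,
        labels=labels,
        counts=counts,
        indicators=indicators,
        recordings=recordings,
        paths=paths,
    )


def report(artifacts: RunArtifacts, *, max_trajectories: int = 4) -> list[Path]:
    """Render the run's figures and return the written paths.

    Produces a normalised-score pairwise correlation figure (all three
    score pairs on common 0–1 axes) and, when recordings are available, 3D
    dual-hand trajectory plots with the right hand in blue and the left in
    red.  Trajectory plots are skipped with a logged notice on scores-only
    runs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .stats import normalize_scores

    out = Path(artifacts.config.output_dir) / "figures"
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    df = trials_to_frame(artifacts.trials)
    norm = {s: normalize_scores(df[s]) for s in ("baba", "mc", "dvss")}
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, (a, b) in zip(axes, (("baba", "mc"), ("mc", "dvss"), ("dvss", "baba"))):
        res = pearson(df[a], df[b])
        ax.scatter(norm[a], norm[b], color="tab:purple", alpha=0.8)
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.set_xlabel(f"{a.upper()} (normalised)")
        ax.set_ylabel(f"{b.upper()} (normalised)")
        ax.set_title(f"r = {res.r:.3f}, p = {res.p:.3g}")
    fig.tight_layout()
    path = out / "score_correlations.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    if artifacts.recordings:
        for key in list(artifacts.recordings)[:max_trajectories]:
            rec = artifacts.recordings[key]
            fig = plt.figure(figsize=(6, 5))
            ax = fig.add_subplot(projection="3d")
            ax.plot(*rec.right.pos.T, color="blue", lw=0.8, label="right hand")
            ax.plot(*rec.left.pos.T, color="red", lw=0.8, label="left hand")
            ax.set_xlabel("x (mm)")
            ax.set_ylabel("y (mm)")
            ax.set_zlabel("z (mm)")
            ax.set_title(f"Trial {key}")
            ax.legend()
            path = out / f"trajectory_{key}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    else:
        logger.info("trajectory plots skipped: run had no recordings")
    return written
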