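"""Cohort orchestration: subject feature extraction to diagnostic report.

``run_subject`` turns one accelerometer trial plus its metadata row into a
:class:`~swaysense.diagnostics.SubjectRecord` with sway scores attached;
``run_cohort`` evaluates the cohort's sway scores against the chosen fall
criteria, direction by direction (AP, ML, V and their mean), producing a
schema-versioned report with per-direction ROC summaries, Youden cut-offs,
confusion metrics and qualitative grades.  The report is a pure function
of its inputs and serializes byte-identically on rerun.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import diagnostics as dx
from .errors import (
    ConfigError,
    DataError,
    DegenerateCohortError,
    ParseError,
    SwaySenseError,
)
from .features import AxisMap, extract_features, read_accel_csv
from .tilt import (
    DEFAULT_SAMPLE_RATE_HZ,
    DEFAULT_TILT_RATE_HZ,
    DEFAULT_TIMING_RTOL,
    tilt_series,
)

logger = logging.getLogger("swaysense")

REPORT_SCHEMA_VERSION = 1

METADATA_COLUMNS = [
    "subject_id",
    "group",
    "bbs_score",
    "tug_seconds",
    "fell_within_3_months",
]

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n"}


@dataclass
class RunConfig:
    """Validated run-wide settings for the pipeline."""

    axis_map: AxisMap = field(default_factory=AxisMap)
    sample_rate: float = DEFAULT_SAMPLE_RATE_HZ
    tilt_rate: float = DEFAULT_TILT_RATE_HZ
    timing_rtol: float = DEFAULT_TIMING_RTOL
    criterion: dx.FallCriterion = field(default_factory=dx.FallCriterion)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.tilt_rate <= 0:
            raise ConfigError("rates must be positive")
        factor = self.sample_rate / self.tilt_rate
        if abs(factor - round(factor)) > 1e-9:
            raise ConfigError(
                f"tilt rate {self.tilt_rate:g} Hz must divide the "
                f"sampling rate {self.sample_rate:g} Hz"
            )
        if self.timing_rtol <= 0:
            raise ConfigError("timing tolerance must be positive")

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "RunConfig":
        kwargs: dict = {}
        if "axis_map" in cfg:
            kwargs["axis_map"] = AxisMap.from_dict(cfg["axis_map"])
        for key in ("sample_rate", "tilt_rate", "timing_rtol", "seed", "log_level"):
            if key in cfg:
                kwargs[key] = cfg[key]
        crit = {
            k: cfg[k]
            for k in ("mode", "bbs_threshold", "tug_threshold", "bbs_inclusive")
            if k in cfg
        }
        if "criterion" in cfg:  # nested form wins
            crit = dict(cfg["criterion"])
        if crit:
            kwargs["criterion"] = dx.FallCriterion(**crit)
        return cls(**kwargs)


def _parse_flag(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ParseError(f"cannot parse boolean value {value!r}")


def read_metadata_csv(path: str | Path) -> list[dict]:
    """Read the subject metadata CSV into a list of row dicts."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise ParseError(f"cannot read metadata CSV {path}: {exc}") from exc
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata columns {missing}")
    rows = []
    for _, row in df.iterrows():
        rows.append(
            {
                "subject_id": str(row["subject_id"]),
                "group": str(row["group"]),
                "bbs_score": int(row["bbs_score"]),
                "tug_seconds": float(row["tug_seconds"]),
                "fell_within_3_months": _parse_flag(row["fell_within_3_months"]),
            }
        )
    return rows


def run_subject(
    accel_csv: str | Path, metadata_row: Mapping, config: RunConfig
) -> dx.SubjectRecord:
    """Process one subject: read the trial, compute tilt and sway features."""
    required = set(METADATA_COLUMNS)
    missing = required - set(metadata_row)
    if missing:
        raise DataError(
            f"metadata row missing fields {sorted(missing)} "
            f"(subject {metadata_row.get('subject_id', '?')})"
        )
    sid = str(metadata_row["subject_id"])
    try:
        series = read_accel_csv(accel_csv)
        tilt = tilt_series(
            series,
            tilt_rate=config.tilt_rate,
            sample_rate=config.sample_rate,
            timing_rtol=config.timing_rtol,
        )
        feats = extract_features(
            series,
            tilt=tilt,
            axis_map=config.axis_map,
            sample_rate=config.sample_rate,
        )
    except SwaySenseError as exc:
        raise type(exc)(f"subject {sid}: {exc}") from exc
    n_amp = len(next(iter(feats.amp_series.values())))
    dropped = len(series) - n_amp * int(round(config.sample_rate))
    logger.info(
        "subject %s: %d samples, %d AMP windows, %d trailing samples dropped",
        sid,
        len(series),
        n_amp,
        dropped,
    )
    return dx.SubjectRecord(
        subject_id=sid,
        group=metadata_row["group"],
        bbs_score=int(metadata_row["bbs_score"]),
        tug_seconds=float(metadata_row["tug_seconds"]),
        fell_within_3_months=_parse_flag(metadata_row["fell_within_3_months"]),
        sway=feats,
    )


def _direction_entry(scores: np.ndarray, labels: np.ndarray) -> dict:
    roc = dx.summarize_roc(scores, labels)
    counts = dx.confusion(scores, labels, roc.cutoff)
    m = dx.metrics(counts)
    return {
        "auc": roc.auc,
        "se": roc.se,
        "ci95": list(roc.ci95),
        "cutoff": roc.cutoff,
        "youden_j": roc.youden_j,
        "auc_grade": dx.grade(roc.auc),
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "accuracy": m.accuracy,
        "grades": m.grades,
        "confusion": {
            "tp": counts.tp,
            "fp": counts.fp,
            "tn": counts.tn,
            "fn": counts.fn,
        },
        "roc": {
            "thresholds": [
                None if np.isinf(t) else float(t) for t in roc.thresholds
            ],
            "sensitivity": [float(v) for v in roc.sensitivity],
            "fpr": [float(v) for v in roc.fpr],
        },
    }


def run_cohort(
    records: Sequence[dx.SubjectRecord],
    config: RunConfig,
    criteria: Sequence[dx.FallCriterion] | None = None,
) -> dict:
    """Evaluate the cohort's sway scores against each fall criterion.

    For every criterion × direction (AP, ML, V, mean) the report holds the
    ROC summary, the Youden operating point and the confusion metrics with
    qualitative grades.
    """
    if len(records) < 2:
        raise DataError("cohort evaluation needs at least 2 subjects")
    criteria = list(criteria) if criteria is not None else [config.criterion]
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_subjects": len(records),
        "criteria": {},
    }
    for criterion in criteria:
        labels = np.array(
            [dx.label_faller(r, criterion) for r in records], dtype=bool
        )
        n_pos = int(labels.sum())
        if n_pos == 0 or n_pos == len(records):
            raise DegenerateCohortError(
                f"criterion {criterion.mode!r} labels all subjects "
                f"{'positive' if n_pos else 'negative'}"
            )
        entry: dict = {
            "criterion": {
                "mode": criterion.mode,
                "bbs_threshold": criterion.bbs_threshold,
                "tug_threshold": criterion.tug_threshold,
                "bbs_inclusive": criterion.bbs_inclusive,
            },
            "n_pos": n_pos,
            "n_neg": len(records) - n_pos,
            "directions": {},
        }
        for direction in dx.DIRECTIONS:
            scores = np.array([r.score(direction) for r in records])
            entry["directions"][direction] = _direction_entry(scores, labels)
        report["criteria"][criterion.mode] = entry
    return report


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a cohort report deterministically (sorted keys)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def plot_report(report: dict, out_dir: str | Path) -> list[Path]:
    """Write one ROC plot per criterion × direction; returns the paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for mode, entry in report["criteria"].items():
        fig, ax = plt.subplots(figsize=(5, 5))
        for direction, d in entry["directions"].items():
            ax.plot(
                d["roc"]["fpr"],
                d["roc"]["sensitivity"],
                marker="o",
                markersize=3,
                label=f"{direction} (AUC {d['auc']:.2f})",
            )
        ax.plot([0, 1], [0, 1], "k--", linewidth=0.8)
        ax.set_xlabel("1 − specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"ROC — {mode.upper()} criterion")
        ax.legend(loc="lower right", fontsize=8)
        path = out_dir / f"roc_{mode}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
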