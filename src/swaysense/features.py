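"""Windowed postural-sway features from acceleration and tilt series.

The sway measure is deliberately simple and filter-free: for each device
axis the per-second amplitude (AMP) is the maximum minus the minimum of
the samples in each non-overlapping one-second window, and the RMS series
takes consecutive groups of three AMP values — so the RMS updates every
3 s.  Because AMP is a within-window range, any constant offset (gravity
on the axis pointing down) cancels; only the dynamic sway component
survives.  The scalar sway score per anatomical axis is the mean of that
axis's RMS series over the trial, and the overall score is the arithmetic
mean of the AP, ML and V axis scores — all in G.

Tilt amplitude series are computed the same way from the tilt angles
(degrees) and reported alongside, but the sway scores are built from
accelerations only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    EmptySeriesError,
    InsufficientDataError,
    ParseError,
    RangeError,
    ValidationError,
)
from .tilt import FULL_SCALE_G, AccelSeries, TiltSeries

ANATOMICAL_AXES = ("AP", "ML", "V")
DEVICE_AXES = ("X", "Y", "Z")

#: AMP window length in seconds.
AMP_WINDOW_S = 1.0

#: Number of AMP values pooled into one RMS value (3 s update cadence).
RMS_GROUP_SIZE = 3


@dataclass(frozen=True)
class AxisMap:
    """Bijective mapping from device axes X/Y/Z to anatomical AP/ML/V.

    The default corresponds to a patch worn flat on the chest with the
    device Z axis pointing outward (anterior), X across the chest and Y
    along the trunk: Z→AP, X→ML, Y→V.
    """

    X: str = "ML"
    Y: str = "V"
    Z: str = "AP"

    def __post_init__(self) -> None:
        values = (self.X, self.Y, self.Z)
        if sorted(values) != sorted(ANATOMICAL_AXES):
            raise ValidationError(
                f"axis map {values} is not a bijection onto {ANATOMICAL_AXES}"
            )

    def device_for(self, anatomical: str) -> str:
        """Device axis mapped to the given anatomical direction."""
        for dev in DEVICE_AXES:
            if getattr(self, dev) == anatomical:
                return dev
        raise ValidationError(f"unknown anatomical axis {anatomical!r}")

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "AxisMap":
        return cls(**{k.upper(): v.upper() for k, v in mapping.items()})


@dataclass
class SwayFeatureSet:
    """Per-axis windowed sway features and scalar scores for one trial.

    ``amp_series``/``rms_series`` are keyed by anatomical axis (AP/ML/V) in
    G; ``tilt_amp_series`` by angle name (theta/psi/phi) in degrees.
    ``axis_scores`` holds the mean RMS per anatomical axis; ``mean_score``
    is their arithmetic mean.
    """

    amp_series: dict[str, np.ndarray]
    rms_series: dict[str, np.ndarray]
    tilt_amp_series: dict[str, np.ndarray] = field(default_factory=dict)
    axis_scores: dict[str, float] = field(default_factory=dict)
    mean_score: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "axis_scores": {k: float(v) for k, v in self.axis_scores.items()},
            "mean_score": float(self.mean_score),
            "amp_series": {k: v.tolist() for k, v in self.amp_series.items()},
            "rms_series": {k: v.tolist() for k, v in self.rms_series.items()},
            "tilt_amp_series": {
                k: v.tolist() for k, v in self.tilt_amp_series.items()
            },
        }


def amp_per_second(values: np.ndarray, rate: float) -> np.ndarray:
    """Per-second amplitude: max − min over non-overlapping 1 s windows.

    Windows are aligned to the start of the trial; a trailing partial
    window is dropped.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptySeriesError("cannot window an empty series")
    if rate <= 0:
        raise ValidationError("rate must be positive")
    win = int(round(rate * AMP_WINDOW_S))
    if win < 1:
        raise ValidationError(f"rate {rate:g} Hz gives an empty 1 s window")
    n_win = values.size // win
    if n_win == 0:
        return np.empty(0)
    w = values[: n_win * win].reshape(n_win, win)
    return w.max(axis=1) - w.min(axis=1)


def rms_of_groups(amp: np.ndarray, group_size: int = RMS_GROUP_SIZE) -> np.ndarray:
    """RMS over consecutive non-overlapping groups of ``group_size`` AMP values."""
    amp = np.asarray(amp, dtype=float)
    if group_size < 1:
        raise ValidationError("group_size must be ≥ 1")
    n_groups = amp.size // group_size
    if n_groups == 0:
        warnings.warn(
            f"fewer than {group_size} AMP values: RMS series is empty",
            stacklevel=2,
        )
        return np.empty(0)
    g = amp[: n_groups * group_size].reshape(n_groups, group_size)
    return np.sqrt(np.mean(g**2, axis=1))


def extract_features(
    series: AccelSeries,
    tilt: TiltSeries | None = None,
    axis_map: AxisMap | None = None,
    sample_rate: float | None = None,
) -> SwayFeatureSet:
    """Compute the full windowed feature set for one trial.

    Applies :func:`amp_per_second` and :func:`rms_of_groups` independently
    per device axis, relabels the axes anatomically, and averages each
    axis's RMS series into its scalar sway score.  A T-second trial yields
    ⌊T⌋ AMP values and ⌊T/3⌋ RMS values per axis; trials shorter than 3 s
    are rejected because no RMS value can be formed.
    """
    axis_map = axis_map or AxisMap()
    rate = sample_rate if sample_rate is not None else series.sample_rate()
    win = int(round(rate))
    if len(series) < RMS_GROUP_SIZE * win:
        raise InsufficientDataError(
            f"trial has {len(series)} samples at {rate:g} Hz "
            f"(< {RMS_GROUP_SIZE} s): no RMS window can be formed"
        )

    device_cols = {"X": series.ax, "Y": series.ay, "Z": series.az}
    amp_series: dict[str, np.ndarray] = {}
    rms_series: dict[str, np.ndarray] = {}
    axis_scores: dict[str, float] = {}
    for dev in DEVICE_AXES:
        anatomical = getattr(axis_map, dev)
        amp = amp_per_second(device_cols[dev], rate)
        rms = rms_of_groups(amp)
        amp_series[anatomical] = amp
        rms_series[anatomical] = rms
        axis_scores[anatomical] = float(np.mean(rms))

    tilt_amp: dict[str, np.ndarray] = {}
    if tilt is not None and len(tilt) > 0:
        for name in ("theta", "psi", "phi"):
            angle = getattr(tilt, name)
            if np.asarray(angle).size >= tilt.rate:
                tilt_amp[name] = amp_per_second(angle, tilt.rate)

    mean_score = float(np.mean([axis_scores[a] for a in ANATOMICAL_AXES]))
    return SwayFeatureSet(
        amp_series=amp_series,
        rms_series=rms_series,
        tilt_amp_series=tilt_amp,
        axis_scores=axis_scores,
        mean_score=mean_score,
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

ACCEL_COLUMNS = ["t", "ax", "ay", "az"]


def read_accel_csv(path: str | Path) -> AccelSeries:
    """Read an accelerometer CSV with header ``t,ax,ay,az``.

    Time in seconds (strictly increasing), accelerations in G; values
    outside the ±8 G full scale are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise ParseError(f"cannot read accelerometer CSV {path}: {exc}") from exc
    missing = [c for c in ACCEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing} (expected {ACCEL_COLUMNS})")
    df = df[ACCEL_COLUMNS]
    try:
        arr = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric value ({exc})") from exc
    if not np.all(np.isfinite(arr)):
        bad = int(np.argwhere(~np.isfinite(arr))[0][0])
        raise ParseError(f"{path}: non-finite value at data row {bad}")
    t = arr[:, 0]
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise ParseError(f"{path}: timestamps are not strictly increasing")
    accel = arr[:, 1:]
    if np.any(np.abs(accel) > FULL_SCALE_G):
        worst = float(np.max(np.abs(accel)))
        raise RangeError(
            f"{path}: acceleration {worst:g} G exceeds the ±{FULL_SCALE_G:g} G scale"
        )
    return AccelSeries(t=t, ax=accel[:, 0], ay=accel[:, 1], az=accel[:, 2])


def write_accel_csv(series: AccelSeries, path: str | Path) -> None:
    """Write an :class:`AccelSeries` to CSV (``t,ax,ay,az``)."""
    df = pd.DataFrame(
        {"t": series.t, "ax": series.ax, "ay": series.ay, "az": series.az}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def write_features(features: SwayFeatureSet, path: str | Path) -> None:
    """Write a feature set to disk.

    ``.json`` paths receive the full per-subject summary (scores plus all
    series); anything else is written as a long-format CSV with columns
    ``window_start,axis,amp,rms`` where ``rms`` is populated on every third
    window (its 3 s update cadence) and empty otherwise.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(features.to_dict(), indent=2))
        return
    rows = []
    for axis in ANATOMICAL_AXES:
        amp = features.amp_series[axis]
        rms = features.rms_series[axis]
        for i, a in enumerate(amp):
            j = (i + 1) // RMS_GROUP_SIZE - 1
            at_update = (i + 1) % RMS_GROUP_SIZE == 0 and j < rms.size
            rows.append(
                {
                    "window_start": float(i),
                    "axis": axis,
                    "amp": float(a),
                    "rms": float(rms[j]) if at_update else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
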