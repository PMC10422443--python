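"""Seeded synthetic cohorts and accelerometer signals.

The study population this package targets — 20 healthy young adults and
20 older adults with mild cognitive impairment (MCI) — is emulated at two
levels:

* **score level**: per-group Gaussian draws of the scalar sway score and
  of the clinical scores (BBS, TUG), parameterized by the published group
  means and standard deviations.  Sway-score distributions are plain
  Gaussians (negative draws permitted) so that the moments being matched
  are unbiased; BBS draws are rounded to integers and clipped to [0, 56],
  TUG draws are clipped positive.
* **signal level**: raw 3-axis accelerometer traces — a gravity-oriented
  baseline plus band-limited postural-sway oscillation (a sum of three
  random-phase sinusoids with frequencies uniform in 0.1–2 Hz, the
  typical sway bandwidth) plus white sensor noise.  The oscillation
  amplitude can be calibrated so that the full windowing pipeline yields
  a prescribed sway score, which lets signal-level cohorts reproduce
  score-level statistics end to end.

One global seed fans out into per-subject substreams via
``numpy.random.SeedSequence`` so that any one subject's data is
reproducible independent of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .diagnostics import SubjectRecord
from .errors import RangeError, ValidationError
from .features import AxisMap, extract_features
from .tilt import FULL_SCALE_G, AccelSeries

# Published group summary statistics (mean, SD) for the two study groups.
# Sway scores are context-specific: each group's sway was summarized
# separately during the BBS and during the TUG clinical test.
TABLE_PARAMS: dict[tuple[str, str], dict[str, float]] = {
    ("healthy", "bbs"): {"sway_mean": 0.16, "sway_sd": 0.20},
    ("healthy", "tug"): {"sway_mean": 0.36, "sway_sd": 0.08},
    ("MCI", "bbs"): {"sway_mean": 0.41, "sway_sd": 0.12},
    ("MCI", "tug"): {"sway_mean": 0.47, "sway_sd": 0.12},
}
CLINICAL_PARAMS: dict[str, dict[str, float]] = {
    "healthy": {"bbs_mean": 54.61, "bbs_sd": 1.33, "tug_mean": 9.42, "tug_sd": 0.25},
    "MCI": {"bbs_mean": 39.0, "bbs_sd": 5.88, "tug_mean": 14.11, "tug_sd": 1.37},
}
DEFAULT_GROUP_N = 20


@dataclass(frozen=True)
class GroupParams:
    """Gaussian summary parameters for one study group."""

    label: Literal["healthy", "MCI"]
    sway_mean: float
    sway_sd: float
    bbs_mean: float
    bbs_sd: float
    tug_mean: float
    tug_sd: float
    n: int = DEFAULT_GROUP_N

    def __post_init__(self) -> None:
        if min(self.sway_sd, self.bbs_sd, self.tug_sd) <= 0:
            raise ValidationError("group standard deviations must be positive")
        if self.n < 1:
            raise ValidationError("group size must be ≥ 1")


def group_params(
    label: Literal["healthy", "MCI"],
    context: Literal["bbs", "tug"] = "bbs",
    n: int = DEFAULT_GROUP_N,
) -> GroupParams:
    """Default :class:`GroupParams` for a study group.

    ``context`` selects which clinical test the sway moments were
    summarized under (the sway distributions differ between the BBS and
    TUG test conditions).
    """
    key = (label, context)
    if key not in TABLE_PARAMS:
        raise ValidationError(f"unknown group/context {key}")
    return GroupParams(label=label, n=n, **TABLE_PARAMS[key], **CLINICAL_PARAMS[label])


def binormal_auc(mean_neg: float, sd_neg: float, mean_pos: float, sd_pos: float) -> float:
    """Closed-form AUC for two Gaussian score distributions.

    Φ(Δμ / √(σ₀² + σ₁²)) — the probability a draw from the positive
    distribution exceeds a draw from the negative one.
    """
    return float(
        stats.norm.cdf((mean_pos - mean_neg) / np.hypot(sd_neg, sd_pos))
    )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_scores(params: GroupParams, seed) -> np.ndarray:
    """Draw ``params.n`` sway scores from the group's Gaussian."""
    return _rng(seed).normal(params.sway_mean, params.sway_sd, size=params.n)


def sample_clinical(params: GroupParams, seed) -> tuple[np.ndarray, np.ndarray]:
    """Draw (BBS, TUG) clinical scores for the group.

    BBS draws are rounded to the nearest integer and clipped to the 0–56
    scale; TUG times are clipped to a small positive floor.
    """
    rng = _rng(seed)
    bbs = np.clip(
        np.rint(rng.normal(params.bbs_mean, params.bbs_sd, size=params.n)), 0, 56
    ).astype(int)
    tug = np.maximum(rng.normal(params.tug_mean, params.tug_sd, size=params.n), 0.1)
    return bbs, tug


# ---------------------------------------------------------------------------
# Raw signal synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalSpec:
    """Recipe for one synthetic accelerometer trial.

    ``amplitude`` is the peak sway oscillation per device axis in G (the
    sum of the three sinusoid components is normalized to that peak);
    ``gravity`` is the baseline orientation as a unit vector scaled to
    1 G; ``band`` bounds the sway frequencies in Hz.
    """

    duration: float = 30.0
    rate: float = 50.0
    gravity: tuple[float, float, float] = (0.0, 0.0, 1.0)
    amplitude: tuple[float, float, float] = (0.1, 0.1, 0.1)
    band: tuple[float, float] = (0.1, 2.0)
    noise_sd: float = 0.0
    seed: int = 0
    n_components: int = 3

    def __post_init__(self) -> None:
        if self.duration < 3.0:
            raise ValidationError("trial must last at least 3 s (one RMS window)")
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        if any(a < 0 for a in self.amplitude):
            raise ValidationError("sway amplitudes must be non-negative")
        if not 0 < self.band[0] < self.band[1]:
            raise ValidationError("sway band must satisfy 0 < low < high")
        if self.noise_sd < 0:
            raise ValidationError("noise SD must be non-negative")
        g = np.asarray(self.gravity, dtype=float)
        if not np.linalg.norm(g) > 0:
            raise ValidationError("gravity vector must be non-zero")
        if self.n_components < 1:
            raise ValidationError("need at least one oscillation component")
        # worst-case per-axis excursion must stay inside the sensor range
        ghat = np.abs(g) / np.linalg.norm(g)
        worst = ghat + np.asarray(self.amplitude) + 6.0 * self.noise_sd
        if np.any(worst > FULL_SCALE_G):
            raise RangeError(
                f"spec can exceed the ±{FULL_SCALE_G:g} G scale "
                f"(worst-case per-axis excursion {worst.max():.2f} G)"
            )


def generate_signal(spec: SignalSpec) -> AccelSeries:
    """Generate one synthetic 3-axis acceleration trial.

    Bit-reproducible for a fixed ``spec.seed``: the sinusoid frequencies,
    phases and noise are all drawn from one seeded substream.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    g = np.asarray(spec.gravity, dtype=float)
    g = g / np.linalg.norm(g)

    accel = np.tile(g, (n, 1))
    for axis in range(3):
        freqs = rng.uniform(spec.band[0], spec.band[1], size=spec.n_components)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_components)
        wave = np.sum(
            [np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs, phases)], axis=0
        ) / spec.n_components
        accel[:, axis] += spec.amplitude[axis] * wave
    if spec.noise_sd > 0:
        accel += rng.normal(0.0, spec.noise_sd, size=accel.shape)

    if np.any(np.abs(accel) > FULL_SCALE_G):
        raise RangeError(
            f"generated signal exceeds the ±{FULL_SCALE_G:g} G full scale"
        )
    return AccelSeries(t=t, ax=accel[:, 0], ay=accel[:, 1], az=accel[:, 2])


def _pipeline_score(
    spec: SignalSpec, amplitude: float, axis_map: AxisMap, direction: str
) -> float:
    sized = replace(spec, amplitude=(amplitude, amplitude, amplitude))
    series = generate_signal(sized)
    feats = extract_features(series, axis_map=axis_map, sample_rate=spec.rate)
    if direction == "mean":
        return feats.mean_score
    return feats.axis_scores[direction]


def calibrate_amplitude(
    target_score: float,
    spec: SignalSpec,
    axis_map: AxisMap | None = None,
    direction: str = "mean",
    rtol: float = 0.02,
) -> float:
    """Find the oscillation amplitude whose pipeline sway score hits a target.

    The windowing pipeline (per-second amplitude → 3 s RMS → mean) is
    linear in the oscillation amplitude for a noiseless signal, and
    monotone in it generally, so a 1-D root search on the fixed signal
    realization (same seed at every trial amplitude) converges quickly.
    The returned amplitude reproduces ``target_score`` to within ``rtol``
    (relative).

    Raises :class:`RangeError` when the target cannot be reached inside
    the ±8 G sensor range, or sits below the noise floor.
    """
    axis_map = axis_map or AxisMap()
    if target_score < 0:
        raise ValidationError("target sway score must be non-negative")
    if target_score == 0.0:
        if spec.noise_sd > 0:
            raise RangeError("zero score unreachable with non-zero sensor noise")
        return 0.0

    floor = _pipeline_score(spec, 0.0, axis_map, direction)
    if target_score < floor:
        raise RangeError(
            f"target {target_score:g} G is below the noise floor {floor:.3g} G"
        )
    if target_score == floor:
        return 0.0

    # largest amplitude that keeps the worst-case excursion inside ±8 G
    hi_max = FULL_SCALE_G - 1.0 - 6.0 * spec.noise_sd
    if hi_max <= 0:
        raise RangeError("noise leaves no headroom inside the ±8 G scale")

    def f(amp: float) -> float:
        return _pipeline_score(spec, amp, axis_map, direction) - target_score

    if spec.noise_sd == 0.0:
        unit = _pipeline_score(spec, 1.0, axis_map, direction)
        if unit <= 0:
            raise ValidationError("degenerate signal spec: unit amplitude scores 0")
        amp = target_score / unit
        if amp > hi_max:
            raise RangeError(
                f"target {target_score:g} G needs amplitude {amp:.3g} G, "
                f"outside the ±{FULL_SCALE_G:g} G scale"
            )
        return amp

    hi = min(1.0, hi_max)
    while f(hi) < 0:
        if hi >= hi_max:
            raise RangeError(
                f"target {target_score:g} G unreachable inside the "
                f"±{FULL_SCALE_G:g} G scale"
            )
        hi = min(2.0 * hi, hi_max)
    amp = float(optimize.brentq(f, 0.0, hi, xtol=1e-6, rtol=1e-6))
    achieved = _pipeline_score(spec, amp, axis_map, direction)
    if abs(achieved - target_score) > rtol * target_score:
        raise ValidationError(
            f"calibration landed at {achieved:.4g} G for target {target_score:g} G"
        )
    return amp


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def _spawn_seeds(seed: int, k: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(k)


def score_level_cohort(
    healthy: GroupParams | None = None,
    mci: GroupParams | None = None,
    context: Literal["bbs", "tug"] = "bbs",
    seed: int = 0,
) -> list[SubjectRecord]:
    """Generate subject records with Gaussian sway scores (no raw signals).

    Each subject's per-direction scores are set to their mean-direction
    draw; clinical scores come from the group's clinical Gaussians.
    MCI subjects carry a positive 3-month fall history (it is one of
    their inclusion criteria), healthy subjects a negative one.
    """
    healthy = healthy or group_params("healthy", context)
    mci = mci or group_params("MCI", context)
    records: list[SubjectRecord] = []
    for params, grp_seed in zip((healthy, mci), _spawn_seeds(seed, 2)):
        s_scores, s_clin = (np.random.default_rng(c) for c in grp_seed.spawn(2))
        sway = sample_scores(params, s_scores)
        bbs, tug = sample_clinical(params, s_clin)
        for i in range(params.n):
            sid = f"{params.label}-{i + 1:03d}"
            score = float(sway[i])
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=params.label,
                    bbs_score=int(bbs[i]),
                    tug_seconds=float(tug[i]),
                    fell_within_3_months=params.label == "MCI",
                    sway_scores={"AP": score, "ML": score, "V": score, "mean": score},
                )
            )
    return records


def signal_level_cohort(
    healthy: GroupParams | None = None,
    mci: GroupParams | None = None,
    context: Literal["bbs", "tug"] = "bbs",
    seed: int = 0,
    template: SignalSpec | None = None,
    axis_map: AxisMap | None = None,
) -> tuple[list[SubjectRecord], dict[str, AccelSeries]]:
    """Generate raw accelerometer trials whose pipeline scores follow the
    group score distributions.

    Each subject's target mean-direction score is drawn from the group
    Gaussian (negative draws clipped to the noise floor, since a windowed
    sway score cannot be negative), the oscillation amplitude is
    calibrated through the real feature pipeline, and the trial signal is
    emitted.  Returns the records (sway scores still unset — they are to
    be computed by the pipeline) and the signals keyed by subject id.
    """
    healthy = healthy or group_params("healthy", context)
    mci = mci or group_params("MCI", context)
    template = template or SignalSpec()
    axis_map = axis_map or AxisMap()

    records: list[SubjectRecord] = []
    signals: dict[str, AccelSeries] = {}
    for params, grp_seed in zip((healthy, mci), _spawn_seeds(seed, 2)):
        children = grp_seed.spawn(2 + params.n)
        s_scores, s_clin = (np.random.default_rng(c) for c in children[:2])
        targets = sample_scores(params, s_scores)
        bbs, tug = sample_clinical(params, s_clin)
        for i in range(params.n):
            sid = f"{params.label}-{i + 1:03d}"
            subj_seed = int(children[2 + i].generate_state(1)[0] % (2**31))
            spec = replace(template, seed=subj_seed)
            floor = _pipeline_score(spec, 0.0, axis_map, "mean")
            target = max(float(targets[i]), floor)
            amp = calibrate_amplitude(target, spec, axis_map=axis_map)
            signals[sid] = generate_signal(
                replace(spec, amplitude=(amp, amp, amp))
            )
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=params.label,
                    bbs_score=int(bbs[i]),
                    tug_seconds=float(tug[i]),
                    fell_within_3_months=params.label == "MCI",
                )
            )
    return records, signals
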