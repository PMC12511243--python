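"""Synthetic PPG population generator.

Emulates a cohort of subjects, each contributing one single-channel
finger-PPG recording (nominally 100 samples/s for 120 s) and one paired
cuff reference measurement of systolic/diastolic blood pressure (SBP/DBP).
The cohort mixes the four AHA blood-pressure categories in configurable
proportions, and the waveform morphology of each subject is a smooth
deterministic function of their BP (plus optional per-subject jitter), so
that BP is genuinely recoverable from the waveform — the premise every
downstream stage (feature extraction, selection, regression) relies on.

The beat model is a sum of two Gaussians per cardiac cycle: a systolic
wave and a delayed, smaller diastolic wave.  A low-frequency sinusoidal
baseline drift and white Gaussian measurement noise are added on top.
This is deliberately the simplest pulsatile model that preserves a
morphology-BP link; it makes no claim of hemodynamic realism (see
docs/methods.md for what it does and does not emulate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CATEGORIES",
    "AHA_THRESHOLDS",
    "SubjectParams",
    "PPGRecording",
    "PopulationConfig",
    "assign_bp_category",
    "largest_remainder_counts",
    "category_sequence",
    "generate_subject",
    "beat_waveform",
    "synthesize_recording",
    "generate_population",
]

#: AHA category labels in increasing severity order.
CATEGORIES = ("normal", "elevated", "stage1", "stage2")

#: Hard-coded AHA (2017 convention) cut-offs in mmHg.  ``normal``:
#: SBP < 120 and DBP < 80; ``elevated``: SBP 120-129 and DBP < 80;
#: ``stage1``: SBP 130-139 or DBP 80-89; ``stage2``: SBP >= 140 or
#: DBP >= 90.  The higher category always wins.
AHA_THRESHOLDS = {
    "elevated_sbp": 120.0,
    "stage1_sbp": 130.0,
    "stage1_dbp": 80.0,
    "stage2_sbp": 140.0,
    "stage2_dbp": 90.0,
}


def assign_bp_category(sbp: float, dbp: float) -> str:
    """Classify a (SBP, DBP) pair into an AHA blood-pressure category.

    Parameters
    ----------
    sbp, dbp : float
        Systolic and diastolic pressure in mmHg.  Must satisfy
        ``sbp > dbp > 0``.

    Returns
    -------
    str
        One of :data:`CATEGORIES`.  When SBP and DBP fall in different
        categories the higher (more severe) one wins.
    """
    if not (sbp > dbp > 0):
        raise ValueError(
            f"invalid blood pressure: require sbp > dbp > 0, got sbp={sbp}, dbp={dbp}"
        )
    t = AHA_THRESHOLDS
    if sbp >= t["stage2_sbp"] or dbp >= t["stage2_dbp"]:
        return "stage2"
    if sbp >= t["stage1_sbp"] or dbp >= t["stage1_dbp"]:
        return "stage1"
    if sbp >= t["elevated_sbp"]:
        return "elevated"
    return "normal"


@dataclass(frozen=True)
class SubjectParams:
    """Waveform-generator parameters for one synthetic subject.

    Amplitudes are in arbitrary units (a.u.), widths/delays in seconds.
    """

    subject_id: str
    heart_rate: float  # beats/min
    sys_amp: float  # systolic wave amplitude, a.u.
    dia_amp: float  # diastolic wave amplitude, a.u.
    sys_width: float  # systolic Gaussian width, s
    dia_width: float  # diastolic Gaussian width, s
    dia_delay: float  # systolic-to-diastolic peak delay, s
    baseline_drift_amp: float  # a.u.
    noise_sd: float  # a.u.
    sbp_ref: float  # mmHg
    dbp_ref: float  # mmHg

    def __post_init__(self) -> None:
        if not (40.0 <= self.heart_rate <= 180.0):
            raise ValueError(f"heart_rate {self.heart_rate} outside [40, 180] bpm")
        if not (self.sys_amp > self.dia_amp > 0):
            raise ValueError("require sys_amp > dia_amp > 0")
        if not (0 < self.dia_delay < 60.0 / self.heart_rate):
            raise ValueError("dia_delay must lie inside one cardiac period")
        if not (self.sbp_ref > self.dbp_ref):
            raise ValueError("require sbp_ref > dbp_ref")


@dataclass(frozen=True)
class PPGRecording:
    """One subject's raw PPG trace plus its reference BP measurement."""

    subject_id: str
    samples: np.ndarray  # a.u.
    fs: float  # samples/s
    duration: float  # s
    sbp_ref: float  # mmHg
    dbp_ref: float  # mmHg
    category: str

    def __post_init__(self) -> None:
        if len(self.samples) != round(self.fs * self.duration):
            raise ValueError(
                f"sample count {len(self.samples)} != fs*duration "
                f"{round(self.fs * self.duration)}"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        expected = assign_bp_category(self.sbp_ref, self.dbp_ref)
        if self.category != expected:
            raise ValueError(
                f"category {self.category!r} inconsistent with "
                f"({self.sbp_ref}, {self.dbp_ref}) -> {expected!r}"
            )


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of the synthetic cohort.

    Defaults reproduce the study conditions: 56 subjects, category mix
    30/20/25/25%, SBP 97-164 mmHg, DBP 57-109 mmHg, 100 samples/s,
    120 s recordings.
    """

    n_subjects: int = 56
    category_fractions: tuple[float, float, float, float] = (0.30, 0.20, 0.25, 0.25)
    sbp_range: tuple[float, float] = (97.0, 164.0)
    dbp_range: tuple[float, float] = (57.0, 109.0)
    seed: int = 0
    fs: float = 100.0
    duration: float = 120.0
    noise_sd: float = 0.02
    baseline_drift_amp: float = 0.1
    jitter_sd: float = 0.02  # relative per-subject morphology jitter; 0 disables

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if len(self.category_fractions) != len(CATEGORIES):
            raise ValueError("need one fraction per category")
        if abs(sum(self.category_fractions) - 1.0) > 1e-9:
            raise ValueError("category_fractions must sum to 1")
        if any(f < 0 for f in self.category_fractions):
            raise ValueError("category_fractions must be non-negative")
        if not (self.sbp_range[0] < self.sbp_range[1]):
            raise ValueError("sbp_range must be ordered")
        if not (self.dbp_range[0] < self.dbp_range[1]):
            raise ValueError("dbp_range must be ordered")


def largest_remainder_counts(fractions, n: int) -> list[int]:
    """Integer allocation of ``n`` items to proportions by largest remainder.

    Guarantees the counts sum to ``n`` exactly; ties in the fractional
    parts are broken by position (earlier categories first).
    """
    quotas = [f * n for f in fractions]
    counts = [math.floor(q) for q in quotas]
    short = n - sum(counts)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def category_sequence(config: PopulationConfig) -> list[str]:
    """Category label per subject index, matching the configured mix exactly."""
    counts = largest_remainder_counts(config.category_fractions, config.n_subjects)
    seq: list[str] = []
    for cat, c in zip(CATEGORIES, counts):
        seq.extend([cat] * c)
    return seq


def _bp_band(category: str, config: PopulationConfig) -> tuple[tuple, tuple]:
    """(SBP, DBP) uniform sampling band for one category, clipped to the
    configured population ranges.  Bands are chosen so that any draw is
    guaranteed to classify into the requested category."""
    t = AHA_THRESHOLDS
    eps = 1e-6  # keep strict '<' thresholds strict under uniform draws
    slo, shi = config.sbp_range
    dlo, dhi = config.dbp_range
    bands = {
        "normal": ((slo, t["elevated_sbp"] - eps), (dlo, t["stage1_dbp"] - eps)),
        "elevated": (
            (t["elevated_sbp"], t["stage1_sbp"] - eps),
            (dlo, t["stage1_dbp"] - eps),
        ),
        "stage1": (
            (t["stage1_sbp"], t["stage2_sbp"] - eps),
            (t["stage1_dbp"], t["stage2_dbp"] - eps),
        ),
        "stage2": ((t["stage2_sbp"], shi), (t["stage2_dbp"], dhi)),
    }
    (sa, sb), (da, db) = bands[category]
    sa, sb = max(sa, slo), min(sb, shi)
    da, db = max(da, dlo), min(db, dhi)
    if not (sa < sb and da < db):
        raise ValueError(
            f"category {category!r} band empty under configured BP ranges"
        )
    return (sa, sb), (da, db)


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    """One independent RNG stream per (population seed, subject index)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_subject(
    config: PopulationConfig, index: int, rng: np.random.Generator | None = None
) -> SubjectParams:
    """Draw one subject's BP and waveform parameters.

    BP is drawn uniformly inside the subject's category band (categories
    are allocated across indices by largest-remainder rounding of the
    configured fractions) intersected with the population ranges.  The
    waveform parameters are then smooth functions of (SBP, DBP):

    * ``sys_amp   = 0.5  + 0.004  * (SBP - 97)``  a.u.
    * ``dia_amp   = 0.2  + 0.002  * (DBP - 57)``  a.u.
    * ``dia_delay = 0.35 - 0.0015 * (DBP - 57)``  s
    * ``heart_rate = 65  + 0.15   * (SBP - 97)``  bpm

    so that morphology genuinely encodes BP.  Multiplicative log-normal
    jitter of relative scale ``config.jitter_sd`` individualises the
    morphology; with ``jitter_sd=0`` the BP -> parameter map is exactly
    deterministic.
    """
    if not (0 <= index < config.n_subjects):
        raise ValueError(f"index {index} outside [0, {config.n_subjects})")
    if rng is None:
        rng = _subject_rng(config.seed, index)
    category = category_sequence(config)[index]
    (sa, sb), (da, db) = _bp_band(category, config)
    sbp = rng.uniform(sa, sb)
    dbp = rng.uniform(da, db)

    def jit() -> float:
        if config.jitter_sd == 0:
            return 1.0
        return float(np.exp(rng.normal(0.0, config.jitter_sd)))

    heart_rate = (65.0 + 0.15 * (sbp - 97.0)) * jit()
    sys_amp = (0.5 + 0.004 * (sbp - 97.0)) * jit()
    dia_amp = (0.2 + 0.002 * (dbp - 57.0)) * jit()
    sys_width = 0.10 * jit()
    dia_width = 0.12 * jit()
    dia_delay = (0.35 - 0.0015 * (dbp - 57.0)) * jit()
    return SubjectParams(
        subject_id=f"S{index:03d}",
        heart_rate=heart_rate,
        sys_amp=sys_amp,
        dia_amp=dia_amp,
        sys_width=sys_width,
        dia_width=dia_width,
        dia_delay=dia_delay,
        baseline_drift_amp=config.baseline_drift_amp,
        noise_sd=config.noise_sd,
        sbp_ref=sbp,
        dbp_ref=dbp,
    )


def beat_waveform(params: SubjectParams, tau: np.ndarray) -> np.ndarray:
    """Noise-free pulse shape evaluated at within-beat times ``tau`` (s).

    ``s(t) = A_s exp(-(t - 0.15T)^2 / 2w_s^2) + A_d exp(-(t - 0.15T - d)^2 / 2w_d^2)``
    with ``T = 60/heart_rate`` the cardiac period: a systolic Gaussian
    peaking early in the cycle plus a delayed diastolic Gaussian.
    """
    T = 60.0 / params.heart_rate
    t_sys = 0.15 * T
    sys_part = params.sys_amp * np.exp(
        -((tau - t_sys) ** 2) / (2.0 * params.sys_width**2)
    )
    dia_part = params.dia_amp * np.exp(
        -((tau - t_sys - params.dia_delay) ** 2) / (2.0 * params.dia_width**2)
    )
    return sys_part + dia_part


#: Frequency (Hz) of the low-frequency baseline wander component.
DRIFT_FREQ_HZ = 0.1


def synthesize_recording(
    params: SubjectParams,
    fs: float = 100.0,
    duration: float = 120.0,
    rng: np.random.Generator | None = None,
) -> PPGRecording:
    """Render one subject's recording from their waveform parameters.

    Concatenated beats (the two-Gaussian pulse, phase-locked to t=0) plus
    a 0.1 Hz sinusoidal baseline drift and white Gaussian noise.  With
    identical ``rng`` state the samples are identical.
    """
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    n = round(fs * duration)
    t = np.arange(n) / fs
    T = 60.0 / params.heart_rate
    tau = np.mod(t, T)
    x = beat_waveform(params, tau)
    if params.baseline_drift_amp != 0:
        x = x + params.baseline_drift_amp * np.sin(2 * np.pi * DRIFT_FREQ_HZ * t)
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, n)
    return PPGRecording(
        subject_id=params.subject_id,
        samples=np.asarray(x, dtype=float),
        fs=fs,
        duration=duration,
        sbp_ref=params.sbp_ref,
        dbp_ref=params.dbp_ref,
        category=assign_bp_category(params.sbp_ref, params.dbp_ref),
    )


def generate_population(
    config: PopulationConfig,
) -> tuple[list[SubjectParams], list[PPGRecording]]:
    """Generate the full cohort: parameters and recordings for every subject.

    Each subject uses an RNG stream derived from ``(config.seed, index)``,
    so the population is reproducible and independent of generation order.
    """
    params_list: list[SubjectParams] = []
    recordings: list[PPGRecording] = []
    for i in range(config.n_subjects):
        rng = _subject_rng(config.seed, i)
        p = generate_subject(config, i, rng)
        params_list.append(p)
        recordings.append(
            synthesize_recording(p, fs=config.fs, duration=config.duration, rng=rng)
        )
    return params_list, recordings
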