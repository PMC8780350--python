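"""Synthetic longitudinal PPG/BP cohort generator.

The real study data (11 subjects measured ~4 times/day for one month with a
fingertip PPG sensor and an upper-arm cuff reference) is private, so this
module generates cohorts with the same statistical structure:

* a two-Gaussian beat morphology (systolic wave + reflected wave) that
  exhibits the downstroke inflection landmark without requiring a dicrotic
  notch or diastolic peak;
* per-subject blood-pressure baselines, feature-to-BP coefficients and
  heart-rate distributions drawn from population hyper-distributions, so
  that samples from different subjects follow different distributions
  (higher intra- than inter-subject similarity in feature space);
* a slow negative BP drift emulating a seasonal decline over the month,
  plus a small circadian oscillation across the four daily time slots;
* sensor white noise, low-frequency baseline wander, and (optionally)
  sessions whose beats are replaced by a symmetric artifact waveform whose
  skewness falls below the signal-quality threshold, to exercise the
  quality-rejection path.

All randomness flows through an explicit :class:`numpy.random.Generator`;
there is no global RNG state, and identical (config, seed) pairs produce
bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .errors import InvalidArgumentError
from .records import PPGRecord

__all__ = [
    "BeatParams",
    "SubjectParams",
    "CohortConfig",
    "PopulationParams",
    "SubjectSessions",
    "synth_beat",
    "synth_session",
    "draw_subject_params",
    "simulate_cohort",
    "write_cohort",
]

#: fraction of the shared physiological signal (HR / reflection excursions,
#: circadian oscillation) that propagates into diastolic pressure
DBP_SHARE = 0.6

#: daily session slots (hours of day) and circadian phase offset
SESSION_HOURS = (8.0, 12.0, 16.0, 20.0)
CIRCADIAN_PHASE = 0.7 * math.pi

COHORT_START = datetime(2021, 5, 15)


@dataclass
class BeatParams:
    """Morphology of one cardiac cycle as a sum of two Gaussian bumps.

    The systolic wave peaks at ``t_sys_frac * period``; the reflected wave
    is centred at ``t_refl_frac * period`` on the downstroke. ``amp_refl``
    is an absolute amplitude constrained to ``[0, amp_sys]``.
    """

    amp_sys: float = 1.0
    amp_refl: float = 0.4
    t_sys_frac: float = 0.20
    t_refl_frac: float = 0.55
    width_sys: float = 0.05
    width_refl: float = 0.085
    period: float = 0.8
    baseline: float = 10.0

    def __post_init__(self) -> None:
        if self.amp_sys <= 0:
            raise InvalidArgumentError("amp_sys must be positive")
        if not 0 <= self.amp_refl <= self.amp_sys:
            raise InvalidArgumentError("amp_refl must lie in [0, amp_sys]")
        if not 0 < self.t_sys_frac < self.t_refl_frac < 1:
            raise InvalidArgumentError("need 0 < t_sys_frac < t_refl_frac < 1")
        if self.t_sys_frac >= 0.5:
            raise InvalidArgumentError("t_sys_frac must be < 0.5")
        if self.period <= 0:
            raise InvalidArgumentError("period must be positive")
        if self.width_sys <= 0 or self.width_refl <= 0:
            raise InvalidArgumentError("widths must be positive")


@dataclass
class SubjectParams:
    """Ground-truth generative parameters for one subject.

    ``beta_hr``, ``beta_ri`` and ``beta_a`` link the latent physiological
    state (heart rate, reflection ratio, amplitude factor) to true BP in
    mmHg per unit; ``drift_sbp``/``drift_dbp`` are mmHg/day slopes of the
    slow seasonal trend (negative by default).
    """

    subject_id: str
    sbp_base: float = 120.0
    dbp_base: float = 75.0
    beta_hr: float = 0.6
    beta_ri: float = 25.0
    beta_a: float = 0.0
    drift_sbp: float = -0.30
    drift_dbp: float = -0.10
    hr_mean: float = 70.0
    hr_sd: float = 5.0
    noise_sbp: float = 3.0
    noise_dbp: float = 2.5
    feature_center: float = 0.45  # mean reflection ratio (amp_refl / amp_sys)
    feature_spread: float = 0.06
    t_sys_frac: float = 0.20
    t_refl_frac: float = 0.55
    width_sys: float = 0.05
    width_refl: float = 0.085
    baseline: float = 10.0
    quad_ri: float = 0.0  # optional nonlinearity in the reflection term

    def __post_init__(self) -> None:
        if self.dbp_base >= self.sbp_base:
            raise InvalidArgumentError("dbp_base must be below sbp_base")
        if self.noise_sbp < 0 or self.noise_dbp < 0:
            raise InvalidArgumentError("noise SDs must be non-negative")
        if not 40 <= self.hr_mean <= 120:
            raise InvalidArgumentError("hr_mean must lie in [40, 120] bpm")


@dataclass
class CohortConfig:
    """Study-design knobs for a simulated cohort."""

    n_subjects: int = 11
    sessions_min: int = 114
    sessions_max: int = 118
    sessions_per_day: int = 4
    fs: float = 125.0
    session_seconds: float = 30.0
    corrupt_beat_prob: float = 0.0
    circadian_amp: float = 3.0  # mmHg
    sensor_noise_sd: float = 0.02  # intensity units (pulse amplitude = 1)
    wander_amp: float = 0.10
    wander_freq: float = 0.25  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 50:
            raise InvalidArgumentError("fs must be at least 50 Hz")
        if self.session_seconds < 10:
            raise InvalidArgumentError("session_seconds must be at least 10")
        if not 0 <= self.corrupt_beat_prob < 1:
            raise InvalidArgumentError("corrupt_beat_prob must lie in [0, 1)")
        if self.sessions_min > self.sessions_max:
            raise InvalidArgumentError("sessions_min must not exceed sessions_max")


@dataclass
class PopulationParams:
    """Hyper-distributions from which per-subject parameters are drawn.

    Each ``(mean, sd)`` pair parameterizes a normal; hard physiological
    clips are applied after sampling. Defaults emulate a middle-aged,
    mostly normotensive office cohort.
    """

    sbp_base: tuple[float, float] = (120.0, 12.0)
    dbp_base: tuple[float, float] = (75.0, 8.0)
    beta_hr: tuple[float, float] = (0.6, 0.15)
    beta_ri: tuple[float, float] = (25.0, 6.0)
    beta_a: tuple[float, float] = (0.0, 0.0)
    drift_sbp: tuple[float, float] = (-0.30, 0.08)
    drift_dbp: tuple[float, float] = (-0.10, 0.04)
    hr_mean: tuple[float, float] = (70.0, 7.0)
    hr_sd: tuple[float, float] = (5.0, 1.0)
    noise_sbp: float = 3.0
    noise_dbp: float = 2.5
    feature_center: tuple[float, float] = (0.45, 0.08)
    feature_spread: float = 0.06
    t_sys_frac: tuple[float, float] = (0.20, 0.02)
    t_refl_frac: tuple[float, float] = (0.55, 0.03)
    width_sys: tuple[float, float] = (0.05, 0.006)
    width_refl: tuple[float, float] = (0.085, 0.008)
    baseline: tuple[float, float] = (10.0, 1.0)
    quad_ri: float = 0.0


@dataclass
class SubjectSessions:
    """All simulated sessions for one subject, time-ordered."""

    params: SubjectParams
    records: list[PPGRecord] = field(default_factory=list)

    @property
    def subject_id(self) -> str:
        return self.params.subject_id


def _gaussian(t: np.ndarray | float, center: float, width: float):
    return np.exp(-((t - center) ** 2) / (2.0 * width**2))


def synth_beat(params: BeatParams, fs: float) -> np.ndarray:
    """Render one beat of ``round(period * fs)`` samples.

    The waveform is ``baseline + amp_sys * G(t; t_sys, w_sys)
    + amp_refl * G(t; t_refl, w_refl)``. With ``amp_refl > 0`` the first
    derivative has a local maximum between the two bump centres — the
    downstroke inflection landmark used by the reflection-index feature.
    """
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    n = int(round(params.period * fs))
    if n < 2:
        raise InvalidArgumentError("period * fs too small to render a beat")
    t = np.arange(n) / fs
    wave = params.baseline + params.amp_sys * _gaussian(
        t, params.t_sys_frac * params.period, params.width_sys
    )
    if params.amp_refl > 0:
        wave = wave + params.amp_refl * _gaussian(
            t, params.t_refl_frac * params.period, params.width_refl
        )
    return wave


def _artifact_beat(n: int, baseline: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """A corrupted beat: symmetric triangular artifact plus wideband noise.

    The value distribution is symmetric about the midline, so the beat's
    skewness sits near zero — below the 0.1 quality threshold — while the
    waveform remains quasi-periodic enough for the segmenter to cut it.
    """
    phase = (np.arange(n) / n + 0.25) % 1.0
    tri = 2.0 * np.abs(2.0 * phase - 1.0) - 1.0  # in [-1, 1], symmetric
    return baseline + amp * tri + 0.05 * amp * rng.standard_normal(n)


def _circadian(hour: float, amp: float) -> float:
    return amp * math.sin(2.0 * math.pi * hour / 24.0 - CIRCADIAN_PHASE)


def synth_session(
    sp: SubjectParams,
    day: float,
    rng: np.random.Generator,
    cfg: CohortConfig,
    hour: float = 8.0,
) -> PPGRecord:
    """Simulate one 30 s measurement session on ``day`` (days since start).

    Draws the subject's latent state (heart rate, reflection ratio, small
    timing/amplitude jitter), maps it linearly to true BP, renders the
    beat train, adds sensor noise and baseline wander, and records the
    noise-contaminated BP as the cuff reference.
    """
    if rng is None:
        raise InvalidArgumentError("an explicit numpy Generator is required")

    hr = float(np.clip(rng.normal(sp.hr_mean, sp.hr_sd), 40.0, 140.0))
    refl = float(np.clip(rng.normal(sp.feature_center, sp.feature_spread), 0.05, 0.95))
    amp_factor = float(np.exp(rng.normal(0.0, 0.05)))

    x_hr = hr - sp.hr_mean
    x_r = refl - sp.feature_center
    shared = sp.beta_hr * x_hr + sp.beta_ri * x_r + sp.beta_a * (amp_factor - 1.0)
    if sp.quad_ri != 0.0:
        shared += sp.quad_ri * x_r**2
    circ = _circadian(hour, cfg.circadian_amp)
    sbp_true = sp.sbp_base + shared + sp.drift_sbp * day + circ
    dbp_true = sp.dbp_base + DBP_SHARE * (shared + circ) + sp.drift_dbp * day
    sbp_ref = sbp_true + rng.normal(0.0, sp.noise_sbp) if sp.noise_sbp > 0 else sbp_true
    dbp_ref = dbp_true + rng.normal(0.0, sp.noise_dbp) if sp.noise_dbp > 0 else dbp_true
    dbp_ref = min(dbp_ref, sbp_ref - 5.0)

    period = 60.0 / hr
    bp = BeatParams(
        amp_sys=amp_factor,
        amp_refl=refl * amp_factor,
        t_sys_frac=sp.t_sys_frac,
        t_refl_frac=sp.t_refl_frac,
        width_sys=sp.width_sys * period / 0.8,
        width_refl=sp.width_refl * period / 0.8,
        period=period,
        baseline=sp.baseline,
    )
    corrupt = rng.random() < cfg.corrupt_beat_prob if cfg.corrupt_beat_prob > 0 else False

    n_target = int(round(cfg.session_seconds * cfg.fs))
    beat_wave = synth_beat(bp, cfg.fs)
    n_beats = math.ceil(n_target / beat_wave.size) + 1
    if corrupt:
        pieces = [
            _artifact_beat(beat_wave.size, sp.baseline, amp_factor, rng)
            for _ in range(n_beats)
        ]
    else:
        pieces = [beat_wave] * n_beats
    signal = np.concatenate(pieces)[:n_target]

    t = np.arange(n_target) / cfg.fs
    if cfg.wander_amp > 0:
        wander_phase = rng.uniform(0.0, 2.0 * math.pi)
        signal = signal + cfg.wander_amp * np.sin(
            2.0 * math.pi * cfg.wander_freq * t + wander_phase
        )
    if cfg.sensor_noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.sensor_noise_sd, n_target)

    ts = COHORT_START + timedelta(days=float(day)) + timedelta(hours=hour - 8.0)
    return PPGRecord(
        samples=signal,
        fs=cfg.fs,
        subject_id=sp.subject_id,
        timestamp=ts,
        sbp_ref=float(sbp_ref),
        dbp_ref=float(dbp_ref),
        hr_bpm=hr,
    )


def draw_subject_params(
    subject_id: str, pop: PopulationParams, rng: np.random.Generator
) -> SubjectParams:
    """Draw one subject's generative parameters from the population."""

    def norm(pair: tuple[float, float]) -> float:
        mean, sd = pair
        return float(rng.normal(mean, sd)) if sd > 0 else float(mean)

    sbp_base = float(np.clip(norm(pop.sbp_base), 95.0, 165.0))
    dbp_base = float(np.clip(norm(pop.dbp_base), 55.0, min(105.0, sbp_base - 20.0)))
    hr_mean = float(np.clip(norm(pop.hr_mean), 50.0, 100.0))
    t_sys = float(np.clip(norm(pop.t_sys_frac), 0.12, 0.30))
    t_refl = float(np.clip(norm(pop.t_refl_frac), t_sys + 0.20, 0.75))
    return SubjectParams(
        subject_id=subject_id,
        sbp_base=sbp_base,
        dbp_base=dbp_base,
        beta_hr=norm(pop.beta_hr),
        beta_ri=norm(pop.beta_ri),
        beta_a=norm(pop.beta_a),
        drift_sbp=norm(pop.drift_sbp),
        drift_dbp=norm(pop.drift_dbp),
        hr_mean=hr_mean,
        hr_sd=float(max(2.0, norm(pop.hr_sd))),
        noise_sbp=pop.noise_sbp,
        noise_dbp=pop.noise_dbp,
        feature_center=float(np.clip(norm(pop.feature_center), 0.20, 0.75)),
        feature_spread=pop.feature_spread,
        t_sys_frac=t_sys,
        t_refl_frac=t_refl,
        width_sys=float(max(0.035, norm(pop.width_sys))),
        width_refl=float(max(0.060, norm(pop.width_refl))),
        baseline=float(max(5.0, norm(pop.baseline))),
        quad_ri=pop.quad_ri,
    )


def simulate_cohort(
    cfg: CohortConfig, population: PopulationParams | None = None
) -> list[SubjectSessions]:
    """Simulate a full cohort: subjects drawn i.i.d. from the population,
    each with ``sessions_min..sessions_max`` time-stamped sessions at four
    fixed daily slots, ordered by time within subject."""
    pop = population if population is not None else PopulationParams()
    rng = np.random.default_rng(cfg.seed)
    cohort: list[SubjectSessions] = []
    hours = SESSION_HOURS[: cfg.sessions_per_day]
    for i in range(cfg.n_subjects):
        sp = draw_subject_params(f"S{i + 1:02d}", pop, rng)
        n_sessions = int(rng.integers(cfg.sessions_min, cfg.sessions_max + 1))
        records = []
        for k in range(n_sessions):
            day = k // len(hours)
            hour = hours[k % len(hours)]
            records.append(synth_session(sp, float(day), rng, cfg, hour=hour))
        cohort.append(SubjectSessions(params=sp, records=records))
    return cohort


def noise_free_config(**overrides) -> CohortConfig:
    """A cohort configuration with every stochastic nuisance disabled;
    convenient for parameter-recovery and monotonicity checks."""
    base = dict(
        corrupt_beat_prob=0.0,
        circadian_amp=0.0,
        sensor_noise_sd=0.0,
        wander_amp=0.0,
    )
    base.update(overrides)
    return CohortConfig(**base)


# ---------------------------------------------------------------------------
# CSV output

SESSION_HEADER_KEYS = (
    "subject_id",
    "timestamp_iso",
    "fs_hz",
    "sbp_ref_mmhg",
    "dbp_ref_mmhg",
    "hr_bpm",
)


def write_session_csv(record: PPGRecord, path) -> None:
    """Write one session: six ``# key,value`` header lines then an
    ``amplitude`` column."""
    with open(path, "w") as fh:
        fh.write(f"# subject_id,{record.subject_id}\n")
        fh.write(f"# timestamp_iso,{record.timestamp.isoformat()}\n")
        fh.write(f"# fs_hz,{record.fs!r}\n")
        fh.write(f"# sbp_ref_mmhg,{record.sbp_ref!r}\n")
        fh.write(f"# dbp_ref_mmhg,{record.dbp_ref!r}\n")
        fh.write(f"# hr_bpm,{record.hr_bpm!r}\n")
        fh.write("amplitude\n")
        np.savetxt(fh, record.samples, fmt="%.10g")


def write_cohort(cohort: list[SubjectSessions], outdir) -> "Path":
    """Write each session as CSV plus a cohort manifest; returns the
    manifest path."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in cohort:
        for j, rec in enumerate(subj.records):
            fname = f"{rec.subject_id}_{j + 1:04d}.csv"
            write_session_csv(rec, outdir / fname)
            rows.append(
                (fname, rec.subject_id, rec.timestamp.isoformat(),
                 rec.sbp_ref, rec.dbp_ref, rec.hr_bpm)
            )
    manifest = outdir / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write("session_path,subject_id,timestamp,sbp,dbp,hr\n")
        for r in rows:
            fh.write(f"{r[0]},{r[1]},{r[2]},{r[3]!r},{r[4]!r},{r[5]!r}\n")
    return manifest
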