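"""Core record containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .errors import InvalidArgumentError


@dataclass
class PPGRecord:
    """One raw measurement session: a sampled PPG waveform plus the paired
    cuff reference readings taken alongside it.

    Attributes
    ----------
    samples : np.ndarray
        Raw light-intensity samples (arbitrary units, DC retained).
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Subject label.
    timestamp : datetime
        Session start time.
    sbp_ref, dbp_ref : float
        Reference systolic / diastolic blood pressure in mmHg.
    hr_bpm : float
        Heart-rate reading (device field) in beats per minute.
    """

    samples: np.ndarray
    fs: float
    subject_id: str
    timestamp: datetime
    sbp_ref: float
    dbp_ref: float
    hr_bpm: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")
        if self.sbp_ref <= self.dbp_ref:
            raise InvalidArgumentError(
                f"sbp_ref ({self.sbp_ref}) must exceed dbp_ref ({self.dbp_ref})"
            )


@dataclass
class Beat:
    """One segmented cardiac cycle, cut foot-to-foot from a session.

    ``samples`` come from the filtered, detrended signal; ``raw_samples``
    are the same index range cut from the unfiltered record so that
    DC-dependent features (PIR) can be computed on true intensities.
    """

    samples: np.ndarray
    raw_samples: np.ndarray
    fs: float
    start: int = 0  # index of the beat's first sample in the session
    skew: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.raw_samples = np.asarray(self.raw_samples, dtype=float)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return (self.n - 1) / self.fs
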