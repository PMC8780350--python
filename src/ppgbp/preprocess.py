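"""Raw-session preprocessing: low-pass filtering, detrending, beat
segmentation and skewness-based quality selection.

The chain per session is: 6th-order Butterworth low-pass (10 Hz cutoff)
applied forward and backward (zero phase), linear detrend over the whole
session, systolic-peak detection, foot-to-foot beat cutting, then the
single beat with the highest skewness is kept as the session's sample —
unless even that maximum falls below the 0.1 signal-quality threshold, in
which case the session is rejected.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .errors import (
    InvalidArgumentError,
    InvalidSamplingRateError,
    TooFewBeatsError,
    UndefinedSkewnessError,
)
from .records import Beat, PPGRecord

__all__ = [
    "FILTER_ORDER",
    "CUTOFF_HZ",
    "SQI_THRESHOLD",
    "lowpass_detrend",
    "segment_beats",
    "beat_skewness",
    "select_best_beat",
]

FILTER_ORDER = 6
CUTOFF_HZ = 10.0
SQI_THRESHOLD = 0.1

#: minimum inter-peak distance, as a fraction of the nominal cardiac period
MIN_PEAK_DISTANCE_FRAC = 0.4
#: prominence threshold as a multiple of the robust amplitude
PROMINENCE_FRAC = 0.3
DEFAULT_HR_HINT = 75.0


def lowpass_detrend(
    record: PPGRecord | np.ndarray, fs: float | None = None
) -> np.ndarray:
    """Zero-phase 6th-order Butterworth low-pass at 10 Hz, then linear
    detrend.

    Forward-backward application squares the magnitude response, so a
    sinusoid at frequency f comes out attenuated by
    ``1 / (1 + (f / 10)^12)`` in amplitude, with zero group delay.
    """
    if isinstance(record, PPGRecord):
        x, fs = record.samples, record.fs
    else:
        if fs is None:
            raise InvalidArgumentError("fs is required for a bare sample array")
        x = np.asarray(record, dtype=float)
    if fs <= 2.0 * CUTOFF_HZ:
        raise InvalidSamplingRateError(
            f"fs = {fs} Hz puts the {CUTOFF_HZ} Hz cutoff at/above Nyquist"
        )
    sos = sps.butter(FILTER_ORDER, CUTOFF_HZ, btype="low", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    return sps.detrend(filtered, type="linear")


def _robust_amplitude(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))) * 1.4826 * 2.0)


def segment_beats(
    filtered: np.ndarray,
    fs: float,
    hr_hint: float | None = None,
    raw: np.ndarray | None = None,
) -> list[Beat]:
    """Cut the filtered session into foot-to-foot beats.

    Systolic peaks are detected with a minimum spacing of 40% of the
    nominal cardiac period and a prominence of 30% of the robust signal
    amplitude (MAD-based, so absolute signal scale is irrelevant). Each
    beat's foot is the signal minimum shortly before a systolic upstroke;
    the partial material before the first foot and after the last foot is
    discarded. When ``raw`` is given, each beat also carries the same
    index range cut from the unfiltered record.
    """
    filtered = np.asarray(filtered, dtype=float)
    hr = DEFAULT_HR_HINT if hr_hint is None else float(hr_hint)
    if hr <= 0:
        raise InvalidArgumentError("hr_hint must be positive")
    distance = max(1, int(round(MIN_PEAK_DISTANCE_FRAC * (60.0 / hr) * fs)))
    prominence = PROMINENCE_FRAC * _robust_amplitude(filtered)
    peaks, _ = sps.find_peaks(filtered, distance=distance, prominence=prominence)
    if peaks.size < 3:
        raise TooFewBeatsError(
            f"only {peaks.size} systolic peaks detected; session unusable"
        )

    # One foot just before each systolic upstroke. Restricting the search
    # to the 45% of the cycle preceding the peak keeps the foot out of the
    # dip between the systolic and reflected waves.
    gap = float(np.median(np.diff(peaks)))
    reach = max(2, int(round(0.45 * gap)))
    feet: list[int] = []
    for b in peaks:
        lo = max(0, b - reach, (feet[-1] + 1) if feet else 0)
        feet.append(lo + int(np.argmin(filtered[lo : b + 1])))

    beats: list[Beat] = []
    min_len = int(0.25 * fs)
    for start, stop in zip(feet[:-1], feet[1:]):
        if stop - start + 1 < max(2, min_len):
            continue
        seg = filtered[start : stop + 1]
        raw_seg = raw[start : stop + 1] if raw is not None else seg
        beats.append(Beat(samples=seg, raw_samples=raw_seg, fs=fs, start=start))
    if len(beats) == 0:
        raise TooFewBeatsError("no complete foot-to-foot beat of plausible length")
    return beats


def beat_skewness(beat: Beat | np.ndarray) -> float:
    """Fisher–Pearson moment skewness g1 = m3 / m2^1.5 of the beat's
    (filtered) samples — the population form, so the 0.1 quality
    threshold is unambiguous."""
    x = beat.samples if isinstance(beat, Beat) else np.asarray(beat, dtype=float)
    d = x - x.mean()
    m2 = float(np.mean(d * d))
    if m2 == 0.0:
        raise UndefinedSkewnessError("zero-variance beat has undefined skewness")
    return float(np.mean(d * d * d)) / m2**1.5


def select_best_beat(beats: list[Beat]) -> tuple[Beat, float] | None:
    """Pick the beat with maximal skewness; reject the session (return
    ``None``) when even that maximum is below the 0.1 threshold.

    Ties at the maximum resolve to the earliest beat. Beats whose
    skewness is undefined (flat) are treated as minus infinity.
    """
    if not beats:
        raise InvalidArgumentError("select_best_beat requires a non-empty beat list")
    best_idx, best_skew = -1, -np.inf
    for i, b in enumerate(beats):
        try:
            s = beat_skewness(b)
        except UndefinedSkewnessError:
            continue
        b.skew = s
        if s > best_skew:
            best_idx, best_skew = i, s
    if best_idx < 0 or best_skew < SQI_THRESHOLD:
        return None
    return beats[best_idx], best_skew


def preprocess_record(record: PPGRecord, hr_hint: float | None = None) -> list[Beat]:
    """Convenience chain: filter + detrend the session and segment it,
    carrying the raw signal alongside for DC-dependent features."""
    filtered = lowpass_detrend(record)
    hint = record.hr_bpm if hr_hint is None else hr_hint
    return segment_beats(filtered, record.fs, hr_hint=hint, raw=record.samples)
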