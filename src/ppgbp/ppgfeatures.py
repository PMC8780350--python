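"""Notch-free PPG waveform features.

Five waveform features plus the device heart-rate reading form the
explanatory set. All of them are deliberately computable without locating
a dicrotic notch or diastolic peak, which deteriorate with age and
hypertension:

* **PIR** — peak-to-foot raw intensity ratio, a surrogate for
  arterial-diameter change (computed on the unfiltered signal; a ratio of
  intensities is meaningless on a zero-mean detrended trace);
* **DTR** — fraction of the beat duration after the systolic peak;
* **ri** — systolic-peak amplitude over the amplitude at the downstroke
  inflection point (the inflection survives even when the diastolic peak
  has vanished), both rebased to the beat minimum;
* **A02 / A25** — areas under the one-sided Fourier magnitude spectrum of
  the beat in the 0–2 Hz and 2–5 Hz bands;
* **HR** — the heart-rate reading recorded by the device during the
  session (a reading, not re-derived from the beat period).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import (
    InvalidArgumentError,
    NoInflectionError,
    PPGBPError,
    TooFewBeatsError,
    UndefinedFeatureError,
)
from .preprocess import lowpass_detrend, segment_beats, select_best_beat
from .records import Beat, PPGRecord

__all__ = [
    "FeatureVector",
    "FeatureSet",
    "FEATURE_SETS",
    "compute_pir",
    "compute_dtr",
    "locate_inflection",
    "compute_ri",
    "band_area",
    "extract_features",
    "Rejection",
]

#: margins of the inflection search window, as a fraction of beat length
INFLECTION_MARGIN = 0.1
#: width of the moving average applied to the first derivative
DERIV_SMOOTH = 5
#: zero-padding target for the beat spectrum, in multiples of fs
SPECTRUM_PAD_FACTOR = 8


@dataclass
class FeatureVector:
    """The six explanatory variables of one session's selected beat."""

    hr: float
    pir: float | None = None
    dtr: float | None = None
    ri: float | None = None
    a02: float | None = None
    a25: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "hr": self.hr, "pir": self.pir, "dtr": self.dtr,
            "ri": self.ri, "a02": self.a02, "a25": self.a25,
        }


class FeatureSet(str, Enum):
    """The three nameable feature combinations used in model comparison."""

    SET1 = "set1"
    SET2 = "set2"
    SET3 = "set3"

    @property
    def features(self) -> tuple[str, ...]:
        return FEATURE_SETS[self]


FEATURE_SETS: dict[FeatureSet, tuple[str, ...]] = {
    FeatureSet.SET1: ("hr", "a02", "a25", "ri"),
    FeatureSet.SET2: ("pir", "dtr", "hr", "a02", "a25", "ri"),
    FeatureSet.SET3: ("hr", "ri"),
}


@dataclass
class Rejection:
    """Marker for a session that contributes no sample."""

    reason: str


def _peak_index(beat: Beat) -> int:
    return int(np.argmax(beat.samples))


def compute_pir(beat: Beat, rebased: bool = False) -> float:
    """Peak-to-foot intensity ratio on the raw (DC-retaining) beat.

    With ``rebased=True`` both intensities are measured from the raw
    beat's minimum instead of absolute zero (alternative convention,
    off by default).
    """
    raw = beat.raw_samples
    if raw.size < 2:
        raise InvalidArgumentError("beat too short for PIR")
    k = int(np.argmax(raw))
    peak, foot = float(raw[k]), float(raw[0])
    if rebased:
        lo = float(np.min(raw))
        peak, foot = peak - lo, foot - lo
    if foot <= 0:
        raise UndefinedFeatureError("non-positive foot intensity; PIR undefined")
    return peak / foot


def compute_dtr(beat: Beat) -> float:
    """Diastole-time ratio: fraction of the beat spent after the systolic
    peak, ``(N - 1 - k) / (N - 1)`` for the peak at index k of N samples."""
    n = beat.n
    if n < 2:
        raise InvalidArgumentError("beat too short for DTR")
    k = _peak_index(beat)
    return (n - 1 - k) / (n - 1)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or x.size < width:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def locate_inflection(beat: Beat) -> int:
    """Index of the downstroke inflection point.

    Searches ``(k + 0.1 N, 0.9 N)`` after the systolic peak k for the
    largest interior local maximum of the smoothed first derivative (the
    reflected wave's upstroke shoulder). If none exists, falls back to
    the second-derivative zero crossing nearest the window midpoint.
    """
    x = beat.samples
    n = x.size
    k = _peak_index(beat)
    lo = int(np.ceil(k + INFLECTION_MARGIN * n))
    hi = int(np.floor(n - INFLECTION_MARGIN * n))
    if hi - lo < 3:
        raise NoInflectionError("search window too short")
    d1 = _smooth(np.gradient(x), DERIV_SMOOTH)
    win = d1[lo:hi]
    interior = np.arange(1, win.size - 1)
    is_locmax = (win[interior] >= win[interior - 1]) & (win[interior] > win[interior + 1])
    candidates = interior[is_locmax]
    if candidates.size:
        best = candidates[np.argmax(win[candidates])]
        return lo + int(best)
    d2 = np.gradient(d1)[lo:hi]
    sign_change = np.nonzero(np.diff(np.signbit(d2)))[0]
    if sign_change.size:
        mid = (win.size - 1) / 2.0
        best = sign_change[np.argmin(np.abs(sign_change - mid))]
        return lo + int(best)
    raise NoInflectionError("no derivative local maximum or curvature zero crossing")


def compute_ri(beat: Beat, inflection: int | None = None) -> float:
    """Reflection-index alternative: rebased systolic-peak amplitude over
    rebased inflection amplitude; ≥ 1 by construction."""
    x = beat.samples
    k = _peak_index(beat)
    j = locate_inflection(beat) if inflection is None else inflection
    base = float(np.min(x))
    denom = float(x[j]) - base
    if denom <= 0:
        raise UndefinedFeatureError("inflection amplitude equals beat minimum")
    return (float(x[k]) - base) / denom


def band_area(beat: Beat, f_lo: float, f_hi: float) -> float:
    """Area under the one-sided DFT magnitude spectrum over [f_lo, f_hi).

    The beat is zero-padded to ``8 * fs`` samples (0.125 Hz bins) and the
    magnitude is integrated by the trapezoidal rule over the band.
    """
    fs = beat.fs
    if f_hi <= f_lo or f_hi > fs / 2.0:
        raise InvalidArgumentError(f"invalid band [{f_lo}, {f_hi}) at fs = {fs}")
    n_fft = max(int(round(SPECTRUM_PAD_FACTOR * fs)), beat.n)
    spec = np.abs(np.fft.rfft(beat.samples, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    mask = (freqs >= f_lo) & (freqs < f_hi)
    if mask.sum() < 2:
        raise InvalidArgumentError("band too narrow for the spectral grid")
    return float(np.trapezoid(spec[mask], freqs[mask]))


def compute_feature_vector(
    record: PPGRecord, beat: Beat, pir_rebased: bool = False
) -> FeatureVector:
    """All six features for one selected beat (errors propagate)."""
    j = locate_inflection(beat)
    return FeatureVector(
        hr=float(record.hr_bpm),
        pir=compute_pir(beat, rebased=pir_rebased),
        dtr=compute_dtr(beat),
        ri=compute_ri(beat, inflection=j),
        a02=band_area(beat, 0.0, 2.0),
        a25=band_area(beat, 2.0, 5.0),
    )


def extract_features(
    record: PPGRecord,
    set_id: FeatureSet = FeatureSet.SET2,
    pir_rebased: bool = False,
) -> FeatureVector | Rejection:
    """Full per-session pipeline: filter/detrend, segment, select the
    best-quality beat, compute the requested feature subset.

    Returns a :class:`Rejection` with a reason code (``"sqi"``,
    ``"too_few_beats"``, ``"no_inflection"``, ...) instead of a partial
    vector when any stage fails.
    """
    try:
        filtered = lowpass_detrend(record)
        beats = segment_beats(
            filtered, record.fs, hr_hint=record.hr_bpm, raw=record.samples
        )
    except TooFewBeatsError as exc:
        return Rejection(reason=exc.reason)
    selected = select_best_beat(beats)
    if selected is None:
        return Rejection(reason="sqi")
    beat, _ = selected
    try:
        full = compute_feature_vector(record, beat, pir_rebased=pir_rebased)
    except PPGBPError as exc:
        return Rejection(reason=getattr(exc, "reason", "feature_error"))
    wanted = FEATURE_SETS[FeatureSet(set_id)]
    kwargs = {name: getattr(full, name) for name in wanted if name != "hr"}
    return FeatureVector(hr=full.hr, **kwargs)


def features_to_frame(cohort, set_id: FeatureSet = FeatureSet.SET2, pir_rebased=False):
    """Tidy feature table for a simulated cohort: one row per session with
    subject_id, timestamp, the six features, references and rejection
    bookkeeping."""
    import pandas as pd

    rows = []
    for subj in cohort:
        for rec in subj.records:
            out = extract_features(rec, set_id=FeatureSet.SET2, pir_rebased=pir_rebased)
            row = {
                "subject_id": rec.subject_id,
                "timestamp": rec.timestamp,
                "sbp_ref": rec.sbp_ref,
                "dbp_ref": rec.dbp_ref,
            }
            if isinstance(out, Rejection):
                row.update({k: np.nan for k in ("hr", "pir", "dtr", "ri", "a02", "a25")})
                row["rejected"] = True
                row["reject_reason"] = out.reason
            else:
                row.update(out.as_dict())
                row["rejected"] = False
                row["reject_reason"] = ""
            rows.append(row)
    return pd.DataFrame(rows)
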