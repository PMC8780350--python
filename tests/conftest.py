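"""Shared fixtures: analytically constructed beats and small simulated
cohorts (generated at test time; nothing is read from disk)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ppgbp.ppgfeatures import features_to_frame
from ppgbp.records import Beat
from ppgbp.synthcohort import (
    BeatParams,
    CohortConfig,
    PopulationParams,
    simulate_cohort,
    synth_beat,
)


def beat_from_params(params: BeatParams, fs: float = 125.0) -> Beat:
    """A Beat built straight from the rendered two-Gaussian waveform (one
    full cycle, foot at t = 0), bypassing segmentation."""
    wave = synth_beat(params, fs)
    return Beat(samples=wave - wave.mean(), raw_samples=wave, fs=fs)


def make_subject_frame(
    subject_id: str,
    n: int,
    rng: np.random.Generator,
    sbp_base: float = 120.0,
    dbp_base: float = 75.0,
    noise: float = 3.0,
) -> pd.DataFrame:
    """A synthetic feature table for one subject with a known linear
    feature-to-BP map — used to exercise the evaluation layer without
    rendering waveforms."""
    hr = rng.normal(70, 5, n)
    ri = rng.normal(2.0, 0.2, n)
    frame = pd.DataFrame(
        {
            "subject_id": subject_id,
            "timestamp": pd.date_range("2021-05-15", periods=n, freq="6h"),
            "hr": hr,
            "pir": rng.normal(1.1, 0.02, n),
            "dtr": rng.uniform(0.6, 0.8, n),
            "ri": ri,
            "a02": rng.normal(24, 2, n),
            "a25": rng.normal(25, 2, n),
            "rejected": False,
            "reject_reason": "",
        }
    )
    frame["sbp_ref"] = sbp_base + 0.6 * (hr - 70) + 8.0 * (ri - 2.0) + rng.normal(0, noise, n)
    frame["dbp_ref"] = dbp_base + 0.4 * (hr - 70) + 5.0 * (ri - 2.0) + rng.normal(0, noise, n)
    return frame


@pytest.fixture(scope="session")
def small_cohort_features() -> pd.DataFrame:
    """Feature table of a 5-subject, 40-session cohort rendered through
    the full waveform pipeline (shared across tests for speed)."""
    cfg = CohortConfig(seed=11, n_subjects=5, sessions_min=40, sessions_max=40)
    return features_to_frame(simulate_cohort(cfg))


@pytest.fixture(scope="session")
def recovery_cohort_features() -> pd.DataFrame:
    """Cohort under the parameter-recovery condition: linear feature-to-BP
    map, 3 mmHg reference noise, and a clean signal chain (no drift,
    circadian, wander, sensor noise or corruption)."""
    pop = PopulationParams(drift_sbp=(0.0, 0.0), drift_dbp=(0.0, 0.0))
    cfg = CohortConfig(
        seed=42, n_subjects=4, sessions_min=115, sessions_max=115,
        circadian_amp=0.0, sensor_noise_sd=0.0, wander_amp=0.0,
    )
    return features_to_frame(simulate_cohort(cfg, pop))
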