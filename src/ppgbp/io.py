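"""Session-CSV reading: the dialect written by the cohort generator, and
any single-channel CSV with the same header rows."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .records import PPGRecord
from .synthcohort import SESSION_HEADER_KEYS

__all__ = ["read_session_csv", "read_sessions", "SessionLoadReport"]


def read_session_csv(path) -> PPGRecord:
    """Parse one session file: ``# key,value`` header lines followed by a
    single ``amplitude`` column."""
    header: dict[str, str] = {}
    samples: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(",")
                header[key.strip()] = value.strip()
            elif line == "amplitude":
                continue
            else:
                samples.append(float(line))
    missing = [k for k in SESSION_HEADER_KEYS if k not in header]
    if missing:
        raise SchemaError(f"{path}: missing header column(s) {missing}")
    if not samples:
        raise SchemaError(f"{path}: no amplitude samples")
    return PPGRecord(
        samples=np.asarray(samples, dtype=float),
        fs=float(header["fs_hz"]),
        subject_id=header["subject_id"],
        timestamp=datetime.fromisoformat(header["timestamp_iso"]),
        sbp_ref=float(header["sbp_ref_mmhg"]),
        dbp_ref=float(header["dbp_ref_mmhg"]),
        hr_bpm=float(header["hr_bpm"]),
    )


@dataclass
class SessionLoadReport:
    """Loader outcome: records that parsed plus an error entry per file
    that did not (malformed inputs are reported, never silently dropped)."""

    records: list[PPGRecord] = field(default_factory=list)
    errors: list[tuple[str, str]] = field(default_factory=list)  # (path, message)
    warnings: list[str] = field(default_factory=list)


def read_sessions(manifest_path) -> SessionLoadReport:
    """Load every session listed in a cohort manifest, ordered by
    (subject, timestamp)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    try:
        manifest = pd.read_csv(manifest_path)
    except pd.errors.EmptyDataError:
        return SessionLoadReport(warnings=["empty manifest"])
    required = {"session_path", "subject_id"}
    missing = required - set(manifest.columns)
    if missing:
        raise SchemaError(f"manifest missing column(s) {sorted(missing)}")
    if manifest.empty:
        return SessionLoadReport(warnings=["empty manifest"])
    report = SessionLoadReport()
    for _, row in manifest.iterrows():
        path = base / str(row["session_path"])
        try:
            report.records.append(read_session_csv(path))
        except (OSError, ValueError, SchemaError) as exc:
            report.errors.append((str(path), str(exc)))
    report.records.sort(key=lambda r: (r.subject_id, r.timestamp))
    return report
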