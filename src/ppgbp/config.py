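"""Run configuration with lossless YAML round-trip.

Defaults mirror the study settings: 6th-order 10 Hz low-pass, 0.1
skewness quality threshold, two PLS components, RBF scale and noise
level initialized at 1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # paths
    input_dir: str = "runs/sessions"
    output_dir: str = "runs/out"
    # preprocessing
    fs: float = 125.0
    filter_order: int = 6
    cutoff_hz: float = 10.0
    sqi_threshold: float = 0.1
    # features
    pir_rebased: bool = False
    inflection_margin: float = 0.1
    # models
    n_components: int = 2
    phi: float = 1.0
    gpr_rbf_scale: float = 1.0
    gpr_noise_level: float = 1.0
    gpr_optimize: bool = True
    # experiment
    models: list[str] = field(default_factory=lambda: ["pls", "lwpls", "gpr"])
    feature_sets: list[str] = field(default_factory=lambda: ["set1", "set2", "set3"])
    schemes: list[str] = field(default_factory=lambda: ["scheme_1", "scheme_2"])
    strategies: list[str] = field(default_factory=lambda: ["individual", "generalized"])
    # cohort
    n_subjects: int = 11
    sessions_min: int = 114
    sessions_max: int = 118
    corrupt_beat_prob: float = 0.0
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def hash(self) -> str:
        """Stable short hash of the configuration, recorded in run manifests."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def write_run_manifest(path, cfg: RunConfig, seed: int, extra: dict | None = None) -> None:
    """JSON manifest recording seed, config hash and software versions."""
    import numpy, pandas, scipy, sklearn

    from . import __version__

    payload = {
        "seed": seed,
        "config_hash": cfg.hash(),
        "config": dataclasses.asdict(cfg),
        "versions": {
            "ppgbp": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    if extra:
        payload.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
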