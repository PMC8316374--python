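"""Pipeline configuration.

Every tunable of the analysis stages lives in one flat, typed configuration
object.  Defaults follow the quantification constants of the underlying
protocols wherever one exists — 10 s contact persistence, 2 consecutive
z-slices, five 2 µm shells with shells 3-5 as the periphery, a 30 nm EM
apposition cutoff, a 5 px PLA dot minimum, and 10-frame ER-association
windows at 2.4 s intervals — and are otherwise calibratable analysis
choices.  Config files are YAML key-value documents; unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["Config", "load_config"]


@dataclass
class Config:
    # acquisition metadata overrides (None = take from sidecar)
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None

    # detector
    min_amplitude: float | None = None  # None = 5x robust background sd
    expected_sigma_px: float = 1.3
    max_fit_residual: float | None = None

    # accumulation threshold
    threshold_method: str = "percentile"
    threshold_level: float = 99.0

    # linker
    max_disp_px: float = 5.0
    max_gap_frames: int = 2
    min_track_len: int = 20

    # MSS classification
    max_lag_fraction: float = 0.25
    min_r2: float = 0.8
    calibration_n_sim: int = 500
    min_overlap_fraction: float = 0.5

    # contact persistence
    min_duration_s: float = 10.0
    contact_max_gap_frames: int = 0
    min_consecutive_z: int = 2
    association_n_frames: int = 10
    association_frame_interval_s: float = 2.4

    # dispersal shells
    step_um: float = 2.0
    n_shells: int = 5
    shell_background_threshold: float = 0.0
    shell_measure: str = "intensity"

    # EM contacts
    cutoff_nm: float = 30.0
    resample_step_nm: float = 5.0
    section_thickness_nm: float = 50.0

    # PLA
    pla_threshold: float | None = None  # None = Otsu fallback
    min_size_px: int = 5

    # run control
    seed: int = 0
    output_dir: str = "results"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


_FIELDS = {f.name: f for f in dataclasses.fields(Config)}


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Load a YAML config merged over defaults.

    An empty (or absent) file yields pure defaults.  Unknown keys are
    rejected by name; values of the wrong type raise naming the key.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must be a mapping of key: value pairs")
        data.update(loaded)
    data.update(overrides)

    unknown = sorted(set(data) - set(_FIELDS))
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    for key, value in data.items():
        if value is None:
            continue
        f = _FIELDS[key]
        if f.type in ("int", int) and isinstance(value, bool):
            raise ValueError(f"config key {key!r} must be an integer, got {value!r}")
        if f.type in ("float", "float | None") and isinstance(value, (int, float)) and not isinstance(value, bool):
            data[key] = float(value)
        elif f.type in ("int",) and not isinstance(value, int):
            raise ValueError(f"config key {key!r} must be an integer, got {value!r}")
        elif f.type in ("str",) and not isinstance(value, str):
            raise ValueError(f"config key {key!r} must be a string, got {value!r}")
        elif f.type in ("float", "float | None") and not isinstance(value, (int, float)):
            raise ValueError(f"config key {key!r} must be a number, got {value!r}")
    return Config(**data)
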