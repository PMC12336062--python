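"""Pipeline configuration and built-in dataset profiles.

Two acquisition profiles ship with the package:

* ``nki-like`` — TR 1.4 s, 404 volumes, respiration-belt RV as the
  respiratory measure, physio at 62.5 Hz, lag grid -2..+15 TRs at TR steps,
  no tissue-level upsampling.
* ``hrver-like`` — TR 2.4 s, 175 volumes, PETCO2 as the respiratory measure,
  lag grid -1..+9 TRs (-2.4..21.6 s), tissue-level upsampling to 0.2 s.

Users may define further profiles in YAML; every numeric field is validated
before a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigurationError
from .xcorr import LagGrid

__all__ = ["PipelineConfig", "profile", "PROFILES"]


@dataclass
class PipelineConfig:
    tr_s: float = 1.4
    n_vols: int = 404
    physio_fs_hz: float = 62.5
    respiratory_measure: str = "rv"  # "rv" or "petco2"
    lag_lo_tr: int = -2
    lag_hi_tr: int = 15
    upsample_dt_s: Optional[float] = None
    drift_order: int = 4
    conv_dt_s: float = 0.5
    pve_denominator: str = "detrended"
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    co2_max_shift_s: float = 10.0
    profile_name: str = "custom"

    def validate(self) -> None:
        if self.tr_s <= 0 or self.n_vols <= 0 or self.physio_fs_hz <= 0:
            raise ConfigurationError("tr_s, n_vols and physio_fs_hz must be positive")
        if self.respiratory_measure not in ("rv", "petco2"):
            raise ConfigurationError("respiratory_measure must be 'rv' or 'petco2'")
        if self.n_perm < 100 or not (0 < self.alpha < 1):
            raise ConfigurationError("need n_perm >= 100 and alpha in (0, 1)")
        if self.lag_hi_tr <= self.lag_lo_tr:
            raise ConfigurationError("lag grid must be non-empty")

    def lag_grid(self) -> LagGrid:
        return LagGrid.from_trs(self.tr_s, self.lag_lo_tr, self.lag_hi_tr)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


PROFILES = {
    "nki-like": PipelineConfig(
        tr_s=1.4,
        n_vols=404,
        physio_fs_hz=62.5,
        respiratory_measure="rv",
        lag_lo_tr=-2,
        lag_hi_tr=15,
        upsample_dt_s=None,
        profile_name="nki-like",
    ),
    "hrver-like": PipelineConfig(
        tr_s=2.4,
        n_vols=175,
        physio_fs_hz=100.0,
        respiratory_measure="petco2",
        lag_lo_tr=-1,
        lag_hi_tr=9,
        upsample_dt_s=0.2,
        profile_name="hrver-like",
    ),
}


def profile(name: str, **overrides) -> PipelineConfig:
    """A copy of a built-in profile with optional field overrides."""
    if name not in PROFILES:
        raise ConfigurationError(f"unknown profile {name!r}; have {sorted(PROFILES)}")
    cfg = PipelineConfig(**{**asdict(PROFILES[name]), **overrides})
    cfg.validate()
    return cfg
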