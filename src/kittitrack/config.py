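"""Pipeline configuration: defaults, YAML loading and a stable hash.

Windows are (month, day) pairs resolved against a season starting year; the
non-breeding season runs Sep 1 – Apr 30, activity analyses Oct 1 – Mar 31,
and the early/late winter blocks are Oct–Dec and Jan–Mar.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


def _resolve(window: tuple, start_year: int) -> tuple[_dt.date, _dt.date]:
    # the season spans Sep-Apr: months Sep-Dec fall in the starting year,
    # Jan-Aug in the following year
    (m0, d0), (m1, d1) = window
    y0 = start_year if m0 >= 9 else start_year + 1
    y1 = start_year if m1 >= 9 else start_year + 1
    return _dt.date(y0, m0, d0), _dt.date(y1, m1, d1)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs besides the input files themselves."""

    tracks_path: str | None = None
    immersion_path: str | None = None
    nests_path: str | None = None

    start_year: int = 2016
    non_breeding_window: tuple = ((9, 1), (4, 30))
    activity_window: tuple = ((10, 1), (3, 31))
    early_winter_window: tuple = ((10, 1), (12, 31))
    late_winter_window: tuple = ((1, 1), (3, 31))

    ud_cell_size_km: float = 50.0
    ud_bandwidth_km: float | None = None  # None = reference bandwidth
    ud_levels: tuple = (0.5, 0.95)
    ud_n_boot: int = 100

    dispersal_n_boot: int = 1000
    james_n_boot: int = 1000
    seed: int = 0

    phase_half_width_min: float = 30.0
    phase_window_mode: str = "centered"
    completeness_tolerance: float = 1.0

    colony_positions: dict = field(
        default_factory=lambda: {"buldir": (52.35, 175.933), "st_george": (56.6, -169.55)}
    )

    def __post_init__(self):
        for name in ("non_breeding_window", "activity_window", "early_winter_window", "late_winter_window"):
            window = getattr(self, name)
            a, b = _resolve(window, self.start_year)
            if a >= b:
                raise ValueError(f"{name} is not well-ordered")
        for n_boot in (self.ud_n_boot, self.dispersal_n_boot, self.james_n_boot):
            if n_boot < 1:
                raise ValueError("bootstrap resample counts must be >= 1")
        if any(not (0 < lv <= 1) for lv in self.ud_levels):
            raise ValueError("UD levels must lie in (0, 1]")
        if not (0 < self.completeness_tolerance <= 1):
            raise ValueError("completeness tolerance must lie in (0, 1]")

    # resolved calendar windows -------------------------------------------
    def window(self, name: str) -> tuple[_dt.date, _dt.date]:
        return _resolve(getattr(self, f"{name}_window"), self.start_year)

    @property
    def season_year_late(self) -> int:
        return self.start_year + 1

    # serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def tup(v):
            return tuple(tup(x) for x in v) if isinstance(v, (list, tuple)) else v

        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: tup(v) if "window" in k or k == "ud_levels" else v for k, v in data.items()}
        if "colony_positions" in kwargs:
            kwargs["colony_positions"] = {
                k: tuple(v) for k, v in kwargs["colony_positions"].items()
            }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
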