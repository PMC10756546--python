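"""Pipeline configuration: tolerances, search bounds and calibration options.

All matching tolerances are engineering defaults (the vendor software used to
integrate the original peaks exposes none): MS1 5 ppm, MS2 10 ppm, RT 0.1 min.
The cross-polarity pairing window defaults to twice the MS1 tolerance, since
two measurements each within tolerance of the same neutral mass can disagree
by up to twice that amount.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

__all__ = ["Config"]


@dataclasses.dataclass
class Config:
    # matching tolerances
    ms1_ppm: float = 5.0
    ms2_ppm: float = 10.0
    rt_tol_min: float = 0.1
    pair_mass_ppm: float | None = None  # None -> 2 * ms1_ppm

    # sum-composition search grid
    c_total_range: tuple[int, int] = (20, 70)
    dbe_total_range: tuple[int, int] = (0, 16)
    # fatty acyl search space (covers the observed 12:0 .. 36:8 range)
    fa_carbon_range: tuple[int, int] = (12, 40)
    fa_dbe_range: tuple[int, int] = (0, 10)

    # confirmation policy
    require_acyl_pairs: bool = True  # False -> keep "sum-composition only" hits

    # calibration / quantification
    grubbs_alpha: float = 0.05
    min_calibration_levels: int = 5
    calibration_fit: str = "ols"  # or "weighted_1_over_x"

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ms1_ppm", "ms2_ppm", "rt_tol_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"tolerance {name} must be positive")
        if self.pair_mass_ppm is not None and self.pair_mass_ppm <= 0:
            raise ValueError("pair_mass_ppm must be positive when set")
        if not 0 < self.grubbs_alpha < 1:
            raise ValueError("grubbs_alpha must lie in (0, 1)")
        self.c_total_range = tuple(self.c_total_range)  # type: ignore[assignment]
        self.dbe_total_range = tuple(self.dbe_total_range)  # type: ignore[assignment]
        self.fa_carbon_range = tuple(self.fa_carbon_range)  # type: ignore[assignment]
        self.fa_dbe_range = tuple(self.fa_dbe_range)  # type: ignore[assignment]

    @property
    def effective_pair_mass_ppm(self) -> float:
        return self.pair_mass_ppm if self.pair_mass_ppm is not None else 2 * self.ms1_ppm

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("c_total_range", "dbe_total_range", "fa_carbon_range",
                    "fa_dbe_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError("unknown config key(s): " + ", ".join(sorted(unknown)))
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ValueError(f"malformed config file {path}")
        return cls.from_dict(data)
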