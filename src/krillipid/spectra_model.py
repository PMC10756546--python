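"""Data model and I/O for features, MS2 spectra, samples and calibrations.

The native interchange format is plain TSV: an MS1 feature table
(``feature_id, rt_min, mz, area``) with a sibling long-format MS2 table
(``feature_id, fragment_mz, intensity``).  This keeps every pipeline stage
testable from text fixtures; mzML ingestion can be layered on as an adapter
producing the same :class:`Feature` model.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    ADDUCTS,
    AdductSpec,
    Polarity,
    neutral_mass_from_mz,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Ms2Spectrum",
    "Feature",
    "Sample",
    "CalibrationLevel",
    "CalibrationSeries",
    "ORGANS",
    "MONTHS",
    "SEASON_OF_MONTH",
    "RT_SANITY_WINDOW",
    "ppm_error",
    "read_feature_table",
    "write_feature_table",
    "pair_features",
    "PairingResult",
]

ORGANS = ("stomach", "digestive_gland", "hind_gut", "tissue")
MONTHS = ("Jan", "Mar", "May")
#: Jan and Mar are Antarctic (late) summer samplings; May is autumn.
SEASON_OF_MONTH = {"Jan": "summer", "Mar": "summer", "May": "autumn"}

#: Observed retention-time window of intact phospholipids (min).  A sanity
#: warning only, never a hard filter.
RT_SANITY_WINDOW = (3.5, 9.0)


@dataclasses.dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"negative peak intensity: {self.intensity}")


@dataclasses.dataclass
class Ms2Spectrum:
    """Fragment peak list attached to an MS1 feature, sorted by m/z."""

    precursor_mz: float
    peaks: list[Peak]

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def match(self, mz: float, tol_ppm: float) -> Peak | None:
        """Most intense peak within *tol_ppm* of *mz*, or None."""
        window = mz * tol_ppm * 1e-6
        hits = [p for p in self.peaks if abs(p.mz - mz) <= window]
        if not hits:
            return None
        return max(hits, key=lambda p: (p.intensity, -abs(p.mz - mz)))


@dataclasses.dataclass
class Feature:
    """One integrated MS1 peak in one polarity, with optional MS2."""

    feature_id: str
    polarity: Polarity
    rt: float
    mz: float
    area: float
    ms2: Ms2Spectrum | None = None

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError(f"retention time must be positive, got {self.rt}")
        if self.mz <= 0:
            raise ValueError(f"feature m/z must be positive, got {self.mz}")
        if self.area < 0:
            raise ValueError(f"negative feature area: {self.area}")


@dataclasses.dataclass
class Sample:
    """All features of one krill sample (or process blank), both polarities."""

    sample_id: str
    organ: str
    month: str
    sex: str = "unknown"  # recorded but unused downstream
    features_pos: list[Feature] = dataclasses.field(default_factory=list)
    features_neg: list[Feature] = dataclasses.field(default_factory=list)
    is_blank: bool = False

    def __post_init__(self) -> None:
        if not self.is_blank:
            if self.organ not in ORGANS:
                raise ValueError(f"unknown organ {self.organ!r}; expected one of {ORGANS}")
            if self.month not in MONTHS:
                raise ValueError(f"unknown month {self.month!r}; expected one of {MONTHS}")

    @property
    def season(self) -> str:
        return SEASON_OF_MONTH.get(self.month, "unknown")


@dataclasses.dataclass
class CalibrationLevel:
    concentration: float  # ug/mL
    ratios: list[float]  # replicate area ratios to the internal standard


@dataclasses.dataclass
class CalibrationSeries:
    """Replicated calibration series for one authentic standard."""

    standard_id: str
    levels: list[CalibrationLevel]

    def __post_init__(self) -> None:
        for level in self.levels:
            if not (1e-7 - 1e-12 <= level.concentration <= 10 + 1e-9):
                raise ValueError(
                    f"calibration level {level.concentration} ug/mL outside "
                    f"the supported range [1e-7, 10]"
                )


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_MS1_COLUMNS = ("feature_id", "rt_min", "mz", "area")
_MS2_COLUMNS = ("feature_id", "fragment_mz", "intensity")


def _default_ms2_path(ms1_path: Path) -> Path:
    return ms1_path.with_suffix(".ms2" + ms1_path.suffix)


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_feature_table(path: str | Path, polarity: Polarity,
                       ms2_path: str | Path | None = None) -> list[Feature]:
    """Read an MS1 feature table (TSV/CSV) and attach MS2 peaks by feature id.

    The MS2 long table defaults to ``<stem>.ms2.<ext>`` next to *path* and is
    optional.  Rows with non-numeric m/z are rejected with a warning.
    """
    path = Path(path)
    ms1 = _read_table(path)
    if ms1.empty and ms1.columns.size == 0:
        logger.warning("empty feature table %s", path)
        return []
    missing = [c for c in _MS1_COLUMNS if c not in ms1.columns]
    if missing:
        raise ValueError(f"feature table {path} missing mandatory column(s): "
                         + ", ".join(missing))

    for col in ("rt_min", "mz", "area"):
        ms1[col] = pd.to_numeric(ms1[col], errors="coerce")
    bad = ms1["mz"].isna() | ms1["rt_min"].isna()
    if bad.any():
        logger.warning("rejecting %d row(s) with non-numeric mz/rt in %s",
                       int(bad.sum()), path)
        ms1 = ms1[~bad]

    ms2_by_id: dict[str, list[Peak]] = {}
    ms2_file = Path(ms2_path) if ms2_path is not None else _default_ms2_path(path)
    if ms2_file.exists():
        ms2 = _read_table(ms2_file)
        if not ms2.empty:
            missing = [c for c in _MS2_COLUMNS if c not in ms2.columns]
            if missing:
                raise ValueError(f"MS2 table {ms2_file} missing mandatory "
                                 f"column(s): " + ", ".join(missing))
            for row in ms2.itertuples(index=False):
                ms2_by_id.setdefault(str(row.feature_id), []).append(
                    Peak(float(row.fragment_mz), float(row.intensity)))

    features: list[Feature] = []
    for row in ms1.itertuples(index=False):
        fid = str(row.feature_id)
        peaks = ms2_by_id.get(fid)
        ms2_spec = Ms2Spectrum(float(row.mz), peaks) if peaks else None
        features.append(Feature(fid, polarity, float(row.rt_min),
                                float(row.mz), float(row.area), ms2_spec))
    outside = [f for f in features
               if not (RT_SANITY_WINDOW[0] <= f.rt <= RT_SANITY_WINDOW[1])]
    if outside:
        logger.warning("%d feature(s) in %s elute outside the expected "
                       "%.1f-%.1f min window", len(outside), path,
                       *RT_SANITY_WINDOW)
    return features


_FLOAT_FMT = "%.10g"  # preserves sub-ppm mass precision through round trips


def write_feature_table(features: Sequence[Feature], path: str | Path,
                        ms2_path: str | Path | None = None) -> None:
    """Write features (and their MS2 peaks) as the native TSV pair."""
    path = Path(path)
    ms1 = pd.DataFrame(
        [(f.feature_id, f.rt, f.mz, f.area) for f in features],
        columns=list(_MS1_COLUMNS),
    )
    ms1.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    rows = []
    for f in features:
        if f.ms2 is not None:
            rows.extend((f.feature_id, p.mz, p.intensity) for p in f.ms2.peaks)
    ms2 = pd.DataFrame(rows, columns=list(_MS2_COLUMNS))
    ms2_file = Path(ms2_path) if ms2_path is not None else _default_ms2_path(path)
    ms2.to_csv(ms2_file, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Cross-polarity feature pairing
# ---------------------------------------------------------------------------

_POSITIVE_ADDUCTS = (ADDUCTS["[M+H]+"], ADDUCTS["[M+NH4]+"])
_NEGATIVE_ADDUCTS = (ADDUCTS["[M-H]-"], ADDUCTS["[M+HCOO]-"])


@dataclasses.dataclass
class PairingResult:
    pairs: list[tuple[Feature, Feature]]
    unpaired_pos: list[Feature]
    unpaired_neg: list[Feature]


def _best_mass_agreement(pos_mz: float, neg_mz: float) -> float | None:
    """Smallest |ppm| disagreement of implied neutral masses over all
    plausible adduct combinations, or None if no combination is sane."""
    best: float | None = None
    for pa in _POSITIVE_ADDUCTS:
        np_mass = neutral_mass_from_mz(pos_mz, pa)
        for na in _NEGATIVE_ADDUCTS:
            nn_mass = neutral_mass_from_mz(neg_mz, na)
            if nn_mass <= 0 or np_mass <= 0:
                continue
            ppm = abs(1e6 * (np_mass - nn_mass) / (0.5 * (np_mass + nn_mass)))
            if best is None or ppm < best:
                best = ppm
    return best


def pair_features(pos: Sequence[Feature], neg: Sequence[Feature],
                  rt_tol: float = 0.1, mass_ppm: float = 10.0) -> PairingResult:
    """Greedily match ESI+ and ESI- features of the same neutral species.

    A candidate pair must co-elute (|dRT| <= *rt_tol* minutes) and the neutral
    masses implied after adduct removal must agree within *mass_ppm* for at
    least one plausible adduct combination.  Candidates are consumed in order
    of RT proximity, ties broken by smaller mass disagreement; each feature
    is used at most once.  Unpaired features are reported, not dropped.
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")
    candidates: list[tuple[float, float, str, str, int, int]] = []
    for i, fp in enumerate(pos):
        for j, fn in enumerate(neg):
            d_rt = abs(fp.rt - fn.rt)
            if d_rt > rt_tol:
                continue
            ppm = _best_mass_agreement(fp.mz, fn.mz)
            if ppm is None or ppm > mass_ppm:
                continue
            candidates.append((d_rt, ppm, fp.feature_id, fn.feature_id, i, j))
    candidates.sort(key=lambda c: (round(c[0], 9), round(c[1], 6), c[2], c[3]))

    used_pos: set[int] = set()
    used_neg: set[int] = set()
    pairs: list[tuple[Feature, Feature]] = []
    for _, _, _, _, i, j in candidates:
        if i in used_pos or j in used_neg:
            continue
        used_pos.add(i)
        used_neg.add(j)
        pairs.append((pos[i], neg[j]))
    unpaired_pos = [f for i, f in enumerate(pos) if i not in used_pos]
    unpaired_neg = [f for j, f in enumerate(neg) if j not in used_neg]
    return PairingResult(pairs, unpaired_pos, unpaired_neg)
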