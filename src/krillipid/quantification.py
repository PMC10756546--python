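"""Internal-standard calibration and quantification of annotated species.

Quantification is strictly relative to the spiked d70-PC internal standard:
each species' peak area is expressed as a ratio to the internal-standard
area, converted to a concentration against a class-matched authentic
standard (PC(16:0) for PCs; PE(16:0) for PE/PME/PDME; PG(16:0) for PG and
PI; PS(16:0) for PS), blank-corrected, and finally reduced to percentage
distributions — absolute tissue-mass normalisation is deliberately out of
scope.

Calibration replicates pass an iterative two-sided Grubbs outlier test
(alpha = 0.05) before averaging; for each sample ratio the five nearest
calibration levels are selected and inverted through a local least-squares
line.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem_core import HeadGroupClass
from .spectra_model import CalibrationSeries

logger = logging.getLogger(__name__)

__all__ = [
    "STANDARD_CLASS_MAP",
    "CalibrationModel",
    "SampleComposition",
    "QuantResult",
    "grubbs_filter",
    "grubbs_critical_value",
    "build_calibration",
    "select_levels",
    "quantify_species",
    "blank_subtract",
    "percentage_distribution",
    "ingest_ffa_table",
    "saturation_class",
]

H = HeadGroupClass
#: Fixed mapping of authentic standards to the classes they calibrate.
STANDARD_CLASS_MAP: dict[str, frozenset[HeadGroupClass]] = {
    "PC(16:0)": frozenset({H.PC}),
    "PE(16:0)": frozenset({H.PE, H.PME, H.PDME}),
    "PG(16:0)": frozenset({H.PG, H.PI}),
    "PS(16:0)": frozenset({H.PS}),
}


# ---------------------------------------------------------------------------
# Grubbs outlier elimination
# ---------------------------------------------------------------------------

def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value ((N-1)/sqrt(N))*sqrt(t^2/(N-2+t^2)),
    with t the upper alpha/(2N) quantile of Student's t with N-2 df."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))


def grubbs_filter(values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Iteratively remove the most extreme value while it fails the Grubbs
    test, one removal per pass, never reducing the set below three values.

    Sets with fewer than three values (or zero variance) are returned
    untouched, with a warning for the former.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        warnings.warn("Grubbs test needs >= 3 replicates; returning values "
                      "untouched", stacklevel=2)
        return vals
    while vals.size > 3:
        mean = vals.mean()
        sd = vals.std(ddof=1)
        if sd == 0:
            break
        deviations = np.abs(vals - mean)
        g = deviations.max() / sd
        if g <= grubbs_critical_value(vals.size, alpha):
            break
        vals = np.delete(vals, int(deviations.argmax()))
    return vals


# ---------------------------------------------------------------------------
# Calibration model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CalibrationModel:
    standard_id: str
    #: (concentration ug/mL, mean area ratio after outlier removal), sorted
    #: by concentration.
    levels: list[tuple[float, float]]
    applies_to: frozenset[HeadGroupClass]
    warnings: list[str] = dataclasses.field(default_factory=list)


def build_calibration(series: CalibrationSeries,
                      alpha: float = 0.05,
                      min_levels: int = 5) -> CalibrationModel:
    """Average replicate ratios per level after Grubbs filtering.

    The level means are expected to increase with concentration; violations
    are flagged as warnings but the model is still built.
    """
    if len(series.levels) < min_levels:
        raise ValueError(
            f"insufficient levels: calibration needs >= {min_levels}, "
            f"got {len(series.levels)}")
    if series.standard_id not in STANDARD_CLASS_MAP:
        raise ValueError(f"unknown calibration standard {series.standard_id!r}")
    levels = []
    for level in sorted(series.levels, key=lambda lv: lv.concentration):
        retained = grubbs_filter(level.ratios, alpha)
        levels.append((level.concentration, float(np.mean(retained))))
    model = CalibrationModel(series.standard_id, levels,
                             STANDARD_CLASS_MAP[series.standard_id])
    means = [m for _, m in levels]
    if any(b <= a for a, b in zip(means, means[1:])):
        msg = f"non-monotone calibration means for {series.standard_id}"
        model.warnings.append(msg)
        logger.warning(msg)
    return model


def select_levels(ratio: float, model: CalibrationModel,
                  n: int = 5) -> tuple[list[tuple[float, float]], bool]:
    """The *n* calibration levels nearest the sample ratio, preferring a
    bracketing window.

    Levels are ranked by |mean ratio - sample ratio| (ties toward the lower
    concentration).  When the ratio lies inside the calibrated range but the
    nearest-*n* window ends up one-sided (which happens on log-spaced
    levels), the farthest selected level is swapped for the nearest level on
    the missing side so that at least one level sits on each side.  Returns
    the selected (concentration, mean ratio) points sorted by concentration
    and an extrapolation flag set when the ratio falls outside the
    calibrated range.
    """
    if len(model.levels) < n:
        raise ValueError(f"model has fewer than {n} levels")
    ranked = sorted(model.levels, key=lambda lv: (abs(lv[1] - ratio), lv[0]))
    chosen = ranked[:n]
    rest = ranked[n:]
    means = [m for _, m in model.levels]
    extrapolated = not (min(means) <= ratio <= max(means))
    if not extrapolated:
        for side in (lambda m: m >= ratio, lambda m: m <= ratio):
            if not any(side(m) for _, m in chosen):
                swap_in = min((lv for lv in rest if side(lv[1])),
                              key=lambda lv: (abs(lv[1] - ratio), lv[0]))
                chosen.remove(max(chosen,
                                  key=lambda lv: (abs(lv[1] - ratio), -lv[0])))
                chosen.append(swap_in)
    else:
        logger.warning("area ratio %.4g outside calibrated range of %s",
                       ratio, model.standard_id)
    return sorted(chosen, key=lambda lv: lv[0]), extrapolated


@dataclasses.dataclass
class QuantResult:
    concentration: float  # ug/mL
    flags: set[str]


def quantify_species(area: float, is_area: float,
                     model: CalibrationModel,
                     fit: str = "ols") -> QuantResult:
    """Concentration of one species from its area ratio to the internal
    standard, via a least-squares line through the five selected levels.

    ``fit="weighted_1_over_x"`` weights the local fit by 1/concentration.
    Negative predictions are floored at zero and flagged.
    """
    if is_area <= 0:
        raise ValueError("internal standard missing (non-positive IS area)")
    if area < 0:
        raise ValueError(f"negative area: {area}")
    if area == 0:
        return QuantResult(0.0, {"below_floor"})
    ratio = area / is_area
    points, extrapolated = select_levels(ratio, model)
    concs = np.array([c for c, _ in points])
    means = np.array([m for _, m in points])
    weights = 1.0 / concs if fit == "weighted_1_over_x" else None
    slope, intercept = np.polyfit(concs, means, 1, w=weights)
    if slope == 0:
        raise ValueError("degenerate calibration fit (zero slope)")
    conc = (ratio - intercept) / slope
    flags: set[str] = set()
    if extrapolated:
        flags.add("extrapolated")
    if conc < 0:
        conc = 0.0
        flags.add("floored")
    return QuantResult(float(conc), flags)


# ---------------------------------------------------------------------------
# Blank subtraction and percentage distributions
# ---------------------------------------------------------------------------

def blank_subtract(sample: pd.Series,
                   blanks: Sequence[pd.Series]) -> tuple[pd.Series, list[str]]:
    """Subtract the mean process-blank concentration per species.

    Corrected concentrations are floored at zero; species whose entire signal
    is explained by the blank are dropped.  With no blanks the table is
    returned unchanged with a warning.
    """
    if not blanks:
        warnings.warn("no process blanks provided; concentrations returned "
                      "uncorrected", stacklevel=2)
        return sample.copy(), []
    blank_mean = pd.concat(blanks, axis=1).fillna(0.0).mean(axis=1)
    corrected = sample.subtract(blank_mean.reindex(sample.index, fill_value=0.0))
    blanked = corrected.index[(corrected <= 0)
                              & (blank_mean.reindex(sample.index,
                                                    fill_value=0.0) > 0)]
    corrected = corrected.clip(lower=0.0).drop(index=blanked)
    return corrected, list(blanked)


@dataclasses.dataclass
class SampleComposition:
    """Per-sample percentage distribution over species; sums to 100."""

    sample_id: str
    organ: str
    month: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        if self.entries:
            total = sum(self.entries.values())
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"percentages sum to {total}, expected 100")


def percentage_distribution(concentrations: pd.Series | Mapping[str, float],
                            sample_id: str = "", organ: str = "",
                            month: str = "") -> SampleComposition:
    """Normalise species concentrations to percentages of their sum."""
    series = pd.Series(dict(concentrations), dtype=float)
    series = series[series > 0]
    total = series.sum()
    if series.empty or total <= 0:
        raise ValueError("empty composition: no species with positive "
                         "concentration")
    pct = series / total * 100.0
    # exact renormalisation so compositions close to machine precision
    pct = pct * (100.0 / pct.sum())
    return SampleComposition(sample_id, organ, month, pct.to_dict())


# ---------------------------------------------------------------------------
# GC-MS free fatty acid ingestion
# ---------------------------------------------------------------------------

def saturation_class(n_dbe: int) -> str:
    """SFA (0 DBE), MUFA (1 DBE) or PUFA (>= 2 DBE)."""
    if n_dbe == 0:
        return "SFA"
    if n_dbe == 1:
        return "MUFA"
    return "PUFA"


def ingest_ffa_table(table: pd.DataFrame,
                     response_factors: Mapping[str, float] | None = None,
                     ) -> dict[str, float]:
    """SFA/MUFA/PUFA percentages of the total lipid extract from a GC-MS
    free-fatty-acid table.

    *table* needs columns ``fa`` (``C:D`` tokens), ``area`` and ``is_area``
    (the deuterated-18:0 internal-standard area used to correct for
    extraction and measurement variability).  Response factors are per
    saturation class, following class-based calibration with one saturated,
    one monounsaturated and one polyunsaturated reference acid.
    """
    rf = {"SFA": 1.0, "MUFA": 1.0, "PUFA": 1.0}
    rf.update(response_factors or {})
    missing = [c for c in ("fa", "area", "is_area") if c not in table.columns]
    if missing:
        raise ValueError("FFA table missing column(s): " + ", ".join(missing))
    totals = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0}
    for row in table.itertuples(index=False):
        token = str(row.fa)
        try:
            carbons, dbe = token.split(":")
            n_dbe = int(dbe)
            int(carbons)
        except ValueError:
            raise ValueError(f"unknown fatty acid token {token!r}") from None
        if float(row.is_area) <= 0:
            raise ValueError("internal standard missing (non-positive IS area)")
        cls = saturation_class(n_dbe)
        totals[cls] += (float(row.area) / float(row.is_area)) / rf[cls]
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("empty composition: all FFA areas are zero")
    return {cls: 100.0 * v / grand for cls, v in totals.items()}
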