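"""Compositional statistics on per-sample species percentage distributions.

Covers molecular-weight / degree-of-unsaturation grouping (with per-class
tertile breakpoints by default and an injection point for explicit
boundaries), the PCA input matrix and scores, seasonal abundance ratios,
SFA/MUFA/PUFA ternary compositions extrapolated from resolved acyl pairs,
per-class unsaturation and EPA/DHA indices, and overlap against an external
reference lipidome table.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .annotation import AnnotatedIPL
from .chem_core import (
    FattyAcyl,
    HeadGroupClass,
    SumComposition,
    composition_mass,
    species_formula,
)
from .quantification import SampleComposition, saturation_class

logger = logging.getLogger(__name__)

__all__ = [
    "GroupingScheme",
    "SeasonalRatio",
    "compositions_to_matrix",
    "derive_grouping",
    "group_matrix",
    "pca_scores",
    "seasonal_ratios",
    "fa_saturation_ternary",
    "pufa_indices",
    "reference_overlap",
]

_MW_LABELS = ("LMW", "MMW", "HMW")
_DU_LABELS = ("LDU", "MDU", "HDU")

EPA = FattyAcyl(20, 5)
DHA = FattyAcyl(22, 6)


def compositions_to_matrix(compositions: Sequence[SampleComposition]
                           ) -> pd.DataFrame:
    """Samples x species percentage matrix (absent species filled with 0)."""
    if not compositions:
        raise ValueError("no sample compositions supplied")
    data = {c.sample_id: c.entries for c in compositions}
    matrix = pd.DataFrame(data).T.fillna(0.0)
    return matrix.reindex(sorted(matrix.columns), axis=1)


@dataclasses.dataclass
class GroupingScheme:
    """Per-class molecular-weight and unsaturation breakpoints.

    A species of neutral mass ``m`` with summed DBE ``d`` maps to LMW/MMW/HMW
    by where ``m`` falls relative to the two mass breakpoints (<= lower, in
    between, > upper), and likewise LDU/MDU/HDU for ``d``.  A class with
    empty breakpoints collapses to a single group.
    """

    mw_breaks: dict[HeadGroupClass, tuple[float, ...]]
    du_breaks: dict[HeadGroupClass, tuple[float, ...]]

    def __post_init__(self) -> None:
        for table in (self.mw_breaks, self.du_breaks):
            for cls, breaks in table.items():
                if any(b >= c for b, c in zip(breaks, breaks[1:])):
                    raise ValueError(
                        f"breakpoints for {cls.value} must strictly increase: "
                        f"{breaks}")

    @staticmethod
    def _bin(value: float, breaks: tuple[float, ...],
             labels: tuple[str, ...]) -> str:
        if not breaks:
            return labels[1]  # single-group class: use the middle label
        idx = int(np.searchsorted(np.asarray(breaks), value, side="left"))
        return labels[min(idx, len(labels) - 1)]

    def group_of(self, sc: SumComposition) -> str:
        if sc.cls not in self.mw_breaks:
            raise ValueError(f"grouping scheme does not cover class {sc.cls.value}")
        mass = composition_mass(species_formula(sc))
        mw = self._bin(mass, self.mw_breaks[sc.cls], _MW_LABELS)
        du = self._bin(sc.dbe_total, self.du_breaks[sc.cls], _DU_LABELS)
        return f"{sc.cls.value}-{mw}-{du}"


def derive_grouping(compositions: Sequence[SampleComposition],
                    explicit_mw: Mapping[HeadGroupClass, Sequence[float]] | None = None,
                    explicit_du: Mapping[HeadGroupClass, Sequence[float]] | None = None,
                    ) -> GroupingScheme:
    """Tertile breakpoints of neutral mass and total DBE within each class.

    Classification is conducted individually for each head group, so the
    boundaries differ between classes.  Explicit breakpoints (e.g. taken from
    a published supplement) override the tertiles per class.  Classes with
    fewer than three distinct values collapse to a single group.
    """
    species = sorted({name for c in compositions for name in c.entries})
    if not species:
        raise ValueError("no species in compositions")
    by_class: dict[HeadGroupClass, list[SumComposition]] = {}
    for name in species:
        sc = SumComposition.parse(name)
        by_class.setdefault(sc.cls, []).append(sc)

    mw_breaks: dict[HeadGroupClass, tuple[float, ...]] = {}
    du_breaks: dict[HeadGroupClass, tuple[float, ...]] = {}
    for cls, members in by_class.items():
        masses = np.unique([composition_mass(species_formula(sc))
                            for sc in members])
        dbes = np.unique([sc.dbe_total for sc in members])
        if explicit_mw is not None and cls in explicit_mw:
            mw_breaks[cls] = tuple(explicit_mw[cls])
        elif masses.size >= 3:
            mw_breaks[cls] = tuple(np.quantile(masses, [1 / 3, 2 / 3]))
        else:
            logger.warning("class %s has < 3 distinct masses; single MW group",
                           cls.value)
            mw_breaks[cls] = ()
        if explicit_du is not None and cls in explicit_du:
            du_breaks[cls] = tuple(explicit_du[cls])
        elif dbes.size >= 3:
            du_breaks[cls] = tuple(np.quantile(dbes.astype(float), [1 / 3, 2 / 3]))
        else:
            du_breaks[cls] = ()
    return GroupingScheme(mw_breaks, du_breaks)


def group_matrix(compositions: Sequence[SampleComposition],
                 scheme: GroupingScheme) -> pd.DataFrame:
    """Samples x (class, MW, DU) group percentage matrix; rows sum to 100."""
    matrix = compositions_to_matrix(compositions)
    try:
        groups = {name: scheme.group_of(SumComposition.parse(name))
                  for name in matrix.columns}
    except ValueError as exc:
        raise ValueError(f"unmapped species in composition matrix: {exc}") from exc
    grouped = matrix.T.groupby(matrix.columns.map(groups)).sum().T
    return grouped.reindex(sorted(grouped.columns), axis=1)


def pca_scores(matrix: pd.DataFrame, n_components: int = 2,
               scale: bool = False) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Column-centred PCA of a percentage matrix.

    Returns (scores, loadings, explained variance ratio).  With
    ``scale=True`` columns are additionally divided by their standard
    deviation (correlation PCA).
    """
    if matrix.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    values = matrix.to_numpy(dtype=float)
    centred = values - values.mean(axis=0)
    if not np.any(centred):
        raise ValueError("constant matrix: no variance to decompose")
    if scale:
        sd = values.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        centred = centred / sd
    n_components = min(n_components, min(centred.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(centred)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return (pd.DataFrame(scores, index=matrix.index, columns=comp_names),
            pd.DataFrame(pca.components_.T, index=matrix.columns,
                         columns=comp_names),
            pca.explained_variance_ratio_)


@dataclasses.dataclass
class SeasonalRatio:
    species: str
    ratio: float  # mean %(group A) / mean %(group B); NaN when one-sided
    log10_ratio: float
    mean_pct_a: float
    mean_pct_b: float  # colour-scale value in the ratio bar plots
    one_sided: str  # "", "a_only" or "b_only"


def seasonal_ratios(compositions: Sequence[SampleComposition],
                    months_a: Iterable[str], months_b: Iterable[str],
                    cls: HeadGroupClass = HeadGroupClass.PC,
                    ) -> list[SeasonalRatio]:
    """Per-species mean-percentage ratio between two month groups.

    The sign convention is "up = more abundant in group A"; with A the autumn
    month(s) and B the summer months this reproduces the seasonal comparison
    layout, with the B-side mean percentage supplied for the colour scale.
    Species absent from one side are flagged one-sided rather than imputed.
    """
    set_a, set_b = set(months_a), set(months_b)
    in_a = [c for c in compositions if c.month in set_a]
    in_b = [c for c in compositions if c.month in set_b]
    if not in_a or not in_b:
        raise ValueError("both month groups must be non-empty")
    species = sorted({name for c in compositions for name in c.entries
                      if SumComposition.parse(name).cls is cls})
    out = []
    for name in species:
        mean_a = float(np.mean([c.entries.get(name, 0.0) for c in in_a]))
        mean_b = float(np.mean([c.entries.get(name, 0.0) for c in in_b]))
        if mean_a > 0 and mean_b > 0:
            ratio = mean_a / mean_b
            out.append(SeasonalRatio(name, ratio, float(np.log10(ratio)),
                                     mean_a, mean_b, ""))
        else:
            side = "a_only" if mean_a > 0 else "b_only"
            out.append(SeasonalRatio(name, float("nan"), float("nan"),
                                     mean_a, mean_b, side))
    return out


# ---------------------------------------------------------------------------
# Fatty-acid level statistics from resolved acyl pairs
# ---------------------------------------------------------------------------

def _pair_weights(ann: AnnotatedIPL) -> list[float]:
    """Relative abundance apportionment over a species' acyl pairs, by the
    intensity of each pair's more abundant acyl fragment."""
    weights = [max(p.intensity_a, p.intensity_b) for p in ann.pairs]
    total = sum(weights)
    if total <= 0:
        return [1.0 / len(weights)] * len(weights)
    return [w / total for w in weights]


def fa_saturation_ternary(compositions: Sequence[SampleComposition],
                          annotations: Mapping[str, Sequence[AnnotatedIPL]],
                          cls: HeadGroupClass,
                          ) -> tuple[pd.DataFrame, int]:
    """Per-sample (SFA%, MUFA%, PUFA%) extrapolated from intact species.

    Each species contributes its percentage split equally over its two acyl
    positions; species with several consistent pairs are split across pairs
    by the stated intensity apportionment.  Species without resolved pairs
    are excluded; their count is returned alongside the table.
    """
    pair_lookup = {sid: {a.species: a for a in anns}
                   for sid, anns in annotations.items()}
    rows = {}
    excluded = 0
    for comp in compositions:
        bins = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0}
        lookup = pair_lookup.get(comp.sample_id, {})
        for name, pct in comp.entries.items():
            sc = SumComposition.parse(name)
            if sc.cls is not cls:
                continue
            ann = lookup.get(name)
            if ann is None or not ann.pairs:
                excluded += 1
                continue
            for pair, w in zip(ann.pairs, _pair_weights(ann)):
                for fa in (pair.fa_a, pair.fa_b):
                    bins[saturation_class(fa.n_dbe)] += pct * w * 0.5
        total = sum(bins.values())
        if total > 0:
            rows[comp.sample_id] = {k: 100.0 * v / total for k, v in bins.items()}
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["SFA", "MUFA", "PUFA"])
    return table, excluded


def pufa_indices(compositions: Sequence[SampleComposition],
                 annotations: Mapping[str, Sequence[AnnotatedIPL]],
                 cls: HeadGroupClass) -> pd.DataFrame:
    """Per-sample unsaturation and EPA/DHA indices for one class.

    ``mean_unsaturation`` is the abundance-weighted mean DBE per fatty acid,
    i.e. sum(pct_i * dbe_total_i / 2) / sum(pct_i) over the class' species.
    ``epa_pct`` / ``dha_pct`` are the summed class percentages of species
    carrying at least one 20:5 / 22:6 acyl, with multi-pair species counted
    by the apportioned fraction of pairs containing the acyl.
    """
    if cls not in (HeadGroupClass.PC, HeadGroupClass.PE):
        raise ValueError("PUFA indices are defined for PC and PE")
    pair_lookup = {sid: {a.species: a for a in anns}
                   for sid, anns in annotations.items()}
    rows = {}
    for comp in compositions:
        cls_entries = {name: pct for name, pct in comp.entries.items()
                       if SumComposition.parse(name).cls is cls}
        if not cls_entries:
            continue
        total_pct = sum(cls_entries.values())
        mean_unsat = sum(pct * SumComposition.parse(name).dbe_total / 2
                         for name, pct in cls_entries.items()) / total_pct
        lookup = pair_lookup.get(comp.sample_id, {})
        epa = dha = paired_total = 0.0
        for name, pct in cls_entries.items():
            ann = lookup.get(name)
            if ann is None or not ann.pairs:
                continue
            paired_total += pct
            for pair, w in zip(ann.pairs, _pair_weights(ann)):
                acyls = (pair.fa_a, pair.fa_b)
                if EPA in acyls:
                    epa += pct * w
                if DHA in acyls:
                    dha += pct * w
        rows[comp.sample_id] = {
            "mean_unsaturation": mean_unsat,
            "epa_pct": 100.0 * epa / paired_total if paired_total else float("nan"),
            "dha_pct": 100.0 * dha / paired_total if paired_total else float("nan"),
        }
    if not rows:
        raise ValueError(f"no {cls.value} species in any composition")
    return pd.DataFrame.from_dict(rows, orient="index")


def reference_overlap(own: pd.DataFrame, reference: pd.DataFrame
                      ) -> pd.DataFrame:
    """Per-class sum-formula overlap and abundance coverage of two lipidomes.

    Both tables need columns ``species`` (e.g. ``"PC(38:6)"``) and ``pct``
    (study-level percentage abundance).  For each class present in either
    table: formula counts on each side, intersection count, and the summed
    percentage of intersecting formulas on each side.
    """
    if reference.empty:
        raise ValueError("empty reference table")
    def by_class(table: pd.DataFrame) -> dict[HeadGroupClass, dict[str, float]]:
        out: dict[HeadGroupClass, dict[str, float]] = {}
        for row in table.itertuples(index=False):
            sc = SumComposition.parse(str(row.species))
            out.setdefault(sc.cls, {})[sc.name] = float(row.pct)
        return out
    own_map, ref_map = by_class(own), by_class(reference)
    rows = []
    for cls in sorted(set(own_map) | set(ref_map), key=lambda c: c.value):
        o = own_map.get(cls, {})
        r = ref_map.get(cls, {})
        shared = set(o) & set(r)
        rows.append({
            "cls": cls.value,
            "n_own": len(o),
            "n_reference": len(r),
            "n_overlap": len(shared),
            "pct_overlap_own": sum(o[s] for s in shared),
            "pct_overlap_reference": sum(r[s] for s in shared),
        })
    return pd.DataFrame(rows).set_index("cls")
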