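"""Identification of intact phospholipids from paired dual-polarity features.

The confirmation chain mirrors how diagnostic fragmentation is read in
dual-polarity HILIC MS/MS lipidomics:

1. the positive-mode MS2 spectrum assigns the head-group class (PC by its
   phosphocholine fragment ion, the other classes by their head-group neutral
   loss);
2. the accurate positive-mode precursor mass fixes the sum composition
   (total acyl carbons : total DBE) by exhaustive grid search;
3. the co-eluting negative-mode precursor must match the expected counter-ion
   of the same neutral species;
4. classes with a negative-mode diagnostic (PC, PI, PS) must also show it;
5. the negative-mode MS2 acyl carboxylate anions must resolve at least one
   acyl pair summing to the inferred composition.  The more intense acyl
   fragment is assigned sn-2.

A species failing any stage is rejected with a machine-readable reason;
rejections are data, not errors.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np
import pandas as pd

from .chem_core import (
    FattyAcyl,
    HeadGroupClass,
    IonRule,
    Polarity,
    SumComposition,
    acyl_anion_mz,
    build_rule_table,
    precursor_mz,
)
from .config import Config
from .spectra_model import Feature, Ms2Spectrum, Sample, pair_features, ppm_error

__all__ = [
    "AcylPairCandidate",
    "AnnotatedIPL",
    "Rejection",
    "identify_class",
    "infer_sum_composition",
    "enumerate_acyl_pairs",
    "confirm_species",
    "annotate_run",
    "annotation_table",
]


@dataclasses.dataclass(frozen=True)
class AcylPairCandidate:
    """An unordered acyl pair {a, b} consistent with a sum composition.

    ``fa_a <= fa_b`` by (carbons, DBE); ``sn2`` names the member whose
    carboxylate anion is more intense, read as occupying the sn-2 position.
    """

    fa_a: FattyAcyl
    fa_b: FattyAcyl
    intensity_a: float
    intensity_b: float
    sn2: str  # "a" or "b"

    @property
    def sn2_acyl(self) -> FattyAcyl:
        return self.fa_a if self.sn2 == "a" else self.fa_b

    @property
    def sn1_acyl(self) -> FattyAcyl:
        return self.fa_b if self.sn2 == "a" else self.fa_a

    @property
    def sn2_intensity(self) -> float:
        return self.intensity_a if self.sn2 == "a" else self.intensity_b

    @property
    def name(self) -> str:
        """Pair label with the more intense (sn-2) acyl listed first."""
        return f"{self.sn2_acyl.name}/{self.sn1_acyl.name}"


@dataclasses.dataclass
class Evidence:
    cls: HeadGroupClass
    matched_rules: list[str]
    ppm_ms1_pos: float
    ppm_ms1_neg: float
    ms2_ppm: dict[str, float]


@dataclasses.dataclass
class AnnotatedIPL:
    """A cross-polarity-confirmed species with its resolved acyl pairs."""

    sum_comp: SumComposition
    pairs: list[AcylPairCandidate]
    evidence: Evidence
    rt: float
    area_pos: float
    pos_id: str = ""
    neg_id: str = ""

    @property
    def species(self) -> str:
        return self.sum_comp.name


@dataclasses.dataclass(frozen=True)
class Rejection:
    pos_id: str
    neg_id: str
    stage: str
    reason: str


# ---------------------------------------------------------------------------
# Stage 1: head-group class from positive-mode MS2
# ---------------------------------------------------------------------------

def identify_class(feature: Feature, rules: tuple[IonRule, ...] | None = None,
                   tol_ppm: float = 10.0) -> list[HeadGroupClass]:
    """Candidate head-group classes for a positive-mode feature.

    PC matches on its characteristic phosphocholine fragment ion; the other
    classes match a fragment at (precursor - head-group neutral loss).
    Candidates are ranked by matched-fragment intensity.
    """
    if feature.ms2 is None or not feature.ms2.peaks:
        return []
    rules = rules or build_rule_table()
    hits: list[tuple[float, HeadGroupClass]] = []
    for rule in rules:
        if rule.mode != "positive":
            continue
        if rule.rule_kind == "fragment_ion":
            target = rule.mass
        else:
            target = feature.mz - rule.mass
            if target <= 0:
                continue
        peak = feature.ms2.match(target, tol_ppm)
        if peak is not None:
            hits.append((peak.intensity, rule.cls))
    hits.sort(key=lambda h: (-h[0], h[1].value))
    seen: set[HeadGroupClass] = set()
    ranked = []
    for _, cls in hits:
        if cls not in seen:
            seen.add(cls)
            ranked.append(cls)
    return ranked


# ---------------------------------------------------------------------------
# Stage 2: sum composition from accurate precursor mass
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _precursor_grid(cls: HeadGroupClass, mode: Polarity,
                    c_range: tuple[int, int], dbe_range: tuple[int, int]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cs, ds, mzs = [], [], []
    for c in range(c_range[0], c_range[1] + 1):
        for d in range(dbe_range[0], dbe_range[1] + 1):
            try:
                sc = SumComposition(cls, c, d)
                mz, _ = precursor_mz(sc, mode)
            except ValueError:
                continue
            cs.append(c)
            ds.append(d)
            mzs.append(mz)
    return np.asarray(cs), np.asarray(ds), np.asarray(mzs)


def infer_sum_composition(mz: float, cls: HeadGroupClass, mode: Polarity,
                          tol_ppm: float = 5.0,
                          c_range: tuple[int, int] = (20, 70),
                          dbe_range: tuple[int, int] = (0, 16),
                          ) -> list[SumComposition]:
    """All sum compositions of *cls* whose precursor matches *mz*.

    Exhaustive scan of the (c_total, dbe_total) grid; results sorted by |ppm|.
    An empty list means no hit; more than one hit signals an over-generous
    tolerance.
    """
    cs, ds, mzs = _precursor_grid(cls, mode, tuple(c_range), tuple(dbe_range))
    if mzs.size == 0:
        return []
    ppm = 1e6 * (mz - mzs) / mzs
    idx = np.flatnonzero(np.abs(ppm) <= tol_ppm)
    order = idx[np.argsort(np.abs(ppm[idx]), kind="stable")]
    return [SumComposition(cls, int(cs[i]), int(ds[i])) for i in order]


# ---------------------------------------------------------------------------
# Stage 3: acyl pair enumeration against negative-mode MS2
# ---------------------------------------------------------------------------

def enumerate_acyl_pairs(sc: SumComposition, neg_ms2: Ms2Spectrum,
                         tol_ppm: float = 10.0,
                         fa_carbon_range: tuple[int, int] = (12, 40),
                         fa_dbe_range: tuple[int, int] = (0, 10),
                         ) -> list[AcylPairCandidate]:
    """All acyl pairs summing to *sc* whose carboxylate anions are observed.

    The search space is all chains with carbons in *fa_carbon_range* and DBE
    in *fa_dbe_range* (subject to the structural guard DBE <= carbons - 2).
    The more intense matched anion is assigned sn-2; ties go to the longer
    chain.  Output order is deterministic: by sn-2 signal intensity
    (descending), then lexicographically by (carbons, DBE) of the pair.
    """
    c_lo, c_hi = fa_carbon_range
    d_lo, d_hi = fa_dbe_range
    results: list[AcylPairCandidate] = []
    for c_a in range(c_lo, c_hi + 1):
        c_b = sc.c_total - c_a
        if c_b < c_a or not (c_lo <= c_b <= c_hi):
            continue
        for d_a in range(d_lo, d_hi + 1):
            d_b = sc.dbe_total - d_a
            if not (d_lo <= d_b <= d_hi):
                continue
            if c_a == c_b and d_b < d_a:
                continue  # unordered pair: keep one orientation
            try:
                fa_a = FattyAcyl(c_a, d_a)
                fa_b = FattyAcyl(c_b, d_b)
            except ValueError:
                continue
            peak_a = neg_ms2.match(acyl_anion_mz(fa_a), tol_ppm)
            peak_b = neg_ms2.match(acyl_anion_mz(fa_b), tol_ppm)
            if peak_a is None or peak_b is None:
                continue
            int_a, int_b = peak_a.intensity, peak_b.intensity
            if int_a > int_b:
                sn2 = "a"
            elif int_b > int_a:
                sn2 = "b"
            else:
                sn2 = "b"  # tie: the longer (or equal) chain
            results.append(AcylPairCandidate(fa_a, fa_b, int_a, int_b, sn2))
    results.sort(key=lambda p: (-p.sn2_intensity, p.fa_a, p.fa_b))
    return results


# ---------------------------------------------------------------------------
# Stage 4: full cross-polarity confirmation
# ---------------------------------------------------------------------------

def _negative_rule_for(cls: HeadGroupClass,
                       rules: tuple[IonRule, ...]) -> IonRule | None:
    for rule in rules:
        if rule.cls is cls and rule.mode == "negative":
            return rule
    return None


def confirm_species(pos: Feature, neg: Feature,
                    config: Config | None = None,
                    rules: tuple[IonRule, ...] | None = None,
                    ) -> tuple[AnnotatedIPL | None, Rejection | None]:
    """Run the full identification chain on one cross-polarity feature pair.

    Returns ``(annotation, None)`` on success and ``(None, rejection)``
    otherwise.  When the positive MS2 supports several classes, candidates
    are tried in ranked order and the first to fully confirm wins.
    """
    cfg = config or Config()
    rules = rules or build_rule_table()

    def reject(stage: str, reason: str) -> tuple[None, Rejection]:
        return None, Rejection(pos.feature_id, neg.feature_id, stage, reason)

    classes = identify_class(pos, rules, cfg.ms2_ppm)
    if not classes:
        return reject("identify_class", "no class-diagnostic fragment in ESI+ MS2")

    last: Rejection | None = None
    for cls in classes:
        compositions = infer_sum_composition(
            pos.mz, cls, "positive", cfg.ms1_ppm,
            cfg.c_total_range, cfg.dbe_total_range)
        if not compositions:
            _, last = reject("infer_sum_composition",
                             f"no {cls.value} sum composition within "
                             f"{cfg.ms1_ppm} ppm of ESI+ precursor")
            continue
        sc = compositions[0]
        neg_mz_theo, _ = precursor_mz(sc, "negative")
        ppm_neg = ppm_error(neg.mz, neg_mz_theo)
        if abs(ppm_neg) > cfg.ms1_ppm:
            _, last = reject("negative_precursor",
                             "not present in both polarities "
                             f"({sc.name}: ESI- precursor off by {ppm_neg:.1f} ppm)")
            continue
        matched_rules = [f"{cls.value}+"]
        ms2_ppm: dict[str, float] = {}
        neg_rule = _negative_rule_for(cls, rules)
        if neg_rule is not None:
            if neg.ms2 is None or not neg.ms2.peaks:
                _, last = reject("negative_rule", "no ESI- MS2 spectrum")
                continue
            target = (neg_rule.mass if neg_rule.rule_kind == "fragment_ion"
                      else neg.mz - neg_rule.mass)
            peak = neg.ms2.match(target, cfg.ms2_ppm)
            if peak is None:
                _, last = reject("negative_rule",
                                 f"{cls.value} negative-mode class rule not matched")
                continue
            matched_rules.append(f"{cls.value}-")
            ms2_ppm["neg_rule"] = ppm_error(peak.mz, target)
        if neg.ms2 is None or not neg.ms2.peaks:
            _, last = reject("acyl_pairs", "no matching fatty acid signals")
            continue
        pairs = enumerate_acyl_pairs(sc, neg.ms2, cfg.ms2_ppm,
                                     cfg.fa_carbon_range, cfg.fa_dbe_range)
        if not pairs and cfg.require_acyl_pairs:
            _, last = reject("acyl_pairs", "no matching fatty acid signals")
            continue
        pos_mz_theo, _ = precursor_mz(sc, "positive")
        evidence = Evidence(cls, matched_rules,
                            ppm_error(pos.mz, pos_mz_theo), ppm_neg, ms2_ppm)
        return AnnotatedIPL(sc, pairs, evidence,
                            rt=0.5 * (pos.rt + neg.rt), area_pos=pos.area,
                            pos_id=pos.feature_id, neg_id=neg.feature_id), None
    return None, last


# ---------------------------------------------------------------------------
# Stage 5: whole-run annotation
# ---------------------------------------------------------------------------

def annotate_run(sample: Sample, config: Config | None = None,
                 ) -> tuple[list[AnnotatedIPL], list[Rejection]]:
    """Annotate one dual-polarity run.

    Features are first paired across polarities, each pair is confirmed, and
    isomeric compositions sharing one chromatographic peak are reported as a
    single combined entry carrying all consistent acyl pairs (isomers
    co-elute and are integrated as combined peaks).
    """
    cfg = config or Config()
    pairing = pair_features(sample.features_pos, sample.features_neg,
                            rt_tol=cfg.rt_tol_min,
                            mass_ppm=cfg.effective_pair_mass_ppm)
    annotations: list[AnnotatedIPL] = []
    rejections: list[Rejection] = [
        Rejection(f.feature_id, "", "pairing", "not present in both polarities")
        for f in pairing.unpaired_pos
    ] + [
        Rejection("", f.feature_id, "pairing", "not present in both polarities")
        for f in pairing.unpaired_neg
    ]
    for pos, neg in pairing.pairs:
        ann, rej = confirm_species(pos, neg, cfg)
        if ann is not None:
            annotations.append(ann)
        elif rej is not None:
            rejections.append(rej)

    # combine duplicate species (same composition, same peak)
    by_species: dict[str, AnnotatedIPL] = {}
    for ann in annotations:
        existing = by_species.get(ann.species)
        if existing is None:
            by_species[ann.species] = ann
        else:
            seen = {(p.fa_a, p.fa_b) for p in existing.pairs}
            existing.pairs.extend(p for p in ann.pairs
                                  if (p.fa_a, p.fa_b) not in seen)
            existing.area_pos += ann.area_pos
    combined = sorted(by_species.values(),
                      key=lambda a: (a.sum_comp.cls.value, a.sum_comp.c_total,
                                     a.sum_comp.dbe_total))
    return combined, rejections


def annotation_table(annotations: list[AnnotatedIPL]) -> pd.DataFrame:
    """Flatten annotations to the tabular (TSV-ready) form."""
    rows = []
    for ann in annotations:
        rows.append({
            "species": ann.species,
            "cls": ann.sum_comp.cls.value,
            "c_total": ann.sum_comp.c_total,
            "dbe_total": ann.sum_comp.dbe_total,
            "rt_min": ann.rt,
            "area_pos": ann.area_pos,
            "n_pairs": len(ann.pairs),
            "pairs": ";".join(p.name for p in ann.pairs),
            "pair_intensities": ";".join(
                f"{p.sn2_intensity:.6g}" for p in ann.pairs),
            "matched_rules": ";".join(ann.evidence.matched_rules),
            "ppm_ms1_pos": ann.evidence.ppm_ms1_pos,
            "ppm_ms1_neg": ann.evidence.ppm_ms1_neg,
        })
    return pd.DataFrame(rows, columns=[
        "species", "cls", "c_total", "dbe_total", "rt_min", "area_pos",
        "n_pairs", "pairs", "pair_intensities", "matched_rules",
        "ppm_ms1_pos", "ppm_ms1_neg"])
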