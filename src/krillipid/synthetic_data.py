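"""Krill-like synthetic lipidomes rendered to noisy dual-polarity peak lists.

The generator emulates the salient features of a krill digestive-organ
phospholipidome — a PC-dominated class profile, an acyl pool spanning 12:0 to
36:8 including very-long-chain PUFAs (26:6, 28:8, 36:8), and an optional
summer digestive-gland shift toward high-molecular-weight, highly unsaturated
species — and renders each sample to MS1 feature tables with attached MS2
peak lists in both ionization modes, plus internal-standard feature, decoy
peaks, process blanks and replicated calibration series.  Everything is
deterministic under a seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import _precursor_grid
from .chem_core import (
    FattyAcyl,
    HeadGroupClass,
    SumComposition,
    acyl_anion_mz,
    build_rule_table,
    composition_mass,
    internal_standard_mz,
    precursor_mz,
    species_formula,
)
from .spectra_model import (
    MONTHS,
    CalibrationLevel,
    CalibrationSeries,
    Feature,
    Ms2Spectrum,
    Peak,
    Sample,
)

__all__ = [
    "NoiseModel",
    "StudyDesign",
    "SimSpecies",
    "Lipidome",
    "SimulatedStudy",
    "DEFAULT_CLASS_WEIGHTS",
    "DEFAULT_FA_POOL",
    "IS_AREA",
    "generate_lipidome",
    "render_run",
    "generate_calibration",
    "simulate_study",
    "write_study",
    "read_study",
]

#: Nominal internal-standard peak area (arbitrary units).
IS_AREA = 1.0e6

#: Class weights proportional to the sum-formula diversity observed in krill
#: digestive organs (PC-dominated, PE second).
DEFAULT_CLASS_WEIGHTS: dict[HeadGroupClass, float] = {
    HeadGroupClass.PC: 59,
    HeadGroupClass.PE: 27,
    HeadGroupClass.PDME: 13,
    HeadGroupClass.PI: 11,
    HeadGroupClass.PME: 7,
    HeadGroupClass.PG: 6,
    HeadGroupClass.PS: 4,
}

#: Acyl pool with weights favouring the predominant krill fatty acids
#: (20:5, 18:1, 22:6, 16:0) and including very-long-chain PUFAs.
DEFAULT_FA_POOL: tuple[tuple[FattyAcyl, float], ...] = (
    (FattyAcyl(12, 0), 2), (FattyAcyl(14, 0), 4), (FattyAcyl(16, 0), 10),
    (FattyAcyl(16, 1), 5), (FattyAcyl(18, 0), 3), (FattyAcyl(18, 1), 10),
    (FattyAcyl(18, 2), 4), (FattyAcyl(18, 3), 3), (FattyAcyl(18, 4), 3),
    (FattyAcyl(20, 1), 3), (FattyAcyl(20, 5), 12), (FattyAcyl(22, 5), 2),
    (FattyAcyl(22, 6), 10), (FattyAcyl(24, 1), 1), (FattyAcyl(26, 6), 1.5),
    (FattyAcyl(28, 8), 1.5), (FattyAcyl(36, 8), 1),
)

#: Class-level retention-time means (min) inside the observed elution window.
_CLASS_RT: dict[HeadGroupClass, float] = {
    HeadGroupClass.PC: 4.3, HeadGroupClass.PE: 5.1, HeadGroupClass.PME: 5.5,
    HeadGroupClass.PDME: 5.9, HeadGroupClass.PG: 6.5, HeadGroupClass.PI: 7.3,
    HeadGroupClass.PS: 8.1,
}

_SUMMER_MONTHS = ("Jan", "Mar")


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    mass_ppm_sigma: float = 2.0  # Gaussian m/z error per rendered peak
    rt_jitter_min: float = 0.02  # per-run RT jitter sd
    area_cv: float = 0.05  # multiplicative (log-normal) area noise
    decoys_per_polarity: int = 10
    blank_contamination: float = 0.0  # ug/mL carried into process blanks

    def __post_init__(self) -> None:
        if self.mass_ppm_sigma < 0 or self.rt_jitter_min < 0 or self.area_cv < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0)


@dataclasses.dataclass(frozen=True)
class StudyDesign:
    """Months x organs x replicates, emulating a two-season sampling design."""

    months: tuple[str, ...] = ("Jan", "Mar", "May")
    organs: tuple[str, ...] = ("stomach", "digestive_gland", "hind_gut")
    replicates: int = 8
    n_blanks: int = 3


@dataclasses.dataclass(frozen=True)
class SimSpecies:
    sum_comp: SumComposition
    fa_sn1: FattyAcyl
    fa_sn2: FattyAcyl
    base_conc: float  # ug/mL
    rt: float  # min
    high_mw_dbe: bool  # participates in the summer digestive-gland shift

    @property
    def species(self) -> str:
        return self.sum_comp.name


@dataclasses.dataclass
class Lipidome:
    species: list[SimSpecies]
    effect_factor: float

    def multiplier(self, month: str, organ: str, sp: SimSpecies) -> float:
        if (sp.high_mw_dbe and month in _SUMMER_MONTHS
                and organ == "digestive_gland"):
            return self.effect_factor
        return 1.0

    def concentration(self, month: str, organ: str, sp: SimSpecies) -> float:
        return sp.base_conc * self.multiplier(month, organ, sp)

    def expected_fractions(self, month: str, organ: str) -> dict[str, float]:
        """Expected relative abundances in one condition; sums to 1."""
        concs = {sp.species: self.concentration(month, organ, sp)
                 for sp in self.species}
        total = sum(concs.values())
        return {k: v / total for k, v in concs.items()}


def generate_lipidome(n_species: int = 40,
                      class_weights: dict[HeadGroupClass, float] | None = None,
                      fa_pool: tuple[tuple[FattyAcyl, float], ...] = DEFAULT_FA_POOL,
                      effect_factor: float = 2.0,
                      conc_log_mu: float = np.log(0.1),
                      conc_log_sigma: float = 1.0,
                      seed: int = 0) -> Lipidome:
    """Draw a random lipidome with unique sum compositions.

    Species are a head-group class (PC-weighted) plus an acyl pair from the
    pool, with the more unsaturated chain placed at sn-2 (as predominantly
    observed in krill).  Baseline concentrations are log-normal with median
    ~0.1 ug/mL, inside the calibrated range.  Species in the upper tertile of
    neutral mass or total DBE are flagged as participating in the summer
    digestive-gland enrichment (x ``effect_factor`` in Jan/Mar digestive
    gland; factor 1 disables the effect).
    """
    if not fa_pool:
        raise ValueError("infeasible FA pool: empty")
    weights = class_weights or DEFAULT_CLASS_WEIGHTS
    rng = np.random.default_rng(seed)
    classes = list(weights)
    p_cls = np.array([weights[c] for c in classes], dtype=float)
    p_cls /= p_cls.sum()
    fas = [fa for fa, _ in fa_pool]
    p_fa = np.array([w for _, w in fa_pool], dtype=float)
    p_fa /= p_fa.sum()

    chosen: dict[tuple[HeadGroupClass, int, int], tuple] = {}
    attempts = 0
    while len(chosen) < n_species:
        attempts += 1
        if attempts > 200 * n_species:
            raise ValueError("infeasible FA pool: cannot draw "
                             f"{n_species} unique sum compositions")
        cls = classes[rng.choice(len(classes), p=p_cls)]
        fa_i = fas[rng.choice(len(fas), p=p_fa)]
        fa_j = fas[rng.choice(len(fas), p=p_fa)]
        sc = SumComposition(cls, fa_i.n_carbon + fa_j.n_carbon,
                            fa_i.n_dbe + fa_j.n_dbe)
        key = (cls, sc.c_total, sc.dbe_total)
        if key in chosen:
            continue
        # the more unsaturated chain sits at sn-2
        if fa_j.n_dbe > fa_i.n_dbe or (fa_j.n_dbe == fa_i.n_dbe
                                       and fa_j.n_carbon >= fa_i.n_carbon):
            sn1, sn2 = fa_i, fa_j
        else:
            sn1, sn2 = fa_j, fa_i
        conc = float(rng.lognormal(conc_log_mu, conc_log_sigma))
        conc = float(np.clip(conc, 1e-4, 9.0))
        rt = _CLASS_RT[cls] + float(rng.uniform(-0.4, 0.4))
        chosen[key] = (sc, sn1, sn2, conc, rt)

    masses = np.array([composition_mass(species_formula(v[0]))
                       for v in chosen.values()])
    dbes = np.array([v[0].dbe_total for v in chosen.values()], dtype=float)
    mass_hi = np.quantile(masses, 2 / 3)
    dbe_hi = np.quantile(dbes, 2 / 3)
    species = [
        SimSpecies(sc, sn1, sn2, conc, rt,
                   high_mw_dbe=bool(m > mass_hi or d > dbe_hi))
        for (sc, sn1, sn2, conc, rt), m, d
        in zip(chosen.values(), masses, dbes)
    ]
    species.sort(key=lambda s: (s.sum_comp.cls.value, s.sum_comp.c_total,
                                s.sum_comp.dbe_total))
    return Lipidome(species, effect_factor)


# ---------------------------------------------------------------------------
# Rendering one sample to dual-polarity feature tables
# ---------------------------------------------------------------------------

_ALL_CLASSES = tuple(HeadGroupClass)


def _theoretical_mz_grid(mode: str) -> np.ndarray:
    grids = [_precursor_grid(cls, mode, (20, 70), (0, 16))[2]
             for cls in _ALL_CLASSES]
    return np.sort(np.concatenate(grids + [np.array([internal_standard_mz(mode)])]))


def _draw_decoy_mz(rng: np.random.Generator, grid: np.ndarray,
                   min_ppm: float = 15.0) -> float:
    """Uniform decoy m/z kept >= min_ppm away from every theoretical species
    m/z so that false-positive tests stay sharp."""
    for _ in range(1000):
        mz = float(rng.uniform(420.0, 1150.0))
        idx = np.searchsorted(grid, mz)
        near = grid[max(0, idx - 1):idx + 1]
        if near.size == 0 or np.min(np.abs(near - mz)) / mz * 1e6 >= min_ppm:
            return mz
    raise RuntimeError("could not place decoy away from the theoretical grid")


def _jitter(rng: np.random.Generator, mz: float, sigma_ppm: float) -> float:
    if sigma_ppm <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, sigma_ppm) * 1e-6)


def _area_noise(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    return float(rng.lognormal(0.0, cv))


def render_run(lipidome: Lipidome, month: str, organ: str,
               noise: NoiseModel | None = None, seed: int = 0,
               sample_id: str = "sample", sex: str = "unknown",
               is_blank: bool = False) -> Sample:
    """Render one sample to a dual-polarity :class:`Sample`.

    Per species: an ESI+ precursor with the class-diagnostic MS2 signal, and
    an ESI- precursor whose MS2 carries the acyl carboxylate anions (the sn-2
    chain twice as intense as sn-1) plus the negative-mode class rule where
    one exists.  The d70-PC internal standard appears as a positive-mode
    feature at fixed nominal area; decoys are uniform in m/z, kept away from
    the theoretical grid.  Process blanks carry no analyte species (unless a
    blank contamination level is configured), but do carry the internal
    standard and decoys.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB10)))
    rules = {(r.cls, r.mode): r for r in build_rule_table()}
    features_pos: list[Feature] = []
    features_neg: list[Feature] = []

    for i, sp in enumerate(lipidome.species):
        conc = (noise.blank_contamination if is_blank
                else lipidome.concentration(month, organ, sp))
        if conc <= 0:
            continue
        area = conc * IS_AREA * _area_noise(rng, noise.area_cv)
        rt = sp.rt + (rng.normal(0.0, noise.rt_jitter_min)
                      if noise.rt_jitter_min > 0 else 0.0)
        rt_neg = sp.rt + (rng.normal(0.0, noise.rt_jitter_min)
                          if noise.rt_jitter_min > 0 else 0.0)
        sc = sp.sum_comp

        # --- positive mode ------------------------------------------------
        mz_pos_theo, _ = precursor_mz(sc, "positive")
        mz_pos = _jitter(rng, mz_pos_theo, noise.mass_ppm_sigma)
        pos_rule = rules[(sc.cls, "positive")]
        if pos_rule.rule_kind == "fragment_ion":
            frag_theo = pos_rule.mass
        else:
            frag_theo = mz_pos_theo - pos_rule.mass
        pos_peaks = [Peak(_jitter(rng, frag_theo, noise.mass_ppm_sigma),
                          0.5 * area)]
        features_pos.append(Feature(f"{sample_id}_p{i}", "positive", rt,
                                    mz_pos, area,
                                    Ms2Spectrum(mz_pos, pos_peaks)))

        # --- negative mode ------------------------------------------------
        mz_neg_theo, _ = precursor_mz(sc, "negative")
        mz_neg = _jitter(rng, mz_neg_theo, noise.mass_ppm_sigma)
        neg_peaks = []
        if sp.fa_sn1 == sp.fa_sn2:
            neg_peaks.append(Peak(_jitter(rng, acyl_anion_mz(sp.fa_sn2),
                                          noise.mass_ppm_sigma), 0.3 * area))
        else:
            neg_peaks.append(Peak(_jitter(rng, acyl_anion_mz(sp.fa_sn2),
                                          noise.mass_ppm_sigma), 0.2 * area))
            neg_peaks.append(Peak(_jitter(rng, acyl_anion_mz(sp.fa_sn1),
                                          noise.mass_ppm_sigma), 0.1 * area))
        neg_rule = rules.get((sc.cls, "negative"))
        if neg_rule is not None:
            target = (neg_rule.mass if neg_rule.rule_kind == "fragment_ion"
                      else mz_neg_theo - neg_rule.mass)
            neg_peaks.append(Peak(_jitter(rng, target, noise.mass_ppm_sigma),
                                  0.4 * area))
        features_neg.append(Feature(f"{sample_id}_n{i}", "negative", rt_neg,
                                    mz_neg, area * 0.8,
                                    Ms2Spectrum(mz_neg, neg_peaks)))

    # internal standard (positive mode only)
    is_mz = _jitter(rng, internal_standard_mz("positive"), noise.mass_ppm_sigma)
    features_pos.append(Feature(f"{sample_id}_IS", "positive", 4.5, is_mz,
                                IS_AREA * _area_noise(rng, noise.area_cv)))

    # decoys
    if noise.decoys_per_polarity > 0:
        for mode, bucket in (("positive", features_pos),
                             ("negative", features_neg)):
            grid = _theoretical_mz_grid(mode)
            for k in range(noise.decoys_per_polarity):
                bucket.append(Feature(
                    f"{sample_id}_d{mode[0]}{k}", mode,  # type: ignore[arg-type]
                    float(rng.uniform(3.5, 9.0)),
                    _draw_decoy_mz(rng, grid),
                    float(rng.lognormal(np.log(1e4), 1.0))))

    return Sample(sample_id, organ if not is_blank else "tissue",
                  month if not is_blank else MONTHS[0], sex,
                  features_pos, features_neg, is_blank=is_blank)


# ---------------------------------------------------------------------------
# Calibration series
# ---------------------------------------------------------------------------

def generate_calibration(standard_id: str,
                         concentrations: np.ndarray | None = None,
                         reps: int = 4, cv: float = 0.05,
                         outlier_rate: float = 0.0,
                         outlier_sigma: float = 5.0,
                         slope: float = 1.0,
                         seed: int = 0) -> CalibrationSeries:
    """Replicated calibration series with a linear true response.

    Replicate ratios are slope*conc with multiplicative Gaussian noise of
    coefficient of variation *cv*; with probability *outlier_rate* a replicate
    is displaced by ``outlier_sigma`` level standard deviations (random sign).
    The default nine levels are log-spaced between 0.1 pg/mL and 10 ug/mL.
    """
    if concentrations is None:
        concentrations = np.logspace(-7, 1, 9)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCA1)))
    levels = []
    for conc in np.sort(np.asarray(concentrations, dtype=float)):
        true = slope * conc
        sigma = cv * true
        ratios = []
        for _ in range(reps):
            value = true + (rng.normal(0.0, sigma) if cv > 0 else 0.0)
            if outlier_rate > 0 and rng.random() < outlier_rate:
                value += outlier_sigma * sigma * (1 if rng.random() < 0.5 else -1)
            ratios.append(float(value))
        levels.append(CalibrationLevel(float(conc), ratios))
    return CalibrationSeries(standard_id, levels)


# ---------------------------------------------------------------------------
# Whole-study simulation and study-directory I/O
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimulatedStudy:
    design: StudyDesign
    lipidome: Lipidome
    noise: NoiseModel
    seed: int
    samples: list[Sample]
    calibrations: dict[str, CalibrationSeries]
    truth_concentrations: pd.DataFrame  # sample_id, species, conc


def simulate_study(n_species: int = 40,
                   design: StudyDesign | None = None,
                   noise: NoiseModel | None = None,
                   effect_factor: float = 2.0,
                   calibration_cv: float = 0.05,
                   calibration_outlier_rate: float = 0.0,
                   seed: int = 0) -> SimulatedStudy:
    """Generate a full study: lipidome, per-condition replicate runs, process
    blanks and the four class-standard calibration series."""
    design = design or StudyDesign()
    noise = noise or NoiseModel()
    lipidome = generate_lipidome(n_species, effect_factor=effect_factor,
                                 seed=seed)
    samples: list[Sample] = []
    truth_rows = []
    run_index = 0
    for month in design.months:
        for organ in design.organs:
            for rep in range(design.replicates):
                sid = f"{month}_{organ}_r{rep + 1}"
                sex = "F" if rep % 2 == 0 else "M"
                samples.append(render_run(lipidome, month, organ, noise,
                                          seed=seed * 100003 + run_index,
                                          sample_id=sid, sex=sex))
                for sp in lipidome.species:
                    truth_rows.append((sid, sp.species,
                                       lipidome.concentration(month, organ, sp)))
                run_index += 1
    for b in range(design.n_blanks):
        sid = f"blank_r{b + 1}"
        samples.append(render_run(lipidome, design.months[0],
                                  design.organs[0], noise,
                                  seed=seed * 100003 + run_index,
                                  sample_id=sid, is_blank=True))
        run_index += 1
    calibrations = {
        std: generate_calibration(std, cv=calibration_cv,
                                  outlier_rate=calibration_outlier_rate,
                                  seed=seed * 7919 + k)
        for k, std in enumerate(("PC(16:0)", "PE(16:0)", "PG(16:0)", "PS(16:0)"))
    }
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "species", "conc"])
    return SimulatedStudy(design, lipidome, noise, seed, samples,
                          calibrations, truth)


_FLOAT_FMT = "%.10g"


def _safe_name(standard_id: str) -> str:
    return standard_id.replace("(", "_").replace(")", "").replace(":", "_")


def write_study(study: SimulatedStudy, directory: str | Path) -> Path:
    """Write a study directory: metadata, per-sample feature TSV pairs,
    calibration TSVs and truth tables (for scoring)."""
    from .spectra_model import write_feature_table

    root = Path(directory)
    (root / "features").mkdir(parents=True, exist_ok=True)
    (root / "calibration").mkdir(exist_ok=True)
    (root / "truth").mkdir(exist_ok=True)

    meta = pd.DataFrame(
        [(s.sample_id, s.organ, s.month, s.sex, int(s.is_blank))
         for s in study.samples],
        columns=["sample_id", "organ", "month", "sex", "is_blank"])
    meta.to_csv(root / "samples.tsv", sep="\t", index=False)

    for sample in study.samples:
        write_feature_table(sample.features_pos,
                            root / "features" / f"{sample.sample_id}.pos.tsv")
        write_feature_table(sample.features_neg,
                            root / "features" / f"{sample.sample_id}.neg.tsv")

    for std, series in study.calibrations.items():
        rows = [(std, lv.concentration, r + 1, ratio)
                for lv in series.levels for r, ratio in enumerate(lv.ratios)]
        pd.DataFrame(rows, columns=["standard_id", "concentration_ug_ml",
                                    "replicate", "area_ratio"]).to_csv(
            root / "calibration" / f"{_safe_name(std)}.tsv", sep="\t",
            index=False, float_format=_FLOAT_FMT)

    lip_rows = [(sp.species, f"{sp.fa_sn2.name}/{sp.fa_sn1.name}",
                 sp.base_conc, sp.rt, int(sp.high_mw_dbe))
                for sp in study.lipidome.species]
    pd.DataFrame(lip_rows, columns=["species", "pair_sn2_first", "base_conc",
                                    "rt_min", "high_mw_dbe"]).to_csv(
        root / "truth" / "lipidome.tsv", sep="\t", index=False,
        float_format=_FLOAT_FMT)
    study.truth_concentrations.to_csv(root / "truth" / "concentrations.tsv",
                                      sep="\t", index=False,
                                      float_format=_FLOAT_FMT)
    return root


def read_study(directory: str | Path
               ) -> tuple[list[Sample], dict[str, CalibrationSeries]]:
    """Read a study directory written by :func:`write_study` (or assembled by
    hand in the same layout)."""
    from .spectra_model import read_feature_table

    root = Path(directory)
    meta_path = root / "samples.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no samples.tsv in study directory {root}")
    meta = pd.read_csv(meta_path, sep="\t")
    samples = []
    for row in meta.itertuples(index=False):
        sid = str(row.sample_id)
        samples.append(Sample(
            sid, str(row.organ), str(row.month), str(row.sex),
            read_feature_table(root / "features" / f"{sid}.pos.tsv", "positive"),
            read_feature_table(root / "features" / f"{sid}.neg.tsv", "negative"),
            is_blank=bool(row.is_blank)))
    calibrations: dict[str, CalibrationSeries] = {}
    for path in sorted((root / "calibration").glob("*.tsv")):
        table = pd.read_csv(path, sep="\t")
        std = str(table["standard_id"].iloc[0])
        levels = [
            CalibrationLevel(float(conc), list(group["area_ratio"]))
            for conc, group in table.groupby("concentration_ug_ml", sort=True)
        ]
        calibrations[std] = CalibrationSeries(std, levels)
    return samples, calibrations
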