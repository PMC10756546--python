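"""End-to-end orchestration: annotate -> quantify -> compose -> analyze.

Operates on a study directory (as written by the simulator, or assembled by
hand in the same plain-TSV layout) and writes a results directory of TSV
tables plus a rejection log.  All stages are deterministic for fixed inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotatedIPL, annotate_run, annotation_table
from .chem_core import HeadGroupClass, internal_standard_mz
from .composition_stats import (
    compositions_to_matrix,
    derive_grouping,
    fa_saturation_ternary,
    group_matrix,
    pca_scores,
    pufa_indices,
    seasonal_ratios,
)
from .config import Config
from .quantification import (
    STANDARD_CLASS_MAP,
    CalibrationModel,
    SampleComposition,
    blank_subtract,
    build_calibration,
    percentage_distribution,
    quantify_species,
)
from .spectra_model import Sample
from .synthetic_data import read_study

logger = logging.getLogger(__name__)

__all__ = ["find_internal_standard", "quantify_sample", "run_pipeline"]

_FLOAT_FMT = "%.10g"


def find_internal_standard(sample: Sample, config: Config) -> float:
    """Area of the d70-PC internal-standard feature in the positive run."""
    target = internal_standard_mz("positive")
    hits = [f for f in sample.features_pos
            if abs(f.mz - target) / target * 1e6 <= config.ms1_ppm]
    if not hits:
        raise ValueError(
            f"internal standard missing in sample {sample.sample_id}")
    return max(hits, key=lambda f: f.area).area


def _model_for(cls: HeadGroupClass,
               models: dict[str, CalibrationModel]) -> CalibrationModel:
    for model in models.values():
        if cls in model.applies_to:
            return model
    raise ValueError(f"no calibration model covers class {cls.value}")


def quantify_sample(annotations: list[AnnotatedIPL], is_area: float,
                    models: dict[str, CalibrationModel],
                    config: Config) -> pd.DataFrame:
    """Concentration table (species, conc, flags) for one annotated sample.

    Isomer-combined annotation entries are quantified as single species, each
    against the calibration standard mapped to its head-group class.
    """
    rows = []
    for ann in annotations:
        model = _model_for(ann.sum_comp.cls, models)
        result = quantify_species(ann.area_pos, is_area, model,
                                  fit=config.calibration_fit)
        rows.append((ann.species, ann.sum_comp.cls.value,
                     result.concentration, ";".join(sorted(result.flags))))
    return pd.DataFrame(rows, columns=["species", "cls", "conc", "flags"])


def run_pipeline(study_dir: str | Path, out_dir: str | Path,
                 config: Config | None = None) -> dict[str, Path]:
    """Run the full pipeline on a study directory; returns written paths."""
    cfg = config or Config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, calibration_series = read_study(study_dir)
    if not samples:
        raise ValueError(f"study directory {study_dir} contains no samples")

    models = {std: build_calibration(series, cfg.grubbs_alpha,
                                     cfg.min_calibration_levels)
              for std, series in calibration_series.items()}
    covered = set().union(*(m.applies_to for m in models.values())) if models else set()
    if covered != set(HeadGroupClass):
        logger.warning("calibration models do not cover all classes: missing %s",
                       sorted(c.value for c in set(HeadGroupClass) - covered))

    annotations_by_sample: dict[str, list[AnnotatedIPL]] = {}
    rejection_rows = []
    quant_tables: dict[str, pd.DataFrame] = {}
    blank_tables: list[pd.Series] = []
    written: dict[str, Path] = {}

    for sample in samples:
        annotations, rejections = annotate_run(sample, cfg)
        rejection_rows.extend(
            (sample.sample_id, r.pos_id, r.neg_id, r.stage, r.reason)
            for r in rejections)
        try:
            is_area = find_internal_standard(sample, cfg)
        except ValueError as exc:
            logger.warning("%s; skipping quantification", exc)
            continue
        quant = quantify_sample(annotations, is_area, models, cfg)
        if sample.is_blank:
            blank_tables.append(quant.set_index("species")["conc"])
        else:
            annotations_by_sample[sample.sample_id] = annotations
            quant_tables[sample.sample_id] = quant

    annotation_rows = []
    for sample in samples:
        anns = annotations_by_sample.get(sample.sample_id)
        if anns is None:
            continue
        table = annotation_table(anns)
        table.insert(0, "sample_id", sample.sample_id)
        annotation_rows.append(table)
    annotations_df = (pd.concat(annotation_rows, ignore_index=True)
                      if annotation_rows else pd.DataFrame())
    written["annotations"] = out / "annotations.tsv"
    annotations_df.to_csv(written["annotations"], sep="\t", index=False,
                          float_format=_FLOAT_FMT)
    written["rejections"] = out / "rejections.tsv"
    pd.DataFrame(rejection_rows, columns=["sample_id", "pos_id", "neg_id",
                                          "stage", "reason"]).to_csv(
        written["rejections"], sep="\t", index=False)

    if not blank_tables:
        logger.warning("no process blanks found; proceeding without blank "
                       "subtraction")

    meta = {s.sample_id: s for s in samples}
    compositions: list[SampleComposition] = []
    quant_rows = []
    for sid, quant in quant_tables.items():
        series = quant.set_index("species")["conc"]
        corrected, dropped = (blank_subtract(series, blank_tables)
                              if blank_tables else (series, []))
        for species, conc in series.items():
            flag = quant.set_index("species").loc[species, "flags"]
            if species in dropped:
                flag = ";".join(filter(None, [flag, "blank_dropped"]))
            quant_rows.append((sid, species, conc, flag))
        if (corrected > 0).any():
            sample = meta[sid]
            compositions.append(percentage_distribution(
                corrected, sid, sample.organ, sample.month))
        else:
            logger.warning("sample %s has no species left after blank "
                           "subtraction", sid)
    written["concentrations"] = out / "concentrations.tsv"
    pd.DataFrame(quant_rows, columns=["sample_id", "species", "conc",
                                      "flags"]).to_csv(
        written["concentrations"], sep="\t", index=False,
        float_format=_FLOAT_FMT)

    if compositions:
        matrix = compositions_to_matrix(compositions)
        written["compositions"] = out / "compositions.tsv"
        matrix.to_csv(written["compositions"], sep="\t",
                      float_format=_FLOAT_FMT, index_label="sample_id")

        scheme = derive_grouping(compositions)
        grouped = group_matrix(compositions, scheme)
        written["groups"] = out / "group_matrix.tsv"
        grouped.to_csv(written["groups"], sep="\t", float_format=_FLOAT_FMT,
                       index_label="sample_id")
        if grouped.shape[0] >= 3 and grouped.to_numpy().std() > 0:
            scores, loadings, evr = pca_scores(grouped)
            scores["organ"] = [meta[s].organ for s in scores.index]
            scores["month"] = [meta[s].month for s in scores.index]
            written["pca_scores"] = out / "pca_scores.tsv"
            scores.to_csv(written["pca_scores"], sep="\t",
                          float_format=_FLOAT_FMT, index_label="sample_id")
            written["pca_loadings"] = out / "pca_loadings.tsv"
            loadings.to_csv(written["pca_loadings"], sep="\t",
                            float_format=_FLOAT_FMT, index_label="group")

        months = {c.month for c in compositions}
        if {"May"} & months and {"Jan", "Mar"} & months:
            ratios = seasonal_ratios(compositions, ["May"],
                                     ["Jan", "Mar"], HeadGroupClass.PC)
            written["seasonal_ratios"] = out / "seasonal_ratios_pc.tsv"
            pd.DataFrame([r.__dict__ for r in ratios]).to_csv(
                written["seasonal_ratios"], sep="\t", index=False,
                float_format=_FLOAT_FMT)

        for cls in (HeadGroupClass.PC, HeadGroupClass.PE):
            try:
                ternary, excluded = fa_saturation_ternary(
                    compositions, annotations_by_sample, cls)
                key = f"ternary_{cls.value.lower()}"
                written[key] = out / f"{key}.tsv"
                ternary.to_csv(written[key], sep="\t",
                               float_format=_FLOAT_FMT,
                               index_label="sample_id")
                if excluded:
                    logger.info("%d sum-composition-only %s entries excluded "
                                "from FA-level statistics", excluded, cls.value)
                indices = pufa_indices(compositions, annotations_by_sample, cls)
                key = f"indices_{cls.value.lower()}"
                written[key] = out / f"{key}.tsv"
                indices.to_csv(written[key], sep="\t",
                               float_format=_FLOAT_FMT,
                               index_label="sample_id")
            except ValueError as exc:
                logger.warning("skipping %s statistics: %s", cls.value, exc)

    logger.info("pipeline complete: %d sample(s), %d composition(s)",
                len(samples), len(compositions))
    return written
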