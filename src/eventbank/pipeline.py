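"""End-to-end pipeline: records -> cohort -> features -> AUC table."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import (
    FeatureMatrix,
    SeriesStore,
    TransformParams,
    build_feature_set,
    fit_transform,
)
from .cohort import (
    ADMISSION_CLASS,
    AssessmentPoint,
    CohortSplit,
    attach_labels,
    find_assessment_points,
    temporal_split,
)
from .config import RunConfig
from .elixhauser import load_comorbidity_map
from .filterbank import FilterBank
from .model_eval import run_experiment
from .schema import EntitySchema, EventRecord, Timeline, expand_hierarchy
from .vocabulary import Vocabulary, apply_vocabulary, build_vocabulary

logger = logging.getLogger("eventbank")


@dataclass
class ExtractionResult:
    timeline: Timeline
    split: CohortSplit
    aps: list[AssessmentPoint]  # derivation rows first, then validation
    derivation_mask: np.ndarray
    labels_by_horizon: dict[int, np.ndarray]
    vocab: Vocabulary
    matrices: dict[str, FeatureMatrix]  # transformed
    transform_params: dict[str, TransformParams]
    M: int
    N: int

    def ap_table(self) -> pd.DataFrame:
        rows = []
        for ap, deriv in zip(self.aps, self.derivation_mask):
            row = {
                "patient_id": ap.patient_id,
                "ap_date": self.timeline.date_of(ap.time).isoformat(),
                "ap_unit": ap.time,
                "split": "derivation" if deriv else "validation",
            }
            for h in sorted(self.labels_by_horizon):
                row[f"label_{h}m"] = ap.labels[h]
            rows.append(row)
        return pd.DataFrame(rows)


def build_cohort(
    records: list[EventRecord], cfg: RunConfig, timeline: Timeline
) -> tuple[CohortSplit, list[AssessmentPoint], np.ndarray, dict[int, np.ndarray]]:
    admissions = [r for r in records if r.entity_class == ADMISSION_CLASS]
    aps = find_assessment_points(
        admissions,
        cfg.disease_codes,
        timeline,
        mode=cfg.ap_mode,
        unplanned_only=cfg.unplanned_only,
    )
    attach_labels(aps, admissions, cfg.horizons_months, timeline)
    split = temporal_split(aps, cfg.validation_unit())
    ordered = split.derivation_aps + split.validation_aps
    mask = np.array(
        [True] * len(split.derivation_aps) + [False] * len(split.validation_aps)
    )
    labels = {
        h: np.array([ap.labels[h] for ap in ordered], dtype=int)
        for h in cfg.horizons_months
    }
    return split, ordered, mask, labels


def extract(
    records: list[EventRecord],
    demographics: pd.DataFrame,
    schema: EntitySchema,
    cfg: RunConfig,
) -> ExtractionResult:
    """Run schema -> series -> vocabulary -> filter bank -> feature sets."""
    timeline = cfg.timeline()
    split, aps, mask, labels = build_cohort(records, cfg, timeline)
    if not aps:
        raise ValueError("no assessment points found for the configured disease codes")

    expanded = expand_hierarchy(records, schema)
    vp = cfg.validation_unit()
    derivation_period = [r for r in expanded if timeline.index(r.start) < vp]
    vocab = build_vocabulary(derivation_period, cfg.min_count, cfg.max_size)
    mapped = apply_vocabulary(expanded, vocab)
    store = SeriesStore.build(mapped, timeline, vocab)
    bank = FilterBank.from_month_specs(cfg.bank_specs, cfg.unit, cfg.bank_family)
    diagnosis_records = [r for r in records if r.entity_class == "diagnosis"]
    cmap = load_comorbidity_map()

    logger.info(
        "extracting features: M=%d series, N=%d kernels, M*N=%d temporal features",
        store.M,
        len(bank),
        store.M * len(bank),
    )

    matrices: dict[str, FeatureMatrix] = {}
    params: dict[str, TransformParams] = {}
    for name in cfg.feature_sets:
        raw = build_feature_set(
            name,
            aps,
            store,
            bank,
            demographics,
            cmap,
            diagnosis_records=diagnosis_records,
            derivation_mask=mask,
        )
        matrices[name], params[name] = fit_transform(raw, mask)
    return ExtractionResult(
        timeline=timeline,
        split=split,
        aps=aps,
        derivation_mask=mask,
        labels_by_horizon=labels,
        vocab=vocab,
        matrices=matrices,
        transform_params=params,
        M=store.M,
        N=len(bank),
    )


def evaluate(
    extraction: ExtractionResult, cfg: RunConfig
) -> tuple[pd.DataFrame, dict]:
    """Fit every (feature set, horizon) pair; return the results table."""
    model_cfg = dataclasses.replace(cfg.model, seed=cfg.seed)
    return run_experiment(
        extraction.matrices,
        extraction.labels_by_horizon,
        extraction.derivation_mask,
        horizons=cfg.horizons_months,
        config=model_cfg,
    )


def run_study(
    records: list[EventRecord],
    demographics: pd.DataFrame,
    schema: EntitySchema,
    cfg: RunConfig,
) -> tuple[ExtractionResult, pd.DataFrame, dict]:
    extraction = extract(records, demographics, schema, cfg)
    results, fits = evaluate(extraction, cfg)
    return extraction, results, fits
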