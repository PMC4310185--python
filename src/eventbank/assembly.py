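"""Assembly of per-assessment-point feature matrices.

Four feature sets are supported:

====================  =====================================================
``baseline_1M``       demographics + 30 Elixhauser flags over 1 month
``baseline_3Y``       demographics + 30 Elixhauser flags over 36 months
``MR``                demographics + M*N filter-bank temporal features
``MR_comorbidities``  MR + 30 Elixhauser flags over 36 months
====================  =====================================================

Demographics are age at the assessment point (years, continuous), a
binary female indicator, and a one-hot encoding of postcode over the
categories seen in derivation rows (categories seen fewer than 50 times
are pooled; categories never seen in derivation encode as all zeros).

All features are min-max normalised to [0, 1] with parameters fitted on
derivation rows only, clipped, and square-root transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import AssessmentPoint
from .elixhauser import ComorbidityMap, map_codes, normalize_icd10, N_COMORBIDITIES
from .filterbank import FilterBank, block_features_at
from .schema import CONTINUING, EventRecord, EventSeries, Timeline
from .vocabulary import Vocabulary

FEATURE_SETS = ("baseline_1M", "baseline_3Y", "MR", "MR_comorbidities")

COMORBIDITY_LOOKBACKS = {"baseline_1M": 1, "baseline_3Y": 36, "MR_comorbidities": 36}

POSTCODE_POOL_MIN = 50  # same rarity threshold as the event vocabulary


@dataclass
class FeatureMatrix:
    feature_set_name: str
    column_names: list[str]
    values: np.ndarray
    aps: list[AssessmentPoint]

    def __post_init__(self) -> None:
        if len(self.column_names) != len(set(self.column_names)):
            raise ValueError("duplicate column names")
        if self.values.shape != (len(self.aps), len(self.column_names)):
            raise ValueError("values shape inconsistent with rows/columns")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)


@dataclass
class TransformParams:
    column_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"column": self.column_names, "min": self.mins, "max": self.maxs}
        )


class SeriesStore:
    """Per-patient event count matrices over a shared code axis.

    Rows are (entity_class, code) pairs in a deterministic order:
    classes sorted lexicographically; codes within a class in
    vocabulary rank order (rare pseudo-code last), or lexicographically
    when no vocabulary is supplied.  Count matrices are materialised
    per patient on demand to keep memory flat.
    """

    def __init__(
        self,
        timeline: Timeline,
        keys: list[tuple[str, str]],
        spans: dict[str, list[tuple[int, int, int]]],
    ):
        self.timeline = timeline
        self.keys = keys
        self.index = {k: i for i, k in enumerate(keys)}
        self._spans = spans

    @property
    def M(self) -> int:
        return len(self.keys)

    @classmethod
    def build(
        cls,
        records: Iterable[EventRecord],
        timeline: Timeline,
        vocab: Vocabulary | None = None,
    ) -> "SeriesStore":
        records = list(records)
        seen: dict[str, set[str]] = {}
        for r in records:
            seen.setdefault(r.entity_class, set()).add(r.code)
        keys: list[tuple[str, str]] = []
        for cls_name in sorted(seen):
            codes = seen[cls_name]
            if vocab is not None and cls_name in vocab.retained:
                ordered = [c for c in vocab.retained[cls_name] if c in codes]
                rare = vocab.rare_code(cls_name)
                leftovers = sorted(codes - set(ordered) - {rare})
                ordered += leftovers
                if rare in codes:
                    ordered.append(rare)
            else:
                ordered = sorted(codes)
            keys.extend((cls_name, c) for c in ordered)
        index = {k: i for i, k in enumerate(keys)}
        spans: dict[str, list[tuple[int, int, int]]] = {}
        T = timeline.n_units
        for r in records:
            i = timeline.index(r.start)
            if i > T:
                continue
            if r.kind == CONTINUING and r.end is not None:
                j = min(timeline.index(r.end), T)
            else:
                j = i
            row = index[(r.entity_class, r.code)]
            spans.setdefault(r.patient_id, []).append((row, i - 1, j - 1))
        return cls(timeline=timeline, keys=keys, spans=spans)

    def counts_matrix(self, patient_id: str, out: np.ndarray | None = None) -> np.ndarray:
        if out is None:
            out = np.zeros((self.M, self.timeline.n_units), dtype=np.int64)
        else:
            out[:] = 0
        for row, a, b in self._spans.get(patient_id, ()):
            out[row, a : b + 1] += 1
        return out

    def series(self, patient_id: str, entity_class: str, code: str) -> EventSeries:
        row = self.index[(entity_class, code)]
        counts = np.zeros(self.timeline.n_units, dtype=np.int64)
        for r, a, b in self._spans.get(patient_id, ()):
            if r == row:
                counts[a : b + 1] += 1
        return EventSeries(patient_id=patient_id, entity_code=code, counts=counts)


def temporal_block(
    aps: Sequence[AssessmentPoint], store: SeriesStore, bank: FilterBank
) -> tuple[np.ndarray, list[str]]:
    """M*N filter-bank features for every AP (rows in AP order)."""
    names = [f"{cls}:{code}|{k.label}" for cls, code in store.keys for k in bank]
    X = np.zeros((len(aps), len(names)))
    buf = np.zeros((store.M, store.timeline.n_units), dtype=np.int64)
    order = sorted(range(len(aps)), key=lambda i: aps[i].patient_id)
    current: str | None = None
    for i in order:
        ap = aps[i]
        if ap.patient_id != current:
            store.counts_matrix(ap.patient_id, out=buf)
            current = ap.patient_id
        X[i] = block_features_at(buf, bank, ap.time)
    return X, names


class StaticEncoder:
    """Encoder for age / gender / postcode demographic features.

    Postcode categories are learned from derivation rows: categories
    seen at least ``pool_min`` times get their own indicator, rarer ones
    share a pooled indicator, unseen ones encode as all zeros.
    """

    def __init__(self, demo: pd.DataFrame, pool_min: int = POSTCODE_POOL_MIN):
        self.demo = demo.set_index("patient_id") if "patient_id" in demo.columns else demo
        self.pool_min = pool_min
        self.postcodes: list[str] = []
        self.pooled: set[str] = set()
        self._has_rare = False

    def fit(self, derivation_aps: Sequence[AssessmentPoint]) -> "StaticEncoder":
        counts: dict[str, int] = {}
        for ap in derivation_aps:
            pc = str(self.demo.loc[ap.patient_id, "postcode"])
            counts[pc] = counts.get(pc, 0) + 1
        self.postcodes = sorted(pc for pc, n in counts.items() if n >= self.pool_min)
        self.pooled = {pc for pc, n in counts.items() if n < self.pool_min}
        self._has_rare = bool(self.pooled)
        return self

    @property
    def column_names(self) -> list[str]:
        cols = ["age", "gender=female"]
        cols += [f"postcode={pc}" for pc in self.postcodes]
        if self._has_rare:
            cols.append("postcode=__rare__")
        return cols

    def encode(self, ap: AssessmentPoint, timeline: Timeline) -> np.ndarray:
        if ap.patient_id not in self.demo.index:
            raise KeyError(f"patient {ap.patient_id!r} missing from demographics")
        row = self.demo.loc[ap.patient_id]
        birth = pd.Timestamp(row["birth_date"]).date()
        ap_date = timeline.date_of(ap.time)
        age = (ap_date - birth).days / 365.25
        female = float(str(row["gender"]).upper().startswith("F"))
        pc = str(row["postcode"])
        vec = np.zeros(len(self.column_names))
        vec[0] = age
        vec[1] = female
        for j, known in enumerate(self.postcodes):
            if pc == known:
                vec[2 + j] = 1.0
                break
        else:
            if self._has_rare and pc in self.pooled:
                vec[-1] = 1.0
        return vec

    def transform(
        self, aps: Sequence[AssessmentPoint], timeline: Timeline
    ) -> np.ndarray:
        return np.vstack([self.encode(ap, timeline) for ap in aps]) if aps else np.zeros(
            (0, len(self.column_names))
        )


def static_features(
    patient_id: str,
    ap: AssessmentPoint,
    demo: pd.DataFrame,
    timeline: Timeline,
    encoder: StaticEncoder | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Demographic vector for one AP (encoder fitted on [ap] if absent)."""
    if encoder is None:
        encoder = StaticEncoder(demo, pool_min=1).fit([ap])
    if ap.patient_id != patient_id:
        raise ValueError("assessment point does not belong to the patient")
    return encoder.encode(ap, timeline), encoder.column_names


def comorbidity_block(
    aps: Sequence[AssessmentPoint],
    records: Sequence[EventRecord],
    lookback_months: int,
    timeline: Timeline,
    cmap: ComorbidityMap,
    diagnosis_class: str = "diagnosis",
    apply_exclusions: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Elixhauser flags per AP over a lookback window, vectorised.

    Per-code flag vectors are cached, then OR-ed over the codes whose
    event unit falls inside [ap.time - lookback, ap.time].
    """
    lb = timeline.months_to_units(lookback_months)
    by_patient: dict[str, list[tuple[int, str]]] = {}
    for rec in records:
        if rec.entity_class != diagnosis_class:
            continue
        u = timeline.index(rec.start)
        if u <= timeline.n_units:
            by_patient.setdefault(rec.patient_id, []).append((u, rec.code))
    code_flags: dict[str, np.ndarray] = {}

    def flags_for(code: str) -> np.ndarray:
        f = code_flags.get(code)
        if f is None:
            f = map_codes([code], cmap, apply_exclusions=False)
            code_flags[code] = f
        return f

    idx = {name: i for i, name in enumerate(cmap.names)}
    X = np.zeros((len(aps), N_COMORBIDITIES), dtype=np.int8)
    for i, ap in enumerate(aps):
        acc = np.zeros(N_COMORBIDITIES, dtype=np.int8)
        for u, code in by_patient.get(ap.patient_id, ()):
            if ap.time - lb <= u <= ap.time:
                acc |= flags_for(code)
        if apply_exclusions:
            if acc[idx["diabetes_complicated"]]:
                acc[idx["diabetes_uncomplicated"]] = 0
            if acc[idx["metastatic_cancer"]]:
                acc[idx["solid_tumor_without_metastasis"]] = 0
        X[i] = acc
    names = [f"elix:{name}" for name in cmap.names]
    return X.astype(float), names


def build_feature_set(
    name: str,
    aps: Sequence[AssessmentPoint],
    store: SeriesStore,
    bank: FilterBank,
    demo: pd.DataFrame,
    cmap: ComorbidityMap,
    diagnosis_records: Sequence[EventRecord] = (),
    derivation_mask: np.ndarray | None = None,
) -> FeatureMatrix:
    """Assemble one of the four feature sets (untransformed values)."""
    if name not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {name!r}; expected one of {FEATURE_SETS}")
    aps = list(aps)
    timeline = store.timeline
    if derivation_mask is None:
        derivation_mask = np.ones(len(aps), dtype=bool)
    derivation_aps = [ap for ap, m in zip(aps, derivation_mask) if m]
    enc = StaticEncoder(demo).fit(derivation_aps)
    blocks = []
    names: list[str] = []
    if name in ("MR", "MR_comorbidities"):
        Xt, nt = temporal_block(aps, store, bank)
        blocks.append(Xt)
        names += nt
    blocks.append(enc.transform(aps, timeline))
    names += enc.column_names
    if name in COMORBIDITY_LOOKBACKS:
        Xc, nc = comorbidity_block(
            aps, diagnosis_records, COMORBIDITY_LOOKBACKS[name], timeline, cmap
        )
        blocks.append(Xc)
        names += nc
    values = np.hstack(blocks) if aps else np.zeros((0, len(names)))
    return FeatureMatrix(
        feature_set_name=name, column_names=names, values=values, aps=aps
    )


def fit_transform(
    matrix: FeatureMatrix, derivation_rows: np.ndarray
) -> tuple[FeatureMatrix, TransformParams]:
    """Min-max to [0,1] (fitted on derivation rows), clip, then sqrt.

    Constant columns map to zero; validation values outside the fitted
    range are clipped before the square root.
    """
    derivation_rows = np.asarray(derivation_rows)
    if derivation_rows.dtype == bool:
        deriv = matrix.values[derivation_rows]
    else:
        deriv = matrix.values[derivation_rows.astype(int)]
    if matrix.values.size == 0:
        params = TransformParams(matrix.column_names, np.zeros(0), np.zeros(0))
        return matrix, params
    if deriv.shape[0] == 0:
        raise ValueError("derivation rows must be non-empty")
    mins = deriv.min(axis=0)
    maxs = deriv.max(axis=0)
    params = TransformParams(list(matrix.column_names), mins, maxs)
    return apply_transform(matrix, params), params


def apply_transform(matrix: FeatureMatrix, params: TransformParams) -> FeatureMatrix:
    rng_ = params.maxs - params.mins
    safe = np.where(rng_ > 0, rng_, 1.0)
    scaled = (matrix.values - params.mins) / safe
    scaled = np.where(rng_ > 0, scaled, 0.0)
    scaled = np.clip(scaled, 0.0, 1.0)
    return FeatureMatrix(
        feature_set_name=matrix.feature_set_name,
        column_names=list(matrix.column_names),
        values=np.sqrt(scaled),
        aps=matrix.aps,
    )
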