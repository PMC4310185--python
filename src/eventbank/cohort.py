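"""Assessment points, readmission labels and the temporal cohort split.

An assessment point (AP) is a (patient, time) unit of analysis: events
before the AP yield features, admissions after it yield labels.  APs
are placed at hospital discharges occurring at or after the patient's
first admission carrying a diagnosis code of the disease under study
(or at fixed calendar dates for already-diagnosed patients).

An unplanned readmission within horizon H is an emergency-flagged
admission starting strictly after the AP and no later than H months
after it; same-unit admissions are excluded because features include
the AP's own unit.

Derivation and validation cohorts are disjoint both in patients and in
time: patients with any AP before the validation point form the
derivation cohort (their later APs are discarded); all remaining
patients form the validation cohort.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .schema import EventRecord, Timeline

ADMISSION_CLASS = "admission"
EMERGENCY_ATTR = "emergency"
DIAGNOSES_ATTR = "diagnoses"

MODE_DISCHARGE = "discharge"
MODE_FIXED_DATE = "fixed_date"


@dataclass
class AssessmentPoint:
    patient_id: str
    time: int  # discrete unit index
    source: str = MODE_DISCHARGE
    labels: dict[int, int] = field(default_factory=dict)


@dataclass
class CohortSplit:
    validation_point: int
    derivation_aps: list[AssessmentPoint]
    validation_aps: list[AssessmentPoint]

    @property
    def derivation_patients(self) -> set[str]:
        return {ap.patient_id for ap in self.derivation_aps}

    @property
    def validation_patients(self) -> set[str]:
        return {ap.patient_id for ap in self.validation_aps}


def _is_emergency(rec: EventRecord) -> bool:
    v = rec.attrs.get(EMERGENCY_ATTR, "0")
    return str(v) in ("1", "True", "true")


def _admission_diagnoses(rec: EventRecord) -> set[str]:
    raw = rec.attrs.get(DIAGNOSES_ATTR, "")
    return {c for c in str(raw).split(";") if c}


def _discharge_unit(rec: EventRecord, timeline: Timeline) -> int:
    return timeline.index(rec.end if rec.end is not None else rec.start)


def find_assessment_points(
    admissions: Sequence[EventRecord],
    disease_codes: Iterable[str],
    timeline: Timeline,
    mode: str = MODE_DISCHARGE,
    fixed_dates: Sequence[dt.date] = (),
    unplanned_only: bool = True,
) -> list[AssessmentPoint]:
    """Place APs after each patient's first diagnosis of the disease.

    ``mode="discharge"``: one AP per eligible discharge at or after the
    discharge of the first admission carrying a disease code.  With
    ``unplanned_only`` (the default) only emergency-flagged admissions
    contribute APs.  ``mode="fixed_date"``: one AP per configured date
    for each patient already diagnosed by that date.

    Patients never diagnosed contribute no APs.
    """
    if mode not in (MODE_DISCHARGE, MODE_FIXED_DATE):
        raise ValueError(f"unknown AP mode {mode!r}")
    disease = set(disease_codes)
    by_patient: dict[str, list[EventRecord]] = {}
    for rec in admissions:
        if rec.entity_class != ADMISSION_CLASS:
            continue
        by_patient.setdefault(rec.patient_id, []).append(rec)

    out: list[AssessmentPoint] = []
    for pid in sorted(by_patient):
        recs = sorted(by_patient[pid], key=lambda r: (r.start, r.end or r.start))
        dx_units = [
            _discharge_unit(r, timeline)
            for r in recs
            if _admission_diagnoses(r) & disease
            and timeline.index(r.start) <= timeline.n_units
        ]
        if not dx_units:
            continue
        first_dx = min(dx_units)
        if mode == MODE_DISCHARGE:
            for r in recs:
                if timeline.index(r.start) > timeline.n_units:
                    continue
                if unplanned_only and not _is_emergency(r):
                    continue
                u = min(_discharge_unit(r, timeline), timeline.n_units)
                if u >= first_dx:
                    out.append(AssessmentPoint(patient_id=pid, time=u))
        else:
            for d in fixed_dates:
                u = timeline.index(d)
                if u <= timeline.n_units and u >= first_dx:
                    out.append(
                        AssessmentPoint(patient_id=pid, time=u, source=MODE_FIXED_DATE)
                    )
    return out


def label_readmission(
    ap: AssessmentPoint,
    admissions: Sequence[EventRecord],
    horizon_months: int,
    timeline: Timeline,
) -> int:
    """1 iff an emergency admission of this patient starts in
    (ap.time, ap.time + horizon] units."""
    if horizon_months <= 0:
        raise ValueError("horizon must be positive")
    h_units = timeline.months_to_units(horizon_months)
    for rec in admissions:
        if rec.patient_id != ap.patient_id or rec.entity_class != ADMISSION_CLASS:
            continue
        if not _is_emergency(rec):
            continue
        u = timeline.index(rec.start)
        if ap.time < u <= ap.time + h_units:
            return 1
    return 0


def attach_labels(
    aps: Sequence[AssessmentPoint],
    admissions: Sequence[EventRecord],
    horizons_months: Sequence[int],
    timeline: Timeline,
) -> None:
    """Fill each AP's label map for every configured horizon, in place."""
    emerg: dict[str, list[int]] = {}
    for rec in admissions:
        if rec.entity_class == ADMISSION_CLASS and _is_emergency(rec):
            emerg.setdefault(rec.patient_id, []).append(timeline.index(rec.start))
    for ap in aps:
        starts = emerg.get(ap.patient_id, ())
        for h in horizons_months:
            h_units = timeline.months_to_units(h)
            ap.labels[h] = int(any(ap.time < u <= ap.time + h_units for u in starts))


def temporal_split(
    aps: Sequence[AssessmentPoint], validation_point: int
) -> CohortSplit:
    """Split APs into patient-and-time-disjoint cohorts.

    A patient with any AP strictly before the validation point belongs
    to the derivation cohort and keeps only those earlier APs; every
    other patient belongs to the validation cohort with all their APs.
    """
    by_patient: dict[str, list[AssessmentPoint]] = {}
    for ap in aps:
        by_patient.setdefault(ap.patient_id, []).append(ap)
    derivation: list[AssessmentPoint] = []
    validation: list[AssessmentPoint] = []
    for pid in sorted(by_patient):
        pts = sorted(by_patient[pid], key=lambda a: a.time)
        early = [a for a in pts if a.time < validation_point]
        if early:
            derivation.extend(early)
        else:
            validation.extend(pts)
    return CohortSplit(
        validation_point=validation_point,
        derivation_aps=derivation,
        validation_aps=validation,
    )
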