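"""Seedable synthetic hospital database with planted readmission risk.

The generator emulates the structure a hospital administrative database
presents to the feature-extraction framework:

* point and continuing entities over several classes — admission
  episodes (continuing, DRG-like codes, emergency/planned flag,
  attached ICD-10-like diagnosis codes), diagnoses, medications and
  standalone emergency-department visits (point events);
* heavy-tailed code frequencies (Zipf), including a rare tail below the
  vocabulary pooling threshold;
* a per-discharge readmission hazard with a planted dependence on
  recent history: the probability of an unplanned (emergency-flagged)
  readmission within the ascertainment window after a discharge is
  ``expit(logit(p0) + sum_k w_k * count_k)`` where ``count_k`` is the
  patient's event count of a designated entity in a designated lag
  window before the discharge.

The hazard is realised by superposition so that the null model is
exactly memoryless: the baseline component ``p0`` is supplied by a
homogeneous per-patient emergency-admission background whose rate is
calibrated to give probability ``p0`` of an arrival within the
ascertainment window, and each discharge additionally spawns an
emergency readmission with the excess probability
``(expit(logit(p0)+lp) - p0)/(1 - p0)``.  With all effect weights at
zero no spawns occur and future admissions are independent of history,
so no feature set can beat chance; with planted effects the marginal
per-discharge readmission probability equals the logistic hazard.

Spawned readmissions arrive after a geometric delay whose median drifts
upward over calendar time, emulating service improvement and stressing
the temporal derivation/validation split.  Per-patient overdispersion
(a gamma-distributed emergency-visit rate and a sticky renal-failure
code) makes recent-history counts genuinely variable across patients.
"""

from __future__ import annotations

import datetime as dt
import heapq
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .filterbank import DEFAULT_BANK_MONTHS
from .schema import (
    CONTINUING,
    POINT,
    EntitySchema,
    EntityType,
    EventRecord,
    Timeline,
)

#: diagnosis codes that hit bundled Elixhauser prefixes (frequent head of the Zipf)
_QUANISH_DX = (
    "E11", "F32", "I10", "N18", "I50", "I48", "J44", "F33", "E66", "F10",
    "D509", "K70", "C34", "G40", "I70", "E03", "D65", "E86", "M05", "I26",
    "F20", "R64", "B18", "K257", "Z950", "I85", "E40", "J45", "E119", "E112",
)


@dataclass(frozen=True)
class Effect:
    """One planted effect: weight on event counts in a lag window.

    An event of (entity_class, code) at unit u contributes to the
    readmission log-odds at a discharge in unit d iff
    ``lag_lo_months <= d - u < lag_hi_months`` (in months).
    """

    entity_class: str
    code: str
    lag_lo_months: int
    lag_hi_months: int
    weight: float


DEFAULT_EFFECTS: tuple[Effect, ...] = (
    Effect("emergency", "ED", 0, 3, 1.0),
    Effect("diagnosis", "N18", 0, 3, 1.0),
)


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 2000
    origin: dt.date = dt.date(2003, 1, 1)
    span_years: int = 8
    unit: str = "month"
    n_generic_diagnosis_codes: int = 200
    n_medication_codes: int = 100
    n_drg_codes: int = 30
    n_postcodes: int = 15
    zipf_exponent: float = 1.1
    disease_codes: tuple[str, ...] = ("E11",)
    disease_incidence: float = 0.55
    base_readmission_prob: float = 0.18
    readmission_window_months: int = 12
    effects: tuple[Effect, ...] = DEFAULT_EFFECTS
    median_readmission_months_start: float = 4.0
    median_readmission_months_end: float = 8.0
    mean_planned_admissions: float = 2.0
    mean_ed_visits: float = 10.0
    ed_rate_gamma_shape: float = 0.5
    mean_extra_diagnoses: float = 1.0
    mean_medications: float = 2.0
    n18_stickiness: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("disease_incidence", "base_readmission_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.base_readmission_prob >= 1.0:
            raise ValueError("base_readmission_prob must be < 1")
        if self.span_years < 4:
            raise ValueError("study span must be at least 4 years")
        if self.unit not in ("day", "month"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")

    def timeline(self) -> Timeline:
        n_units = self.span_years * (12 if self.unit == "month" else 360)
        return Timeline(unit=self.unit, origin=self.origin, n_units=n_units)

    def diagnosis_codes(self) -> list[str]:
        return list(_QUANISH_DX) + [
            f"U{i:03d}" for i in range(self.n_generic_diagnosis_codes)
        ]

    def null_effects(self) -> "SimConfig":
        """Copy of the config with every planted effect weight zeroed."""
        return replace(
            self, effects=tuple(replace(e, weight=0.0) for e in self.effects)
        )


def _zipf_weights(n: int, s: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** s
    return w / w.sum()


def build_sim_schema(cfg: SimConfig) -> EntitySchema:
    """Entity schema matching the generator's code universes.

    Diagnosis codes hang under one-letter block parents (codes
    ``BLK_<letter>``), exercising hierarchy expansion; other classes
    are flat.
    """
    types: list[EntityType] = []
    dx = cfg.diagnosis_codes()
    blocks = sorted({c[0] for c in dx})
    for b in blocks:
        types.append(EntityType(code=f"BLK_{b}", entity_class="diagnosis", kind=POINT))
    for c in dx:
        types.append(
            EntityType(
                code=c, entity_class="diagnosis", kind=POINT, parent_code=f"BLK_{c[0]}"
            )
        )
    for i in range(cfg.n_medication_codes):
        types.append(EntityType(code=f"MED{i:03d}", entity_class="medication", kind=POINT))
    for i in range(cfg.n_drg_codes):
        types.append(
            EntityType(code=f"DRG{i:02d}", entity_class="admission", kind=CONTINUING)
        )
    types.append(EntityType(code="ED", entity_class="emergency", kind=POINT))
    return EntitySchema(types)


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_database(cfg: SimConfig, audit: bool = False):
    """Generate (EventRecord list, demographics DataFrame).

    With ``audit=True`` a third value is returned: a per-discharge
    DataFrame with the linear predictor, the modelled readmission
    probability and the realised outcome (spawned readmission or
    background emergency admission within the ascertainment window),
    for calibration checks.
    """
    rng = np.random.default_rng(cfg.seed)
    timeline = cfg.timeline()
    T = timeline.n_units
    upm = 1 if cfg.unit == "month" else 30  # units per month
    W = cfg.readmission_window_months * upm

    dx_codes = np.array(cfg.diagnosis_codes())
    dx_w = _zipf_weights(len(dx_codes), cfg.zipf_exponent)
    med_codes = np.array([f"MED{i:03d}" for i in range(cfg.n_medication_codes)])
    med_w = _zipf_weights(len(med_codes), cfg.zipf_exponent)
    drg_codes = np.array([f"DRG{i:02d}" for i in range(cfg.n_drg_codes)])
    drg_w = _zipf_weights(len(drg_codes), cfg.zipf_exponent)
    postcodes = np.array([f"PC{i:02d}" for i in range(cfg.n_postcodes)])
    pc_w = _zipf_weights(len(postcodes), 1.2)

    effect_windows = [
        (
            e,
            timeline.months_to_units(e.lag_lo_months),
            timeline.months_to_units(e.lag_hi_months),
        )
        for e in cfg.effects
    ]
    p0 = cfg.base_readmission_prob
    base_logit = math.log(p0 / (1 - p0))
    # homogeneous emergency-admission rate with P(arrival within W) = p0
    lam_em = -math.log(1 - p0) / W

    records: list[EventRecord] = []
    demo_rows = []
    audit_rows = []

    for p in range(cfg.n_patients):
        pid = f"P{p:05d}"
        age0 = rng.uniform(35.0, 90.0)
        birth = cfg.origin - dt.timedelta(days=int(age0 * 365.25))
        gender = "F" if rng.random() < 0.5 else "M"
        postcode = str(rng.choice(postcodes, p=pc_w))
        demo_rows.append(
            {
                "patient_id": pid,
                "birth_date": birth.isoformat(),
                "gender": gender,
                "postcode": postcode,
            }
        )

        diseased = rng.random() < cfg.disease_incidence
        n_planned = int(rng.poisson(cfg.mean_planned_admissions))
        n_em_bg = int(rng.poisson(lam_em * T))
        if diseased and n_planned + n_em_bg == 0:
            n_planned = 1
        planned_units = sorted(int(u) for u in rng.integers(1, T + 1, size=n_planned))
        em_bg_units = sorted(int(u) for u in rng.integers(1, T + 1, size=n_em_bg))

        ed_rate = rng.gamma(
            cfg.ed_rate_gamma_shape, cfg.mean_ed_visits / cfg.ed_rate_gamma_shape
        )
        ed_units = sorted(int(u) for u in rng.integers(1, T + 1, size=int(rng.poisson(ed_rate))))

        effect_units: list[list[int]] = [[] for _ in cfg.effects]

        def note_event(entity_class: str, code: str, unit: int) -> None:
            for k, (e, _, _) in enumerate(effect_windows):
                if e.entity_class == entity_class and e.code == code:
                    effect_units[k].append(unit)

        for u in ed_units:
            records.append(
                EventRecord(
                    patient_id=pid,
                    code="ED",
                    entity_class="emergency",
                    kind=POINT,
                    start=timeline.date_of(u),
                )
            )
            note_event("emergency", "ED", u)

        has_n18 = False

        def make_admission(unit: int, emergency: bool, include_disease: bool) -> int:
            """Emit one admission episode with attached diagnoses and
            medications; returns the discharge unit."""
            nonlocal has_n18
            if cfg.unit == "month":
                los = 1 if rng.random() < 0.15 else 0
            else:
                los = int(rng.integers(1, 11))
            end_unit = min(unit + los, T)
            start_d, end_d = timeline.date_of(unit), timeline.date_of(end_unit)
            drg = str(rng.choice(drg_codes, p=drg_w))
            k = 1 + int(rng.poisson(cfg.mean_extra_diagnoses))
            dxs = list(dict.fromkeys(rng.choice(dx_codes, size=k, p=dx_w).tolist()))
            if include_disease:
                dxs.append(str(rng.choice(np.array(cfg.disease_codes))))
            if has_n18 and "N18" not in dxs and rng.random() < cfg.n18_stickiness:
                dxs.append("N18")
            dxs = list(dict.fromkeys(dxs))
            if "N18" in dxs:
                has_n18 = True
            records.append(
                EventRecord(
                    patient_id=pid,
                    code=drg,
                    entity_class="admission",
                    kind=CONTINUING,
                    start=start_d,
                    end=end_d,
                    attrs={
                        "emergency": "1" if emergency else "0",
                        "diagnoses": ";".join(dxs),
                    },
                )
            )
            for c in dxs:
                records.append(
                    EventRecord(
                        patient_id=pid,
                        code=c,
                        entity_class="diagnosis",
                        kind=POINT,
                        start=start_d,
                    )
                )
                note_event("diagnosis", c, unit)
            for c in rng.choice(
                med_codes, size=int(rng.poisson(cfg.mean_medications)), p=med_w
            ):
                records.append(
                    EventRecord(
                        patient_id=pid,
                        code=str(c),
                        entity_class="medication",
                        kind=POINT,
                        start=start_d,
                    )
                )
            return end_unit

        # background admissions (planned + homogeneous emergency), oldest
        # first; the patient's first admission carries the disease code
        background = sorted(
            [(u, False) for u in planned_units] + [(u, True) for u in em_bg_units]
        )
        heap: list[tuple[int, int]] = []
        seq = 0
        for i, (u, emergency) in enumerate(background):
            d_unit = make_admission(u, emergency, include_disease=diseased and i == 0)
            heapq.heappush(heap, (d_unit, seq))
            seq += 1

        # follow every discharge; spawn the excess readmission probability
        while heap:
            d, _ = heapq.heappop(heap)
            lp = 0.0
            for k, (e, lo_u, hi_u) in enumerate(effect_windows):
                if e.weight == 0.0:
                    continue
                n = sum(1 for u in effect_units[k] if d - hi_u < u <= d - lo_u)
                lp += e.weight * n
            prob = _expit(base_logit + lp)
            p_extra = max(0.0, (prob - p0) / (1.0 - p0))
            spawn = rng.random() < p_extra
            if audit:
                bg_hit = any(d < u <= d + W for u in em_bg_units)
                audit_rows.append(
                    {
                        "patient_id": pid,
                        "discharge_unit": d,
                        "linear_predictor": lp,
                        "prob": prob,
                        "readmitted": int(spawn or bg_hit),
                    }
                )
            if spawn and d < T:
                frac = d / T
                median_m = (
                    cfg.median_readmission_months_start
                    + (
                        cfg.median_readmission_months_end
                        - cfg.median_readmission_months_start
                    )
                    * frac
                )
                p_geom = 1.0 - 0.5 ** (1.0 / (median_m * upm))
                gap = int(rng.geometric(p_geom))
                u_new = d + gap
                if u_new <= T:
                    d_new = make_admission(u_new, emergency=True, include_disease=False)
                    heapq.heappush(heap, (d_new, seq))
                    seq += 1

    demographics = pd.DataFrame(
        demo_rows, columns=["patient_id", "birth_date", "gender", "postcode"]
    )
    if audit:
        audit_df = pd.DataFrame(
            audit_rows,
            columns=[
                "patient_id",
                "discharge_unit",
                "linear_predictor",
                "prob",
                "readmitted",
            ],
        )
        return records, demographics, audit_df
    return records, demographics


def planted_truth(
    cfg: SimConfig,
    bank_months: Sequence[tuple[int, int]] = DEFAULT_BANK_MONTHS,
    family: str = "uniform",
) -> dict:
    """Map each nonzero planted effect to the feature columns expected
    to carry it.

    A kernel with (sigma, delay) in months covers event ages
    [delay, delay + sigma); a kernel column is flagged iff that span
    overlaps the effect's lag window [lag_lo, lag_hi).
    """
    out = []
    for e in cfg.effects:
        if e.weight == 0.0:
            continue
        cols = []
        for sigma_m, delay_m in bank_months:
            if max(e.lag_lo_months, delay_m) < min(e.lag_hi_months, delay_m + sigma_m):
                cols.append(f"{e.entity_class}:{e.code}|{family}|{sigma_m}|{delay_m}")
        out.append(
            {
                "entity_class": e.entity_class,
                "code": e.code,
                "lag_lo_months": e.lag_lo_months,
                "lag_hi_months": e.lag_hi_months,
                "weight": e.weight,
                "sign": "positive" if e.weight > 0 else "negative",
                "columns": cols,
            }
        )
    return {"effects": out}
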