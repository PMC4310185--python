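"""Elixhauser comorbidity flags from ICD-10 codes (Quan coding).

The 30 Elixhauser comorbidity indicators are the hand-crafted baseline
feature set against which the auto-extracted temporal features are
compared.  The bundled table maps each comorbidity to a set of ICD-10
code prefixes following Quan et al.'s coding algorithm, with the two
hypertension categories merged into one so that exactly 30 indicators
result.  Matching is prefix-based, case- and dot-insensitive.

By default the algorithm's hierarchy exclusions are applied:
complicated diabetes switches off uncomplicated diabetes, and
metastatic cancer switches off solid tumour without metastasis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import AssessmentPoint
from .schema import EventRecord, Timeline

logger = logging.getLogger("eventbank")

N_COMORBIDITIES = 30

_EXCLUSIONS = {
    # winner -> loser: if the first flag is set, clear the second
    "diabetes_complicated": "diabetes_uncomplicated",
    "metastatic_cancer": "solid_tumor_without_metastasis",
}


@dataclass(frozen=True)
class ComorbidityMap:
    """Ordered comorbidity -> ICD-10 prefix tuples (30 comorbidities)."""

    names: tuple[str, ...]
    prefixes: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.names) != N_COMORBIDITIES:
            raise ValueError(
                f"expected {N_COMORBIDITIES} comorbidities, got {len(self.names)}"
            )
        for name in self.names:
            if not self.prefixes.get(name):
                raise ValueError(f"comorbidity {name!r} has no code prefixes")


def load_comorbidity_map() -> ComorbidityMap:
    """Load the bundled Quan ICD-10 prefix table."""
    with resources.files("eventbank.data").joinpath(
        "quan_elixhauser_icd10.csv"
    ).open() as f:
        df = pd.read_csv(f, dtype=str)
    names = tuple(dict.fromkeys(df["comorbidity"]))
    prefixes = {
        name: tuple(df.loc[df["comorbidity"] == name, "icd10_prefix"])
        for name in names
    }
    return ComorbidityMap(names=names, prefixes=prefixes)


def normalize_icd10(code: str) -> str | None:
    """Uppercase, strip dots/whitespace; None if clearly malformed."""
    c = str(code).replace(".", "").replace(" ", "").upper()
    if len(c) < 2 or not c[0].isalpha() or not c[1].isdigit():
        return None
    return c


def map_codes(
    icd_codes: Iterable[str],
    cmap: ComorbidityMap,
    apply_exclusions: bool = True,
) -> np.ndarray:
    """30-dim binary vector of comorbidity flags for a code list.

    Malformed codes are ignored with a warning; flag order is the
    (fixed) order of ``cmap.names``.
    """
    flags = np.zeros(N_COMORBIDITIES, dtype=np.int8)
    normed = []
    for code in icd_codes:
        c = normalize_icd10(code)
        if c is None:
            logger.warning("ignoring malformed ICD-10 code %r", code)
            continue
        normed.append(c)
    for i, name in enumerate(cmap.names):
        pfx = cmap.prefixes[name]
        flags[i] = int(any(c.startswith(p) for c in normed for p in pfx))
    if apply_exclusions:
        idx = {name: i for i, name in enumerate(cmap.names)}
        for winner, loser in _EXCLUSIONS.items():
            if flags[idx[winner]]:
                flags[idx[loser]] = 0
    return flags


def comorbidity_features(
    patient_id: str,
    ap: AssessmentPoint,
    records: Sequence[EventRecord],
    lookback_months: int,
    timeline: Timeline,
    cmap: ComorbidityMap,
    diagnosis_class: str = "diagnosis",
    apply_exclusions: bool = True,
) -> np.ndarray:
    """Flags from all diagnosis codes within the lookback window.

    The window is [ap.time - lookback, ap.time] in units, closed at the
    AP end so the index stay's own codes count.
    """
    lb_units = timeline.months_to_units(lookback_months)
    codes = []
    for rec in records:
        if rec.patient_id != patient_id or rec.entity_class != diagnosis_class:
            continue
        u = timeline.index(rec.start)
        if ap.time - lb_units <= u <= ap.time:
            codes.append(rec.code)
    return map_codes(codes, cmap, apply_exclusions=apply_exclusions)
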