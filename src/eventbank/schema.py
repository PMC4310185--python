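"""Entity schema and event time series.

Hospital administrative data are modelled as timestamped *entities*:
an emergency visit, a hospital stay, a coded diagnosis, a dispensed
medication.  Entities are either *point* (instantaneous) or
*continuing* (span an interval, e.g. an admission episode).  Entity
types are organised in a tree so that events on a leaf code also count
toward every ancestor category.

A patient's history is discretised onto a :class:`Timeline` of units
1..T, and each (patient, entity) pair yields an :class:`EventSeries`
``E(t)`` counting occurrences per unit — the raw signals the filter
bank aggregates.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("eventbank")

POINT = "point"
CONTINUING = "continuing"

#: days per month used for all calendar-independent month arithmetic
DAYS_PER_MONTH = 30


class SchemaError(ValueError):
    """Malformed entity schema (unknown code, cycle, duplicate)."""


@dataclass(frozen=True)
class EntityType:
    """One node of the entity schema tree."""

    code: str
    entity_class: str
    kind: str = POINT
    parent_code: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (POINT, CONTINUING):
            raise SchemaError(f"unknown entity kind {self.kind!r}")


@dataclass
class EventRecord:
    """One timestamped occurrence of an entity for a patient."""

    patient_id: str
    code: str
    entity_class: str
    kind: str
    start: dt.date
    end: dt.date | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end is not None and self.end < self.start:
            raise ValueError(
                f"event end {self.end} precedes start {self.start} "
                f"({self.entity_class}:{self.code})"
            )


@dataclass(frozen=True)
class Timeline:
    """Discrete time axis: units 1..n_units of equal width from origin.

    ``unit`` is ``"day"`` or ``"month"``; a month is defined as exactly
    30 days so that index arithmetic is deterministic and
    calendar-independent.
    """

    unit: str
    origin: dt.date
    n_units: int

    def __post_init__(self) -> None:
        if self.unit not in ("day", "month"):
            raise ValueError(f"unknown time unit {self.unit!r}")
        if self.n_units < 1:
            raise ValueError("timeline must have at least one unit")

    @property
    def unit_days(self) -> int:
        return 1 if self.unit == "day" else DAYS_PER_MONTH

    def index(self, d: dt.date) -> int:
        """1-based index of the unit containing calendar date ``d``."""
        days = (d - self.origin).days
        if days < 0:
            raise ValueError(f"date {d} precedes timeline origin {self.origin}")
        return days // self.unit_days + 1

    def months_to_units(self, months: float) -> int:
        """Convert a duration in months to whole timeline units."""
        if self.unit == "month":
            return int(round(months))
        return int(round(months * DAYS_PER_MONTH))

    def date_of(self, index: int) -> dt.date:
        """First calendar date of the given 1-based unit index."""
        return self.origin + dt.timedelta(days=(index - 1) * self.unit_days)


def date_to_index(d: dt.date, timeline: Timeline) -> int:
    """1-based unit index of date ``d``; raises if ``d`` precedes origin."""
    return timeline.index(d)


@dataclass
class EventSeries:
    """Per-unit occurrence counts for one (patient, entity) pair."""

    patient_id: str
    entity_code: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("event counts must be non-negative")


class EntitySchema:
    """A set of entity types whose parent links form a forest."""

    def __init__(self, types: Iterable[EntityType] = ()):
        self._types: dict[tuple[str, str], EntityType] = {}
        for t in types:
            self.add(t)
        self.validate()

    def add(self, t: EntityType) -> None:
        key = (t.entity_class, t.code)
        if key in self._types:
            raise SchemaError(f"duplicate entity {t.entity_class}:{t.code}")
        self._types[key] = t

    def get(self, entity_class: str, code: str) -> EntityType:
        try:
            return self._types[(entity_class, code)]
        except KeyError:
            raise SchemaError(f"unknown entity {entity_class}:{code}") from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._types

    def __iter__(self):
        return iter(self._types.values())

    def __len__(self) -> int:
        return len(self._types)

    def validate(self) -> None:
        """Check that parent links resolve and contain no cycles."""
        for t in self._types.values():
            seen = {t.code}
            node = t
            while node.parent_code is not None:
                node = self.get(t.entity_class, node.parent_code)
                if node.code in seen:
                    raise SchemaError(
                        f"cycle in schema tree at {t.entity_class}:{node.code}"
                    )
                seen.add(node.code)

    def ancestors(self, entity_class: str, code: str) -> list[EntityType]:
        """Ancestor types from parent up to the root (may be empty)."""
        out: list[EntityType] = []
        node = self.get(entity_class, code)
        seen = {code}
        while node.parent_code is not None:
            node = self.get(entity_class, node.parent_code)
            if node.code in seen:  # pragma: no cover - validate() catches this
                raise SchemaError(f"cycle in schema tree at {node.code}")
            seen.add(node.code)
            out.append(node)
        return out

    # -- serialization ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "code": t.code,
                "class": t.entity_class,
                "kind": t.kind,
                "parent_code": t.parent_code or "",
            }
            for t in self._types.values()
        ]
        return pd.DataFrame(rows, columns=["code", "class", "kind", "parent_code"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EntitySchema":
        types = [
            EntityType(
                code=str(r["code"]),
                entity_class=str(r["class"]),
                kind=str(r["kind"]),
                parent_code=str(r["parent_code"]) or None
                if not pd.isna(r["parent_code"]) and str(r["parent_code"]) != ""
                else None,
            )
            for _, r in df.iterrows()
        ]
        return cls(types)


def expand_hierarchy(
    records: Iterable[EventRecord], schema: EntitySchema
) -> list[EventRecord]:
    """Duplicate every record onto each ancestor entity code.

    Parent-level series therefore aggregate their children's events.
    """
    out: list[EventRecord] = []
    for rec in records:
        out.append(rec)
        for anc in schema.ancestors(rec.entity_class, rec.code):
            out.append(
                dataclasses.replace(rec, code=anc.code, kind=anc.kind)
            )
    return out


def build_event_series(
    records: Iterable[EventRecord],
    entity_code: str,
    timeline: Timeline,
    *,
    entity_class: str | None = None,
    schema: EntitySchema | None = None,
) -> EventSeries:
    """Discretise one entity's events into per-unit counts.

    Point entities increment the unit containing their start date once
    per record; continuing entities increment every unit intersecting
    [start, end] (a missing end is treated as a single unit).  Events
    starting after the end of the timeline are dropped with a warning.
    """
    if schema is not None and entity_class is not None:
        schema.get(entity_class, entity_code)  # raises SchemaError if unknown
    recs = [
        r
        for r in records
        if r.code == entity_code
        and (entity_class is None or r.entity_class == entity_class)
    ]
    counts = np.zeros(timeline.n_units, dtype=np.int64)
    patient = recs[0].patient_id if recs else ""
    for r in recs:
        i = timeline.index(r.start)
        if i > timeline.n_units:
            logger.warning(
                "dropping event %s:%s at %s past timeline end",
                r.entity_class,
                r.code,
                r.start,
            )
            continue
        if r.kind == CONTINUING and r.end is not None:
            j = min(timeline.index(r.end), timeline.n_units)
            counts[i - 1 : j] += 1
        else:
            counts[i - 1] += 1
    return EventSeries(patient_id=patient, entity_code=entity_code, counts=counts)


# -- CSV interchange -----------------------------------------------------

_EVENT_COLUMNS = ["patient_id", "code", "class", "kind", "start_date", "end_date"]


def events_to_frame(records: Iterable[EventRecord]) -> pd.DataFrame:
    attr_keys: list[str] = []
    rows = []
    for r in records:
        for k in r.attrs:
            if k not in attr_keys:
                attr_keys.append(k)
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "code": r.code,
            "class": r.entity_class,
            "kind": r.kind,
            "start_date": r.start.isoformat(),
            "end_date": r.end.isoformat() if r.end is not None else "",
        }
        for k in attr_keys:
            row[k] = r.attrs.get(k, "")
        rows.append(row)
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS + attr_keys)


def frame_to_events(df: pd.DataFrame) -> list[EventRecord]:
    attr_cols = [c for c in df.columns if c not in _EVENT_COLUMNS]
    records = []
    for d in df.to_dict(orient="records"):
        end = d.get("end_date")
        end_date = (
            dt.date.fromisoformat(str(end))
            if end is not None and str(end) not in ("", "nan", "NaT")
            else None
        )
        attrs = {}
        for c in attr_cols:
            v = d[c]
            if v is not None and str(v) not in ("", "nan"):
                attrs[c] = str(v)
        records.append(
            EventRecord(
                patient_id=str(d["patient_id"]),
                code=str(d["code"]),
                entity_class=str(d["class"]),
                kind=str(d["kind"]),
                start=dt.date.fromisoformat(str(d["start_date"])),
                end=end_date,
                attrs=attrs,
            )
        )
    return records


def read_events_csv(path) -> list[EventRecord]:
    return frame_to_events(pd.read_csv(path, dtype=str, keep_default_na=False))


def write_events_csv(records: Iterable[EventRecord], path) -> None:
    events_to_frame(records).to_csv(path, index=False)


def read_schema_csv(path) -> EntitySchema:
    return EntitySchema.from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))


def write_schema_csv(schema: EntitySchema, path) -> None:
    schema.to_frame().to_csv(path, index=False)
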