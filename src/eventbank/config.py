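"""Run configuration: timeline, filter bank, vocabulary, cohort, model."""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .assembly import FEATURE_SETS
from .filterbank import DEFAULT_BANK_MONTHS
from .model_eval import ModelConfig
from .schema import Timeline
from .vocabulary import DEFAULT_MAX_SIZE, DEFAULT_MIN_COUNT

DEFAULT_HORIZONS = (1, 2, 3, 6, 12)


def _parse_date(v) -> dt.date:
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v))


@dataclass
class RunConfig:
    # timeline
    unit: str = "month"
    origin: dt.date = dt.date(2003, 1, 1)
    n_units: int = 96
    # filter bank: (sigma_months, delay_months) pairs (uniform family)
    bank_specs: tuple = DEFAULT_BANK_MONTHS
    bank_family: str = "uniform"
    # vocabulary heuristics
    min_count: int = DEFAULT_MIN_COUNT
    max_size: int = DEFAULT_MAX_SIZE
    # cohort
    disease_codes: tuple[str, ...] = ("E11",)
    horizons_months: tuple[int, ...] = DEFAULT_HORIZONS
    validation_date: dt.date = dt.date(2009, 1, 1)
    ap_mode: str = "discharge"
    unplanned_only: bool = True
    # features / model
    feature_sets: tuple[str, ...] = FEATURE_SETS
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 1

    def timeline(self) -> Timeline:
        return Timeline(unit=self.unit, origin=self.origin, n_units=self.n_units)

    def validation_unit(self) -> int:
        return self.timeline().index(self.validation_date)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["origin"] = self.origin.isoformat()
        d["validation_date"] = self.validation_date.isoformat()
        d["bank_specs"] = [list(s) for s in self.bank_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("sim", None)  # generator settings live in the same YAML
        if "origin" in d:
            d["origin"] = _parse_date(d["origin"])
        if "validation_date" in d:
            d["validation_date"] = _parse_date(d["validation_date"])
        if "bank_specs" in d:
            d["bank_specs"] = tuple(tuple(s) for s in d["bank_specs"])
        for key in ("disease_codes", "horizons_months", "feature_sets"):
            if key in d:
                d[key] = tuple(d[key])
        if "model" in d and isinstance(d["model"], dict):
            m = dict(d["model"])
            if "Cs" in m:
                m["Cs"] = tuple(m["Cs"])
            d["model"] = ModelConfig(**m)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()
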