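import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eventbank.schema import EventRecord, Timeline

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

ORIGIN = dt.date(2003, 1, 1)


@pytest.fixture
def month_timeline() -> Timeline:
    return Timeline(unit="month", origin=ORIGIN, n_units=96)


@pytest.fixture
def day_timeline() -> Timeline:
    return Timeline(unit="day", origin=ORIGIN, n_units=400)


def make_event(
    patient_id="P1",
    code="X",
    entity_class="diagnosis",
    kind="point",
    start_unit=1,
    end_unit=None,
    timeline=None,
    **attrs,
):
    """Event at given 1-based month-unit indices on the default timeline."""
    tl = timeline or Timeline(unit="month", origin=ORIGIN, n_units=96)
    end = tl.date_of(end_unit) if end_unit is not None else None
    return EventRecord(
        patient_id=patient_id,
        code=code,
        entity_class=entity_class,
        kind=kind,
        start=tl.date_of(start_unit),
        end=end,
        attrs={k: str(v) for k, v in attrs.items()},
    )


def make_admission(
    patient_id, start_unit, end_unit=None, emergency=1, diagnoses="", timeline=None
):
    return make_event(
        patient_id=patient_id,
        code="DRG01",
        entity_class="admission",
        kind="continuing",
        start_unit=start_unit,
        end_unit=end_unit if end_unit is not None else start_unit,
        timeline=timeline,
        emergency=emergency,
        diagnoses=diagnoses,
    )


@pytest.fixture(scope="session")
def cmap():
    from eventbank.elixhauser import load_comorbidity_map

    return load_comorbidity_map()
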