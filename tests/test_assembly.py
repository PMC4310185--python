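"""Feature-matrix assembly and the normalisation + sqrt transform."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from eventbank.assembly import (
    FeatureMatrix,
    SeriesStore,
    StaticEncoder,
    build_feature_set,
    fit_transform,
    static_features,
    temporal_block,
)
from eventbank.cohort import AssessmentPoint
from eventbank.filterbank import default_bank, extract_block

from conftest import ORIGIN, make_event


@pytest.fixture
def demo():
    return pd.DataFrame(
        {
            "patient_id": ["P1", "P2", "P3"],
            "birth_date": [
                (ORIGIN - dt.timedelta(days=int(30 * 365.25))).isoformat(),
                "1950-06-15",
                "1950-06-15",
            ],
            "gender": ["F", "M", "M"],
            "postcode": ["PC01", "PC01", "PC99"],
        }
    )


def small_store(month_timeline):
    recs = [
        make_event("P1", "E11", start_unit=10),
        make_event("P1", "N18", start_unit=40),
        make_event("P2", "E11", start_unit=12),
        make_event(
            "P2", "DRG01", entity_class="admission", kind="continuing",
            start_unit=12, end_unit=13,
        ),
        make_event("P3", "ED", entity_class="emergency", start_unit=50),
    ]
    return recs, SeriesStore.build(recs, month_timeline)


class TestFitTransform:
    def _matrix(self, values, names=None):
        n, p = values.shape
        aps = [AssessmentPoint(f"P{i}", 1) for i in range(n)]
        names = names or [f"c{j}" for j in range(p)]
        return FeatureMatrix("MR", names, values.astype(float), aps)

    def test_min_max_then_sqrt(self):
        m = self._matrix(np.array([[0.0], [4.0], [1.0]]))
        out, params = fit_transform(m, np.array([True, True, True]))
        assert out.values[2, 0] == pytest.approx(0.5)  # sqrt((1-0)/4)
        assert out.values[0, 0] == 0.0

    def test_constant_column_maps_to_zero(self):
        m = self._matrix(np.full((4, 1), 7.0))
        out, _ = fit_transform(m, np.ones(4, dtype=bool))
        assert (out.values == 0).all()

    def test_binary_columns_are_fixed_points(self):
        m = self._matrix(np.array([[0.0], [1.0], [1.0], [0.0]]))
        out, _ = fit_transform(m, np.ones(4, dtype=bool))
        assert (out.values == m.values).all()

    def test_validation_rows_never_influence_params(self):
        rng = np.random.default_rng(0)
        deriv = rng.normal(size=(10, 3))
        val_a = rng.normal(size=(5, 3)) * 10
        val_b = val_a[::-1] * 3 + 1
        mask = np.array([True] * 10 + [False] * 5)
        _, pa = fit_transform(self._matrix(np.vstack([deriv, val_a])), mask)
        _, pb = fit_transform(self._matrix(np.vstack([deriv, val_b])), mask)
        assert np.allclose(pa.mins, pb.mins) and np.allclose(pa.maxs, pb.maxs)

    def test_out_of_range_validation_values_clipped(self):
        m = self._matrix(np.array([[0.0], [1.0], [5.0], [-3.0]]))
        out, _ = fit_transform(m, np.array([True, True, False, False]))
        assert out.values[2, 0] == 1.0 and out.values[3, 0] == 0.0
        assert ((0 <= out.values) & (out.values <= 1)).all()

    def test_duplicate_column_names_rejected(self):
        with pytest.raises(ValueError):
            self._matrix(np.zeros((2, 2)), names=["a", "a"])


class TestStaticFeatures:
    def test_age_in_years_at_ap(self, demo, month_timeline):
        ap = AssessmentPoint("P1", 1)
        vec, names = static_features("P1", ap, demo, month_timeline)
        assert names[0] == "age"
        assert vec[0] == pytest.approx(30.0, abs=0.05)

    def test_gender_indicator(self, demo, month_timeline):
        enc = StaticEncoder(demo, pool_min=1).fit(
            [AssessmentPoint("P1", 1), AssessmentPoint("P2", 1)]
        )
        v1 = enc.encode(AssessmentPoint("P1", 1), month_timeline)
        v2 = enc.encode(AssessmentPoint("P2", 1), month_timeline)
        assert v1[1] == 1.0 and v2[1] == 0.0

    def test_unseen_postcode_encodes_all_zero(self, demo, month_timeline):
        enc = StaticEncoder(demo, pool_min=1).fit(
            [AssessmentPoint("P1", 1), AssessmentPoint("P2", 1)]
        )  # PC99 never seen in derivation
        v3 = enc.encode(AssessmentPoint("P3", 1), month_timeline)
        pc_part = v3[2:]
        assert pc_part.sum() == 0

    def test_identical_demographics_identical_vectors(self, demo, month_timeline):
        demo2 = demo.copy()
        demo2.loc[2, "postcode"] = "PC01"
        enc = StaticEncoder(demo2, pool_min=1).fit([AssessmentPoint("P2", 1)])
        v2 = enc.encode(AssessmentPoint("P2", 30), month_timeline)
        v3 = enc.encode(AssessmentPoint("P3", 30), month_timeline)
        assert (v2 == v3).all()

    def test_missing_patient_raises(self, demo, month_timeline):
        enc = StaticEncoder(demo, pool_min=1).fit([AssessmentPoint("P1", 1)])
        with pytest.raises(KeyError):
            enc.encode(AssessmentPoint("P9", 1), month_timeline)


class TestBuildFeatureSet:
    def test_mr_column_count_is_m_times_n_plus_demographics(
        self, demo, month_timeline, cmap
    ):
        recs, store = small_store(month_timeline)
        aps = [AssessmentPoint("P1", 50), AssessmentPoint("P2", 60)]
        m = build_feature_set(
            "MR", aps, store, default_bank(), demo, cmap, diagnosis_records=recs
        )
        n_demo = sum(
            1 for c in m.column_names if not ("|" in c or c.startswith("elix:"))
        )
        assert len(m.column_names) == store.M * 6 + n_demo

    def test_mr_comorbidities_adds_exactly_thirty_columns(
        self, demo, month_timeline, cmap
    ):
        recs, store = small_store(month_timeline)
        aps = [AssessmentPoint("P1", 50)]
        mr = build_feature_set(
            "MR", aps, store, default_bank(), demo, cmap, diagnosis_records=recs
        )
        mrc = build_feature_set(
            "MR_comorbidities", aps, store, default_bank(), demo, cmap,
            diagnosis_records=recs,
        )
        assert len(mrc.column_names) == len(mr.column_names) + 30

    def test_baseline_without_history_has_only_demographics(
        self, demo, month_timeline, cmap
    ):
        recs, store = small_store(month_timeline)
        aps = [AssessmentPoint("P3", 60)]  # P3 has no diagnosis history
        m = build_feature_set(
            "baseline_1M", aps, store, default_bank(), demo, cmap,
            diagnosis_records=recs,
        )
        elix = [j for j, c in enumerate(m.column_names) if c.startswith("elix:")]
        assert len(elix) == 30
        assert m.values[0, elix].sum() == 0
        assert m.values[0, m.column_names.index("age")] > 0

    def test_unknown_set_name_rejected(self, demo, month_timeline, cmap):
        recs, store = small_store(month_timeline)
        with pytest.raises(ValueError):
            build_feature_set(
                "bogus", [], store, default_bank(), demo, cmap, diagnosis_records=recs
            )

    def test_column_names_deterministic(self, demo, month_timeline, cmap):
        recs, store = small_store(month_timeline)
        aps = [AssessmentPoint("P1", 50)]
        a = build_feature_set(
            "MR", aps, store, default_bank(), demo, cmap, diagnosis_records=recs
        )
        b = build_feature_set(
            "MR", aps, store, default_bank(), demo, cmap, diagnosis_records=recs
        )
        assert a.column_names == b.column_names


def test_temporal_block_matches_series_level_extraction(month_timeline):
    recs, store = small_store(month_timeline)
    bank = default_bank()
    aps = [AssessmentPoint("P1", 50), AssessmentPoint("P2", 20), AssessmentPoint("P3", 60)]
    X, names = temporal_block(aps, store, bank)
    for i, ap in enumerate(aps):
        sset = [store.series(ap.patient_id, cls, code) for cls, code in store.keys]
        vec, block_names = extract_block(sset, bank, ap.time)
        assert np.allclose(X[i], vec, atol=1e-12)
    assert [n.split("|", 1)[0] for n in names] == [
        f"{cls}:{code}" for cls, code in store.keys for _ in range(6)
    ]
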