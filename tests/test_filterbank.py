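"""One-sided kernels and the convolution feature extractor."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from eventbank.filterbank import (
    DEFAULT_BANK_MONTHS,
    FilterBank,
    Kernel,
    default_bank,
    extract_block,
    extract_feature,
    gaussian_kernel_value,
    uniform_kernel_value,
)
from eventbank.schema import EventSeries


def series(counts):
    return EventSeries(patient_id="P1", entity_code="X", counts=np.asarray(counts))


def brute_force_feature(counts, kernel, t):
    """Independent oracle: literal evaluation of the defining sum."""
    return sum(
        kernel.value(h - kernel.delay) * counts[(t - h) - 1] for h in range(t)
    )


class TestUniformKernel:
    def test_value_inside_support(self):
        assert uniform_kernel_value(1, 3) == pytest.approx(1 / 3)

    def test_one_sided(self):
        assert uniform_kernel_value(-1, 3) == 0.0

    def test_half_open_support_and_unit_mass(self):
        assert uniform_kernel_value(3, 3) == 0.0
        assert sum(uniform_kernel_value(t, 3) for t in range(-5, 10)) == pytest.approx(1.0)

    @pytest.mark.parametrize("sigma", range(1, 37))
    def test_unit_mass_every_bandwidth(self, sigma):
        total = sum(uniform_kernel_value(t, sigma) for t in range(-1, sigma + 2))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            uniform_kernel_value(0, 0)


class TestGaussianKernel:
    def test_zero_at_origin_and_negative_offsets(self):
        assert gaussian_kernel_value(0, 3) == 0.0
        assert gaussian_kernel_value(-4, 3) == 0.0

    def test_closed_form_at_one_bandwidth(self):
        sigma = 2.5
        expected = math.sqrt(2 / (math.pi * sigma**2)) * math.exp(-0.5)
        assert gaussian_kernel_value(sigma, sigma) == pytest.approx(expected)

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 3.0, 12.0])
    def test_continuous_mass_is_one(self, sigma):
        total, _ = quad(lambda t: gaussian_kernel_value(t, sigma), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestExtractFeature:
    def test_zero_series_gives_zero_for_all_kernels(self):
        s = series([0] * 40)
        for k in default_bank():
            for t in (1, 10, 40):
                assert extract_feature(s, k, t) == 0.0

    def test_same_unit_event_contributes_h0_term(self):
        s = series([0] * 40)
        s.counts[19] = 1
        k = Kernel("uniform", 3, 0)
        assert extract_feature(s, k, 20) == pytest.approx(1 / 3)

    def test_delay_excludes_recent_event(self):
        s = series([0] * 40)
        s.counts[19] = 1
        k = Kernel("uniform", 12, 12)
        assert extract_feature(s, k, 20) == 0.0

    def test_out_of_range_point_rejected(self):
        with pytest.raises(IndexError):
            extract_feature(series([0] * 10), Kernel("uniform", 1, 0), 11)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        kernels = [Kernel("uniform", s, d) for s, d in DEFAULT_BANK_MONTHS]
        kernels += [Kernel("gaussian", 2.0, 0), Kernel("gaussian", 6.0, 3)]
        for _ in range(20):
            counts = rng.poisson(0.7, size=50)
            s = series(counts)
            for k in kernels:
                for t in range(1, 51, 7):
                    assert extract_feature(s, k, t) == pytest.approx(
                        brute_force_feature(counts, k, t), abs=1e-12
                    )

    def test_linearity(self):
        rng = np.random.default_rng(3)
        a, b = rng.poisson(1.0, 30), rng.poisson(1.0, 30)
        k = Kernel("uniform", 6, 3)
        for t in (5, 17, 30):
            assert extract_feature(series(a + b), k, t) == pytest.approx(
                extract_feature(series(a), k, t) + extract_feature(series(b), k, t)
            )

    def test_causality_future_counts_ignored(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(1.0, 40)
        t = 20
        tampered = counts.copy()
        tampered[t:] += 5
        for k in default_bank():
            assert extract_feature(series(counts), k, t) == extract_feature(
                series(tampered), k, t
            )

    def test_delay_window_is_blind_to_recent_units(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(1.0, 60)
        t, d = 50, 12
        k = Kernel("uniform", 12, d)
        tampered = counts.copy()
        tampered[t - d : t] += 7  # units (t-d, t]
        assert extract_feature(series(counts), k, t) == extract_feature(
            series(tampered), k, t
        )


class TestExtractBlock:
    def test_default_bank_has_six_kernels(self):
        bank = default_bank()
        assert len(bank) == 6
        values, names = extract_block([series([0] * 20)], bank, 10)
        assert len(values) == len(names) == 6

    def test_empty_series_set_gives_empty_vector(self):
        values, names = extract_block([], default_bank(), 5)
        assert values.size == 0 and names == []

    def test_cartesian_product_naming(self):
        bank = default_bank()
        sset = [
            EventSeries("P1", f"code{i}", np.zeros(20, dtype=int)) for i in range(7)
        ]
        values, names = extract_block(sset, bank, 10)
        assert len(values) == 42
        assert len(set(names)) == 42
        assert names[0] == "code0|uniform|1|0"
        assert names[6] == "code1|uniform|1|0"

    def test_mixed_timelines_rejected(self):
        sset = [series([0] * 20), EventSeries("P1", "Y", np.zeros(30, dtype=int))]
        with pytest.raises(ValueError):
            extract_block(sset, default_bank(), 5)


class TestFilterBank:
    def test_duplicate_kernels_rejected(self):
        with pytest.raises(ValueError):
            FilterBank((Kernel("uniform", 3, 0), Kernel("uniform", 3, 0)))

    def test_default_lookback_is_36_months(self):
        assert default_bank().max_lookback == 36

    def test_day_unit_conversion_scales_by_thirty(self):
        bank = FilterBank.from_month_specs([(1, 0), (12, 12)], "day")
        assert bank.kernels[0].sigma == 30
        assert bank.kernels[1].delay == 360
        # labels keep month values for stable column names
        assert bank.kernels[1].label == "uniform|12|12"
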