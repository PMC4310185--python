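"""One-sided multi-resolution filter bank.

Each kernel is a causal (one-sided) window of bandwidth sigma, optionally
shifted ``delay`` units into the past.  Convolving an event count series
E with a kernel K at an evaluation point t gives one temporal feature

    X(t) = sum_{h=0}^{t-1} K(h - delay) * E(t - h),

so a uniform kernel with bandwidth s and delay d reports the mean event
rate over the units (t-d-s, t-d].  With a bank of N kernels of different
bandwidths and delays, each event series yields N features capturing
recent activity at several time scales as well as activity in older
epochs (delayed windows), and M series yield M*N features per point.

The discrete uniform kernel uses half-open support [0, sigma) so that it
sums to exactly 1; the one-sided Gaussian is the closed form
sqrt(2/(pi*sigma^2)) * exp(-t^2 / (2*sigma^2)) for t > 0, which
integrates to 1 over (0, inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .schema import EventSeries, Timeline

UNIFORM = "uniform"
GAUSSIAN = "gaussian"

#: (bandwidth, delay) pairs in months of the default uniform bank
DEFAULT_BANK_MONTHS: tuple[tuple[int, int], ...] = (
    (1, 0),
    (3, 0),
    (6, 0),
    (12, 0),
    (12, 12),
    (12, 24),
)

#: truncation of the (infinite-support) Gaussian at this many bandwidths
_GAUSSIAN_SUPPORT_SIGMAS = 8.0


def uniform_kernel_value(t: int, sigma: float) -> float:
    """Uniform (rectangular) kernel: 1/sigma on 0 <= t < sigma, else 0."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 1.0 / sigma if 0 <= t < sigma else 0.0


def gaussian_kernel_value(t: float, sigma: float) -> float:
    """One-sided Gaussian kernel: positive offsets only."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if t <= 0:
        return 0.0
    return math.sqrt(2.0 / (math.pi * sigma**2)) * math.exp(-(t**2) / (2.0 * sigma**2))


@dataclass(frozen=True)
class Kernel:
    """A one-sided kernel: family, bandwidth and delay in timeline units.

    ``label`` names the kernel in feature columns; by convention it
    carries the bandwidth/delay in months regardless of the timeline
    unit, so column names are stable across day/month discretisations.
    """

    family: str
    sigma: float
    delay: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.family not in (UNIFORM, GAUSSIAN):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.family}|{_fmt(self.sigma)}|{self.delay}"
            )

    def value(self, t: float) -> float:
        if self.family == UNIFORM:
            return uniform_kernel_value(t, self.sigma)
        return gaussian_kernel_value(t, self.sigma)

    @property
    def support_end(self) -> int:
        """Smallest L such that K(h - delay) = 0 for every h >= L."""
        if self.family == UNIFORM:
            return self.delay + int(math.ceil(self.sigma))
        return self.delay + int(math.ceil(_GAUSSIAN_SUPPORT_SIGMAS * self.sigma)) + 1

    def weights(self, length: int) -> np.ndarray:
        """K(h - delay) for h = 0..length-1."""
        h = np.arange(length, dtype=float) - self.delay
        if self.family == UNIFORM:
            w = np.where((h >= 0) & (h < self.sigma), 1.0 / self.sigma, 0.0)
        else:
            w = np.where(
                h > 0,
                math.sqrt(2.0 / (math.pi * self.sigma**2))
                * np.exp(-(h**2) / (2.0 * self.sigma**2)),
                0.0,
            )
        return w


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


@dataclass(frozen=True)
class FilterBank:
    """An ordered set of one-sided kernels."""

    kernels: tuple[Kernel, ...]

    def __post_init__(self) -> None:
        if len(self.kernels) < 1:
            raise ValueError("filter bank must contain at least one kernel")
        triples = [(k.family, k.sigma, k.delay) for k in self.kernels]
        if len(set(triples)) != len(triples):
            raise ValueError("duplicate (family, sigma, delay) in filter bank")

    def __len__(self) -> int:
        return len(self.kernels)

    def __iter__(self):
        return iter(self.kernels)

    @property
    def max_lookback(self) -> int:
        """Units of history any kernel in the bank can reach."""
        return max(k.support_end for k in self.kernels)

    def weight_matrix(self, length: int) -> np.ndarray:
        """(N, length) matrix of kernel weights K_i(h - delay_i)."""
        return np.vstack([k.weights(length) for k in self.kernels])

    @classmethod
    def from_month_specs(
        cls,
        specs: Sequence[tuple] | None = None,
        timeline_unit: str = "month",
        family: str = UNIFORM,
    ) -> "FilterBank":
        """Build a bank from (sigma_months, delay_months) pairs.

        Bandwidths/delays are converted to timeline units (a month is 30
        days when the unit is ``day``); labels keep the month values.
        Entries may also be (family, sigma_months, delay_months) triples
        or mappings with keys family/sigma_months/delay_months.
        """
        if specs is None:
            specs = DEFAULT_BANK_MONTHS
        scale = 1 if timeline_unit == "month" else 30
        kernels = []
        for spec in specs:
            if isinstance(spec, dict):
                fam = spec.get("family", family)
                s_m, d_m = spec["sigma_months"], spec.get("delay_months", 0)
            elif len(spec) == 3:
                fam, s_m, d_m = spec
            else:
                fam = family
                s_m, d_m = spec
            kernels.append(
                Kernel(
                    family=fam,
                    sigma=float(s_m) * scale,
                    delay=int(d_m) * scale,
                    label=f"{fam}|{_fmt(s_m)}|{_fmt(d_m)}",
                )
            )
        return cls(kernels=tuple(kernels))


def default_bank(timeline_unit: str = "month") -> FilterBank:
    return FilterBank.from_month_specs(None, timeline_unit)


def extract_feature(series: EventSeries, kernel: Kernel, t: int) -> float:
    """Temporal feature X(t) = sum_{h=0}^{t-1} K(h - delay) E(t - h)."""
    counts = series.counts
    if not 1 <= t <= len(counts):
        raise IndexError(f"evaluation point {t} outside series of length {len(counts)}")
    length = min(t, kernel.support_end)
    if length <= 0:
        return 0.0
    w = kernel.weights(length)
    # E(t - h) for h = 0..length-1 is counts[t-1], counts[t-2], ...
    hist = counts[t - length : t][::-1]
    return float(w @ hist)


def extract_block(
    series_set: Sequence[EventSeries], bank: FilterBank, t: int
) -> tuple[np.ndarray, list[str]]:
    """All M*N temporal features at point t, with deterministic names.

    Ordering is series-major: all kernels of series 1, then series 2,
    etc.  Names follow ``<entity_code>|<family>|<sigma>|<delay>``; the
    caller typically prefixes codes with their entity class.
    """
    lengths = {len(s.counts) for s in series_set}
    if len(lengths) > 1:
        raise ValueError("all series must share one timeline length")
    names = [f"{s.entity_code}|{k.label}" for s in series_set for k in bank]
    if not series_set:
        return np.zeros(0), names
    T = lengths.pop()
    if not 1 <= t <= T:
        raise IndexError(f"evaluation point {t} outside timeline of length {T}")
    length = min(t, bank.max_lookback)
    W = bank.weight_matrix(length)  # (N, length)
    hist = np.vstack([s.counts[t - length : t][::-1] for s in series_set])  # (M, length)
    block = hist @ W.T  # (M, N)
    return block.reshape(-1), names


def block_features_at(
    counts_matrix: np.ndarray, bank: FilterBank, t: int
) -> np.ndarray:
    """Vectorised extract_block for a dense (M, T) count matrix.

    Returns the flattened (M*N,) feature vector in series-major order.
    Used by the feature-assembly layer; semantics are identical to
    :func:`extract_block` on the corresponding EventSeries list.
    """
    M, T = counts_matrix.shape
    if not 1 <= t <= T:
        raise IndexError(f"evaluation point {t} outside timeline of length {T}")
    length = min(t, bank.max_lookback)
    W = bank.weight_matrix(length)
    hist = counts_matrix[:, t - length : t][:, ::-1]
    return (hist @ W.T).reshape(-1)
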