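"""Vocabulary control: rare-event pooling and per-class dictionary caps.

The number of event series M is kept manageable with two heuristics:
codes occurring fewer than ``min_count`` times are pooled into one
reserved rare pseudo-code per entity class, and at most ``max_size``
codes per class are retained (the most frequent ones), the rest being
pooled likewise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .schema import EventRecord

DEFAULT_MIN_COUNT = 50
DEFAULT_MAX_SIZE = 2000

_RARE_PREFIX = "__rare__"


def rare_code_for(entity_class: str) -> str:
    return f"{_RARE_PREFIX}{entity_class}"


@dataclass
class Vocabulary:
    """Retained codes per entity class, plus a rare pool per class."""

    retained: dict[str, list[str]]
    counts: dict[str, dict[str, int]]
    min_count: int = DEFAULT_MIN_COUNT
    max_size: int = DEFAULT_MAX_SIZE

    def __post_init__(self) -> None:
        for cls, codes in self.retained.items():
            if len(codes) != len(set(codes)):
                raise ValueError(f"duplicate retained codes in class {cls!r}")
            if len(codes) > self.max_size:
                raise ValueError(f"class {cls!r} exceeds max_size")
            if rare_code_for(cls) in codes:
                raise ValueError("rare pseudo-code collides with a real code")

    def rare_code(self, entity_class: str) -> str:
        return rare_code_for(entity_class)

    def classes(self) -> list[str]:
        return sorted(self.retained)

    def map_code(self, entity_class: str, code: str) -> str:
        if code in self._retained_sets[entity_class]:
            return code
        return self.rare_code(entity_class)

    @property
    def _retained_sets(self) -> dict[str, set[str]]:
        sets = getattr(self, "_cached_sets", None)
        if sets is None:
            sets = {c: set(v) for c, v in self.retained.items()}
            object.__setattr__(self, "_cached_sets", sets)
        return sets

    # -- serialization ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.classes():
            kept = set(self.retained[cls])
            ranked = sorted(
                self.counts[cls].items(), key=lambda kv: (-kv[1], kv[0])
            )
            for rank, (code, n) in enumerate(ranked, start=1):
                rows.append(
                    {
                        "class": cls,
                        "code": code,
                        "rank": rank,
                        "count": n,
                        "retained": int(code in kept),
                    }
                )
        return pd.DataFrame(rows, columns=["class", "code", "rank", "count", "retained"])

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, min_count: int = DEFAULT_MIN_COUNT,
        max_size: int = DEFAULT_MAX_SIZE,
    ) -> "Vocabulary":
        retained: dict[str, list[str]] = {}
        counts: dict[str, dict[str, int]] = {}
        for c, grp in df.groupby("class", sort=True):
            grp = grp.sort_values("rank")
            retained[str(c)] = [str(r.code) for r in grp.itertuples() if int(r.retained)]
            counts[str(c)] = {str(r.code): int(r.count) for r in grp.itertuples()}
        return cls(retained=retained, counts=counts, min_count=min_count, max_size=max_size)


def build_vocabulary(
    records: Iterable[EventRecord],
    min_count: int = DEFAULT_MIN_COUNT,
    max_size: int = DEFAULT_MAX_SIZE,
) -> Vocabulary:
    """Rank codes per class by frequency; retain frequent ones.

    A code is retained iff it occurs at least ``min_count`` times and
    ranks within the top ``max_size`` of its class.  Ties at the rank
    boundary are broken lexicographically on the code, so output is
    deterministic.
    """
    if min_count < 1 or max_size < 1:
        raise ValueError("min_count and max_size must be >= 1")
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        cls_counts = counts.setdefault(r.entity_class, {})
        cls_counts[r.code] = cls_counts.get(r.code, 0) + 1
    retained: dict[str, list[str]] = {}
    for cls, cc in counts.items():
        frequent = [(code, n) for code, n in cc.items() if n >= min_count]
        frequent.sort(key=lambda kv: (-kv[1], kv[0]))
        retained[cls] = [code for code, _ in frequent[:max_size]]
    return Vocabulary(retained=retained, counts=counts, min_count=min_count, max_size=max_size)


def apply_vocabulary(
    records: Iterable[EventRecord], vocab: Vocabulary
) -> list[EventRecord]:
    """Rewrite non-retained codes to their class's rare pseudo-code.

    Record count (total and per class) is conserved.
    """
    out = []
    for r in records:
        if r.entity_class not in vocab.retained:
            # class unseen when the vocabulary was built: everything rare
            out.append(dataclasses.replace(r, code=rare_code_for(r.entity_class)))
            continue
        mapped = vocab.map_code(r.entity_class, r.code)
        out.append(r if mapped == r.code else dataclasses.replace(r, code=mapped))
    return out
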