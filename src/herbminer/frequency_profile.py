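"""Herb usage frequencies and property/taste/meridian profiles.

Percentages are displayed at two decimals, rounded half away from zero.
Attribute percentages share a single denominator: the total number of herb
occurrences across the corpus (equal to the sum of the property-section
counts, since each herb carries exactly one property).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping

import pandas as pd

from .corpus_io import HerbAttributeTable, PrescriptionCorpus
from .errors import EmptyCorpusError, UnknownAttributeError

__all__ = [
    "FrequencyRow",
    "FrequencyTable",
    "AttributeProfile",
    "round2",
    "herb_frequency",
    "herbs_above",
    "attribute_profile",
]


def round2(x: float) -> float:
    """Round a non-negative finite value half-away-from-zero at 2 decimals."""
    if not (x >= 0):
        raise ValueError(f"round2 expects a finite non-negative value, got {x!r}")
    return float(Decimal(x).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FrequencyRow:
    herb: str
    count: int
    percentage: float


@dataclass
class FrequencyTable:
    """Per-herb case counts, sorted count-descending (ties: herb name)."""

    rows: list[FrequencyRow]
    n_cases: int

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], n_cases: int) -> "FrequencyTable":
        if n_cases <= 0:
            raise EmptyCorpusError("frequency table needs n_cases > 0")
        rows = []
        for herb, count in counts.items():
            if not 0 < count <= n_cases:
                raise ValueError(f"herb {herb!r}: count {count} outside (0, {n_cases}]")
            rows.append(FrequencyRow(herb, count, round2(100.0 * count / n_cases)))
        rows.sort(key=lambda r: (-r.count, r.herb))
        return cls(rows, n_cases)

    @property
    def herbs(self) -> list[str]:
        return [row.herb for row in self.rows]

    def count_of(self, herb: str) -> int:
        for row in self.rows:
            if row.herb == herb:
                return row.count
        raise KeyError(herb)

    def percentage_of(self, herb: str) -> float:
        for row in self.rows:
            if row.herb == herb:
                return row.percentage
        raise KeyError(herb)

    def top(self, m: int) -> list[str]:
        if m < 1:
            raise ValueError("top m must be >= 1")
        return self.herbs[:m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "herb": [r.herb for r in self.rows],
                "frequency": [r.count for r in self.rows],
                "percentage": [r.percentage for r in self.rows],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def herb_frequency(corpus: PrescriptionCorpus) -> FrequencyTable:
    """Count, per herb, the number of cases containing it."""
    if corpus.n_cases == 0:
        raise EmptyCorpusError("cannot profile an empty corpus")
    counts: Counter[str] = Counter()
    for case in corpus:
        counts.update(case.herbs)
    return FrequencyTable.from_counts(counts, corpus.n_cases)


def herbs_above(
    table: FrequencyTable,
    threshold: float,
    mode: Literal["count", "percentage"] = "count",
) -> list[str]:
    """Herbs strictly above a count or percentage threshold, table order kept."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if not table.rows:
        raise ValueError("frequency table is empty")
    if mode == "count":
        return [r.herb for r in table.rows if r.count > threshold]
    if mode == "percentage":
        return [r.herb for r in table.rows if r.percentage > threshold]
    raise ValueError(f"mode must be 'count' or 'percentage', got {mode!r}")


@dataclass
class AttributeProfile:
    """Weighted property/taste/meridian counts over all herb occurrences.

    ``total_occurrences`` (the property-count sum) is the shared percentage
    denominator for all three sections; taste and meridian counts may exceed
    it because those attributes are multi-valued.
    """

    properties: list[tuple[str, int, float]]
    tastes: list[tuple[str, int, float]]
    meridians: list[tuple[str, int, float]]
    total_occurrences: int

    @classmethod
    def from_counts(
        cls,
        property_counts: Mapping[str, int],
        taste_counts: Mapping[str, int],
        meridian_counts: Mapping[str, int],
    ) -> "AttributeProfile":
        total = sum(property_counts.values())
        if total <= 0:
            raise ValueError("property counts must sum to a positive total")

        def section(counts: Mapping[str, int]) -> list[tuple[str, int, float]]:
            rows = [
                (cat, n, round2(100.0 * n / total)) for cat, n in counts.items() if n > 0
            ]
            rows.sort(key=lambda r: (-r[1], r[0]))
            return rows

        return cls(
            properties=section(property_counts),
            tastes=section(taste_counts),
            meridians=section(meridian_counts),
            total_occurrences=total,
        )

    def percentage_of(self, section: str, category: str) -> float:
        for cat, _, pct in getattr(self, section):
            if cat == category:
                return pct
        raise KeyError((section, category))

    def to_frame(self) -> pd.DataFrame:
        records = []
        for name in ("properties", "tastes", "meridians"):
            for cat, n, pct in getattr(self, name):
                records.append(
                    {"section": name, "category": cat, "frequency": n, "percentage": pct}
                )
        return pd.DataFrame.from_records(
            records, columns=["section", "category", "frequency", "percentage"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def attribute_profile(
    corpus: PrescriptionCorpus, attrs: HerbAttributeTable
) -> AttributeProfile:
    """Weighted attribute counts: one contribution per (case, herb) occurrence."""
    if corpus.n_cases == 0:
        raise EmptyCorpusError("cannot profile an empty corpus")
    property_counts: Counter[str] = Counter()
    taste_counts: Counter[str] = Counter()
    meridian_counts: Counter[str] = Counter()
    for case in corpus:
        for herb in case.herbs:
            if herb not in attrs.property_of:
                raise UnknownAttributeError(herb)
            property_counts[attrs.property_of[herb]] += 1
            taste_counts.update(attrs.tastes_of[herb])
            meridian_counts.update(attrs.meridians_of[herb])
    return AttributeProfile.from_counts(property_counts, taste_counts, meridian_counts)
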