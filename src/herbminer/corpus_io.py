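"""Prescription-corpus input/output.

Reads, standardizes, deduplicates, filters and writes clinical prescription
corpora and herb attribute dictionaries.  File schemas:

* Prescriptions CSV: header ``case_id,patient_id,herbs,syndromes``; the
  ``herbs`` and ``syndromes`` fields are ``;``-separated; empty
  ``patient_id``/``syndromes`` are allowed.  The equivalent JSON format is a
  list of objects with the same keys, herbs/syndromes as arrays.
* Herb attribute CSV: header ``herb,property,tastes,meridians`` with
  ``;``-separated multi-valued fields.
* Synonym map CSV: header ``raw,canonical``.

Canonical herb names are hyphenated pinyin forms ("Gan-cao", "Huang-qi", ...);
matching is case-sensitive after trimming surrounding whitespace.
"""

from __future__ import annotations

import csv
import json
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

from .errors import CorpusParseError, UnknownHerbError

__all__ = [
    "Prescription",
    "PrescriptionCorpus",
    "SynonymMap",
    "HerbAttributeTable",
    "PROPERTY_CATEGORIES",
    "TASTE_CATEGORIES",
    "MERIDIAN_CATEGORIES",
    "standardize_names",
    "load_corpus",
    "write_corpus",
    "deduplicate_first_prescription",
    "filter_by_syndromes",
]

PROPERTY_CATEGORIES = ("Warm", "Cold", "Mild", "Cool", "Hot")
TASTE_CATEGORIES = ("Pungent", "Bitter", "Sweet", "Mild", "Puckery", "Sour", "Salty")
MERIDIAN_CATEGORIES = (
    "Heart",
    "Liver",
    "Spleen",
    "Lung",
    "Stomach",
    "Kidney",
    "Large Intestine",
    "Gallbladder",
    "Bladder",
    "Pericardium",
    "Tri-jiao",
    "Small Intestine",
)


@dataclass(frozen=True)
class Prescription:
    """One clinical case: an herb set plus optional syndrome tags.

    ``patient_id`` links follow-up records of the same patient so that the
    first-prescription rule can collapse them; it may be ``None``.
    """

    case_id: str
    herbs: frozenset[str]
    syndromes: frozenset[str] = frozenset()
    patient_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "herbs", frozenset(self.herbs))
        object.__setattr__(self, "syndromes", frozenset(self.syndromes))
        if not self.herbs:
            raise ValueError(f"case {self.case_id!r}: herb set must be non-empty")


@dataclass
class PrescriptionCorpus:
    """Ordered collection of prescriptions with derived vocabulary."""

    cases: list[Prescription]

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def vocabulary(self) -> frozenset[str]:
        vocab: set[str] = set()
        for case in self.cases:
            vocab |= case.herbs
        return frozenset(vocab)

    def __iter__(self):
        return iter(self.cases)

    def __len__(self) -> int:
        return len(self.cases)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PrescriptionCorpus):
            return NotImplemented
        return self.cases == other.cases


@dataclass
class SynonymMap:
    """Raw-name to canonical-name mapping, idempotently closed.

    Every canonical name (any value of ``mapping`` plus the explicit
    ``canonical`` set) maps to itself.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    canonical: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        closed = dict(self.mapping)
        names = set(self.canonical) | set(self.mapping.values())
        for name in names:
            closed.setdefault(name, name)
        self.mapping = closed
        self.canonical = frozenset(names)

    def resolve(self, raw: str) -> str:
        name = raw.strip()
        try:
            return self.mapping[name]
        except KeyError:
            raise UnknownHerbError(name) from None

    @classmethod
    def from_csv(cls, path: str | Path, canonical: Iterable[str] = ()) -> "SynonymMap":
        mapping: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or {"raw", "canonical"} - set(reader.fieldnames):
                raise CorpusParseError("synonym map must have columns raw,canonical")
            for record in reader:
                mapping[record["raw"].strip()] = record["canonical"].strip()
        return cls(mapping=mapping, canonical=frozenset(canonical))


def standardize_names(raw_herbs: Iterable[str], synonym_map: SynonymMap) -> list[str]:
    """Map raw herb names to canonical ones, preserving order.

    Raises :class:`UnknownHerbError` for any name that is neither mapped nor
    already canonical.  Duplicates after mapping are kept; downstream set
    construction collapses them.
    """
    return [synonym_map.resolve(raw) for raw in raw_herbs]


@dataclass
class HerbAttributeTable:
    """Per-herb property (one of five), tastes and meridians (non-empty sets)."""

    property_of: dict[str, str]
    tastes_of: dict[str, frozenset[str]]
    meridians_of: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for herb, prop in self.property_of.items():
            if prop not in PROPERTY_CATEGORIES:
                raise ValueError(f"herb {herb!r}: unknown property {prop!r}")
        for herb, tastes in self.tastes_of.items():
            if not tastes:
                raise ValueError(f"herb {herb!r}: tastes must be non-empty")
            unknown = set(tastes) - set(TASTE_CATEGORIES)
            if unknown:
                raise ValueError(f"herb {herb!r}: unknown tastes {sorted(unknown)}")
        for herb, meridians in self.meridians_of.items():
            if not meridians:
                raise ValueError(f"herb {herb!r}: meridians must be non-empty")
            unknown = set(meridians) - set(MERIDIAN_CATEGORIES)
            if unknown:
                raise ValueError(f"herb {herb!r}: unknown meridians {sorted(unknown)}")

    def herbs(self) -> frozenset[str]:
        return frozenset(self.property_of)

    @classmethod
    def from_csv(cls, path: str | Path) -> "HerbAttributeTable":
        property_of: dict[str, str] = {}
        tastes_of: dict[str, frozenset[str]] = {}
        meridians_of: dict[str, frozenset[str]] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            expected = {"herb", "property", "tastes", "meridians"}
            if reader.fieldnames is None or expected - set(reader.fieldnames):
                raise CorpusParseError(
                    "attribute table must have columns herb,property,tastes,meridians"
                )
            for i, record in enumerate(reader, start=2):
                herb = record["herb"].strip()
                if not herb:
                    raise CorpusParseError("empty herb name", row=i)
                property_of[herb] = record["property"].strip()
                tastes_of[herb] = frozenset(_split_multi(record["tastes"]))
                meridians_of[herb] = frozenset(_split_multi(record["meridians"]))
        return cls(property_of, tastes_of, meridians_of)


def _split_multi(value: str | None) -> list[str]:
    if not value:
        return []
    return [part.strip() for part in value.split(";") if part.strip()]


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"unsupported corpus format: {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    return "json" if suffix == ".json" else "csv"


def load_corpus(
    path: str | Path,
    fmt: str | None = None,
    synonym_map: SynonymMap | None = None,
) -> PrescriptionCorpus:
    """Load a prescription corpus from CSV or JSON.

    Herb names are standardized through ``synonym_map`` when one is given.
    Malformed rows (missing case_id, empty herb list) raise
    :class:`CorpusParseError` with the offending row number.
    """
    fmt = _infer_format(path, fmt)
    cases: list[Prescription] = []
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            expected = {"case_id", "patient_id", "herbs", "syndromes"}
            if reader.fieldnames is None or expected - set(reader.fieldnames):
                raise CorpusParseError(
                    "corpus CSV must have columns case_id,patient_id,herbs,syndromes"
                )
            for i, record in enumerate(reader, start=2):
                cases.append(
                    _build_case(
                        case_id=record["case_id"],
                        patient_id=record["patient_id"],
                        herbs=_split_multi(record["herbs"]),
                        syndromes=_split_multi(record["syndromes"]),
                        row=i,
                        synonym_map=synonym_map,
                    )
                )
    else:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if not isinstance(payload, list):
            raise CorpusParseError("corpus JSON must be a list of case objects")
        for i, record in enumerate(payload, start=1):
            cases.append(
                _build_case(
                    case_id=record.get("case_id"),
                    patient_id=record.get("patient_id"),
                    herbs=list(record.get("herbs") or []),
                    syndromes=list(record.get("syndromes") or []),
                    row=i,
                    synonym_map=synonym_map,
                )
            )
    return PrescriptionCorpus(cases)


def _build_case(
    case_id,
    patient_id,
    herbs: list[str],
    syndromes: list[str],
    row: int,
    synonym_map: SynonymMap | None,
) -> Prescription:
    case_id = (case_id or "").strip() if isinstance(case_id, str) else case_id
    if not case_id:
        raise CorpusParseError("missing case_id", row=row)
    if not herbs:
        raise CorpusParseError(f"case {case_id!r}: empty herb list", row=row)
    if synonym_map is not None:
        herbs = standardize_names(herbs, synonym_map)
    else:
        herbs = [h.strip() for h in herbs]
    patient = (patient_id or "").strip() or None if isinstance(patient_id, str) else patient_id
    return Prescription(
        case_id=str(case_id),
        herbs=frozenset(herbs),
        syndromes=frozenset(s.strip() for s in syndromes),
        patient_id=patient,
    )


def write_corpus(corpus: PrescriptionCorpus, path: str | Path, fmt: str | None = None) -> None:
    """Write a corpus back out; round-trips exactly through :func:`load_corpus`."""
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["case_id", "patient_id", "herbs", "syndromes"])
            for case in corpus:
                writer.writerow(
                    [
                        case.case_id,
                        case.patient_id or "",
                        ";".join(sorted(case.herbs)),
                        ";".join(sorted(case.syndromes)),
                    ]
                )
    else:
        payload = [
            {
                "case_id": case.case_id,
                "patient_id": case.patient_id,
                "herbs": sorted(case.herbs),
                "syndromes": sorted(case.syndromes),
            }
            for case in corpus
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False, indent=1)
            fh.write("\n")


def deduplicate_first_prescription(corpus: PrescriptionCorpus) -> PrescriptionCorpus:
    """Keep only each patient's first prescription and drop repeated cases.

    For every ``patient_id`` the earliest case in input order is retained.
    Cases without a patient id are retained unless their (patient, herb-set)
    pair exactly repeats an earlier case.  Idempotent.
    """
    seen_patients: set[str] = set()
    seen_exact: set[tuple[str | None, frozenset[str]]] = set()
    kept: list[Prescription] = []
    for case in corpus:
        if case.patient_id is not None:
            if case.patient_id in seen_patients:
                continue
            seen_patients.add(case.patient_id)
        key = (case.patient_id, case.herbs)
        if key in seen_exact:
            continue
        seen_exact.add(key)
        kept.append(case)
    return PrescriptionCorpus(kept)


def filter_by_syndromes(
    corpus: PrescriptionCorpus, required: Iterable[str]
) -> PrescriptionCorpus:
    """Sub-corpus of cases tagged with *every* required syndrome, order kept."""
    required = frozenset(required)
    if not required:
        raise ValueError("required syndrome set must be non-empty")
    return PrescriptionCorpus([c for c in corpus if required <= c.syndromes])


def attribute_table_to_rows(attrs: HerbAttributeTable) -> list[dict[str, str]]:
    """Flatten an attribute table to CSV-schema rows (herb sorted order)."""
    rows = []
    for herb in sorted(attrs.property_of):
        rows.append(
            {
                "herb": herb,
                "property": attrs.property_of[herb],
                "tastes": ";".join(sorted(attrs.tastes_of[herb])),
                "meridians": ";".join(sorted(attrs.meridians_of[herb])),
            }
        )
    return rows


def write_attribute_table(attrs: HerbAttributeTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=["herb", "property", "tastes", "meridians"])
        writer.writeheader()
        writer.writerows(attribute_table_to_rows(attrs))


def corpus_from_mapping(records: Iterable[Mapping]) -> PrescriptionCorpus:
    """Build a corpus from in-memory dicts (same keys as the JSON schema)."""
    cases = [
        Prescription(
            case_id=str(rec["case_id"]),
            herbs=frozenset(rec["herbs"]),
            syndromes=frozenset(rec.get("syndromes") or ()),
            patient_id=rec.get("patient_id"),
        )
        for rec in records
    ]
    return PrescriptionCorpus(cases)
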