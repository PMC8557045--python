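"""Synthetic prescription-corpus generator with planted herb combinations.

Each case draws at most one template prescription (mixture by weight;
residual mass means no template), includes each template herb independently
with the template's inclusion probability, and adds background herbs
independently at their marginal probabilities.  Empty draws are redrawn so
every case is non-empty (a small bias at tiny probabilities, ignored since
test configs keep expected case sizes >= 3).  Expected itemset supports stay
in closed form, so mining results can be checked against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .corpus_io import Prescription, PrescriptionCorpus
from .errors import DegenerateConfigError
from .frequency_profile import FrequencyTable

__all__ = [
    "TemplateSpec",
    "SyndromeRule",
    "SimConfig",
    "generate_corpus",
    "calibrate_marginals",
    "planted_truth",
    "exact_marginal_corpus",
]


@dataclass(frozen=True)
class TemplateSpec:
    """A planted herb combination drawn with ``weight`` per case."""

    herbs: tuple[str, ...]
    weight: float
    inclusion_prob: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "herbs", tuple(sorted(set(self.herbs))))
        if not self.herbs:
            raise ValueError("template herb set must be non-empty")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError(f"template weight outside (0, 1]: {self.weight}")
        if not 0.0 < self.inclusion_prob <= 1.0:
            raise ValueError(f"inclusion_prob outside (0, 1]: {self.inclusion_prob}")


@dataclass(frozen=True)
class SyndromeRule:
    tags: frozenset[str]
    prob: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tags", frozenset(self.tags))
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"syndrome tag probability outside [0, 1]: {self.prob}")


@dataclass
class SimConfig:
    n_cases: int = 715
    templates: list[TemplateSpec] = field(default_factory=list)
    background_probs: dict[str, float] = field(default_factory=dict)
    syndrome_rules: dict[int, SyndromeRule] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError(f"n_cases must be >= 1, got {self.n_cases}")
        total_weight = sum(t.weight for t in self.templates)
        if total_weight > 1.0 + 1e-9:
            raise ValueError(f"template weights sum to {total_weight} > 1")
        for herb, p in self.background_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"background prob for {herb!r} outside [0, 1]: {p}")
        for idx in self.syndrome_rules:
            if not 0 <= idx < len(self.templates):
                raise ValueError(f"syndrome rule for missing template index {idx}")
        can_draw = any(p > 0 for p in self.background_probs.values()) or bool(
            self.templates
        )
        if not can_draw:
            raise DegenerateConfigError("no herb can ever be drawn under this config")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "seed": self.seed,
            "templates": [
                {
                    "herbs": list(t.herbs),
                    "weight": t.weight,
                    "inclusion_prob": t.inclusion_prob,
                }
                for t in self.templates
            ],
            "background_probs": dict(sorted(self.background_probs.items())),
            "syndrome_rules": {
                str(idx): {"tags": sorted(rule.tags), "prob": rule.prob}
                for idx, rule in sorted(self.syndrome_rules.items())
            },
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SimConfig":
        templates = [
            TemplateSpec(
                herbs=tuple(t["herbs"]),
                weight=float(t["weight"]),
                inclusion_prob=float(t.get("inclusion_prob", 1.0)),
            )
            for t in payload.get("templates", [])
        ]
        rules = {
            int(idx): SyndromeRule(
                tags=frozenset(rule["tags"]), prob=float(rule.get("prob", 1.0))
            )
            for idx, rule in (payload.get("syndrome_rules") or {}).items()
        }
        return cls(
            n_cases=int(payload.get("n_cases", 715)),
            templates=templates,
            background_probs={
                str(h): float(p)
                for h, p in (payload.get("background_probs") or {}).items()
            },
            syndrome_rules=rules,
            seed=int(payload.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True, allow_unicode=True)


def generate_corpus(config: SimConfig, seed: int | None = None) -> PrescriptionCorpus:
    """Draw a corpus; fully reproducible from ``seed`` (default: config.seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    weights = np.array([t.weight for t in config.templates], dtype=float)
    cum_weights = np.cumsum(weights) if len(weights) else np.empty(0)
    background = sorted(config.background_probs.items())

    cases: list[Prescription] = []
    for i in range(config.n_cases):
        while True:
            herbs: set[str] = set()
            template_idx: int | None = None
            if len(cum_weights):
                u = rng.random()
                hit = int(np.searchsorted(cum_weights, u, side="right"))
                if hit < len(cum_weights):
                    template_idx = hit
                    template = config.templates[hit]
                    draws = rng.random(len(template.herbs))
                    herbs.update(
                        h
                        for h, d in zip(template.herbs, draws)
                        if d < template.inclusion_prob
                    )
            if background:
                draws = rng.random(len(background))
                herbs.update(h for (h, p), d in zip(background, draws) if d < p)
            if herbs:
                break
        syndromes: frozenset[str] = frozenset()
        if template_idx is not None and template_idx in config.syndrome_rules:
            rule = config.syndrome_rules[template_idx]
            if rng.random() < rule.prob:
                syndromes = rule.tags
        cases.append(
            Prescription(
                case_id=f"case-{i + 1:05d}",
                herbs=frozenset(herbs),
                syndromes=syndromes,
            )
        )
    return PrescriptionCorpus(cases)


def calibrate_marginals(freq: FrequencyTable, n_cases: int) -> SimConfig:
    """Template-free config whose expected marginals reproduce ``freq``."""
    if not freq.rows:
        raise ValueError("frequency table must be non-empty")
    probs: dict[str, float] = {}
    for row in freq.rows:
        if row.count > n_cases:
            raise ValueError(
                f"herb {row.herb!r}: count {row.count} exceeds n_cases {n_cases}"
            )
        probs[row.herb] = row.count / n_cases
    return SimConfig(n_cases=n_cases, templates=[], background_probs=probs)


def exact_marginal_corpus(freq: FrequencyTable) -> PrescriptionCorpus:
    """Deterministic corpus realizing a frequency table's marginals exactly.

    Each herb occupies a contiguous (mod n_cases) block of cases starting
    where the previous herb's block ended, so every herb's case count matches
    its table row exactly.  Raises if the staggering leaves any case empty
    (possible only when total occurrences are scarce).
    """
    n = freq.n_cases
    case_herbs: list[set[str]] = [set() for _ in range(n)]
    offset = 0
    for row in freq.rows:
        for j in range(row.count):
            case_herbs[(offset + j) % n].add(row.herb)
        offset = (offset + row.count) % n
    empty = [i for i, herbs in enumerate(case_herbs) if not herbs]
    if empty:
        raise ValueError(
            f"{len(empty)} cases left empty; marginals too sparse to realize"
        )
    return PrescriptionCorpus(
        [
            Prescription(case_id=f"case-{i + 1:05d}", herbs=frozenset(herbs))
            for i, herbs in enumerate(case_herbs)
        ]
    )


def _presence_prob(herb: str, template: TemplateSpec | None, config: SimConfig) -> float:
    bg = config.background_probs.get(herb, 0.0)
    if template is not None and herb in template.herbs:
        return 1.0 - (1.0 - template.inclusion_prob) * (1.0 - bg)
    return bg


def unconditional_expected_support(config: SimConfig, items: Sequence[str]) -> float:
    """Mixture closed form without the non-empty conditioning."""
    return _raw_containment_prob(config, sorted(set(items)))


def _raw_containment_prob(config: SimConfig, items: Sequence[str]) -> float:
    total_weight = sum(t.weight for t in config.templates)
    value = (1.0 - total_weight) * float(
        np.prod([_presence_prob(h, None, config) for h in items])
    )
    for template in config.templates:
        value += template.weight * float(
            np.prod([_presence_prob(h, template, config) for h in items])
        )
    return value


def empty_draw_prob(config: SimConfig) -> float:
    """Probability a single unconditioned draw yields an empty herb set."""
    total_weight = sum(t.weight for t in config.templates)
    bg_herbs = set(config.background_probs)
    p = (1.0 - total_weight) * float(
        np.prod([1.0 - config.background_probs[h] for h in sorted(bg_herbs)])
    )
    for template in config.templates:
        universe = sorted(set(template.herbs) | bg_herbs)
        p += template.weight * float(
            np.prod([1.0 - _presence_prob(h, template, config) for h in universe])
        )
    return p


def expected_support(config: SimConfig, herbs: Sequence[str]) -> float:
    """Exact expected support of a non-empty itemset under the generator.

    Cases are drawn conditional on being non-empty (empty draws are redrawn),
    so the mixture closed form is normalized by 1 - P(empty draw).  When
    empty draws are negligible this reduces to the plain mixture product
    weight x inclusion_prob^k combined with background probabilities.
    """
    items = sorted(set(herbs))
    if not items:
        return 1.0
    return _raw_containment_prob(config, items) / (1.0 - empty_draw_prob(config))


def planted_truth(
    config: SimConfig, max_subset_size: int | None = None
) -> list[tuple[tuple[str, ...], float]]:
    """Expected supports of every subset of every template's herbs."""
    config.validate()
    truth: dict[tuple[str, ...], float] = {}
    for template in config.templates:
        if len(template.herbs) > 16:
            raise ValueError("template too large for subset enumeration (> 16 herbs)")
        top = len(template.herbs) if max_subset_size is None else max_subset_size
        for k in range(1, top + 1):
            for subset in combinations(template.herbs, k):
                truth.setdefault(subset, expected_support(config, subset))
    # background-only singletons round out the ground truth
    template_herbs = {h for t in config.templates for h in t.herbs}
    for herb in sorted(config.background_probs):
        if herb not in template_herbs:
            truth.setdefault((herb,), expected_support(config, (herb,)))
    return sorted(truth.items(), key=lambda kv: (len(kv[0]), kv[0]))
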