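"""Apriori frequent-itemset mining with exact supports.

Level-wise candidate generation over sorted herb tuples (prefix join + prune)
with vertical case-id sets for support counting, plus an exhaustive
brute-force miner used as an independent oracle in tests.

Supports are exact fractions count/n_cases kept unrounded; two-decimal
rounding is display-only.  The frequency filter keeps itemsets with
support >= min_support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable

from .corpus_io import PrescriptionCorpus
from .errors import EmptyCorpusError, VocabularyTooLargeError
from .frequency_profile import round2

__all__ = [
    "Itemset",
    "FrequentItemsetLevels",
    "support",
    "apriori",
    "brute_force_frequent",
    "rule_confidence",
]

_BRUTE_FORCE_MAX_VOCAB = 20


@dataclass(frozen=True)
class Itemset:
    """A sorted herb tuple with its exact support (and raw case count)."""

    herbs: tuple[str, ...]
    support: float
    count: int = 0

    def __post_init__(self) -> None:
        if list(self.herbs) != sorted(set(self.herbs)):
            raise ValueError(f"herbs must be strictly sorted and unique: {self.herbs}")
        if not 0.0 <= self.support <= 1.0:
            raise ValueError(f"support outside [0, 1]: {self.support}")


@dataclass
class FrequentItemsetLevels:
    """Frequent k-itemsets for k = 1..max_k, each level support-sorted."""

    min_support: float
    max_k: int
    levels: dict[int, list[Itemset]] = field(default_factory=dict)
    n_cases: int = 0

    def level(self, k: int) -> list[Itemset]:
        return self.levels.get(k, [])

    def deepest_nonempty(self) -> int | None:
        nonempty = [k for k, sets in self.levels.items() if sets]
        return max(nonempty) if nonempty else None

    def itemsets(self) -> Iterable[Itemset]:
        for k in sorted(self.levels):
            yield from self.levels[k]

    def to_dict(self) -> dict:
        return {
            "min_support": self.min_support,
            "max_k": self.max_k,
            "n_cases": self.n_cases,
            "levels": {
                str(k): [
                    {"herbs": list(it.herbs), "support": it.support, "count": it.count}
                    for it in sets
                ]
                for k, sets in sorted(self.levels.items())
            },
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def write_tsv(self, path: str | Path, k: int) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("herbs\tsupport\n")
            for it in self.level(k):
                fh.write(f"{','.join(it.herbs)}\t{round2(it.support):.2f}\n")


def _tidsets(corpus: PrescriptionCorpus) -> dict[str, frozenset[int]]:
    tids: dict[str, set[int]] = {}
    for i, case in enumerate(corpus):
        for herb in case.herbs:
            tids.setdefault(herb, set()).add(i)
    return {herb: frozenset(ids) for herb, ids in tids.items()}


def support(corpus: PrescriptionCorpus, herbs: Iterable[str]) -> float:
    """Exact fraction of cases whose herb set contains ``herbs``.

    The empty itemset has support 1.0 (vacuous containment).
    """
    if corpus.n_cases == 0:
        raise EmptyCorpusError("support is undefined on an empty corpus")
    items = frozenset(herbs)
    if not items:
        return 1.0
    count = sum(1 for case in corpus if items <= case.herbs)
    return count / corpus.n_cases


def _validate_mining_args(corpus: PrescriptionCorpus, min_support: float, max_k: int) -> None:
    if corpus.n_cases == 0:
        raise EmptyCorpusError("cannot mine an empty corpus")
    if not 0.0 < min_support <= 1.0:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if max_k < 1:
        raise ValueError(f"max_k must be >= 1, got {max_k}")


def _sort_level(itemsets: list[Itemset]) -> list[Itemset]:
    return sorted(itemsets, key=lambda it: (-it.count, it.herbs))


def apriori(
    corpus: PrescriptionCorpus, min_support: float, max_k: int
) -> FrequentItemsetLevels:
    """Level-wise frequent-itemset mining.

    Level 1 holds the single herbs at or above ``min_support``; level k is
    generated from level k-1 by joining itemsets sharing their first k-2
    sorted items, pruning candidates with any infrequent (k-1)-subset, and
    filtering by exact support.  Stops at ``max_k`` or the first empty level.
    """
    _validate_mining_args(corpus, min_support, max_k)
    n = corpus.n_cases
    # keep count >= min_support * n; epsilon guards float threshold products
    min_count = min_support * n - 1e-9

    tids = _tidsets(corpus)
    result = FrequentItemsetLevels(min_support=min_support, max_k=max_k, n_cases=n)

    frequent: dict[tuple[str, ...], frozenset[int]] = {
        (herb,): ids for herb, ids in tids.items() if len(ids) >= min_count
    }
    result.levels[1] = _sort_level(
        [Itemset(herbs, len(ids) / n, len(ids)) for herbs, ids in frequent.items()]
    )

    k = 2
    while k <= max_k and frequent:
        prev = frequent
        prev_keys = set(prev)
        ordered = sorted(prev)
        candidates: dict[tuple[str, ...], frozenset[int]] = {}
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break  # sorted order: no further shared prefix
                cand = a + (b[-1],)
                if any(
                    cand[:j] + cand[j + 1 :] not in prev_keys for j in range(len(cand) - 2)
                ):
                    continue  # prune by downward closure
                ids = prev[a] & prev[b]
                if len(ids) >= min_count:
                    candidates[cand] = frozenset(ids)
        frequent = candidates
        if not frequent:
            break
        result.levels[k] = _sort_level(
            [Itemset(herbs, len(ids) / n, len(ids)) for herbs, ids in frequent.items()]
        )
        k += 1
    return result


def brute_force_frequent(
    corpus: PrescriptionCorpus, min_support: float, max_k: int
) -> FrequentItemsetLevels:
    """Exhaustive miner: enumerate every vocabulary subset up to ``max_k``.

    Testing oracle only; guarded to vocabularies of at most 20 herbs.
    """
    _validate_mining_args(corpus, min_support, max_k)
    vocab = sorted(corpus.vocabulary)
    if len(vocab) > _BRUTE_FORCE_MAX_VOCAB:
        raise VocabularyTooLargeError(
            f"brute force limited to {_BRUTE_FORCE_MAX_VOCAB} herbs, got {len(vocab)}"
        )
    n = corpus.n_cases
    min_count = min_support * n - 1e-9
    case_sets = [case.herbs for case in corpus]
    result = FrequentItemsetLevels(min_support=min_support, max_k=max_k, n_cases=n)
    for k in range(1, max_k + 1):
        level = []
        for herbs in combinations(vocab, k):
            items = frozenset(herbs)
            count = sum(1 for s in case_sets if items <= s)
            if count >= min_count:
                level.append(Itemset(herbs, count / n, count))
        if not level:
            break
        result.levels[k] = _sort_level(level)
    return result


def rule_confidence(
    corpus: PrescriptionCorpus,
    antecedent: Iterable[str],
    consequent: Iterable[str],
) -> float:
    """support(antecedent ∪ consequent) / support(antecedent)."""
    ante = frozenset(antecedent)
    cons = frozenset(consequent)
    if not ante:
        raise ValueError("antecedent must be non-empty")
    if ante & cons:
        raise ValueError(f"antecedent and consequent overlap: {sorted(ante & cons)}")
    s_ante = support(corpus, ante)
    if s_ante == 0.0:
        raise ZeroDivisionError("confidence undefined: antecedent has zero support")
    return support(corpus, ante | cons) / s_ante
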