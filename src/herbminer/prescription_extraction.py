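"""Basic-prescription extraction ("Top N groups"), core prescription, pairs.

The motherboard is the highest-support itemset at the deepest non-empty
frequent level.  Iterating the remaining itemsets of that level in rank
order, every herb not yet in the accumulating union is appended as a
daughterboard; the final union is the basic prescription.  The core
prescription is its intersection with the top high-frequency herbs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import PrescriptionCorpus
from .errors import EmptyCorpusError, NoMotherboardError
from .frequency_profile import FrequencyTable, round2
from .itemset_mining import FrequentItemsetLevels, Itemset, apriori

__all__ = [
    "BasicPrescriptionResult",
    "HerbalPairRanking",
    "select_motherboard",
    "top_n_groups",
    "core_prescription",
    "mine_herbal_pairs",
]

ALL = None  # sentinel: consume every itemset at the deepest level


@dataclass
class BasicPrescriptionResult:
    motherboard: Itemset
    daughterboards: list[str]
    basic_prescription: frozenset[str]
    n_used: int

    def to_dict(self) -> dict:
        return {
            "motherboard": list(self.motherboard.herbs),
            "motherboard_support": self.motherboard.support,
            "daughterboards": self.daughterboards,
            "basic_prescription": sorted(self.basic_prescription),
            "n_used": self.n_used,
        }


def select_motherboard(levels: FrequentItemsetLevels) -> Itemset:
    """Highest-support itemset at the deepest non-empty level (ties: lex)."""
    deepest = levels.deepest_nonempty()
    if deepest is None:
        raise NoMotherboardError("all frequent-itemset levels are empty")
    return min(levels.level(deepest), key=lambda it: (-it.count, -it.support, it.herbs))


def top_n_groups(levels: FrequentItemsetLevels, n: int | None = ALL) -> BasicPrescriptionResult:
    """Accumulate daughterboard herbs from the top-n deepest-level itemsets.

    ``n`` counts itemsets including the motherboard; ``n=1`` returns the
    motherboard alone, ``n=ALL`` (None) consumes the whole level.
    """
    if n is not None and n < 1:
        raise ValueError(f"n must be >= 1 or ALL, got {n}")
    deepest = levels.deepest_nonempty()
    if deepest is None:
        raise NoMotherboardError("all frequent-itemset levels are empty")
    ranked = sorted(levels.level(deepest), key=lambda it: (-it.count, -it.support, it.herbs))
    motherboard = ranked[0]
    take = ranked if n is None else ranked[:n]
    union = set(motherboard.herbs)
    daughterboards: list[str] = []
    for itemset in take[1:]:
        for herb in itemset.herbs:  # within-itemset lexicographic order
            if herb not in union:
                union.add(herb)
                daughterboards.append(herb)
    return BasicPrescriptionResult(
        motherboard=motherboard,
        daughterboards=daughterboards,
        basic_prescription=frozenset(union),
        n_used=len(take),
    )


def core_prescription(
    basic: BasicPrescriptionResult | Iterable[str],
    freq: FrequencyTable,
    top_m: int,
) -> frozenset[str]:
    """Intersection of the basic prescription with the top-m frequent herbs."""
    if top_m < 1:
        raise ValueError(f"top_m must be >= 1, got {top_m}")
    if top_m > len(freq.rows):
        raise ValueError(f"top_m {top_m} exceeds table size {len(freq.rows)}")
    herbs = (
        basic.basic_prescription
        if isinstance(basic, BasicPrescriptionResult)
        else frozenset(basic)
    )
    return herbs & frozenset(freq.top(top_m))


@dataclass
class HerbalPairRanking:
    """Herb pairs with scores, ranked score-descending (ties: lex)."""

    rows: list[tuple[tuple[str, str], float]]
    min_score: float = 0.0

    @classmethod
    def from_scores(
        cls,
        scores: Iterable[tuple[Sequence[str], float]],
        min_score: float = 0.0,
    ) -> "HerbalPairRanking":
        rows = []
        seen = set()
        for pair, score in scores:
            key = tuple(sorted(pair))
            if len(key) != 2:
                raise ValueError(f"not a pair: {pair!r}")
            if key in seen:
                raise ValueError(f"duplicate pair: {key}")
            seen.add(key)
            if score >= min_score - 1e-12:  # tolerate 1-ulp float drift
                rows.append((key, float(score)))
        rows.sort(key=lambda r: (-r[1], r[0]))
        return cls(rows, min_score=min_score)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, _ in self.rows]

    def to_dict(self) -> list[dict]:
        return [{"herbs": list(pair), "score": score} for pair, score in self.rows]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("herbs\tscore\n")
            for pair, score in self.rows:
                fh.write(f"{','.join(pair)}\t{round2(score):.2f}\n")

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def mine_herbal_pairs(
    corpus: PrescriptionCorpus, min_support: float
) -> HerbalPairRanking:
    """All 2-itemsets at or above ``min_support``, scored by joint support."""
    if corpus.n_cases == 0:
        raise EmptyCorpusError("cannot mine pairs from an empty corpus")
    levels = apriori(corpus, min_support=min_support, max_k=2)
    return HerbalPairRanking.from_scores(
        ((it.herbs, it.support) for it in levels.level(2)),
        min_score=min_support,
    )
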