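"""Published summary statistics of a 715-case coronary-heart-disease corpus.

The raw case records behind these numbers are not publicly deposited; the
study reports only aggregate tables.  Those aggregates are embedded here as
worked-example inputs and calibration targets: per-herb case counts for the
48 most-used herbs, weighted property/taste/meridian counts, the seven
five-herb frequent combinations, and the 21 pair scores mined on the
372-case qi-deficiency/blood-stasis subset.
"""

from __future__ import annotations

from .frequency_profile import AttributeProfile, FrequencyTable
from .itemset_mining import FrequentItemsetLevels, Itemset

REFERENCE_N_CASES = 715
SYNDROME_SUBSET_N_CASES = 372
REFERENCE_VOCAB_SIZE = 182

# (herb, number of cases containing it), count-descending
HERB_CASE_COUNTS: tuple[tuple[str, int], ...] = (
    ("Gan-cao", 543),
    ("Huang-qi", 536),
    ("Dang-gui", 525),
    ("Chuan-xiong", 509),
    ("Yan-hu-suo", 483),
    ("San-qi", 444),
    ("Mai-dong", 423),
    ("Dan-shen", 417),
    ("Ye-ge-gen", 372),
    ("Wu-wei-zi", 361),
    ("Huang-lian", 333),
    ("Bing-pian", 322),
    ("Suan-zao-ren", 286),
    ("Huang-qin", 181),
    ("Gui-zhi", 176),
    ("Gou-teng", 175),
    ("Fu-ling", 170),
    ("Ze-xie", 167),
    ("Shui-zhi", 154),
    ("Mu-xiang", 148),
    ("Bai-shao", 140),
    ("Ren-shen", 119),
    ("Yin-yang-huo", 110),
    ("Sheng-di", 105),
    ("Gua-lou", 102),
    ("Qing-hao", 101),
    ("Qiang-huo", 101),
    ("Sha-ren", 94),
    ("Dan-pi", 93),
    ("Chai-hu", 92),
    ("Huang-bo", 90),
    ("Rou-gui", 89),
    ("Zi-shi-ying", 89),
    ("Hou-pu", 79),
    ("He-shou-wu", 70),
    ("Shu-di", 70),
    ("Ye-jiao-teng", 67),
    ("Zhi-zi", 67),
    ("Xing-ren", 65),
    ("Zhi-qiao", 63),
    ("Ban-xia", 62),
    ("Jue-ming-zi", 61),
    ("Da-huang", 59),
    ("Xie-bai", 58),
    ("Fu-zi", 56),
    ("Bai-zhu", 56),
    ("Dang-shen", 53),
    ("Xi-xin", 51),
)

# weighted attribute counts over all herb occurrences of the full corpus
PROPERTY_COUNTS: dict[str, int] = {
    "Warm": 4742,
    "Cold": 3463,
    "Mild": 1729,
    "Cool": 440,
    "Hot": 175,
}

TASTE_COUNTS: dict[str, int] = {
    "Pungent": 4234,
    "Bitter": 5066,
    "Sweet": 6134,
    "Mild": 369,
    "Puckery": 159,
    "Sour": 898,
    "Salty": 351,
}

MERIDIAN_COUNTS: dict[str, int] = {
    "Heart": 5987,
    "Liver": 5236,
    "Spleen": 4353,
    "Lung": 3962,
    "Stomach": 3679,
    "Kidney": 2037,
    "Large Intestine": 1420,
    "Gallbladder": 1362,
    "Bladder": 704,
    "Pericardium": 684,
    "Tri-jiao": 108,
    "Small Intestine": 35,
}

# the seven five-herb frequent combinations with their published supports
FIVE_HERB_COMBOS: tuple[tuple[tuple[str, ...], float], ...] = (
    (("Huang-qi", "Mai-dong", "San-qi", "Wu-wei-zi", "Yan-hu-suo"), 0.33),
    (("Gan-cao", "Huang-qi", "Mai-dong", "San-qi", "Yan-hu-suo"), 0.32),
    (("Gan-cao", "Huang-qi", "Mai-dong", "Wu-wei-zi", "Yan-hu-suo"), 0.32),
    (("Gan-cao", "Huang-qi", "Mai-dong", "San-qi", "Wu-wei-zi"), 0.32),
    (("Dang-gui", "Gan-cao", "Huang-qi", "Mai-dong", "Wu-wei-zi"), 0.31),
    (("Dang-gui", "Gan-cao", "Huang-qi", "San-qi", "Yan-hu-suo"), 0.30),
    (("Gan-cao", "Huang-qi", "San-qi", "Wu-wei-zi", "Yan-hu-suo"), 0.30),
)

# pair scores mined at min support 0.6 on the syndrome-filtered subset
SYNDROME_PAIR_SCORES: tuple[tuple[tuple[str, str], float], ...] = (
    (("Dang-gui", "Huang-qi"), 0.85),
    (("Gan-cao", "Huang-qi"), 0.82),
    (("Huang-qi", "Mai-dong"), 0.75),
    (("Huang-qi", "Yan-hu-suo"), 0.75),
    (("Huang-qi", "San-qi"), 0.74),
    (("Dan-shen", "Huang-qi"), 0.72),
    (("Dang-gui", "Gan-cao"), 0.72),
    (("San-qi", "Yan-hu-suo"), 0.69),
    (("Chuan-xiong", "Huang-qi"), 0.67),
    (("Gan-cao", "Mai-dong"), 0.67),
    (("Huang-qi", "Wu-wei-zi"), 0.67),
    (("Dang-gui", "Mai-dong"), 0.66),
    (("Dang-gui", "Yan-hu-suo"), 0.65),
    (("Mai-dong", "Wu-wei-zi"), 0.65),
    (("Dang-gui", "San-qi"), 0.64),
    (("Gan-cao", "Yan-hu-suo"), 0.64),
    (("Gan-cao", "San-qi"), 0.63),
    (("Dan-shen", "Gan-cao"), 0.62),
    (("Dan-shen", "Dang-gui"), 0.62),
    (("Mai-dong", "Yan-hu-suo"), 0.61),
    (("Chuan-xiong", "Dang-gui"), 0.60),
)

SYNDROME_TAGS = ("qi deficiency", "blood stasis")


def reference_frequency_table() -> FrequencyTable:
    """The 48-herb frequency table as a :class:`FrequencyTable`."""
    return FrequencyTable.from_counts(dict(HERB_CASE_COUNTS), REFERENCE_N_CASES)


def reference_attribute_profile() -> AttributeProfile:
    """Attribute profile built from the published weighted counts."""
    return AttributeProfile.from_counts(PROPERTY_COUNTS, TASTE_COUNTS, MERIDIAN_COUNTS)


def reference_five_herb_levels(min_support: float = 0.3) -> FrequentItemsetLevels:
    """The published five-herb combinations wrapped as a deepest level.

    Only level 5 is populated; lower levels are not reported itemset-by-
    itemset with enough precision to reconstruct, and the extraction
    operations only consume the deepest level.
    """
    levels = FrequentItemsetLevels(min_support=min_support, max_k=5, n_cases=REFERENCE_N_CASES)
    levels.levels[5] = sorted(
        (
            Itemset(herbs, support, round(support * REFERENCE_N_CASES))
            for herbs, support in FIVE_HERB_COMBOS
        ),
        key=lambda it: (-it.support, it.herbs),
    )
    return levels
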