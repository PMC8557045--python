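"""Exception hierarchy shared across the package."""


class HerbMinerError(Exception):
    """Base class for all package-specific errors."""


class UnknownHerbError(HerbMinerError):
    """A raw herb name has no canonical form in the synonym map."""

    def __init__(self, herb: str):
        self.herb = herb
        super().__init__(f"unknown herb name: {herb!r}")


class UnknownAttributeError(HerbMinerError):
    """An herb in the corpus is missing from the attribute table."""

    def __init__(self, herb: str):
        self.herb = herb
        super().__init__(f"no attribute record for herb: {herb!r}")


class CorpusParseError(HerbMinerError):
    """A corpus file row violates the input schema."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class EmptyCorpusError(HerbMinerError):
    """An operation that needs at least one case received an empty corpus."""


class VocabularyTooLargeError(HerbMinerError):
    """Guard against exponential enumeration in the brute-force miner."""


class NoMotherboardError(HerbMinerError):
    """All frequent-itemset levels are empty; no motherboard exists."""


class DegenerateConfigError(HerbMinerError):
    """A simulation config under which no herb can ever be drawn."""
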