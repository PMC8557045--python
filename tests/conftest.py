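import pytest

from herbminer.corpus_io import Prescription, PrescriptionCorpus


def make_corpus(herb_sets, syndromes=None, patient_ids=None):
    """Build a corpus from a list of herb iterables."""
    syndromes = syndromes or [()] * len(herb_sets)
    patient_ids = patient_ids or [None] * len(herb_sets)
    return PrescriptionCorpus(
        [
            Prescription(
                case_id=f"c{i + 1}",
                herbs=frozenset(herbs),
                syndromes=frozenset(tags),
                patient_id=pid,
            )
            for i, (herbs, tags, pid) in enumerate(
                zip(herb_sets, syndromes, patient_ids)
            )
        ]
    )


@pytest.fixture
def toy4():
    """The 4-case worked example: {A,B}, {A}, {B,C}, {A,B,C}."""
    return make_corpus([{"A", "B"}, {"A"}, {"B", "C"}, {"A", "B", "C"}])


@pytest.fixture
def random_corpus_factory():
    """Factory for seeded random corpora over a small vocabulary."""
    import numpy as np

    def build(seed, n_herbs=10, n_cases=50, density=0.35):
        rng = np.random.default_rng(seed)
        herbs = [f"H{i:02d}" for i in range(n_herbs)]
        sets = []
        while len(sets) < n_cases:
            mask = rng.random(n_herbs) < density
            chosen = {h for h, m in zip(herbs, mask) if m}
            if chosen:
                sets.append(chosen)
        return make_corpus(sets)

    return build
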