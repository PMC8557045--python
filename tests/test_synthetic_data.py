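import math

import pytest

from herbminer.errors import DegenerateConfigError
from herbminer.frequency_profile import FrequencyTable, herb_frequency
from herbminer.itemset_mining import apriori, support
from herbminer import reference
from herbminer.synthetic_data import (
    SimConfig,
    SyndromeRule,
    TemplateSpec,
    calibrate_marginals,
    exact_marginal_corpus,
    expected_support,
    generate_corpus,
    planted_truth,
    unconditional_expected_support,
)


def one_template_config(n_cases=100, weight=1.0, inclusion=1.0, seed=0, background=None):
    return SimConfig(
        n_cases=n_cases,
        templates=[TemplateSpec(herbs=("A", "B", "C"), weight=weight, inclusion_prob=inclusion)],
        background_probs=background or {},
        seed=seed,
    )


class TestGenerateCorpus:
    def test_pure_template_every_case_identical(self):
        corpus = generate_corpus(one_template_config())
        assert corpus.n_cases == 100
        assert all(case.herbs == {"A", "B", "C"} for case in corpus)

    def test_pure_template_recovered_by_apriori(self):
        corpus = generate_corpus(one_template_config())
        levels = apriori(corpus, min_support=0.9, max_k=3)
        assert levels.level(3)[0].herbs == ("A", "B", "C")
        assert levels.level(3)[0].support == 1.0

    def test_empirical_support_within_3_se(self):
        # template {A,B} w=0.6 inc=0.9, background C at 0.3, n=5000
        config = SimConfig(
            n_cases=5000,
            templates=[TemplateSpec(herbs=("A", "B"), weight=0.6, inclusion_prob=0.9)],
            background_probs={"C": 0.3},
            seed=42,
        )
        # plain mixture product, before non-empty conditioning
        assert unconditional_expected_support(config, ("A", "B")) == pytest.approx(
            0.6 * 0.81
        )
        corpus = generate_corpus(config)
        p = expected_support(config, ("A", "B"))
        se = math.sqrt(p * (1 - p) / 5000)
        assert abs(support(corpus, {"A", "B"}) - p) < 3 * se

    def test_same_seed_bit_stable(self):
        config = one_template_config(weight=0.7, inclusion=0.8, background={"D": 0.4}, seed=9)
        a = generate_corpus(config)
        b = generate_corpus(config)
        assert a == b

    def test_different_seed_differs(self):
        config = one_template_config(weight=0.5, inclusion=0.8, background={"D": 0.4})
        a = generate_corpus(config, seed=1)
        b = generate_corpus(config, seed=2)
        assert a != b

    def test_cases_never_empty(self):
        config = SimConfig(n_cases=300, background_probs={"A": 0.05, "B": 0.05}, seed=3)
        corpus = generate_corpus(config)
        assert all(case.herbs for case in corpus)

    def test_degenerate_config_rejected(self):
        config = SimConfig(n_cases=10, background_probs={"A": 0.0})
        with pytest.raises(DegenerateConfigError):
            generate_corpus(config)

    def test_syndrome_tags_attached(self):
        config = one_template_config(seed=5)
        config.syndrome_rules = {0: SyndromeRule(tags=frozenset({"qi deficiency"}), prob=1.0)}
        corpus = generate_corpus(config)
        assert all(case.syndromes == {"qi deficiency"} for case in corpus)

    def test_yaml_round_trip(self, tmp_path):
        config = one_template_config(weight=0.6, inclusion=0.9, background={"D": 0.2})
        config.syndrome_rules = {0: SyndromeRule(tags=frozenset({"x"}), prob=0.5)}
        path = tmp_path / "sim.yaml"
        config.to_yaml(path)
        loaded = SimConfig.from_yaml(path)
        assert loaded.to_dict() == config.to_dict()
        assert generate_corpus(loaded) == generate_corpus(config)


class TestCalibrateMarginals:
    def test_background_probs_match_counts(self):
        freq = reference.reference_frequency_table()
        config = calibrate_marginals(freq, reference.REFERENCE_N_CASES)
        assert config.templates == []
        assert config.background_probs["Gan-cao"] == pytest.approx(543 / 715)

    def test_count_equal_to_n_gives_certain_herb(self):
        freq = FrequencyTable.from_counts({"A": 10, "B": 4}, 10)
        config = calibrate_marginals(freq, 10)
        config.seed = 1
        corpus = generate_corpus(config)
        assert all("A" in case.herbs for case in corpus)

    def test_count_above_n_rejected(self):
        freq = FrequencyTable.from_counts({"A": 5}, 10)
        with pytest.raises(ValueError):
            calibrate_marginals(freq, 3)

    def test_generated_counts_within_3_se(self):
        freq = reference.reference_frequency_table()
        config = calibrate_marginals(freq, 715)
        config.seed = 0
        counts = {
            row.herb: row.count for row in herb_frequency(generate_corpus(config)).rows
        }
        for row in freq.rows:
            p = row.count / 715
            se = math.sqrt(715 * p * (1 - p))
            assert abs(counts.get(row.herb, 0) - row.count) <= 3 * se, row.herb


class TestPlantedTruth:
    def test_closed_form_template_pair(self):
        config = SimConfig(
            n_cases=100,
            templates=[TemplateSpec(herbs=("A", "B"), weight=0.6, inclusion_prob=0.9)],
        )
        assert unconditional_expected_support(config, ("A", "B")) == pytest.approx(0.486)
        # redraw conditioning: 40% of raw draws are empty (no background)
        truth = dict(planted_truth(config))
        p_empty = 0.4 + 0.6 * 0.1 * 0.1
        assert truth[("A", "B")] == pytest.approx(0.486 / (1 - p_empty))

    def test_full_template_support_equals_weight_given_nonempty(self):
        config = one_template_config(weight=0.4)
        truth = dict(planted_truth(config))
        # inclusion 1, no background: every non-empty draw is the template
        assert truth[("A", "B", "C")] == pytest.approx(1.0)
        assert unconditional_expected_support(config, ("A", "B", "C")) == pytest.approx(0.4)

    def test_background_only_singleton(self):
        config = SimConfig(
            n_cases=50,
            templates=[TemplateSpec(herbs=("A", "B", "C"), weight=0.5)],
            background_probs={"D": 0.3},
        )
        truth = dict(planted_truth(config))
        # empty draws are rare here (only no-template, no-D draws redraw)
        assert truth[("D",)] == pytest.approx(0.3 / (1 - 0.5 * 0.7))

    def test_overlapping_background_inclusion_exclusion(self):
        config = SimConfig(
            n_cases=50,
            templates=[TemplateSpec(herbs=("A",), weight=0.5, inclusion_prob=0.9)],
            background_probs={"A": 0.2},
        )
        # P(A) = w(1-(1-inc)(1-bg)) + (1-w)bg = 0.5*0.92 + 0.5*0.2
        assert unconditional_expected_support(config, ("A",)) == pytest.approx(0.56)
        # A is the only herb, so every non-empty case contains it
        assert expected_support(config, ("A",)) == pytest.approx(1.0)

    def test_empirical_convergence_to_truth(self):
        config = SimConfig(
            n_cases=4000,
            templates=[TemplateSpec(herbs=("A", "B", "C"), weight=0.5, inclusion_prob=0.9)],
            background_probs={"D": 0.35, "E": 0.15},
            seed=77,
        )
        corpus = generate_corpus(config)
        for herbs, p in planted_truth(config):
            se = math.sqrt(p * (1 - p) / config.n_cases)
            assert abs(support(corpus, herbs) - p) <= 3 * se + 1e-12, herbs


class TestExactMarginalCorpus:
    def test_reproduces_published_counts(self):
        freq = reference.reference_frequency_table()
        corpus = exact_marginal_corpus(freq)
        assert corpus.n_cases == 715
        observed = herb_frequency(corpus)
        for row in freq.rows:
            assert observed.count_of(row.herb) == row.count

    def test_sparse_marginals_rejected(self):
        freq = FrequencyTable.from_counts({"A": 1}, 10)
        with pytest.raises(ValueError, match="empty"):
            exact_marginal_corpus(freq)
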