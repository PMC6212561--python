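"""Synthetic corpus generator: calibration, determinism, label recovery."""

import numpy as np
import pytest
from scipy import stats

from temporient.corpus import GoldSentinel, Orientation, filter_valid
from temporient.cues import classify_naive, classify_no_ties
from temporient.evaluation import concordance
from temporient.synthetic import (
    DEFAULT_CATEGORY_PROBS,
    ConfigError,
    GeneratorConfig,
    TemplateBank,
    generate_corpus,
    summarize_corpus,
)
from temporient.tagging import tag_lexicon


def test_default_template_bank_verifies():
    bank = TemplateBank.default()
    bank.verify()  # label-recovery invariant over the full slot vocabulary


def test_broken_template_bank_is_rejected():
    with pytest.raises(ConfigError, match="classifies as"):
        TemplateBank(
            templates={
                "past": ["I will go"],  # future cue in the past pool
                "present": ["eating"],
                "future": ["will go"],
                "other": ["not much"],
            },
            fillers={},
            slots={},
        )
    with pytest.raises(ConfigError, match="no templates"):
        TemplateBank(
            templates={"past": ["napped"], "present": ["eating"], "future": ["will go"]},
            fillers={},
            slots={},
        )


def test_config_validation():
    with pytest.raises(ConfigError, match="sum to 1"):
        GeneratorConfig(category_probs={o: 0.3 for o in Orientation})
    with pytest.raises(ConfigError, match="ambiguity_rate"):
        GeneratorConfig(ambiguity_rate=1.5)
    with pytest.raises(ConfigError, match="out of range"):
        GeneratorConfig(n_records=10, tied_or_missing_count=11)


def test_generate_empty():
    assert len(generate_corpus(GeneratorConfig(n_records=0, tied_or_missing_count=0))) == 0


def test_generation_is_deterministic_under_seed():
    a = generate_corpus(GeneratorConfig(n_records=150, seed=9))
    b = generate_corpus(GeneratorConfig(n_records=150, seed=9))
    c = generate_corpus(GeneratorConfig(n_records=150, seed=10))
    assert list(a) == list(b)
    assert list(a) != list(c)


def test_default_config_filters_to_study_size(default_corpus):
    kept, excluded = filter_valid(default_corpus)
    assert (len(default_corpus), excluded, len(kept)) == (2884, 379, 2505)


def test_lengths_within_bounds_and_mean_near_43(default_corpus):
    lengths = [len(rec.text) for rec in default_corpus]
    assert min(lengths) >= 1 and max(lengths) <= 358
    assert abs(np.mean(lengths) - 43.0) < 4.0


def test_length_floor_across_seeds():
    for seed in range(15):
        corpus = generate_corpus(GeneratorConfig(n_records=80, seed=seed))
        assert min(len(rec.text) for rec in corpus) >= 1


def test_category_proportions_chi_square():
    """Empirical gold mix is consistent with the configured probabilities."""
    corpus = generate_corpus(
        GeneratorConfig(n_records=10_000, tied_or_missing_count=0, seed=11)
    )
    counts = {o: 0 for o in Orientation}
    for rec in corpus:
        counts[rec.gold] += 1
    observed = [counts[o] for o in Orientation]
    expected = [DEFAULT_CATEGORY_PROBS[o] * 10_000 for o in Orientation]
    _, p_value = stats.chisquare(observed, expected)
    assert p_value > 0.01


def test_sentinel_records_split_tied_and_missing(default_corpus):
    tied = sum(1 for r in default_corpus if r.gold is GoldSentinel.TIED)
    missing = sum(1 for r in default_corpus if r.gold is GoldSentinel.MISSING)
    assert tied + missing == 379
    assert tied > 0 and missing > 0


def test_label_recovery_at_zero_ambiguity(default_valid):
    """Template construction guarantees 100% strict accuracy with no ambiguity."""
    for classifier in (classify_naive, classify_no_ties):
        judgements = [classifier(tag_lexicon(rec.text)) for rec in default_valid]
        report = concordance(judgements, default_valid, mode="strict")
        assert report.accuracy_pct == 100.0


def _naive_strict_accuracy(ambiguity, seed=41, n=1200):
    corpus = generate_corpus(
        GeneratorConfig(n_records=n, tied_or_missing_count=0,
                        ambiguity_rate=ambiguity, seed=seed)
    )
    kept, _ = filter_valid(corpus)
    judgements = [classify_naive(tag_lexicon(rec.text)) for rec in kept]
    return concordance(judgements, kept, mode="strict").accuracy_pct


def test_accuracy_monotone_nonincreasing_in_ambiguity():
    accuracies = [_naive_strict_accuracy(a) for a in (0.0, 0.25, 0.5, 1.0)]
    assert accuracies[0] == 100.0
    assert all(x >= y for x, y in zip(accuracies, accuracies[1:]))
    assert accuracies[-1] == 0.0  # every record mixes cues, ties never score


def test_ambiguous_records_flagged_in_provenance():
    corpus = generate_corpus(
        GeneratorConfig(n_records=300, tied_or_missing_count=0,
                        ambiguity_rate=1.0, seed=2)
    )
    assert len(corpus.meta["ambiguous_record_ids"]) == 300
    summary = summarize_corpus(corpus)
    assert summary["ambiguous_proportion"] == 1.0


def test_summarize_corpus_study_statistics(default_corpus):
    summary = summarize_corpus(default_corpus)
    assert summary["n_records"] == 2884
    assert summary["n_valid"] == 2505
    props = summary["label_proportions"]
    assert max(props, key=props.get) == "present"
    assert 10 <= summary["participants"]["responses_mean"] <= 18
    assert 1 <= summary["participants"]["responses_min"]
    assert summary["participants"]["responses_max"] <= 20
    assert 3 <= summary["participants"]["responses_sd"] <= 9
    assert all(rec.reference_time is not None for rec in default_corpus)


def test_summarize_single_record():
    corpus = generate_corpus(GeneratorConfig(n_records=1, tied_or_missing_count=0, seed=0))
    props = summarize_corpus(corpus)["label_proportions"]
    assert sorted(props.values()) == [0.0, 0.0, 0.0, 1.0]
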