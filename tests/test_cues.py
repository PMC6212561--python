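"""POS-cue extraction, anchor terms, and the three rule-based coders."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from temporient.corpus import Orientation
from temporient.cues import (
    AnchorLexicon,
    Judgement,
    classify_anchored,
    classify_naive,
    classify_no_ties,
    extract_anchor_cues,
    extract_pos_cues,
)
from temporient.tagging import tag_lexicon

PAST, PRESENT, FUTURE, OTHER = (
    Orientation.PAST,
    Orientation.PRESENT,
    Orientation.FUTURE,
    Orientation.OTHER,
)


def orientations_of(judgement: Judgement) -> set[Orientation]:
    return set(judgement.orientations)


def test_worked_example_pos_cues(worked_sentence):
    cues = extract_pos_cues(worked_sentence)
    assert [(c.orientation, c.strength, c.trigger_surface) for c in cues] == [
        (FUTURE, "strong", "will"),
        (PAST, "strong", "remembered"),
        (PRESENT, "weak", "example"),
    ]


def test_pos_cues_all_punctuation():
    assert extract_pos_cues(tag_lexicon("?! ...")) == []


def test_pos_cues_she_runs_daily():
    cues = extract_pos_cues(tag_lexicon("She runs daily"))
    assert [(c.orientation, c.strength) for c in cues] == [
        (PRESENT, "strong"),
        (PRESENT, "weak"),
    ]


def test_plural_noun_cue_is_configurable():
    sentence = tag_lexicon("dinner plans")
    assert len(extract_pos_cues(sentence)) == 2
    assert len(extract_pos_cues(sentence, include_plural_nouns=False)) == 1


def test_naive_worked_example_is_future_past_mixture(worked_sentence):
    judgement = classify_naive(worked_sentence)
    assert orientations_of(judgement) == {FUTURE, PAST}
    assert judgement.is_tie
    assert judgement.label() == "future;past"


def test_naive_no_markers_is_other():
    assert orientations_of(classify_naive(tag_lexicon(""))) == {OTHER}
    assert orientations_of(classify_naive(tag_lexicon("not much"))) == {OTHER}


def test_naive_weak_cues_apply_without_strong_ones():
    """Noun-only text codes present through weak cues."""
    judgement = classify_naive(tag_lexicon("dinner plans"))
    assert orientations_of(judgement) == {PRESENT}
    assert all(c.strength == "weak" for c in judgement.cues)


def test_naive_weak_cues_suppressed_by_strong_ones(worked_sentence):
    """'example/NN' contributes no present reading when verb cues exist."""
    assert PRESENT not in orientations_of(classify_naive(worked_sentence))


def test_anchor_cues():
    lexicon = AnchorLexicon.default()
    cues = extract_anchor_cues(tag_lexicon("remembered my exam"), lexicon)
    assert [(c.orientation, c.source, c.token_index) for c in cues] == [
        (PAST, "anchor", 0)
    ]
    assert extract_anchor_cues(tag_lexicon("eating dinner"), lexicon) == []
    future_cues = extract_anchor_cues(tag_lexicon("my future plans"), lexicon)
    assert [(c.orientation, c.token_index) for c in future_cues] == [(FUTURE, 1)]


def test_anchored_worked_example(worked_sentence):
    assert orientations_of(classify_anchored(worked_sentence)) == {FUTURE, PAST}


def test_anchored_anchor_vs_pos_conflict():
    """'remember' tags VBP (present) but anchors past: a two-way tie."""
    judgement = classify_anchored(tag_lexicon("I remember that"))
    assert orientations_of(judgement) == {PAST, PRESENT}


def test_no_ties_worked_example(worked_sentence):
    judgement = classify_no_ties(worked_sentence)
    assert orientations_of(judgement) == {FUTURE}
    assert not judgement.is_tie


def test_no_ties_single_cue():
    assert orientations_of(classify_no_ties(tag_lexicon("napped"))) == {PAST}


def test_no_ties_earliest_cue_wins():
    assert orientations_of(classify_no_ties(tag_lexicon("Remembered I will go"))) == {PAST}


def test_no_ties_same_token_precedence():
    """Anchor-past and VBP-present on one token resolve by precedence."""
    assert orientations_of(classify_no_ties(tag_lexicon("remember"))) == {PAST}


def test_no_ties_no_cues_is_other():
    assert orientations_of(classify_no_ties(tag_lexicon("out and about"))) == {OTHER}


_word = st.sampled_from(
    "i we she they will would might have had was is are eating slept remembered "
    "remember future dinner exam plans yesterday tomorrow not much oh and the "
    "my go see walked thinking".split()
)
_sentence = st.lists(_word, min_size=0, max_size=12).map(" ".join)


@given(_sentence)
def test_no_ties_member_of_anchored_set(text):
    """The tie-broken label is always one of the anchored coder's candidates."""
    sentence = tag_lexicon(text)
    anchored = orientations_of(classify_anchored(sentence))
    no_ties = classify_no_ties(sentence).single
    if anchored != {OTHER}:
        assert no_ties in anchored
    else:
        assert no_ties is OTHER


@given(_sentence)
def test_empty_anchor_lexicon_reduces_to_naive(text):
    sentence = tag_lexicon(text)
    anchored = classify_anchored(sentence, AnchorLexicon.empty())
    naive = classify_naive(sentence)
    assert anchored.orientations == naive.orientations


def test_anchor_lexicon_from_csv(tmp_path):
    path = tmp_path / "anchors.csv"
    path.write_text("stem,orientation\nremember,past\nfuture,future\nplan,future\n")
    lexicon = AnchorLexicon.from_csv(path)
    assert lexicon.match("planning") is FUTURE
    assert lexicon.match("dinner") is None
    judgement = classify_anchored(tag_lexicon("planning dinner"), lexicon)
    assert orientations_of(judgement) == {FUTURE, PRESENT}
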