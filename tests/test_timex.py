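"""Temporal-expression recognition, resolution, and the sutime-style coder."""

from datetime import date, datetime, timedelta

import numpy as np
import pytest

from temporient.corpus import Orientation, ThoughtRecord
from temporient.timex import (
    annotate_timex,
    classify_sutime,
    recognize_timex,
    resolve_timex,
)

from conftest import WORKED_SENTENCE

REF_2018 = datetime(2018, 6, 15, 12, 0)


def brute_force_relation(resolved: tuple[date, date], ref: datetime) -> Orientation:
    """Day-by-day enumeration of the resolved range against the reference day."""
    refd = ref.date()
    start, end = resolved
    days = [start + timedelta(days=i) for i in range((end - start).days + 1)]
    if all(d < refd for d in days):
        return Orientation.PAST
    if all(d > refd for d in days):
        return Orientation.FUTURE
    return Orientation.PRESENT


def test_recognize_worked_example_year():
    expressions = recognize_timex(WORKED_SENTENCE)
    assert [(e.kind, e.surface) for e in expressions] == [("year", "2019")]
    assert WORKED_SENTENCE[expressions[0].char_start : expressions[0].char_end] == "2019"


def test_recognize_no_temporal_language():
    assert recognize_timex("thinking about dinner") == []


def test_recognize_longest_match_wins():
    expressions = recognize_timex("next week on 3/5/2019")
    assert [(e.kind, e.surface) for e in expressions] == [
        ("deictic_relative", "next week"),
        ("full_date", "3/5/2019"),
    ]


@pytest.mark.parametrize(
    "text, kind",
    [
        ("see you in January", "month_name"),
        ("due 2019-03-01", "full_date"),
        ("at 9:30 pm", "clock_time"),
        ("last Friday", "deictic_relative"),
        ("tonight", "deictic_day"),
    ],
)
def test_recognize_kinds(text, kind):
    kinds = [e.kind for e in recognize_timex(text)]
    assert kinds == [kind]


def test_lowercase_may_is_not_a_month():
    assert recognize_timex("it may rain") == []
    assert [e.kind for e in recognize_timex("back in May")] == ["month_name"]


@pytest.mark.parametrize(
    "text, expected",
    [
        ("2019", Orientation.FUTURE),
        ("2017", Orientation.PAST),
        ("2018", Orientation.PRESENT),  # range contains the reference day
        ("today", Orientation.PRESENT),
        ("now", Orientation.PRESENT),
        ("yesterday", Orientation.PAST),
        ("tomorrow", Orientation.FUTURE),
        ("next Friday", Orientation.FUTURE),
        ("last week", Orientation.PAST),
        ("next month", Orientation.FUTURE),
        ("last year", Orientation.PAST),
        ("September", Orientation.FUTURE),  # ref is mid-June
        ("March", Orientation.PAST),  # nearest occurrence is 3 months back
        ("June", Orientation.PRESENT),
        ("3:15 pm", Orientation.PRESENT),
        ("1/1/2019", Orientation.FUTURE),
    ],
)
def test_resolution_relations(text, expected):
    (expr,) = recognize_timex(text)
    resolved = resolve_timex(expr, REF_2018)
    assert resolved.relation is expected
    assert brute_force_relation(resolved.resolved, REF_2018) is expected


def test_impossible_date_stays_unresolved(caplog):
    (expr,) = recognize_timex("31/2/2019")
    with caplog.at_level("WARNING"):
        resolved = resolve_timex(expr, REF_2018)
    assert resolved.relation is None and resolved.resolved is None


def test_relation_agrees_with_day_enumeration_oracle():
    """Seeded random (expression, reference) pairs against the brute-force oracle."""
    rng = np.random.default_rng(7)
    texts = (
        ["today", "tonight", "now", "yesterday", "tomorrow", "next week",
         "last week", "next month", "last month", "next year", "last year",
         "next Monday", "last Saturday", "January", "May", "August", "December"]
        + [str(y) for y in rng.integers(1950, 2080, size=20)]
        + [f"{d}/{m}/{y}" for d, m, y in zip(
            rng.integers(1, 29, size=20),
            rng.integers(1, 13, size=20),
            rng.integers(1990, 2040, size=20),
        )]
    )
    base = datetime(2000, 1, 1)
    for _ in range(400):
        text = texts[rng.integers(len(texts))]
        ref = base + timedelta(days=int(rng.integers(0, 365 * 40)),
                               minutes=int(rng.integers(0, 24 * 60)))
        (expr,) = recognize_timex(text)
        resolved = resolve_timex(expr, ref)
        assert resolved.resolved is not None, (text, ref)
        assert resolved.relation is brute_force_relation(resolved.resolved, ref), (
            text, ref,
        )


def _record(text, ref=REF_2018):
    return ThoughtRecord(record_id="x", text=text, reference_time=ref)


def test_sutime_worked_example_is_future():
    judgement = classify_sutime(_record(WORKED_SENTENCE))
    assert judgement.method == "sutime"
    assert set(judgement.orientations) == {Orientation.FUTURE}
    assert not judgement.is_tie


def test_sutime_no_temporal_language_is_other():
    assert set(classify_sutime(_record("no time words here")).orientations) == {
        Orientation.OTHER
    }


def test_sutime_earliest_span_wins():
    judgement = classify_sutime(_record("yesterday and tomorrow"))
    assert set(judgement.orientations) == {Orientation.PAST}


def test_sutime_without_reference_time_is_other(caplog):
    record = ThoughtRecord(record_id="x", text="see you tomorrow")
    with caplog.at_level("WARNING"):
        judgement = classify_sutime(record)
    assert set(judgement.orientations) == {Orientation.OTHER}
    assert "no reference time" in caplog.text
    # a corpus-wide default reference makes it resolvable again
    assert set(
        classify_sutime(record, default_reference=REF_2018).orientations
    ) == {Orientation.FUTURE}


def test_sutime_is_other_on_cue_free_text(default_corpus):
    """Digit-free, temporal-word-free text always codes other."""
    for text in ["thinking about dinner", "not much", "we talked about the exam"]:
        assert set(classify_sutime(_record(text)).orientations) == {Orientation.OTHER}


def test_annotate_timex_matches_inline_xml_shape():
    annotated = annotate_timex(WORKED_SENTENCE)
    assert '<TIMEX3 tid="t1" type="DATE" value="2019">2019</TIMEX3>' in annotated
    assert annotate_timex("nothing here") == "nothing here"
    timed = annotate_timex("at 9:30", ref=REF_2018)
    assert 'type="TIME"' in timed
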