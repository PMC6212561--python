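"""Explicit temporal-expression recognition and resolution.

This is the fourth automated coder: instead of tense cues it looks for
explicit temporal language — calendar years, month names, numeric dates,
deictic day words ("today", "yesterday", "tomorrow", "tonight", "now"),
relative phrases ("next week", "last Friday") and clock times — resolves each
expression to a calendar day or day range against the record's reference
time (when the text was created), and codes the record by comparing that
range with the reference day:

* entirely after the reference day  -> future
* entirely before                   -> past
* containing the reference day      -> present

The "present" window is the reference calendar day, matching the granularity
of the deictic vocabulary.  Records with no expression, or none resolvable
(e.g. no reference time is available), code as "other".  When several
expressions resolve, the earliest span in the text wins, so the method is
tie-free by construction.

Numeric dates are parsed day-first (d/m/y); ISO dates (yyyy-mm-dd) are
year-first.  Bare month names resolve to the nearest occurrence within six
months, preferring the future; "May" and "March" must be capitalized to
count as months (lower-case they collide with the modal verb and the verb
"march").
"""

from __future__ import annotations

import calendar
import logging
import re
from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta
from typing import Sequence

from .corpus import Orientation, ThoughtRecord
from .cues import Judgement

logger = logging.getLogger(__name__)

__all__ = [
    "TemporalExpression",
    "recognize_timex",
    "resolve_timex",
    "classify_sutime",
    "annotate_timex",
]


@dataclass(frozen=True)
class TemporalExpression:
    """A recognized temporal expression with optional resolution."""

    char_start: int
    char_end: int
    surface: str
    kind: str  # year | month_name | full_date | deictic_day | deictic_relative | clock_time
    resolved: tuple[date, date] | None = None  # inclusive day range
    relation: Orientation | None = None  # past | present | future once resolved


_MONTHS = {
    "january": 1, "jan": 1, "february": 2, "feb": 2, "march": 3, "mar": 3,
    "april": 4, "apr": 4, "may": 5, "june": 6, "jun": 6, "july": 7, "jul": 7,
    "august": 8, "aug": 8, "september": 9, "sep": 9, "sept": 9,
    "october": 10, "oct": 10, "november": 11, "nov": 11,
    "december": 12, "dec": 12,
}
# Months safe to match in any case; May/March/Mar need a capital.
_MONTHS_CASELESS = (
    "january|jan|february|feb|april|apr|june|jun|july|jul|august|aug|"
    "september|sept|sep|october|oct|november|nov|december|dec"
)
_WEEKDAYS = {
    "monday": 0, "tuesday": 1, "wednesday": 2, "thursday": 3,
    "friday": 4, "saturday": 5, "sunday": 6,
}

_PATTERNS: list[tuple[str, re.Pattern[str]]] = [
    ("full_date", re.compile(r"\b(19|20)\d{2}-\d{2}-\d{2}\b")),
    ("full_date", re.compile(r"\b\d{1,2}/\d{1,2}/(\d{4}|\d{2})\b")),
    ("clock_time", re.compile(r"\b\d{1,2}:\d{2}(\s?[ap]\.?m\.?)?\b", re.IGNORECASE)),
    (
        "deictic_relative",
        re.compile(
            r"\b(next|last)\s+(monday|tuesday|wednesday|thursday|friday|"
            r"saturday|sunday|week|month|year)\b",
            re.IGNORECASE,
        ),
    ),
    ("deictic_day", re.compile(r"\b(today|tonight|now|yesterday|tomorrow)\b", re.IGNORECASE)),
    ("month_name", re.compile(rf"\b({_MONTHS_CASELESS})\b", re.IGNORECASE)),
    ("month_name", re.compile(r"\b(May|March|Mar)\b")),
    ("year", re.compile(r"\b(19|20)\d{2}\b")),
]


def recognize_timex(text: str) -> list[TemporalExpression]:
    """Find temporal expressions; overlaps resolved longest-match-first.

    Candidate matches from all patterns are merged by taking, left to right,
    the longest candidate at each position; later candidates overlapping an
    accepted span are discarded ("3/5/2019" beats the bare year "2019" inside
    it).
    """
    candidates: list[tuple[int, int, str, str]] = []
    for kind, pattern in _PATTERNS:
        for m in pattern.finditer(text):
            candidates.append((m.start(), -(m.end() - m.start()), kind, m.group()))
    candidates.sort()
    chosen: list[TemporalExpression] = []
    taken: list[tuple[int, int]] = []
    for start, neg_len, kind, surface in candidates:
        end = start - neg_len
        if any(start < e and end > s for s, e in taken):
            continue
        taken.append((start, end))
        chosen.append(
            TemporalExpression(char_start=start, char_end=end, surface=surface, kind=kind)
        )
    chosen.sort(key=lambda e: e.char_start)
    return chosen


def _month_range(year: int, month: int) -> tuple[date, date]:
    last = calendar.monthrange(year, month)[1]
    return date(year, month, 1), date(year, month, last)


def _resolve_range(
    expr: TemporalExpression, ref: datetime
) -> tuple[date, date] | None:
    refd = ref.date()
    surface = expr.surface
    low = surface.lower()
    if expr.kind == "year":
        year = int(surface)
        return date(year, 1, 1), date(year, 12, 31)
    if expr.kind == "full_date":
        try:
            if "-" in surface:
                d = date.fromisoformat(surface)
            else:
                day_s, month_s, year_s = surface.split("/")
                year = int(year_s)
                if year < 100:
                    year += 2000 if year < 50 else 1900
                d = date(year, int(month_s), int(day_s))
        except ValueError:
            logger.warning("unresolvable date %r", surface)
            return None
        return d, d
    if expr.kind == "deictic_day":
        if low in ("today", "tonight", "now"):
            return refd, refd
        if low == "yesterday":
            d = refd - timedelta(days=1)
            return d, d
        d = refd + timedelta(days=1)  # tomorrow
        return d, d
    if expr.kind == "clock_time":
        return refd, refd
    if expr.kind == "deictic_relative":
        direction, _, unit = low.partition(" ")
        unit = unit.strip()
        sign = 1 if direction == "next" else -1
        if unit in _WEEKDAYS:
            target = _WEEKDAYS[unit]
            if sign > 0:
                delta = (target - refd.weekday() - 1) % 7 + 1
            else:
                delta = -((refd.weekday() - target - 1) % 7 + 1)
            d = refd + timedelta(days=delta)
            return d, d
        if unit == "week":
            monday = refd - timedelta(days=refd.weekday())
            start = monday + timedelta(days=7 * sign)
            return start, start + timedelta(days=6)
        if unit == "month":
            month = refd.month + sign
            year = refd.year
            if month == 0:
                month, year = 12, year - 1
            elif month == 13:
                month, year = 1, year + 1
            return _month_range(year, month)
        if unit == "year":
            year = refd.year + sign
            return date(year, 1, 1), date(year, 12, 31)
        return None
    if expr.kind == "month_name":
        month = _MONTHS[low]
        # Nearest occurrence within +/- 6 months, preferring the future.
        delta = (month - refd.month) % 12
        if delta <= 6:
            year = refd.year + (1 if refd.month + delta > 12 else 0)
        else:
            year = refd.year - (1 if refd.month + delta - 12 < 1 else 0)
        return _month_range(year, month)
    return None


def _relation(resolved: tuple[date, date], ref: datetime) -> Orientation:
    refd = ref.date()
    start, end = resolved
    if end < refd:
        return Orientation.PAST
    if start > refd:
        return Orientation.FUTURE
    return Orientation.PRESENT


def resolve_timex(expr: TemporalExpression, ref: datetime) -> TemporalExpression:
    """Resolve an expression against a reference time and attach its relation.

    Unresolvable expressions (impossible calendar dates, unknown units) are
    returned unchanged apart from a logged warning; their ``relation`` stays
    ``None``.
    """
    resolved = _resolve_range(expr, ref)
    if resolved is None:
        return expr
    return replace(expr, resolved=resolved, relation=_relation(resolved, ref))


def classify_sutime(
    record: ThoughtRecord, default_reference: datetime | None = None
) -> Judgement:
    """Code a record by its explicit temporal expressions.

    Uses the record's own reference time, falling back to
    ``default_reference``.  Without any reference time nothing resolves and
    the record codes "other".  Multiple resolved expressions reduce to the
    earliest span, so the output is always a single orientation.
    """
    ref = record.reference_time or default_reference
    expressions = recognize_timex(record.text)
    resolved: list[TemporalExpression] = []
    if ref is not None:
        resolved = [
            e for e in (resolve_timex(expr, ref) for expr in expressions)
            if e.relation is not None
        ]
    elif expressions:
        logger.warning(
            "record %s: no reference time; %d temporal expression(s) unresolvable",
            record.record_id,
            len(expressions),
        )
    if not resolved:
        return Judgement(method="sutime", orientations=frozenset({Orientation.OTHER}))
    earliest = min(resolved, key=lambda e: e.char_start)
    return Judgement(method="sutime", orientations=frozenset({earliest.relation}))


def _timex_value(expr: TemporalExpression) -> str:
    if expr.kind == "year":
        return expr.surface
    if expr.resolved is not None:
        start, end = expr.resolved
        if start == end:
            return start.isoformat()
        if (start.day, end.day) == (1, calendar.monthrange(end.year, end.month)[1]) and (
            start.year, start.month) == (end.year, end.month):
            return f"{start.year:04d}-{start.month:02d}"
        return f"{start.isoformat()}/{end.isoformat()}"
    return expr.surface


def annotate_timex(text: str, ref: datetime | None = None) -> str:
    """Return ``text`` with inline TIMEX3-like XML tags for inspection.

    Each recognized expression is wrapped as
    ``<TIMEX3 tid="t1" type="DATE" value="...">surface</TIMEX3>``; clock
    times carry ``type="TIME"``.
    """
    expressions = recognize_timex(text)
    if ref is not None:
        expressions = [resolve_timex(e, ref) for e in expressions]
    out: list[str] = []
    pos = 0
    for i, expr in enumerate(expressions, start=1):
        out.append(text[pos : expr.char_start])
        timex_type = "TIME" if expr.kind == "clock_time" else "DATE"
        out.append(
            f'<TIMEX3 tid="t{i}" type="{timex_type}" value="{_timex_value(expr)}">'
            f"{expr.surface}</TIMEX3>"
        )
        pos = expr.char_end
    out.append(text[pos:])
    return "".join(out)
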