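"""Data model and I/O for thought-report corpora.

A corpus is an ordered collection of :class:`ThoughtRecord` objects, one per
momentary-thought report: the free-text description a participant typed, the
participant's own (gold) orientation judgement, and the time the report was
created.  Gold labels may be one of the four orientations, or one of two
sentinel states: *tied* (the participant selected several orientations) and
*missing*.  Records in either sentinel state are dropped by
:func:`filter_valid` before any concordance scoring.

Supported on-disk formats are CSV (UTF-8, header row, quoted fields) and
JSON Lines (one object per line).  Timestamps are ISO-8601.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

logger = logging.getLogger(__name__)

__all__ = [
    "Orientation",
    "GoldSentinel",
    "Gold",
    "ThoughtRecord",
    "Corpus",
    "SchemaError",
    "parse_gold",
    "format_gold",
    "read_corpus",
    "write_corpus",
    "filter_valid",
]


class Orientation(str, Enum):
    """One of the four single-category temporal orientations.

    "mixed" is deliberately not a member: a multi-orientation coder output is
    represented as a set of orientations on a judgement, never as a fifth
    category.
    """

    PAST = "past"
    PRESENT = "present"
    FUTURE = "future"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class GoldSentinel(str, Enum):
    """Sentinel states for a self-report gold label that cannot be scored."""

    TIED = "tied"
    MISSING = "missing"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: A gold label: a single orientation, or tied/missing.
Gold = Union[Orientation, GoldSentinel]

_ORIENTATION_VALUES = {o.value: o for o in Orientation}


class SchemaError(ValueError):
    """A required column or key is absent from an input file."""


def parse_gold(raw: object) -> Gold:
    """Map a raw gold field to an :class:`Orientation` or sentinel.

    Empty / absent values map to ``missing``.  A ";"-separated field with two
    or more distinct valid labels maps to ``tied`` (a participant who selected
    multiple orientations).  The literal strings ``"tied"`` and ``"missing"``
    round-trip.  Unrecognized strings map to ``missing`` with a logged
    warning -- experience-sampling exports are dirty and the exclusion filter
    handles these records anyway.
    """
    if raw is None:
        return GoldSentinel.MISSING
    text = str(raw).strip().lower()
    if not text:
        return GoldSentinel.MISSING
    if text == GoldSentinel.TIED.value:
        return GoldSentinel.TIED
    if text == GoldSentinel.MISSING.value:
        return GoldSentinel.MISSING
    parts = [p.strip() for p in text.split(";") if p.strip()]
    valid = []
    for part in parts:
        if part in _ORIENTATION_VALUES:
            if _ORIENTATION_VALUES[part] not in valid:
                valid.append(_ORIENTATION_VALUES[part])
        else:
            logger.warning("unrecognized gold label %r; treating as missing", part)
    if len(valid) >= 2:
        return GoldSentinel.TIED
    if len(valid) == 1:
        return valid[0]
    return GoldSentinel.MISSING


def format_gold(gold: Gold) -> str:
    """Inverse of :func:`parse_gold` for the values it can produce."""
    if isinstance(gold, Orientation):
        return gold.value
    if gold is GoldSentinel.MISSING:
        return ""
    return gold.value


def _parse_reference_time(raw: object, record_id: str) -> datetime | None:
    if raw is None:
        return None
    text = str(raw).strip()
    if not text:
        return None
    try:
        return datetime.fromisoformat(text)
    except ValueError:
        logger.warning(
            "record %s: malformed reference_time %r; treating as absent", record_id, text
        )
        return None


@dataclass(frozen=True)
class ThoughtRecord:
    """One momentary-thought report."""

    record_id: str
    text: str
    participant_id: str = ""
    gold: Gold = GoldSentinel.MISSING
    reference_time: datetime | None = None

    def with_gold(self, gold: Gold) -> "ThoughtRecord":
        return replace(self, gold=gold)


@dataclass
class Corpus:
    """An ordered, stably iterable collection of thought records."""

    records: list[ThoughtRecord] = field(default_factory=list)
    source: str = ""
    note: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValueError(f"duplicate record_id {rec.record_id!r} in corpus")
            seen.add(rec.record_id)

    def __iter__(self) -> Iterator[ThoughtRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> ThoughtRecord:
        return self.records[i]


_CSV_FIELDS = ["record_id", "participant_id", "text", "gold", "reference_time"]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "jsonl"):
            raise ValueError(f"unknown corpus format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    return "csv"


def _record_from_mapping(row: dict, where: str) -> ThoughtRecord:
    for required in ("record_id", "text"):
        if row.get(required) is None:
            raise SchemaError(f"{where}: missing required field {required!r}")
    record_id = str(row["record_id"])
    return ThoughtRecord(
        record_id=record_id,
        participant_id=str(row.get("participant_id") or ""),
        text=str(row["text"]),
        gold=parse_gold(row.get("gold")),
        reference_time=_parse_reference_time(row.get("reference_time"), record_id),
    )


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from CSV or JSONL.

    ``record_id`` and ``text`` are required; ``participant_id``, ``gold`` and
    ``reference_time`` are optional.  Missing gold maps to the ``missing``
    sentinel, a multi-label gold field to ``tied``; a malformed timestamp is
    dropped with a logged warning.

    Raises
    ------
    SchemaError
        if a required column/key is absent.
    OSError
        if the file cannot be read.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    records: list[ThoughtRecord] = []
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return Corpus(records=[], source=str(path))
            for required in ("record_id", "text"):
                if required not in reader.fieldnames:
                    raise SchemaError(f"{path}: missing required column {required!r}")
            for i, row in enumerate(reader):
                records.append(_record_from_mapping(row, f"{path}:{i + 2}"))
    else:
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                records.append(_record_from_mapping(obj, f"{path}:{i + 1}"))
    return Corpus(records=records, source=str(path))


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus to CSV or JSONL such that :func:`read_corpus` round-trips."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS, quoting=csv.QUOTE_ALL)
            writer.writeheader()
            for rec in corpus:
                writer.writerow(
                    {
                        "record_id": rec.record_id,
                        "participant_id": rec.participant_id,
                        "text": rec.text,
                        "gold": format_gold(rec.gold),
                        "reference_time": (
                            rec.reference_time.isoformat() if rec.reference_time else ""
                        ),
                    }
                )
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in corpus:
                obj = {
                    "record_id": rec.record_id,
                    "participant_id": rec.participant_id,
                    "text": rec.text,
                    "gold": format_gold(rec.gold),
                    "reference_time": (
                        rec.reference_time.isoformat() if rec.reference_time else None
                    ),
                }
                fh.write(json.dumps(obj) + "\n")


def filter_valid(corpus: Corpus) -> tuple[Corpus, int]:
    """Drop records whose gold label is tied or missing.

    Returns the kept corpus (original order preserved) and the number of
    excluded records; ``len(kept) + excluded == len(corpus)`` always, and the
    filter is idempotent.
    """
    kept = [rec for rec in corpus if isinstance(rec.gold, Orientation)]
    excluded = len(corpus) - len(kept)
    return (
        Corpus(records=kept, source=corpus.source, note=corpus.note, meta=dict(corpus.meta)),
        excluded,
    )
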