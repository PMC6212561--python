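"""Orientation cues and the POS-rule classifiers.

Three rule-based coders operate on a tagged sentence:

``naive``
    POS cues only.  Future is marked by a modal (MD); present by present-tense
    verbs (VBG, VBP, VBZ), nouns (NN/NNS) or interjections (UH); past by
    past-tense and participle verbs (VBD, VBN).  A sentence with no markers
    codes "other"; two or more distinct orientations code as a tie (mixed).
``anchored``
    The naive cues plus explicit lexical anchor terms (by default
    "remember*" -> past and "future*" -> future), matched case-insensitively
    by stem prefix.
``no_ties``
    The anchored cues with ties broken by the earliest cue in the sentence
    (smallest token index); a fixed precedence (future > past > present)
    breaks the degenerate case of two cues on one token.  Always emits a
    single orientation.

Noun/interjection cues are *weak*: they count only when no verb-derived or
anchor cue is present.  Without this suppression the worked-example sentence
("... this example") would pick up a spurious present reading from its final
noun on top of the modal-future and participle-past evidence; with it, the
sentence codes as a future/past mixture, which is the intended behaviour of
the naive rule set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import Orientation
from .tagging import TaggedSentence

__all__ = [
    "OrientationCue",
    "Judgement",
    "AnchorLexicon",
    "POS_CUE_TABLE",
    "extract_pos_cues",
    "extract_anchor_cues",
    "classify_naive",
    "classify_anchored",
    "classify_no_ties",
    "DEFAULT_PRECEDENCE",
]


@dataclass(frozen=True)
class OrientationCue:
    """One token-level piece of orientation evidence."""

    orientation: Orientation
    source: str  # "pos" | "anchor"
    strength: str  # "strong" | "weak"
    token_index: int
    trigger_surface: str
    trigger_tag: str

    def __post_init__(self) -> None:
        if self.source == "anchor" and self.strength != "strong":
            raise ValueError("anchor cues are always strong")


@dataclass(frozen=True)
class Judgement:
    """A coder's output for one record."""

    method: str
    orientations: frozenset[Orientation]
    cues: tuple[OrientationCue, ...] = ()

    def __post_init__(self) -> None:
        if not self.orientations:
            raise ValueError("a judgement must contain at least one orientation")

    @property
    def is_tie(self) -> bool:
        return len(self.orientations) >= 2

    @property
    def single(self) -> Orientation:
        """The sole orientation of a tie-free judgement."""
        if self.is_tie:
            raise ValueError("judgement is a tie")
        return next(iter(self.orientations))

    def label(self) -> str:
        """Serialized form, tie members ";"-joined in sorted order."""
        return ";".join(sorted(o.value for o in self.orientations))


#: POS tag -> (orientation, strength) for the naive rule set.
POS_CUE_TABLE: Mapping[str, tuple[Orientation, str]] = {
    "MD": (Orientation.FUTURE, "strong"),
    "VBG": (Orientation.PRESENT, "strong"),
    "VBP": (Orientation.PRESENT, "strong"),
    "VBZ": (Orientation.PRESENT, "strong"),
    "VBD": (Orientation.PAST, "strong"),
    "VBN": (Orientation.PAST, "strong"),
    "NN": (Orientation.PRESENT, "weak"),
    "NNS": (Orientation.PRESENT, "weak"),
    "UH": (Orientation.PRESENT, "weak"),
}

#: Tie-break order when two cues share a token index.
DEFAULT_PRECEDENCE: tuple[Orientation, ...] = (
    Orientation.FUTURE,
    Orientation.PAST,
    Orientation.PRESENT,
)


@dataclass(frozen=True)
class AnchorLexicon:
    """Word stems carrying an explicit orientation, matched by prefix.

    Stems are lower-case; a token matches when its lower-cased surface starts
    with a stem ("remember" fires on "remembered", "remembering").
    """

    stems: tuple[tuple[str, Orientation], ...] = (
        ("remember", Orientation.PAST),
        ("future", Orientation.FUTURE),
    )

    def __post_init__(self) -> None:
        for stem, _ in self.stems:
            if stem != stem.lower():
                raise ValueError(f"anchor stems must be lower-case: {stem!r}")

    @classmethod
    def default(cls) -> "AnchorLexicon":
        return cls()

    @classmethod
    def empty(cls) -> "AnchorLexicon":
        return cls(stems=())

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnchorLexicon":
        """Load a two-column (stem, orientation) CSV, header optional."""
        stems: list[tuple[str, Orientation]] = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or not row[0].strip():
                    continue
                stem, label = row[0].strip().lower(), row[1].strip().lower()
                if stem == "stem" and label == "orientation":
                    continue  # header
                stems.append((stem, Orientation(label)))
        return cls(stems=tuple(stems))

    def match(self, surface: str) -> Orientation | None:
        low = surface.lower()
        for stem, orientation in self.stems:
            if low.startswith(stem):
                return orientation
        return None


def extract_pos_cues(
    sentence: TaggedSentence, include_plural_nouns: bool = True
) -> list[OrientationCue]:
    """Extract POS cues, one per qualifying token, in token order."""
    cues: list[OrientationCue] = []
    for token in sentence.tokens:
        if token.tag == "NNS" and not include_plural_nouns:
            continue
        rule = POS_CUE_TABLE.get(token.tag)
        if rule is None:
            continue
        orientation, strength = rule
        cues.append(
            OrientationCue(
                orientation=orientation,
                source="pos",
                strength=strength,
                token_index=token.index,
                trigger_surface=token.surface,
                trigger_tag=token.tag,
            )
        )
    return cues


def extract_anchor_cues(
    sentence: TaggedSentence, lexicon: AnchorLexicon
) -> list[OrientationCue]:
    """Extract strong anchor-term cues by case-insensitive stem prefix."""
    cues: list[OrientationCue] = []
    for token in sentence.tokens:
        orientation = lexicon.match(token.surface)
        if orientation is not None:
            cues.append(
                OrientationCue(
                    orientation=orientation,
                    source="anchor",
                    strength="strong",
                    token_index=token.index,
                    trigger_surface=token.surface,
                    trigger_tag=token.tag,
                )
            )
    return cues


def _effective(cues: Sequence[OrientationCue]) -> list[OrientationCue]:
    strong = [c for c in cues if c.strength == "strong"]
    return strong if strong else list(cues)


def _aggregate(method: str, cues: Sequence[OrientationCue]) -> Judgement:
    effective = _effective(cues)
    orientations = frozenset(c.orientation for c in effective)
    if not orientations:
        orientations = frozenset({Orientation.OTHER})
    return Judgement(method=method, orientations=orientations, cues=tuple(effective))


def classify_naive(
    sentence: TaggedSentence, include_plural_nouns: bool = True
) -> Judgement:
    """POS-cue coder with ties allowed ("lack of these markers" -> other)."""
    return _aggregate("naive", extract_pos_cues(sentence, include_plural_nouns))


def classify_anchored(
    sentence: TaggedSentence,
    lexicon: AnchorLexicon | None = None,
    include_plural_nouns: bool = True,
) -> Judgement:
    """POS cues plus anchor terms, same aggregation as the naive coder."""
    lexicon = AnchorLexicon.default() if lexicon is None else lexicon
    cues = extract_pos_cues(sentence, include_plural_nouns) + extract_anchor_cues(
        sentence, lexicon
    )
    cues.sort(key=lambda c: c.token_index)
    return _aggregate("anchored", cues)


def classify_no_ties(
    sentence: TaggedSentence,
    lexicon: AnchorLexicon | None = None,
    include_plural_nouns: bool = True,
    precedence: Sequence[Orientation] = DEFAULT_PRECEDENCE,
) -> Judgement:
    """Anchored coder with ties broken by the earliest cue in the sentence.

    Among cues sharing a token index, ``precedence`` decides; the result is
    always a single orientation.
    """
    lexicon = AnchorLexicon.default() if lexicon is None else lexicon
    cues = extract_pos_cues(sentence, include_plural_nouns) + extract_anchor_cues(
        sentence, lexicon
    )
    effective = _effective(cues)
    if not effective:
        return Judgement(method="no_ties", orientations=frozenset({Orientation.OTHER}))
    rank = {o: i for i, o in enumerate(precedence)}
    winner = min(
        effective, key=lambda c: (c.token_index, rank.get(c.orientation, len(rank)))
    )
    return Judgement(
        method="no_ties",
        orientations=frozenset({winner.orientation}),
        cues=(winner,),
    )
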