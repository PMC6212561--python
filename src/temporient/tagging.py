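"""Tokenization and deterministic Penn Treebank POS tagging.

The built-in tagger is a pure function of the input text: a closed-class
lexicon (modals, pronouns, determiners, prepositions, conjunctions, common
adverbs/adjectives, interjections), a numeral pattern, a verb lexicon of
roughly two hundred common English verbs with their irregular past and
participle forms, suffix rules for unknown verbs, and a noun fallback.  It is
intentionally small: the downstream orientation rules consume only the tag
layer, so a deterministic tagger keeps every classification reproducible
without a model download.  External taggers (e.g. a full statistical parser)
can be plugged in through the adapter contract of :func:`tag_external`.

Disambiguation of the -ed ambiguity (simple past VBD vs. past participle
VBN) looks for a preceding auxiliary ("have"/"be" form), skipping adverbs:
"will have remembered" tags VBN, "I remembered" tags VBD.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, NamedTuple, Sequence

__all__ = [
    "Token",
    "TaggedSentence",
    "Span",
    "AdapterContractError",
    "PTB_TAGSET",
    "tokenize",
    "tag_lexicon",
    "tag_external",
    "FixtureTaggerAdapter",
]


class Span(NamedTuple):
    """A token surface with its half-open character span in the source text."""

    surface: str
    char_start: int
    char_end: int


@dataclass(frozen=True)
class Token:
    surface: str
    index: int
    char_start: int
    char_end: int
    tag: str


@dataclass(frozen=True)
class TaggedSentence:
    """Source text with its ordered, tagged, non-overlapping tokens."""

    text: str
    tokens: tuple[Token, ...]

    def tags(self) -> tuple[str, ...]:
        return tuple(t.tag for t in self.tokens)

    def surfaces(self) -> tuple[str, ...]:
        return tuple(t.surface for t in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


class AdapterContractError(ValueError):
    """An external tagger adapter violated its contract."""


# ---------------------------------------------------------------------------
# Tokenization

_PUNCT = set(string.punctuation)


def tokenize(text: str) -> list[Span]:
    """Whitespace tokenization with terminal punctuation detached.

    Leading and trailing punctuation characters become their own tokens; a
    trailing period is kept attached when the remainder still contains a
    period ("e.g." stays one token).  Internal punctuation (apostrophes,
    hyphens) is never split.
    """
    spans: list[Span] = []
    for match in re.finditer(r"\S+", text):
        chunk, start = match.group(), match.start()
        leading: list[Span] = []
        while len(chunk) > 1 and chunk[0] in _PUNCT:
            leading.append(Span(chunk[0], start, start + 1))
            chunk, start = chunk[1:], start + 1
        trailing: list[Span] = []
        end = start + len(chunk)
        while len(chunk) > 1 and chunk[-1] in _PUNCT:
            if chunk[-1] == "." and "." in chunk[:-1]:
                break  # abbreviation-like: keep the final period attached
            trailing.append(Span(chunk[-1], end - 1, end))
            chunk, end = chunk[:-1], end - 1
        spans.extend(leading)
        if chunk:
            spans.append(Span(chunk, start, end))
        spans.extend(reversed(trailing))
    return spans


# ---------------------------------------------------------------------------
# Lexicons

_MODALS = {"will", "would", "shall", "should", "can", "could", "may", "might", "must", "ought"}
_PRONOUNS = {
    "i", "you", "he", "she", "it", "we", "they", "me", "him", "us", "them",
    "myself", "yourself", "himself", "herself", "itself", "ourselves",
    "themselves", "mine", "yours", "hers", "ours", "theirs", "someone",
    "something", "anyone", "anything", "everyone", "everything",
}
_POSSESSIVES = {"my", "your", "his", "her", "its", "our", "their"}
_DETERMINERS = {
    "the", "a", "an", "this", "that", "these", "those", "some", "any", "no",
    "every", "each", "all", "both", "another",
}
_PREPOSITIONS = {
    "in", "on", "at", "by", "of", "for", "with", "about", "against",
    "between", "into", "through", "during", "before", "after", "above",
    "below", "under", "over", "out", "off", "up", "down", "near", "since",
    "until", "while", "because", "if", "than", "as", "like", "around",
    "without", "towards", "toward", "across", "along", "behind", "beside",
    "despite", "except", "inside", "outside", "onto", "upon", "within",
}
_CONJUNCTIONS = {"and", "or", "but", "nor"}
_INTERJECTIONS = {
    "oh", "wow", "hmm", "hmmm", "ugh", "yeah", "hey", "ah", "um", "uh", "hi",
    "hello", "ouch", "oops", "yay", "nah", "meh", "huh", "ha", "haha", "lol",
}
_ADVERBS = {
    "not", "very", "really", "just", "so", "too", "also", "here", "there",
    "now", "then", "always", "never", "often", "sometimes", "soon", "again",
    "still", "already", "quite", "maybe", "perhaps", "well", "back", "away",
    "ever", "later", "earlier", "yet", "almost", "only", "even", "rather",
    "instead", "anyway", "together", "probably",
}
_ADJECTIVES = {
    "good", "bad", "happy", "sad", "big", "small", "new", "old", "nice",
    "great", "little", "much", "more", "most", "busy", "tired", "hungry",
    "late", "early", "same", "other", "sure", "fine", "okay", "ok", "few",
    "many", "next", "last", "free", "ready", "hard", "easy", "long", "short",
    "cold", "hot", "warm", "general", "random",
}

_CLOSED_CLASS: dict[str, str] = {}
for _w in _MODALS:
    _CLOSED_CLASS[_w] = "MD"
for _w in _PRONOUNS:
    _CLOSED_CLASS[_w] = "PRP"
for _w in _POSSESSIVES:
    _CLOSED_CLASS[_w] = "PRP$"
for _w in _DETERMINERS:
    _CLOSED_CLASS[_w] = "DT"
for _w in _PREPOSITIONS:
    _CLOSED_CLASS[_w] = "IN"
for _w in _CONJUNCTIONS:
    _CLOSED_CLASS[_w] = "CC"
for _w in _INTERJECTIONS:
    _CLOSED_CLASS[_w] = "UH"
for _w in _ADVERBS:
    _CLOSED_CLASS[_w] = "RB"
for _w in _ADJECTIVES:
    _CLOSED_CLASS[_w] = "JJ"
_CLOSED_CLASS["to"] = "TO"
_CLOSED_CLASS["what"] = "WP"
_CLOSED_CLASS["who"] = "WP"
_CLOSED_CLASS["which"] = "WDT"
_CLOSED_CLASS["when"] = "WRB"
_CLOSED_CLASS["where"] = "WRB"
_CLOSED_CLASS["why"] = "WRB"
_CLOSED_CLASS["how"] = "WRB"

# Irregular verbs: base -> (simple past, past participle).
_IRREGULAR = {
    "be": ("was", "been"), "have": ("had", "had"), "do": ("did", "done"),
    "go": ("went", "gone"), "say": ("said", "said"), "get": ("got", "gotten"),
    "make": ("made", "made"), "know": ("knew", "known"),
    "think": ("thought", "thought"), "take": ("took", "taken"),
    "see": ("saw", "seen"), "come": ("came", "come"), "find": ("found", "found"),
    "give": ("gave", "given"), "tell": ("told", "told"), "feel": ("felt", "felt"),
    "become": ("became", "become"), "leave": ("left", "left"),
    "put": ("put", "put"), "mean": ("meant", "meant"), "keep": ("kept", "kept"),
    "let": ("let", "let"), "begin": ("began", "begun"), "show": ("showed", "shown"),
    "hear": ("heard", "heard"), "run": ("ran", "run"), "hold": ("held", "held"),
    "bring": ("brought", "brought"), "write": ("wrote", "written"),
    "sit": ("sat", "sat"), "stand": ("stood", "stood"), "lose": ("lost", "lost"),
    "pay": ("paid", "paid"), "meet": ("met", "met"), "set": ("set", "set"),
    "lead": ("led", "led"), "read": ("read", "read"), "grow": ("grew", "grown"),
    "fall": ("fell", "fallen"), "send": ("sent", "sent"),
    "build": ("built", "built"), "understand": ("understood", "understood"),
    "draw": ("drew", "drawn"), "break": ("broke", "broken"),
    "spend": ("spent", "spent"), "cut": ("cut", "cut"), "rise": ("rose", "risen"),
    "drive": ("drove", "driven"), "buy": ("bought", "bought"),
    "wear": ("wore", "worn"), "choose": ("chose", "chosen"),
    "eat": ("ate", "eaten"), "sleep": ("slept", "slept"),
    "drink": ("drank", "drunk"), "sing": ("sang", "sung"),
    "swim": ("swam", "swum"), "win": ("won", "won"), "sell": ("sold", "sold"),
    "catch": ("caught", "caught"), "teach": ("taught", "taught"),
    "fight": ("fought", "fought"), "forget": ("forgot", "forgotten"),
    "fly": ("flew", "flown"), "speak": ("spoke", "spoken"),
    "ride": ("rode", "ridden"), "throw": ("threw", "thrown"),
    "wake": ("woke", "woken"), "ring": ("rang", "rung"),
    "steal": ("stole", "stolen"), "hit": ("hit", "hit"),
    "hurt": ("hurt", "hurt"), "shut": ("shut", "shut"),
    "lend": ("lent", "lent"), "bend": ("bent", "bent"),
    "deal": ("dealt", "dealt"), "hang": ("hung", "hung"),
    "feed": ("fed", "fed"), "shake": ("shook", "shaken"),
}

# Regular verbs (inflections generated); "plan" is deliberately absent so
# "plans" tags NNS, not VBZ.
_REGULAR = [
    "want", "like", "need", "look", "use", "ask", "seem", "help", "talk",
    "turn", "start", "play", "move", "live", "believe", "happen", "include",
    "continue", "change", "watch", "follow", "stop", "create", "open",
    "walk", "offer", "remember", "love", "consider", "appear", "wait",
    "serve", "die", "expect", "stay", "reach", "kill", "remain", "suggest",
    "raise", "pass", "require", "report", "decide", "pull", "return",
    "explain", "hope", "develop", "carry", "receive", "agree", "support",
    "hate", "cause", "listen", "finish", "study", "visit", "relax", "enjoy",
    "call", "work", "try", "clean", "cook", "shop", "chat", "text", "jog",
    "nap", "worry", "miss", "wonder", "wish", "practice", "prepare",
    "organise", "organize", "travel", "paint", "dance", "laugh", "cry",
    "smile", "answer", "argue", "arrive", "attend", "bake", "borrow",
    "check", "climb", "close", "collect", "complete", "count", "cover",
    "cross", "daydream", "deliver", "discuss", "dress", "dream", "email",
    "empty", "end", "exercise", "fail", "fill", "fix", "fold", "gather",
    "greet", "guess", "imagine", "invite", "join", "jump", "kick", "kiss",
    "knock", "learn", "lift", "lock", "mark", "marry", "mention", "mind",
    "notice", "order", "pack", "park", "phone", "pick", "point", "post",
    "pour", "print", "promise", "push", "rain", "realise", "realize",
    "recall", "remind", "rent", "repeat", "rest", "ring", "save", "search",
    "share", "shout", "sign", "slip", "smell", "sort", "sound", "stress",
    "stretch", "submit", "taste", "thank", "tidy", "train", "type", "wash",
    "wave", "wipe", "yell",
]

_DOUBLING = {"stop", "shop", "chat", "jog", "nap", "slip", "plan", "grab", "hug", "drop"}

# Common nouns whose shape collides with a verb suffix rule.
_NOUN_EXCEPTIONS = {
    "morning": "NN", "evening": "NN", "thing": "NN", "things": "NNS",
    "nothing": "NN", "wedding": "NN", "ceiling": "NN", "building": "NN",
    "breakfast": "NN", "bed": "NN", "weekend": "NN", "friend": "NN",
    "friends": "NNS", "news": "NN",
}
_AUXILIARIES = {
    "have", "has", "had", "having", "'ve", "'d",
    "be", "am", "is", "are", "was", "were", "been", "being", "'m", "'re", "'s",
}


def _third_person(base: str) -> str:
    if base.endswith(("s", "sh", "ch", "x", "z", "o")):
        return base + "es"
    if base.endswith("y") and base[-2:-1] not in "aeiou":
        return base[:-1] + "ies"
    return base + "s"


def _gerund(base: str) -> str:
    if base in _DOUBLING:
        return base + base[-1] + "ing"
    if base.endswith("e") and not base.endswith(("ee", "ye", "oe")):
        return base[:-1] + "ing"
    return base + "ing"


def _regular_past(base: str) -> str:
    if base in _DOUBLING:
        return base + base[-1] + "ed"
    if base.endswith("e"):
        return base + "d"
    if base.endswith("y") and base[-2:-1] not in "aeiou":
        return base[:-1] + "ied"
    return base + "ed"


def _build_verb_forms() -> tuple[dict[str, str], set[str]]:
    """Map verb surface forms to a tag kind; return (forms, bases)."""
    forms: dict[str, str] = {}
    bases: set[str] = set()

    def put(form: str, kind: str) -> None:
        forms.setdefault(form, kind)

    for base, (past, part) in _IRREGULAR.items():
        bases.add(base)
        put(base, "base")
        put(_third_person(base), "3sg")
        put(_gerund(base), "ing")
        if past == part:
            put(past, "pastpart")
        else:
            put(past, "past")
            put(part, "part")
    for base in _REGULAR:
        bases.add(base)
        put(base, "base")
        put(_third_person(base), "3sg")
        put(_gerund(base), "ing")
        put(_regular_past(base), "pastpart")
    # Copula/auxiliary special forms.
    forms.update(
        {"am": "1sg", "is": "3sg", "are": "pl", "was": "past", "were": "past",
         "been": "part", "being": "ing", "has": "3sg", "having": "ing",
         "does": "3sg", "done": "part", "did": "past"}
    )
    return forms, bases


_VERB_FORMS, _VERB_BASES = _build_verb_forms()

_CD_RE = re.compile(r"^\d+([.,/:\-]\d+)*(st|nd|rd|th)?$")
_PUNCT_TAGS = {
    ".": ".", "!": ".", "?": ".", ",": ",", ";": ":", ":": ":", "...": ":",
    "(": "-LRB-", ")": "-RRB-", "$": "$", "#": "#", "‘": "``",
    "’": "''", '"': "''", "'": "''", "`": "``", "-": ":", "--": ":",
}

PTB_TAGSET = frozenset(
    {
        "CC", "CD", "DT", "EX", "FW", "IN", "JJ", "JJR", "JJS", "LS", "MD",
        "NN", "NNS", "NNP", "NNPS", "PDT", "POS", "PRP", "PRP$", "RB", "RBR",
        "RBS", "RP", "SYM", "TO", "UH", "VB", "VBD", "VBG", "VBN", "VBP",
        "VBZ", "WDT", "WP", "WP$", "WRB", ".", ",", ":", "''", "``", "-LRB-",
        "-RRB-", "$", "#",
    }
)


def _prev_content(spans: Sequence[Span], tags: Sequence[str], i: int) -> tuple[str, str]:
    """Nearest preceding (surface, tag), skipping adverbs and punctuation."""
    for j in range(i - 1, -1, -1):
        if tags[j] in ("RB", ".", ",", ":", "''", "``"):
            continue
        return spans[j].surface.lower(), tags[j]
    return "", ""


def _ed_tag(spans: Sequence[Span], tags: Sequence[str], i: int) -> str:
    surface, _tag = _prev_content(spans, tags, i)
    return "VBN" if surface in _AUXILIARIES else "VBD"


def _tag_span(spans: Sequence[Span], tags: list[str], i: int) -> str:
    surface = spans[i].surface
    low = surface.lower()
    if all(ch in _PUNCT for ch in surface):
        return _PUNCT_TAGS.get(surface, "SYM")
    if low in _CLOSED_CLASS:
        return _CLOSED_CLASS[low]
    if _CD_RE.match(low):
        return "CD"
    if low in _NOUN_EXCEPTIONS:
        return _NOUN_EXCEPTIONS[low]
    kind = _VERB_FORMS.get(low)
    if kind is not None:
        if kind == "base":
            _surf, prev_tag = _prev_content(spans, tags, i)
            return "VB" if prev_tag in ("MD", "TO") else "VBP"
        if kind in ("1sg", "pl"):
            return "VBP"
        if kind == "3sg":
            return "VBZ"
        if kind == "ing":
            return "VBG"
        if kind == "past":
            return "VBD"
        if kind == "part":
            return "VBN"
        if kind == "pastpart":
            return _ed_tag(spans, tags, i)
    if low.endswith("ed") and len(low) > 3:
        return _ed_tag(spans, tags, i)
    if low.endswith("ing") and len(low) > 4:
        return "VBG"
    if low.endswith("s") and not low.endswith("ss") and len(low) > 2:
        stem = low[:-1]
        if stem in _VERB_BASES or (low.endswith("es") and low[:-2] in _VERB_BASES):
            return "VBZ"
        if low.endswith("ies") and low[:-3] + "y" in _VERB_BASES:
            return "VBZ"
        return "NNS"
    return "NN"


def tag_lexicon(text: str, spans: Sequence[Span] | None = None) -> TaggedSentence:
    """Tag ``text`` with the built-in deterministic lexicon tagger.

    ``spans`` may be supplied to reuse an existing tokenization; otherwise
    :func:`tokenize` is applied first.
    """
    if spans is None:
        spans = tokenize(text)
    tags: list[str] = []
    for i in range(len(spans)):
        tags.append(_tag_span(spans, tags, i))
    tokens = tuple(
        Token(surface=s.surface, index=i, char_start=s.char_start, char_end=s.char_end, tag=t)
        for i, (s, t) in enumerate(zip(spans, tags))
    )
    return TaggedSentence(text=text, tokens=tokens)


# ---------------------------------------------------------------------------
# External tagger contract

TaggerAdapter = Callable[[Sequence[str]], Sequence[str]]


def tag_external(
    text: str, adapter: TaggerAdapter, spans: Sequence[Span] | None = None
) -> TaggedSentence:
    """Tag with an external adapter (token surfaces in, PTB tag strings out).

    The adapter output is validated for length and tagset membership so that
    downstream cue extraction can rely on the same contract as the built-in
    tagger.
    """
    if spans is None:
        spans = tokenize(text)
    surfaces = [s.surface for s in spans]
    tags = list(adapter(surfaces))
    if len(tags) != len(surfaces):
        raise AdapterContractError(
            f"adapter returned {len(tags)} tags for {len(surfaces)} tokens"
        )
    for tag in tags:
        if tag not in PTB_TAGSET:
            raise AdapterContractError(f"adapter returned non-PTB tag {tag!r}")
    tokens = tuple(
        Token(surface=s.surface, index=i, char_start=s.char_start, char_end=s.char_end, tag=t)
        for i, (s, t) in enumerate(zip(spans, tags))
    )
    return TaggedSentence(text=text, tokens=tokens)


class FixtureTaggerAdapter:
    """Replay recorded tags from a two-column TSV fixture.

    The fixture holds blank-line-separated sentence blocks of
    ``surface<TAB>tag`` lines; lookup is by the exact token-surface sequence.
    """

    def __init__(self, path: str | Path):
        self._table: dict[tuple[str, ...], tuple[str, ...]] = {}
        surfaces: list[str] = []
        tags: list[str] = []
        for line in Path(path).read_text(encoding="utf-8").splitlines() + [""]:
            if not line.strip():
                if surfaces:
                    self._table[tuple(surfaces)] = tuple(tags)
                surfaces, tags = [], []
                continue
            surface, _, tag = line.partition("\t")
            surfaces.append(surface)
            tags.append(tag.strip())

    def __call__(self, surfaces: Sequence[str]) -> Sequence[str]:
        key = tuple(surfaces)
        if key not in self._table:
            raise AdapterContractError(f"no recorded tags for token sequence {key!r}")
        return list(self._table[key])
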