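"""Concordance scoring of coder judgements against self-report gold labels.

A judgement is *correct* when its orientation matches the participant's own
self-report.  Two scoring modes exist: ``strict`` (the default) counts a
multi-orientation (mixed) judgement as incorrect regardless of its members;
``lenient`` counts it correct when the gold label is among them.  Strict is
the default because allowing ties can only lower a coder's accuracy under
it, which is the phenomenon the concordance comparison is designed to
expose; lenient is provided for sensitivity analysis.

With four orientations, a coder guessing uniformly at random scores 25% in
expectation whatever the gold distribution; :func:`chance_baseline` checks
this by seeded Monte-Carlo.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus import Corpus, Orientation
from .cues import Judgement

__all__ = [
    "ConcordanceReport",
    "score_record",
    "concordance",
    "chance_baseline",
    "write_reports_json",
    "format_reports_text",
]

_CATS = [o.value for o in Orientation]


def score_record(judgement: Judgement, gold: Orientation, mode: str = "strict") -> bool:
    """Return whether a judgement is correct against a single gold label."""
    if not isinstance(gold, Orientation):
        raise ValueError(
            f"gold must be a single orientation, got {gold!r}; filter the corpus first"
        )
    if mode == "strict":
        return not judgement.is_tie and judgement.single == gold
    if mode == "lenient":
        return gold in judgement.orientations
    raise ValueError(f"unknown scoring mode {mode!r}")


@dataclass
class ConcordanceReport:
    """Accuracy and confusion structure for one method over one corpus.

    ``confusion`` maps (gold, judged) orientation-value pairs to counts; a
    tie contributes one count per member orientation, so the confusion total
    can exceed ``n_records`` exactly when ties occurred.
    """

    method: str
    n_records: int
    n_correct: int
    tie_count: int
    scoring_mode: str
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.n_correct / self.n_records

    def to_dict(self) -> dict:
        nested: dict[str, dict[str, int]] = {}
        for (gold, judged), count in sorted(self.confusion.items()):
            nested.setdefault(gold, {})[judged] = count
        return {
            "method": self.method,
            "scoring_mode": self.scoring_mode,
            "n_records": self.n_records,
            "n_correct": self.n_correct,
            "accuracy_pct": round(self.accuracy_pct, 2),
            "tie_count": self.tie_count,
            "confusion": nested,
        }


def concordance(
    judgements: Sequence[Judgement],
    corpus: Corpus,
    mode: str = "strict",
    method: str | None = None,
) -> ConcordanceReport:
    """Aggregate :func:`score_record` over a pre-filtered corpus.

    Requires one judgement per record, aligned by position, and at least one
    record; every gold label must be a single orientation (apply
    :func:`temporient.corpus.filter_valid` first).
    """
    if len(judgements) != len(corpus):
        raise ValueError(
            f"{len(judgements)} judgements for {len(corpus)} records"
        )
    if len(corpus) == 0:
        raise ValueError("cannot score an empty corpus")
    n_correct = 0
    tie_count = 0
    confusion: dict[tuple[str, str], int] = {}
    names = {j.method for j in judgements}
    for judgement, record in zip(judgements, corpus):
        correct = score_record(judgement, record.gold, mode)
        n_correct += int(correct)
        tie_count += int(judgement.is_tie)
        for judged in judgement.orientations:
            key = (record.gold.value, judged.value)
            confusion[key] = confusion.get(key, 0) + 1
    return ConcordanceReport(
        method=method or (names.pop() if len(names) == 1 else "mixed-methods"),
        n_records=len(corpus),
        n_correct=n_correct,
        tie_count=tie_count,
        scoring_mode=mode,
        confusion=confusion,
    )


def chance_baseline(
    corpus: Corpus, n_reps: int = 200, seed: int | None = None
) -> tuple[float, float]:
    """Monte-Carlo accuracy of a uniform-random single-orientation coder.

    Each repetition assigns every record one of the four orientations
    uniformly at random and scores strict accuracy.  Returns the mean
    accuracy (percent) over repetitions and its Monte-Carlo standard error.
    The expectation is 25% regardless of the gold label mix.
    """
    if len(corpus) == 0:
        raise ValueError("cannot score an empty corpus")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    index = {o: i for i, o in enumerate(Orientation)}
    gold = np.array([index[rec.gold] for rec in corpus])
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 4, size=(n_reps, len(gold)))
    accuracies = 100.0 * (draws == gold).mean(axis=1)
    se = float(accuracies.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return float(accuracies.mean()), se


def write_reports_json(reports: Sequence[ConcordanceReport], path: str | Path) -> None:
    payload = [r.to_dict() for r in reports]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def format_reports_text(reports: Sequence[ConcordanceReport]) -> str:
    """Aligned-column plain-text table: method, mode, accuracy, ties, confusion."""
    lines = [
        f"{'method':<12} {'mode':<8} {'n':>6} {'accuracy%':>10} {'ties':>6}  confusion (gold->judged)"
    ]
    for r in reports:
        cells = " ".join(
            f"{g[:4]}->{j[:4]}:{c}" for (g, j), c in sorted(r.confusion.items())
        )
        lines.append(
            f"{r.method:<12} {r.scoring_mode:<8} {r.n_records:>6} "
            f"{r.accuracy_pct:>10.2f} {r.tie_count:>6}  {cells}"
        )
    return "\n".join(lines) + "\n"
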