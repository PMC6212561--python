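"""Synthetic experience-sampling corpus generator.

Generates thought-report corpora with *known* gold labels whose statistical
structure emulates the study corpus the package's evaluation pipeline was
designed around:

* four-category self-report mix — past 19.03%, present 58.78%,
  future 19.56%, other 2.64%;
* a fixed count of records with tied or missing self-report (379 of 2884 by
  default), which the exclusion filter removes;
* record lengths clipped to [1, 358] characters with mean ≈ 43;
* per-participant response counts with mean ≈ 14 of 20 prompts (SD ≈ 6),
  drawn beta-binomially;
* a controllable rate of *cue-ambiguous* records whose text mixes cues of
  two orientations while keeping a single gold label — these depress
  measured coder accuracy, the central phenomenon the evaluation exposes.

Texts come from a template bank, not a language model: every unambiguous
template is verified at build time to be recovered by the built-in tagger
plus naive POS-rule coder as exactly its intended orientation, which gives
the generator a construction-level ground truth.  Realism of linguistic
diversity is explicitly secondary.

Two independent RNG substreams are used (labels/text vs. ambiguity flags) so
that at a fixed seed the set of ambiguous records grows monotonically with
``ambiguity_rate``.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from importlib import resources
from itertools import product
from pathlib import Path

import numpy as np

from .corpus import Corpus, Gold, GoldSentinel, Orientation, ThoughtRecord
from .cues import classify_naive
from .tagging import tag_lexicon

__all__ = ["GeneratorConfig", "TemplateBank", "generate_corpus", "summarize_corpus"]

#: Self-report category mix of the emulated study corpus.  The published
#: rounded percentages sum to 100.01%, so they are renormalized here.
_RAW_CATEGORY_PROBS = {
    Orientation.PAST: 0.1903,
    Orientation.PRESENT: 0.5878,
    Orientation.FUTURE: 0.1956,
    Orientation.OTHER: 0.0264,
}
_RAW_TOTAL = sum(_RAW_CATEGORY_PROBS.values())
DEFAULT_CATEGORY_PROBS: dict[Orientation, float] = {
    o: p / _RAW_TOTAL for o, p in _RAW_CATEGORY_PROBS.items()
}

_TIED_OR_MISSING_RATE = 379 / 2884

# Gamma-distributed target lengths; shape/scale chosen so the realized
# character-length mean lands at ~43 after template discretization.
_LENGTH_GAMMA_SHAPE = 1.6
_LENGTH_GAMMA_SCALE = 27.6
_LENGTH_MIN, _LENGTH_MAX = 1, 358

# Prompt schedule of the emulated design: 20 SMS prompts over 2 days,
# 8 am - 8 pm, mean 14 responses per participant with SD 6.
_N_PROMPTS = 20
_RESPONSE_MEAN = 14.0
_RESPONSE_SD = 6.0
_STUDY_START = datetime(2017, 9, 4, 0, 0)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic corpus.

    ``tied_or_missing_count`` defaults to the study proportion 379/2884 of
    ``n_records``; ``ambiguity_rate`` is the probability that a record's text
    mixes cues of two orientations (its gold label stays single, as in real
    self-report).
    """

    n_records: int = 2884
    category_probs: dict[Orientation, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    tied_or_missing_count: int | None = None
    ambiguity_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ConfigError("n_records must be >= 0")
        total = sum(self.category_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"category_probs must sum to 1 (got {total!r})")
        if any(p < 0 for p in self.category_probs.values()):
            raise ConfigError("category_probs must be non-negative")
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ConfigError("ambiguity_rate must be in [0, 1]")
        if self.tied_or_missing_count is not None and not (
            0 <= self.tied_or_missing_count <= self.n_records
        ):
            raise ConfigError("tied_or_missing_count out of range")

    @property
    def resolved_tied_or_missing(self) -> int:
        if self.tied_or_missing_count is not None:
            return self.tied_or_missing_count
        return round(self.n_records * _TIED_OR_MISSING_RATE)


class TemplateBank:
    """Per-orientation sentence templates with slot words.

    Unambiguous templates are constructed so that the built-in lexicon
    tagger plus the naive POS-rule coder recover exactly the intended
    orientation; :meth:`verify` asserts this over the full slot vocabulary at
    construction.  "Ambiguous" templates deliberately mix the cues of two
    orientations and must classify as a tie.
    """

    def __init__(
        self,
        templates: dict[str, list[str]],
        fillers: dict[str, list[str]],
        slots: dict[str, list[str]],
        verify: bool = True,
    ):
        self.templates = templates
        self.fillers = fillers
        self.slots = slots
        for orientation in Orientation:
            if not templates.get(orientation.value):
                raise ConfigError(f"template bank has no templates for {orientation.value!r}")
        if verify:
            self.verify()

    @classmethod
    def from_json(cls, path: str | Path, verify: bool = True) -> "TemplateBank":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            templates=data["templates"],
            fillers=data.get("fillers", {}),
            slots=data.get("slots", {}),
            verify=verify,
        )

    @classmethod
    def default(cls) -> "TemplateBank":
        global _DEFAULT_BANK
        if _DEFAULT_BANK is None:
            with resources.files("temporient.data").joinpath("templates.json").open(
                "r", encoding="utf-8"
            ) as fh:
                data = json.load(fh)
            _DEFAULT_BANK = cls(
                templates=data["templates"],
                fillers=data.get("fillers", {}),
                slots=data.get("slots", {}),
            )
        return _DEFAULT_BANK

    # -- rendering ---------------------------------------------------------

    def _slot_names(self, template: str) -> list[str]:
        return [f for _, f, _, _ in string.Formatter().parse(template) if f]

    def render(self, template: str, rng: np.random.Generator) -> str:
        values = {
            name: self.slots[name][rng.integers(len(self.slots[name]))]
            for name in set(self._slot_names(template))
        }
        return template.format(**values)

    def renderings(self, template: str) -> list[str]:
        """All slot fillings of a template (used by :meth:`verify`)."""
        names = sorted(set(self._slot_names(template)))
        if not names:
            return [template]
        combos = product(*(self.slots[name] for name in names))
        return [template.format(**dict(zip(names, combo))) for combo in combos]

    def verify(self) -> None:
        """Assert the label-recovery invariant of every template and filler."""
        for orientation in Orientation:
            key = orientation.value
            base = self.renderings(self.templates[key][0])[0]
            candidates = [
                text
                for template in self.templates[key]
                for text in self.renderings(template)
            ] + [
                base + filler_text
                for filler in self.fillers.get(key, [])
                for filler_text in self.renderings(filler)
            ]
            for text in candidates:
                judgement = classify_naive(tag_lexicon(text))
                if judgement.orientations != frozenset({orientation}):
                    raise ConfigError(
                        f"template text {text!r} classifies as "
                        f"{sorted(o.value for o in judgement.orientations)}, "
                        f"expected {key!r}"
                    )
        for template in self.templates.get("ambiguous", []):
            for text in self.renderings(template):
                judgement = classify_naive(tag_lexicon(text))
                if not judgement.is_tie:
                    raise ConfigError(
                        f"ambiguous template text {text!r} does not classify as a tie"
                    )


_DEFAULT_BANK: TemplateBank | None = None


def _response_counts(rng: np.random.Generator, n_records: int) -> list[int]:
    """Beta-binomial per-participant response counts summing to n_records."""
    p = _RESPONSE_MEAN / _N_PROMPTS
    npq = _N_PROMPTS * p * (1 - p)
    rho = max((_RESPONSE_SD**2 / npq - 1) / (_N_PROMPTS - 1), 0.0)
    counts: list[int] = []
    total = 0
    while total < n_records:
        if rho > 0:
            s = (1 - rho) / rho
            p_i = rng.beta(p * s, (1 - p) * s)
        else:
            p_i = p
        count = max(int(rng.binomial(_N_PROMPTS, p_i)), 1)
        count = min(count, n_records - total)
        counts.append(count)
        total += count
    return counts


def _build_text(
    rng: np.random.Generator, bank: TemplateBank, pool: str, target_length: int
) -> str:
    templates = bank.templates[pool]
    rendered = [bank.render(t, rng) for t in templates]
    fitting = [t for t in rendered if len(t) <= target_length]
    if fitting:
        text = max(fitting, key=len)
    else:
        text = min(rendered, key=len)
    fillers = bank.fillers.get(pool, [])
    while fillers and len(text) < target_length:
        filler = bank.render(fillers[rng.integers(len(fillers))], rng)
        new_length = len(text) + len(filler)
        if new_length > _LENGTH_MAX:
            break
        # append only if it brings the length closer to target
        if abs(new_length - target_length) >= abs(len(text) - target_length):
            break
        text += filler
    return text[:_LENGTH_MAX]


def generate_corpus(
    config: GeneratorConfig | None = None, bank: TemplateBank | None = None
) -> Corpus:
    """Generate a corpus under ``config``; reproducible at a fixed seed.

    Records flagged ambiguous (per ``ambiguity_rate``) draw their text from
    the mixed-cue template pool but keep their single sampled gold label.
    Tied/missing-gold records keep an orientation-consistent text; only
    their gold field carries the sentinel.  Ambiguous record ids are listed
    in ``corpus.meta["ambiguous_record_ids"]``.
    """
    config = GeneratorConfig() if config is None else config
    bank = TemplateBank.default() if bank is None else bank
    n = config.n_records

    seed_seq = np.random.SeedSequence(config.seed)
    main_seed, ambiguity_seed = seed_seq.spawn(2)
    rng = np.random.default_rng(main_seed)
    rng_ambiguity = np.random.default_rng(ambiguity_seed)

    orientations = list(config.category_probs)
    probs = np.array([config.category_probs[o] for o in orientations])
    labels = rng.choice(len(orientations), size=n, p=probs)
    ambiguous_flags = rng_ambiguity.random(n) < config.ambiguity_rate

    sentinel_gold: dict[int, GoldSentinel] = {}
    m = config.resolved_tied_or_missing
    if m:
        chosen = rng.choice(n, size=m, replace=False)
        kinds = rng.random(m) < 0.5
        for idx, is_tied in zip(chosen, kinds):
            sentinel_gold[int(idx)] = GoldSentinel.TIED if is_tied else GoldSentinel.MISSING

    counts = _response_counts(rng, n)
    participant_of: list[int] = []
    for pid, count in enumerate(counts):
        participant_of.extend([pid] * count)
    # per-participant 2-day window within an 8-week term
    start_day = {pid: int(rng.integers(0, 56)) for pid in range(len(counts))}

    target_lengths = np.clip(
        1 + rng.gamma(_LENGTH_GAMMA_SHAPE, _LENGTH_GAMMA_SCALE, size=n),
        _LENGTH_MIN,
        _LENGTH_MAX,
    ).astype(int)

    records: list[ThoughtRecord] = []
    ambiguous_ids: list[str] = []
    for i in range(n):
        orientation = orientations[labels[i]]
        pool = "ambiguous" if (ambiguous_flags[i] and bank.templates.get("ambiguous")) else orientation.value
        text = _build_text(rng, bank, pool, int(target_lengths[i]))
        gold: Gold = sentinel_gold.get(i, orientation)
        pid = participant_of[i]
        day = int(rng.integers(0, 2))
        minute = int(rng.integers(0, 12 * 60))  # 8 am - 8 pm window
        reference_time = _STUDY_START + timedelta(
            days=start_day[pid] + day, hours=8, minutes=minute
        )
        record_id = f"r{i + 1:06d}"
        if ambiguous_flags[i]:
            ambiguous_ids.append(record_id)
        records.append(
            ThoughtRecord(
                record_id=record_id,
                participant_id=f"p{pid + 1:04d}",
                text=text,
                gold=gold,
                reference_time=reference_time,
            )
        )
    return Corpus(
        records=records,
        source="synthetic",
        note=(
            f"generated: n={n}, tied_or_missing={m}, "
            f"ambiguity_rate={config.ambiguity_rate}, seed={config.seed}"
        ),
        meta={
            "seed": config.seed,
            "ambiguity_rate": config.ambiguity_rate,
            "ambiguous_record_ids": ambiguous_ids,
            "tied_or_missing_count": m,
        },
    )


def summarize_corpus(corpus: Corpus) -> dict:
    """Empirical summaries: label mix, lengths, per-participant responses."""
    n = len(corpus)
    valid = [rec for rec in corpus if isinstance(rec.gold, Orientation)]
    tied = sum(1 for rec in corpus if rec.gold is GoldSentinel.TIED)
    missing = sum(1 for rec in corpus if rec.gold is GoldSentinel.MISSING)
    proportions = {
        o.value: (
            sum(1 for rec in valid if rec.gold is o) / len(valid) if valid else 0.0
        )
        for o in Orientation
    }
    lengths = [len(rec.text) for rec in corpus]
    per_participant: dict[str, int] = {}
    for rec in corpus:
        if rec.participant_id:
            per_participant[rec.participant_id] = per_participant.get(rec.participant_id, 0) + 1
    response_counts = np.array(list(per_participant.values())) if per_participant else np.array([])
    summary = {
        "n_records": n,
        "n_valid": len(valid),
        "tied_count": tied,
        "missing_count": missing,
        "label_proportions": proportions,
        "length": {
            "mean": float(np.mean(lengths)) if lengths else 0.0,
            "min": int(min(lengths)) if lengths else 0,
            "max": int(max(lengths)) if lengths else 0,
        },
        "participants": {
            "n": len(per_participant),
            "responses_mean": float(response_counts.mean()) if per_participant else 0.0,
            "responses_sd": (
                float(response_counts.std(ddof=1)) if len(per_participant) > 1 else 0.0
            ),
            "responses_min": int(response_counts.min()) if per_participant else 0,
            "responses_max": int(response_counts.max()) if per_participant else 0,
        },
    }
    if "ambiguous_record_ids" in corpus.meta:
        count = len(corpus.meta["ambiguous_record_ids"])
        summary["ambiguous_count"] = count
        summary["ambiguous_proportion"] = count / n if n else 0.0
    return summary
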