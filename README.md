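# temporient

Rule-based temporal-orientation coding of short English text, with
self-report concordance evaluation and a synthetic experience-sampling
corpus generator.

## The problem

Experience-sampling studies and social-media corpora yield large numbers of
very short text reports of momentary thoughts ("thinking about dinner",
"In 2019, I will have remembered this example"). Researchers studying
temporal cognition want to know each report's *temporal orientation* —
whether the thought refers to the **past**, **present** or **future** (or
none of these, "**other**") — but English tense is a slippery guide:
present-tense forms describe future events, past participles appear in
future constructions, and many reports carry no tense cue at all. The
defensible gold standard is the participant's own categorical self-report,
and the scientific question is how closely any *post hoc* coder — human or
automated — concords with it.

`temporient` implements the automated side of that comparison as a small,
fully deterministic pipeline:

- **tagging** — a pure-function Penn Treebank POS tagger (closed-class
  lexicon, ~200-verb lexicon with irregular forms, suffix rules, noun
  fallback), plus an adapter contract for plugging in external taggers;
- **cues** — three tense-rule coders over the tag layer:
  - *naive*: MD ⇒ future; VBG/VBP/VBZ ⇒ present; VBD/VBN ⇒ past; NN/NNS/UH
    ⇒ present (weak — counted only when no verb cue exists); no markers ⇒
    other; ≥2 distinct orientations ⇒ tie ("mixed");
  - *anchored*: naive plus explicit anchor stems (`remember*` ⇒ past,
    `future*` ⇒ future), matched case-insensitively by prefix;
  - *no_ties*: anchored with ties broken by the earliest cue in the
    sentence — always a single label;
- **timex** — a SUTime-style coder: recognize explicit temporal expressions
  (years, month names, numeric dates, "yesterday"/"tomorrow"/"today",
  "next week"/"last Friday", clock times), resolve each to a calendar day
  range against the record's creation time *t₀*, and code future/past/
  present according to whether the range lies entirely after, entirely
  before, or contains the day of *t₀*;
- **evaluation** — concordance = % of records whose coded orientation
  matches self-report, in *strict* mode (a mixed judgement is never
  correct) or *lenient* mode (correct when the gold label is a member),
  with tie-expanded confusion counts and a seeded Monte-Carlo chance
  baseline (analytically 25% with four categories);
- **synthetic** — a template-based corpus generator that emulates the
  statistical structure of a real SMS experience-sampling corpus
  (label mix past 19.03% / present 58.78% / future 19.56% / other 2.64%;
  379 of 2884 records with tied-or-missing self-report; lengths in
  [1, 358] characters with mean ≈ 43; ~20 prompts per participant with
  mean 14 responses), with a controllable rate of cue-ambiguous records
  whose text mixes two orientations' cues while keeping a single gold
  label.

## Worked example

```bash
python examples/01_code_a_sentence.py
```

prints

```
text: 'In 2019, I will have remembered this example'
tags: In/IN 2019/CD ,/, I/PRP will/MD have/VB remembered/VBN this/DT example/NN
    naive: future;past (tie)
 anchored: future;past (tie)
  no_ties: future
   sutime: future
```

The modal `will/MD` is a future cue and the participle `remembered/VBN` a
past cue, so the tie-allowing coders report a future/past mixture; the
tie-breaking coder takes the earliest cue (the modal) and commits to
future; and the expression coder tags `2019`, which lies after the 2018
reference time, also future. `examples/02_simulate_and_evaluate.py` runs
the full generate → filter → classify → score pipeline (at
`ambiguity_rate=0.3` it prints, e.g., naive strict accuracy 70.98% vs.
lenient 90.62% over 2505 records, with a chance baseline of 24.97%), and
`examples/03_temporal_expressions.py` walks the TIMEX3-style annotation
layer.

There is also a thin CLI:

```bash
temporient simulate --n 2884 --seed 1 --output corpus.csv --summary summary.json
temporient classify --input corpus.csv --output coded.csv --ref-time 2018-06-15T12:00
temporient evaluate --input corpus.csv --output-json reports.json
```

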