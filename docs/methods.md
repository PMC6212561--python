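# Methods

This note documents the models and procedures implemented in `temporient`,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Orientation model

A *temporal orientation* is one of four categories: past, present, future,
other. "Mixed" is not a fifth category: a coder that proposes several
candidate orientations for one record emits a multi-element orientation
set (a *tie*), and scoring decides how to treat it. Self-report gold labels
are always single categories; records where the participant nevertheless
selected several (tied) or none (missing) are excluded from scoring by
`filter_valid`, which is idempotent and preserves order.

## The deterministic tagger

The built-in POS tagger is a pure function of the text, by design: the
object of study here is the *rule layer* that maps tags to orientations,
and a deterministic tagger makes every downstream judgement exactly
reproducible with no model download. Tagging proceeds per token:

1. punctuation-only tokens get their PTB punctuation tag;
2. closed-class lookup (modals → MD, pronouns → PRP/PRP$, determiners →
   DT, prepositions → IN, conjunctions → CC, a short adverb/adjective/
   interjection list → RB/JJ/UH, `to` → TO, wh-words);
3. numerals → CD;
4. a small list of nouns whose shape collides with a verb suffix
   ("morning", "evening", "nothing", …) → NN;
5. verb lexicon (~80 irregular verbs with distinct past/participle forms,
   ~160 regular verbs with generated inflections): base forms tag VB after
   a modal or `to` and VBP otherwise; `-s` forms VBZ; `-ing` forms VBG;
   past/participle forms that coincide (all regular verbs, some
   irregulars) are disambiguated by the nearest preceding non-adverb
   token — after a form of *have*/*be* → VBN, else VBD;
6. suffix rules for unknown words (`-ed` with the same auxiliary rule,
   `-ing` → VBG, `-s` → NNS);
7. fallback NN.

The auxiliary rule is the minimal one that yields VBN for a perfect
construction like "will have remembered". The NN fallback matters
downstream: unknown content words become weak present cues, which is why
weak-cue suppression exists (below). External taggers plug in through
`tag_external`, which validates length and tagset membership; a
`FixtureTaggerAdapter` replays recorded tags from a TSV for reproducible
use of any third-party tagger's output.

Tokenization is whitespace splitting with terminal punctuation detached;
a trailing period stays attached when the token contains another period
("e.g."), so abbreviations survive.

## Cue rules and the three tense coders

Tag-to-cue mapping: MD → future; VBG/VBP/VBZ → present; VBD/VBN → past
(all *strong*); NN/NNS/UH → present (*weak*). Weak cues count only when a
sentence has no strong (verb-derived or anchor) cue. This suppression is a
deliberate reconstruction choice: the rule table alone would add a present
reading to almost every sentence (nearly all content words are nouns or
fall back to NN), and the reference behaviour of the naive coder on the
worked example — a future/past mixture, not a three-way one — requires
nouns to be subordinate to verb evidence. Whether the original method
suppressed noun cues globally or per clause is not determinable; global
suppression is the minimal rule consistent with the worked example.
Plural nouns are included with NN (nouns are nouns); `include_plural_nouns=False`
turns them off.

Anchor terms are lower-case stems matched by case-insensitive prefix
("remember" fires on "remembered", "remembering"), always strong. The
shipped default lexicon has exactly two entries (`remember*` → past,
`future*` → future); the full anchor list used in the original study is
unpublished, so the lexicon is a user-editable two-column CSV.

`no_ties` breaks ties by the earliest cue in token order. When two cues
share a token (e.g. "remember" is simultaneously a VBP present cue and a
past anchor), a fixed total order future > past > present decides;
the order is configurable, and exists only to keep the method
deterministic — no published behaviour constrains it. Token order rather
than character order is used; the two cannot disagree for non-overlapping
tokens.

## Temporal-expression coder

`recognize_timex` is a deliberately small pattern grammar, not a full
SUTime reimplementation: 4-digit years restricted to 1900–2099 (so
quantities are not tagged as years), month names, numeric dates (d/m/y and
ISO y-m-d), deictic day words, `next|last` + weekday/week/month/year, and
h:mm clock times. Overlaps resolve longest-match-first, left to right.
Numeric dates parse day-first, the convention of the study population;
ISO dates year-first. "May", "March" and "Mar" must be capitalized to
count as months (lower-case they collide with the modal and the verb);
other month names match case-insensitively.

`resolve_timex` maps each expression to an inclusive calendar-day range:
a year to Jan 1–Dec 31; a month name to its calendar month, choosing the
nearest occurrence within ±6 months and preferring the future (a logged
heuristic, configurable in spirit — SUTime behaves similarly); deictic
days to single days around the reference; `next`/`last` units to the
adjacent calendar week (Mon–Sun), month, year, or nearest
following/preceding weekday; clock times to the reference day. The
*present window is the reference calendar day*: a range entirely after the
reference day is future, entirely before is past, otherwise present. This
day-level granularity matches the deictic vocabulary (today / yesterday /
tomorrow); no finer granularity is defensible from short thought reports.

`classify_sutime` codes a record by the earliest resolved expression
(mirroring the earliest-cue spirit of `no_ties`, so the method is tie-free
by construction) and falls back to "other" when nothing is recognized or
resolvable — in particular whenever no reference time is available, which
is logged. An inline TIMEX3-like annotation (`annotate_timex`) is provided
for inspection and fixtures.

Impossible calendar dates (e.g. `31/2/2019`) stay unresolved with a
warning rather than erroring: on dirty corpora a single malformed date
must not abort a run.

## Scoring

`score_record` is strict by default: a mixed judgement is never correct.
The choice is forced by arithmetic, not taste: allowing ties can only
*reduce* a coder's accuracy if ties score as incorrect against a
single-category gold label, and that reduction is the central phenomenon
the evaluation is designed to expose. Lenient mode (correct when the gold
label is a member of the set) is provided for sensitivity analysis;
lenient ≥ strict always, with equality for tie-free coders.

Confusion counts expand each tie into one entry per member orientation,
so the confusion total exceeds the record count exactly when ties
occurred. Accuracy is reported to two decimals in text output.

`chance_baseline` draws, per repetition, a uniform-random orientation per
record and reports the mean strict accuracy and its Monte-Carlo standard
error; the expectation is 25% independent of the gold mix, and tests
assert against that analytic value.

## Synthetic corpus generator

The generator exists so that every pipeline stage is testable end-to-end
with *known* gold labels. It emulates the statistical structure of a real
two-day SMS experience-sampling corpus:

| parameter | default | meaning |
|---|---|---|
| `n_records` | 2884 | raw records before exclusion |
| `category_probs` | .1903/.5878/.1956/.0264 | past/present/future/other self-report mix (renormalized: the published rounded percentages sum to 100.01%) |
| `tied_or_missing_count` | 379/2884 of `n_records` | records given a tied or missing gold sentinel (split ~evenly) |
| `ambiguity_rate` | 0 | probability a record's text mixes two orientations' cues |
| target length | gamma(1.6, 27.6)+1, clipped to [1, 358] | character-length distribution, mean calibrated to ≈ 43 |
| responses/participant | beta-binomial(20, mean 14, SD 6) | prompt-response structure, used by `summarize_corpus` only |

Texts are assembled from a verified template bank, not a language model:
realism is explicitly secondary to ground truth. Every unambiguous
template (over its full slot vocabulary, and with each filler phrase
appended) is asserted at bank construction to be tagged and naive-coded
back to exactly its intended orientation; "other" templates are built
entirely from closed-class words so they carry no cue at all; ambiguous
templates must code as ties. Record texts grow toward a per-record target
length by appending orientation-consistent filler clauses, stopping when a
filler would move the length further from the target; the gamma scale was
set so the realized corpus mean lands at ≈ 43 characters.

Ambiguous records keep their single sampled gold label, as real
self-report does, so they depress measured accuracy — by construction a
tie never scores strict-correct, which makes naive strict accuracy equal
1 − (ambiguous fraction) and hence *exactly* monotone in
`ambiguity_rate`. Two independent RNG substreams (labels/text vs.
ambiguity flags) guarantee that at a fixed seed the ambiguous set grows
monotonically with the rate. Response counts are beta-binomial rather
than plain binomial because a binomial(20, 0.7) has SD ≈ 2 while the
emulated design's dispersion is SD ≈ 6; the overdispersion parameter is
solved from those two moments.

What passing tests on synthetic corpora do **not** show: the generator's
template language is a tiny, clean fragment of English. Real thought
reports contain misspellings, fragments, slang, and tense used
non-temporally; absolute accuracies measured here (e.g. 100% label
recovery at zero ambiguity) say nothing about accuracy on real corpora —
only the *relative* phenomena (ties lowering strict accuracy,
expression-only coding failing on cue-free text, present-orientation
over-assignment under the NN fallback) transfer as qualitative
predictions.

## Numerical and degenerate-input choices

- Empty text tags to an empty sentence and codes "other" (no markers).
- An empty corpus cannot be scored (accuracy undefined); `concordance`
  raises.
- Gold fields with ≥2 distinct valid labels parse to *tied*; unrecognized
  strings parse to *missing* with a warning, never an error.
- Tie sets serialize as ";"-joined sorted labels ("future;past").
- All stochastic components (generator, chance baseline) take explicit
  seeds; identical seeds give byte-identical outputs.

## Known limitations

- The anchor lexicon ships with only the two documented default stems.
- The expression grammar omits durations, sets, holidays and nested
  expressions.
- The tagger has no statistical disambiguation; noun/verb ambiguity
  ("plans") is resolved by lexicon membership, not context.
- Human coding is not modelled; externally produced codes can be scored
  through the `external` method of the evaluation CLI.
- Problem sizes in the test suite (corpora of 600–10,000 records, a
  1000-pair resolution oracle) were chosen as the smallest sizes at which
  the binomial/chi-square tolerances are meaningful.
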