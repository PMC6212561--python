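"""Code one sentence with all four automated coders.

The example sentence mixes a modal future cue ("will") with a past
participle ("remembered") and an explicit year, so the coders disagree in an
instructive way: the tie-allowing coders report a future/past mixture, the
tie-breaking coder picks the earliest cue (the modal, hence future), and the
temporal-expression coder compares "2019" with the reference time.
"""

from datetime import datetime

from temporient import (
    ThoughtRecord,
    classify_anchored,
    classify_naive,
    classify_no_ties,
    classify_sutime,
    tag_lexicon,
)

sentence_text = "In 2019, I will have remembered this example"
sentence = tag_lexicon(sentence_text)

print(f"text: {sentence_text!r}")
print("tags:", " ".join(f"{t.surface}/{t.tag}" for t in sentence.tokens))

for judgement in (
    classify_naive(sentence),
    classify_anchored(sentence),
    classify_no_ties(sentence),
    classify_sutime(
        ThoughtRecord(
            record_id="ex1",
            text=sentence_text,
            reference_time=datetime(2018, 6, 15, 12, 0),
        )
    ),
):
    tie = " (tie)" if judgement.is_tie else ""
    print(f"{judgement.method:>9}: {judgement.label()}{tie}")

# A ";"-joined label means the coder proposed several orientations (a tie,
# reported as "mixed"); a single label is a committed orientation.
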