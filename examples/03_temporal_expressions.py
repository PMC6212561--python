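"""Recognize, resolve, and annotate explicit temporal expressions.

Each text is scanned for temporal language (years, dates, deictic day words,
relative phrases, clock times); every expression is resolved to a calendar
day range against a reference time and compared with the reference day to
yield a past/present/future relation.  The TIMEX3-like inline annotation at
the end shows the normalized value of each expression.
"""

from datetime import datetime

from temporient import annotate_timex, recognize_timex, resolve_timex

reference = datetime(2018, 6, 15, 12, 0)
texts = [
    "In 2019, I will have remembered this example",
    "we met last Friday and fly out tomorrow at 6:30 am",
    "the conference is in September",
    "thinking about dinner",
]

for text in texts:
    print(f"text: {text!r}")
    for expr in recognize_timex(text):
        resolved = resolve_timex(expr, reference)
        span = f"[{resolved.char_start}:{resolved.char_end}]"
        relation = resolved.relation.value if resolved.relation else "unresolved"
        print(f"  {span:>9} {resolved.kind:<16} {resolved.surface!r:<14} -> "
              f"{resolved.resolved} ({relation})")
    print("  annotated:", annotate_timex(text, reference))
    print()

# The relation is day-granular: a range entirely before the reference day is
# past, entirely after is future, and any range containing it is present.
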