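"""Compare skip-event abundance between two conditions.

A desk-scale experiment: an upregulated transcript with two skipped exons
(40 -> 80 unique reads) and a downregulated transcript with one skip
(40 -> 20).  Event totals are reads x event count summed per condition;
a chi-square goodness-of-fit test against an equal split (df = 1, no
continuity correction) decides whether overall skip abundance changed.
"""

from splicevents import (
    Gene,
    Interval,
    QueryRecord,
    Transcript,
    classify_batch,
    condition_totals,
    differential_table,
    table_to_tsv,
)

exons = [(101, 200), (301, 400), (501, 600), (701, 800)]
structure = {"T0": [0, 1, 2, 3], "TA": [0, 3], "TB": [0, 2, 3]}
gene = Gene("G1", "chrT", "+", [
    Transcript(tid, "G1", "protein_coding", "+",
               tuple(Interval(*exons[i]) for i in keep))
    for tid, keep in structure.items()
])

counts = [QueryRecord("TA", 40, 80), QueryRecord("TB", 40, 20)]
calls = classify_batch(counts, [gene])
rows = differential_table(condition_totals(calls, counts))
print(table_to_tsv(rows), end="")
# The ES row shows totals 120 vs 180, chi-square 12 and p = 0.000532
# (prints as 0.0005 at 4 decimals): the skip load shifted significantly.
# Swapping the read columns balances the totals at 120 vs 120 and p = 1.
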