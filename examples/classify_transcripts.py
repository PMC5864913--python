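"""Classify query transcripts against their gene's splice graph.

Five variants of a four-exon gene are classified: an exact match, an exon
skip, a retained intron, an alternative donor site, and a partial intron
retention.  The one-line call strings use the tool's output dialect
(SE = skipped exon, primed names for alternative splice sites).
"""

from splicevents import (
    Gene,
    Interval,
    QueryRecord,
    Transcript,
    classify_batch,
)

BACKBONE = [(101, 200), (301, 400), (501, 600), (701, 800)]
VARIANTS = {
    "T1": BACKBONE,                                      # identity
    "T2": [(101, 200), (501, 600), (701, 800)],          # skips exon 2
    "T6": [(101, 200), (301, 600), (701, 800)],          # retains intron 2
    "T4": [(101, 200), (301, 380), (501, 600), (701, 800)],  # alt donor
    "T5": [(101, 200), (301, 450), (501, 600), (701, 800)],  # partial RI
}

transcripts = [
    Transcript(tid, "TOYGENE1", "protein_coding", "+",
               tuple(Interval(a, b) for a, b in exons),
               graph_eligible=(tid in {"T1", "T2"}))
    for tid, exons in VARIANTS.items()
]
gene = Gene("TOYGENE1", "chrT", "+", transcripts)

queries = [QueryRecord(tid) for tid in VARIANTS]
for call in classify_batch(queries, [gene], dialect="classic"):
    print(f"{call.transcript_id}: {call.formatted}")
# T1 prints "none" (it equals the graph); the others name the event and
# the putative exon it touches, e.g. "SE(Exon2)" for the skipped exon.
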