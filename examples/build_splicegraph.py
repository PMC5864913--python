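"""Build a splice graph for a two-transcript toy gene.

The gene has a four-exon transcript and a three-exon transcript; pooling
their exon boundaries and applying the selection rules yields four
putative exons, each with the pooled frequency of its boundaries.
"""

from splicevents import (
    Gene,
    Interval,
    Transcript,
    build_splicegraph,
    graph_to_tsv,
    orient_forward,
)

t1 = Transcript("T1", "TOYGENE1", "protein_coding", "+", (
    Interval(101, 200), Interval(301, 400), Interval(501, 600),
    Interval(701, 800),
))
t2 = Transcript("T2", "TOYGENE1", "protein_coding", "+", (
    Interval(101, 200), Interval(501, 600), Interval(701, 800),
))
gene = orient_forward(Gene("TOYGENE1", "chrT", "+", [t1, t2]))

graph = build_splicegraph(gene)
print(graph_to_tsv(graph), end="")
# Each row is one putative exon: the start_freq/end_freq columns say how
# many transcript exons contributed that boundary (exon 2 is supported by
# only one of the two transcripts).
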