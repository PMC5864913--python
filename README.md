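# splicevents

Detect alternative-splicing (AS) events of known transcripts directly from
gene annotation — no read alignment, no transcript reconstruction.

Most AS tools start from raw RNA-seq reads. But a great deal of splicing
analysis happens downstream of such pipelines, when what you have is a
list of transcript IDs (for example, the differentially expressed
transcripts of a treatment-vs-control comparison) and what you want to
know is *which splicing choices* distinguish each transcript from the
rest of its gene. `splicevents` answers that question from annotation
alone, for bulk or single-cell transcriptomics in any organism with a
GTF/GFF3 gene model.

## The method

For each gene, a **SpliceGraph** — an ordered set of non-overlapping
*putative exons* — is built from all protein-coding transcripts:

1. all exon start/end coordinates are pooled (minus-strand genes are first
   mirrored so ascending coordinates equal transcription order) and their
   frequencies counted, starts and ends separately;
2. within each cluster of overlapping observed exons the boundary with
   the highest pooled frequency is selected; frequency ties go to the
   longer exon (minimum start for a repeated end, maximum end for a
   repeated start);
3. an exon equivalent to several smaller, mutually non-overlapping exons
   is discarded in favour of the smaller exons.

Each query transcript is then compared exon-by-exon against the graph and
every divergence is typed as one of eight events: exon skipping (ES/SE),
alternative 5′/3′ splice site (A5′SS / A3′SS, or both at once), retained
intron (RI), partial intron retention (sub_RI), and alternative
promoter/terminator (AP/AT).

When per-transcript unique-read counts for two conditions are supplied,
per-kind event totals

&nbsp;&nbsp;&nbsp;&nbsp;total(kind, condition) = Σ_transcripts reads(transcript, condition) × n_events(transcript, kind)

are compared with a chi-square goodness-of-fit test against an equal
split: expected = (T_control + T_treatment)/2, df = 1, no continuity
correction.

## Worked example

```python
from splicevents import (Gene, Interval, QueryRecord, Transcript,
                         classify_batch, condition_totals,
                         differential_table, table_to_tsv)

exons = [(101, 200), (301, 400), (501, 600), (701, 800)]
structure = {"T0": [0, 1, 2, 3], "TA": [0, 3], "TB": [0, 2, 3]}
gene = Gene("G1", "chrT", "+", [
    Transcript(tid, "G1", "protein_coding", "+",
               tuple(Interval(*exons[i]) for i in keep))
    for tid, keep in structure.items()])

counts = [QueryRecord("TA", 40, 80), QueryRecord("TB", 40, 20)]
calls = classify_batch(counts, [gene], dialect="classic")
for c in calls:
    print(c.transcript_id, c.formatted)
print(table_to_tsv(differential_table(condition_totals(calls, counts))))
```

prints

```
TA SE(Exon3),SE(Exon2)
TB SE(Exon2)
event_kind  total_control  total_treatment  chi_square  p_value   significance
ES          120            180              12          0.000532  Significant
...
```

`TA` skips putative exons 2 and 3, `TB` skips exon 2. Weighted by unique
reads (TA: 40 → 80, TB: 40 → 20) the skip totals are 120 before and 180
after treatment; χ² = 12 at df = 1 gives p ≈ 0.0005, so overall skip
abundance changed significantly. Swapping the event loads balances the
totals at 120 vs 120 and p = 1 exactly.

The scripts in `examples/` run each capability end to end: graph
building, event classification, differential testing, and
simulate-and-recover on synthetic loci.

## Command line

```sh
splicevents classify --gtf annot.gtf --transcripts ids.txt --dialect classic --out calls.tsv
splicevents diff     --gtf annot.gtf --counts counts.tsv --out diff.tsv
splicevents graph    --gtf annot.gtf --gene MYGENE --svg graph.svg
splicevents simulate --seed 7 --out-gtf sim.gtf --out-truth truth.tsv
splicevents fetch    --transcript ENST... --out-gtf locus.gtf   # needs network
```

## Scope

Graphs are built from annotation only (no read-evidence augmentation),
events are typed but not quantified (no PSI), and differential testing
covers exactly two conditions. The Ensembl REST mode is a convenience for
fetching loci; its results track the live database and are not fixed.
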