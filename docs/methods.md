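# Methods

## Coordinate model and orientation

All coordinates are 1-based inclusive, the GTF/Ensembl convention; GFF3
input uses the same convention natively and BED export converts to
0-based half-open at the boundary. Before any graph work a gene is
*oriented*: plus-strand genes are used as-is; minus-strand genes are
mirrored within their span by `m(x) = span_min + span_max − x` (start and
end swapped per exon, exons re-sorted) so that ascending coordinates
always equal transcription order. The pivot is kept on the gene, making
the mirror an involution; exports that face the genome (BED, GTF) map
back through it. The mirror is defined per gene span rather than per
chromosome because only relative order matters to the method; this keeps
the transform local and self-inverse.

Acceptor and donor follow transcription orientation after normalization:
acceptor = exon start, donor = exon end. A5SS is donor-side variation,
A3SS acceptor-side, consistent with the standard reading of alternative
donor/acceptor usage.

## SpliceGraph construction

Graph-eligible transcripts default to biotype `protein_coding`;
transcripts of other biotypes are retained on the gene so they can still
be classified as queries. Transcript support level and exon repetition
are deliberately ignored: every exon occurrence of every eligible
transcript contributes one count to its start and one to its end
coordinate, in two separate tables — donors and acceptors are distinct
site classes even when they share a coordinate, so they never pool.
Terminal (TSS/TES) coordinates are pooled like splice sites; the
resulting inflation of terminal-exon boundary frequencies is accepted.

Observed exons are clustered into connected components under ≥1-base
overlap. Each cluster is checked for *spanning* exons — an exon
containing two or more mutually non-overlapping distinct smaller exons of
the same cluster. Spanning exons are discarded, the remainder
re-clustered, and the check repeated until stable. A single contained
exon does **not** trigger the split: that configuration is an
alternative-splice-site situation, not a multi-exon one. Discarded
spanning exons are recorded on the graph; as query exons they surface as
retained introns.

Within each final sub-cluster the putative exon is selected by
independent argmax over boundary frequencies: the start with the highest
pooled start-frequency (ties → smaller coordinate, i.e. the longer exon)
and the end with the highest end-frequency (ties → larger coordinate).
Selecting boundaries independently rather than whole observed exon pairs
is the only reading under which the tie rule "minimum start for a
repeated end, maximum end for a repeated start" is well-defined, and it
always yields an interval — except for pathological clusters where the
winning start exceeds the winning end (constructible with crossed shared
boundaries); there graph building aborts with a diagnostic naming the
cluster rather than guessing. Putative exons are numbered 1..n left to
right in forward orientation; construction is deterministic.

## Event classification

For each query exon an `ExonRelation` records the (necessarily
contiguous) putative exons it overlaps and its boundary offsets against
the anchor (first overlapped) exon; the donor boundary is compared
against the last overlapped exon. The decision procedure:

* **AP** — the first query exon anchors at index > 1 or overlaps no
  putative exon; **AT** symmetrically on the last exon against index n.
* **ES(k)** — putative exon k lies strictly between the first exon's
  anchor and the last exon's anchor and is overlapped by no query exon.
  Putative exons upstream/downstream of those anchors are subsumed by
  AP/AT and not reported as skips.
* **RI(j)** — one query exon overlaps consecutive putative exons; each
  bridged intron j (labelled by its upstream putative exon) is retained.
  Overlapping two consecutive putative exons already implies the whole
  intervening intron is covered, so no separate coverage check is needed.
* **A5SS(k)/A3SS(k)** — a spliced-side boundary truncated strictly into
  its putative exon (donor side / acceptor side); both boundaries of one
  internal exon truncated merge into **A5A3SS(k)**.
* **sub_RI(k)** — a spliced-side boundary extending strictly into the
  adjacent intron without reaching the next putative exon, labelled by
  the anchor putative exon whose boundary extends.

Truncation vs extension disambiguates alternative splice sites from
partial intron retention: the selection rules prefer maximal exons, so
putative exons bound the long variants and alternative sites manifest as
truncations. A boundary is matched only by exact coordinate equality —
no fuzz window. Terminal exons contribute only their spliced-side
boundary; TSS/TES shifts never trigger events (whether the original
GUI reported such shifts as AP/AT is not decidable from its published
output; this package reports AP/AT only for anchor changes). When AP and
AT co-occur, both events are recorded; the report dialect merges them
into a single `AP/AT` token.

A query exon lying entirely inside an intron (overlapping nothing) in an
internal position matches no event type and is currently silent; none of
the eight types covers a novel intronic exon.

Output ordering — AP/AT first, then ES, A5SS, A3SS, A5A3SS, sub_RI, RI
with descending exon index within a type — is a presentation choice of
the report dialect, not part of correctness; the published call strings
are not fully consistent on internal order.

## Differential test

Per kind, per condition: total = Σ reads(transcript, condition) ×
n_events(transcript, kind), with unique mapped reads as weights
(non-integer counts are rejected — multi-mapping fractions are out of
scope). The two totals are tested against an equal-split null, expected
= grand/2 each, χ² with df = (conditions − 1) = 1 and **no** Yates
correction: on the desk example (120, 180) this gives χ² = 12 and
p = 5.32×10⁻⁴ (printed 0.0005); a continuity-corrected test would print
0.0007 and is therefore not what the method specifies. Both totals zero
means no events to test: statistic 0, probability undefined, reported as
NA. No multiple-testing correction is applied across the seven reported
kinds by default (the report carries plain per-kind labels); a Bonferroni
flag is available. The A5&3SS combination is appended as an eighth row
only when observed, keeping the default report in the canonical
seven-kind column order.

## Synthetic loci

`simulate.make_gene` draws a backbone of n putative exons (defaults:
n = 5, exon lengths 80–300 nt, introns 100–1,000 nt — compact but
realistic human-like scales chosen to keep loci small) on `chrSim`
starting at 1,001, always includes the backbone transcript, and derives
alternative transcripts by sampling events. Rates are per-transcript
attempt probabilities; defaults make exon skipping the most common event
(0.30), splice-site changes intermediate (0.15 each side, 0.05 both),
and intron retention rare (0.05, matching its observed rarity in
vertebrate transcriptomes), with 0.15 for each terminal alternative.

Planted events are mutually non-interacting within a transcript: each
event claims the putative exons and introns it touches and claims must
be disjoint, because the classification semantics of two events on the
same exon are undefined in the method being implemented. Three further
construction rules guarantee the frequency vote always reproduces the
backbone as the graph, making truth labels exactly recoverable:
alternative boundary coordinates are globally distinct across
transcripts (an alternative coordinate can then at best tie the
backbone, and ties go to the longer exon); truncation depths stay below
half the exon length (so any two variants of an exon share its midpoint
and the multi-exon rule can never split a backbone exon); and a partial
intron retention is kept only where at least two transcripts retain the
unmodified donor — otherwise the longer extended coordinate would win
the tie. Events that cannot satisfy these constraints are skipped unless
their rate is 1.0, in which case generation fails loudly.

What the generator does **not** emulate: real exon/intron length
distributions, sequence content, expression-level realism, interacting
events on one exon, novel intronic exons, and TSS/TES jitter. Passing
recovery tests therefore show the classifier is exact on clean,
non-interacting annotation-level events — not that it resolves ambiguous
overlapping events in real annotations, where event interplay (e.g. an
alternative site on a skipped exon's neighbour) can make labels
genuinely ambiguous.

Read-count tables put `base_reads` (default 40) in the control column
and fold-change-scaled counts in treatment, optionally
Poisson-distributed around those means with a seeded generator.

## Test and verification sizes

The suite checks exact recovery on 240 simulated loci (2–8 putative
exons, both strands, mixed events) including a GTF write→read→rebuild
round trip per locus; rule-level equivalence against a brute-force
literal implementation of the selection rules on all ~190 exhaustively
enumerated loci over a 6-interval candidate pool (≤4 distinct exons,
multiplicity ≤2, ≤3 transcripts) plus randomized multisets; strand
symmetry on 40 loci; and the size of the goodness-of-fit test on 2,000
equal-mean Poisson pairs (rejection rate at α = 0.05 required to lie in
[0.035, 0.065]). These sizes keep the whole suite under a few seconds
while leaving each property with enough cases to be informative.

## Known limitations

* Chromosome identity is carried but not validated across genes; query
  transcripts are matched to genes by transcript ID, so a query absent
  from the annotation cannot be classified (the REST fetch exists for
  that case).
* The equal-split null treats read totals as counts; overdispersion
  between biological replicates is not modelled (the test is the
  method's own, not a replacement for replicate-aware differential
  splicing).
* Only two-condition designs are supported.
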