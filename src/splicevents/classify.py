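"""Classify query transcripts against a splice graph into typed AS events.

The decision procedure compares each query exon, in forward orientation,
with the ordered putative exons of the gene's splice graph:

* the first / last query exon anchoring away from putative exon 1 / n (or
  overlapping nothing) yields an alternative promoter / terminator;
* an internal putative exon overlapped by no query exon is a skipped exon;
* one query exon overlapping several consecutive putative exons retains
  every intervening intron;
* a spliced-side boundary truncated into its putative exon is an
  alternative splice site (acceptor side: A3SS, donor side: A5SS; both on
  one internal exon merge into A5A3SS);
* a spliced-side boundary extending into the adjacent intron without
  reaching the next putative exon is partial intron retention (sub_RI).

Terminal exons contribute only their spliced-side boundary; TSS/TES shifts
never trigger events.  Boundary matching is exact (zero tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import (
    A3SS,
    A5A3SS,
    A5SS,
    AP,
    AT,
    ASEvent,
    ES,
    EVENT_KINDS,
    Gene,
    Interval,
    QueryRecord,
    RI,
    SUB_RI,
    Transcript,
    TranscriptCall,
    UsageError,
    orient_forward,
)
from .graph import SpliceGraph, build_splicegraph


@dataclass
class ExonRelation:
    """How one query exon sits relative to the graph: which putative exons
    it overlaps (contiguous indices) and how its boundaries compare with the
    anchor (first overlapped) putative exon."""

    query_exon: Interval
    overlapped_indices: tuple[int, ...]
    start_match: bool
    end_match: bool
    start_shift: Optional[int]
    end_shift: Optional[int]


def relate_exon(exon: Interval, graph: SpliceGraph) -> ExonRelation:
    """Overlap a query exon with the graph's putative exons (>= 1 shared
    base); boundary matches are exact coordinate equality against the anchor
    exon.  Zero overlaps is a valid relation."""
    indices = tuple(
        i
        for i, p in enumerate(graph.putative_exons, start=1)
        if p.overlaps(exon)
    )
    if indices:
        anchor = graph.exon(indices[0])
        start_shift = exon.start - anchor.start
        # the donor boundary is compared against the last overlapped exon,
        # which is the anchor itself unless the query exon bridges introns
        donor = graph.exon(indices[-1])
        end_shift = exon.end - donor.end
        return ExonRelation(
            exon, indices, start_shift == 0, end_shift == 0, start_shift, end_shift
        )
    return ExonRelation(exon, (), False, False, None, None)


def classify_transcript(
    transcript: Transcript, graph: SpliceGraph
) -> list[ASEvent]:
    """Apply the decision procedure; returns events in detection order
    (use :func:`format_events` for the canonical presentation order)."""
    if transcript.gene_id != graph.gene_id:
        raise UsageError(
            f"transcript {transcript.transcript_id} is from gene "
            f"{transcript.gene_id}, graph is for {graph.gene_id}"
        )
    rels = [relate_exon(e, graph) for e in transcript.exons]
    events: list[ASEvent] = []
    n = graph.n
    first, last = rels[0], rels[-1]

    if not first.overlapped_indices or first.overlapped_indices[0] > 1:
        events.append(ASEvent(AP))
    if not last.overlapped_indices or last.overlapped_indices[-1] < n:
        events.append(ASEvent(AT))

    covered = {i for r in rels for i in r.overlapped_indices}
    if covered:
        # skipped-exon window: strictly between the first exon's anchor and
        # the last exon's anchor; putative exons outside it are subsumed by
        # AP/AT rather than reported as skips
        f = first.overlapped_indices[0] if first.overlapped_indices else min(covered)
        l = last.overlapped_indices[0] if last.overlapped_indices else max(covered)
        for k in range(f + 1, l):
            if k not in covered:
                events.append(ASEvent(ES, k))

    m = len(rels)
    for i, rel in enumerate(rels):
        if not rel.overlapped_indices:
            continue
        ks, ke = rel.overlapped_indices[0], rel.overlapped_indices[-1]
        for j in range(ks, ke):
            # a query exon bridging putative exons j and j+1 necessarily
            # covers the whole intervening intron
            events.append(ASEvent(RI, j, detail=f"intron after Exon{j}"))
        check_start = i > 0       # acceptor side is spliced unless first exon
        check_end = i < m - 1     # donor side is spliced unless last exon
        exon = rel.query_exon
        trunc_start = trunc_end = False
        if check_start:
            shift = exon.start - graph.exon(ks).start
            if shift > 0:
                trunc_start = True
            elif shift < 0:
                events.append(
                    ASEvent(SUB_RI, ks, detail=f"acceptor extends {-shift} nt")
                )
        if check_end:
            shift = exon.end - graph.exon(ke).end
            if shift < 0:
                trunc_end = True
            elif shift > 0:
                events.append(
                    ASEvent(SUB_RI, ke, detail=f"donor extends {shift} nt")
                )
        if trunc_start and trunc_end and ks == ke:
            events.append(ASEvent(A5A3SS, ks, detail="both boundaries truncated"))
        else:
            if trunc_start:
                events.append(
                    ASEvent(A3SS, ks, detail=f"acceptor at {exon.start}")
                )
            if trunc_end:
                events.append(ASEvent(A5SS, ke, detail=f"donor at {exon.end}"))
    return events


# presentation order of event groups after AP/AT
_GROUP_ORDER = (ES, A5SS, A3SS, A5A3SS, SUB_RI, RI)

_CLASSIC_NAMES = {
    ES: "SE",
    A5SS: "A5′SS",
    A3SS: "A3′SS",
    A5A3SS: "A5′&3′SS",
    SUB_RI: "sub_RI",
    RI: "RI",
    AP: "AP",
    AT: "AT",
}


def format_events(events: Iterable[ASEvent], dialect: str = "canonical") -> str:
    """Render events as the tool's one-line call string.

    ``canonical`` uses the ES/A5SS/A3SS/A5A3SS/sub_RI/RI/AP/AT codes;
    ``classic`` renames ES to SE and the splice-site kinds to their primed
    forms, and merges co-occurring AP and AT into a single "AP/AT" token.
    Ordering: AP/AT first, then event groups in the order ES, A5SS, A3SS,
    A5A3SS, sub_RI, RI with descending exon index within a group.  An empty
    event list renders as "none".
    """
    if dialect not in {"canonical", "classic"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    events = list(events)
    if not events:
        return "none"
    names = _CLASSIC_NAMES if dialect == "classic" else {k: k for k in EVENT_KINDS}
    tokens: list[str] = []
    has_ap = any(e.kind == AP for e in events)
    has_at = any(e.kind == AT for e in events)
    if dialect == "classic" and has_ap and has_at:
        tokens.append("AP/AT")
    else:
        if has_ap:
            tokens.append(names[AP])
        if has_at:
            tokens.append(names[AT])
    for kind in _GROUP_ORDER:
        indexed = sorted(
            (e for e in events if e.kind == kind),
            key=lambda e: -(e.exon_index or 0),
        )
        tokens.extend(f"{names[kind]}(Exon{e.exon_index})" for e in indexed)
    return ",".join(tokens)


def classify_batch(
    queries: Sequence[QueryRecord],
    genes: Iterable[Gene],
    dialect: str = "canonical",
) -> list[TranscriptCall]:
    """Classify a batch of query transcript IDs against their genes.

    Genes may be passed oriented or not; graphs are built once per gene.
    Unresolvable IDs yield a call flagged ``found=False`` rather than
    aborting; a batch in which nothing resolves is an error.
    """
    oriented: list[Gene] = [
        g if g.oriented else orient_forward(g) for g in genes
    ]
    by_tid: dict[str, Gene] = {}
    for g in oriented:
        for t in g.transcripts:
            by_tid[t.transcript_id] = g
    graphs: dict[str, SpliceGraph] = {}
    calls: list[TranscriptCall] = []
    for q in queries:
        gene = by_tid.get(q.transcript_id)
        if gene is None:
            calls.append(
                TranscriptCall(q.transcript_id, None, (), "not found", found=False)
            )
            continue
        if gene.gene_id not in graphs:
            graphs[gene.gene_id] = build_splicegraph(gene)
        graph = graphs[gene.gene_id]
        events = tuple(
            classify_transcript(gene.transcript(q.transcript_id), graph)
        )
        calls.append(
            TranscriptCall(
                q.transcript_id,
                gene.gene_id,
                events,
                format_events(events, dialect),
            )
        )
    if queries and not any(c.found for c in calls):
        raise UsageError("no query transcript resolved to an annotated gene")
    return calls


def calls_to_tsv(calls: Sequence[TranscriptCall]) -> str:
    """Tabular export: one row per query with per-type event counts."""
    header = ["transcript_id", "gene_id", "n_events", "events"] + list(EVENT_KINDS)
    lines = ["\t".join(header)]
    for c in calls:
        counts = {k: 0 for k in EVENT_KINDS}
        for e in c.events:
            counts[e.kind] += 1
        lines.append(
            "\t".join(
                [
                    c.transcript_id,
                    c.gene_id or "NA",
                    str(len(c.events)),
                    c.formatted,
                ]
                + [str(counts[k]) for k in EVENT_KINDS]
            )
        )
    return "\n".join(lines) + "\n"
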