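"""Core domain types: genomic intervals, transcript and gene models, AS events.

All coordinates are 1-based inclusive (GTF/Ensembl convention).  A gene is
"oriented" once its exons have been mirrored, if necessary, so that ascending
coordinates equal transcription order; the mirror pivot is retained so results
can be reported back in original genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional


class SpliceventsError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(SpliceventsError):
    """Malformed annotation or query input."""


class InputError(SpliceventsError):
    """Semantically invalid user input (negative counts, missing columns...)."""


class BuildError(SpliceventsError):
    """Splice-graph construction failed (no eligible transcripts, bad cluster)."""


class UsageError(SpliceventsError):
    """API misuse, e.g. classifying a transcript against a foreign gene's graph."""


class RetrievalError(SpliceventsError):
    """Remote lookup failed; carries the offending identifier."""

    def __init__(self, message: str, identifier: str = ""):
        super().__init__(message)
        self.identifier = identifier


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive genomic interval."""

    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class Transcript:
    """An ordered exon chain of one transcript."""

    transcript_id: str
    gene_id: str
    biotype: str
    strand: str
    exons: tuple[Interval, ...]
    graph_eligible: bool = True

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(self.exons))
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end + 1:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons {a} and {b} "
                    "overlap or touch; consecutive exons need a gap of >= 1"
                )
        self.exons = exons

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)


@dataclass
class Gene:
    """All transcripts of one gene on one strand.

    ``mirror_pivot`` is set after forward normalization of a minus-strand
    gene; ``mirror(x) = pivot - x`` maps oriented coordinates back to
    genomic ones (an involution).
    """

    gene_id: str
    chromosome: str
    strand: str
    transcripts: list[Transcript]
    oriented: bool = False
    mirror_pivot: Optional[int] = None

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(
                    f"transcript {t.transcript_id} belongs to {t.gene_id}, "
                    f"not {self.gene_id}"
                )

    @property
    def span(self) -> Interval:
        starts = [t.exons[0].start for t in self.transcripts]
        ends = [t.exons[-1].end for t in self.transcripts]
        return Interval(min(starts), max(ends))

    @property
    def eligible_transcripts(self) -> list[Transcript]:
        return [t for t in self.transcripts if t.graph_eligible]

    def transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    def to_genomic(self, x: int) -> int:
        """Map an oriented coordinate back to the original genomic one."""
        if self.mirror_pivot is None:
            return x
        return self.mirror_pivot - x


@dataclass(frozen=True)
class QueryRecord:
    """One query transcript, optionally with per-condition unique-read counts."""

    transcript_id: str
    reads_control: Optional[int] = None
    reads_treatment: Optional[int] = None

    def __post_init__(self):
        for name in ("reads_control", "reads_treatment"):
            v = getattr(self, name)
            if v is not None and (not isinstance(v, int) or v < 0):
                raise InputError(
                    f"{self.transcript_id}: {name} must be a non-negative "
                    f"integer, got {v!r}"
                )


# ---------------------------------------------------------------------------
# AS event vocabulary

ES = "ES"            # exon skipping
A5SS = "A5SS"        # alternative donor (5' splice site)
A3SS = "A3SS"        # alternative acceptor (3' splice site)
A5A3SS = "A5A3SS"    # both boundaries alternative
RI = "RI"            # retained intron
SUB_RI = "sub_RI"    # partial intron retention
AP = "AP"            # alternative promoter
AT = "AT"            # alternative terminator

EVENT_KINDS = (ES, A5SS, A3SS, A5A3SS, RI, SUB_RI, AP, AT)

#: kinds that carry a putative-exon index
INDEXED_KINDS = frozenset({ES, A5SS, A3SS, A5A3SS, RI, SUB_RI})


@dataclass(frozen=True, order=True)
class ASEvent:
    """One typed alternative-splicing event, anchored to a putative exon."""

    kind: str
    exon_index: Optional[int] = None
    detail: str = ""

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if (self.exon_index is not None) != (self.kind in INDEXED_KINDS):
            raise ValueError(
                f"{self.kind}: exon_index must be present iff the kind is "
                "anchored to a putative exon"
            )
        if self.exon_index is not None and self.exon_index < 1:
            raise ValueError("exon_index is 1-based")


@dataclass
class TranscriptCall:
    """Classification result for one query transcript."""

    transcript_id: str
    gene_id: Optional[str]
    events: tuple[ASEvent, ...]
    formatted: str
    found: bool = True


def orient_forward(gene: Gene) -> Gene:
    """Normalize a gene to forward orientation.

    Plus-strand genes are returned unchanged apart from the ``oriented``
    flag.  Minus-strand genes are mirrored within the gene span by
    ``m(x) = span.start + span.end - x`` (start/end swapped per exon, exons
    re-sorted) so that ascending coordinates equal transcription order.
    The pivot is kept on the gene for mapping back.
    """
    if gene.oriented:
        raise UsageError(f"gene {gene.gene_id} is already oriented")
    if gene.strand == "+":
        return replace(gene, oriented=True)
    pivot = gene.span.start + gene.span.end
    mirrored = []
    for t in gene.transcripts:
        exons = tuple(
            sorted(Interval(pivot - e.end, pivot - e.start) for e in t.exons)
        )
        mirrored.append(replace(t, exons=exons))
    return replace(gene, transcripts=mirrored, oriented=True, mirror_pivot=pivot)


def mirror_back(gene: Gene) -> Gene:
    """Undo :func:`orient_forward` on a mirrored gene (involution)."""
    if not gene.oriented:
        raise UsageError(f"gene {gene.gene_id} is not oriented")
    if gene.mirror_pivot is None:
        return replace(gene, oriented=False)
    pivot = gene.mirror_pivot
    restored = []
    for t in gene.transcripts:
        exons = tuple(
            sorted(Interval(pivot - e.end, pivot - e.start) for e in t.exons)
        )
        restored.append(replace(t, exons=exons))
    return replace(gene, transcripts=restored, oriented=False, mirror_pivot=None)
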