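"""Deterministic SVG rendering of a splice graph and a query transcript.

Two horizontal tracks: putative exons as labelled boxes on top, the query
transcript's exons below with introns drawn as lines.  Regions where the
transcript diverges from the graph (skipped exons, boundary shifts,
retained-intron bridges) are highlighted.
"""

from __future__ import annotations

from typing import Optional

from .model import Interval, Transcript, UsageError
from .graph import SpliceGraph

_W, _MARGIN = 900, 40
_EXON_H, _TRACK_GAP = 26, 60
_GRAPH_Y, _TX_Y = 40, 40 + _TRACK_GAP


def _scale(span: Interval):
    width = _W - 2 * _MARGIN
    denom = max(span.length - 1, 1)

    def to_x(coord: int) -> float:
        return _MARGIN + (coord - span.start) * width / denom

    return to_x


def render_graph_svg(
    graph: SpliceGraph, transcript: Optional[Transcript] = None
) -> str:
    """Render the graph (and optionally one query transcript) as SVG text."""
    if transcript is not None and transcript.gene_id != graph.gene_id:
        raise UsageError(
            f"transcript {transcript.transcript_id} is not from gene "
            f"{graph.gene_id}"
        )
    lo = graph.putative_exons[0].start
    hi = graph.putative_exons[-1].end
    if transcript is not None:
        lo = min(lo, transcript.exons[0].start)
        hi = max(hi, transcript.exons[-1].end)
    to_x = _scale(Interval(lo, hi))
    height = _TX_Y + _EXON_H + _MARGIN if transcript is not None else _GRAPH_Y + _EXON_H + _MARGIN

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_W}" height="{height}" '
        f'viewBox="0 0 {_W} {height}">',
        f'<text x="{_MARGIN}" y="20" font-size="14">{graph.gene_id} SpliceGraph'
        f" ({graph.n} putative exons)</text>",
    ]

    # highlights first so boxes draw on top
    if transcript is not None:
        covered = [
            any(p.overlaps(e) for e in transcript.exons)
            for p in graph.putative_exons
        ]
        for p, cov in zip(graph.putative_exons, covered):
            if not cov:
                parts.append(
                    f'<rect class="highlight" x="{to_x(p.start):.1f}" y="{_GRAPH_Y - 6}" '
                    f'width="{to_x(p.end) - to_x(p.start):.1f}" '
                    f'height="{_TRACK_GAP + _EXON_H + 12}" fill="#fdd" stroke="none"/>'
                )
        for e in transcript.exons:
            for i, p in enumerate(graph.putative_exons, start=1):
                if not p.overlaps(e):
                    continue
                for q_coord, p_coord in ((e.start, p.start), (e.end, p.end)):
                    if q_coord != p_coord:
                        a, b = sorted((q_coord, p_coord))
                        parts.append(
                            f'<rect class="highlight" x="{to_x(a):.1f}" '
                            f'y="{_TX_Y - 6}" '
                            f'width="{max(to_x(b) - to_x(a), 2):.1f}" '
                            f'height="{_EXON_H + 12}" fill="#fdd" stroke="none"/>'
                        )

    # graph track
    intron_y = _GRAPH_Y + _EXON_H / 2
    parts.append(
        f'<line x1="{to_x(graph.putative_exons[0].start):.1f}" y1="{intron_y}" '
        f'x2="{to_x(graph.putative_exons[-1].end):.1f}" y2="{intron_y}" '
        'stroke="#888"/>'
    )
    for i, p in enumerate(graph.putative_exons, start=1):
        x, w = to_x(p.start), to_x(p.end) - to_x(p.start)
        parts.append(
            f'<rect class="putative" x="{x:.1f}" y="{_GRAPH_Y}" width="{max(w, 2):.1f}" '
            f'height="{_EXON_H}" fill="#4a7fb5" stroke="#123"/>'
        )
        parts.append(
            f'<text x="{x + max(w, 2) / 2:.1f}" y="{_GRAPH_Y - 4}" '
            f'font-size="11" text-anchor="middle">Exon{i}</text>'
        )

    # transcript track
    if transcript is not None:
        ty = _TX_Y + _EXON_H / 2
        parts.append(
            f'<line x1="{to_x(transcript.exons[0].start):.1f}" y1="{ty}" '
            f'x2="{to_x(transcript.exons[-1].end):.1f}" y2="{ty}" stroke="#888"/>'
        )
        for e in transcript.exons:
            x, w = to_x(e.start), to_x(e.end) - to_x(e.start)
            parts.append(
                f'<rect class="query" x="{x:.1f}" y="{_TX_Y}" width="{max(w, 2):.1f}" '
                f'height="{_EXON_H}" fill="#6aa84f" stroke="#123"/>'
            )
        parts.append(
            f'<text x="{_MARGIN}" y="{_TX_Y + _EXON_H + 16}" font-size="12">'
            f"{transcript.transcript_id}</text>"
        )

    parts.append("</svg>")
    return "\n".join(parts) + "\n"
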