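"""Differential splicing: read-count-weighted event totals and the
chi-square goodness-of-fit test between two conditions.

Each transcript's event count for a kind is weighted by its unique mapped
reads in each condition; per-kind totals are compared against an equal-split
null (expected = grand total / 2 per condition) with one degree of freedom
and no continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy.stats import chi2

from .model import (
    A3SS,
    A5A3SS,
    A5SS,
    AP,
    AT,
    ES,
    EVENT_KINDS,
    InputError,
    QueryRecord,
    RI,
    SUB_RI,
    TranscriptCall,
)

#: row order of the differential report (the A5&3SS combination is appended
#: only when observed)
TABLE_ORDER = (ES, RI, A3SS, A5SS, SUB_RI, AP, AT)


@dataclass(frozen=True)
class EventTotals:
    event_kind: str
    total_control: int
    total_treatment: int


@dataclass(frozen=True)
class GofResult:
    event_kind: str
    total_control: int
    total_treatment: int
    chi_square: float
    p_value: Optional[float]
    significant: Optional[bool]
    alpha: float

    @property
    def label(self) -> str:
        if self.significant is None:
            return "NA"
        return "Significant" if self.significant else "Not-significant"


def transcript_event_total(event_count: int, unique_reads: int) -> int:
    """Weight one transcript's event count by its unique mapped reads."""
    for name, v in (("event_count", event_count), ("unique_reads", unique_reads)):
        if not isinstance(v, int) or isinstance(v, bool) or v < 0:
            raise InputError(f"{name} must be a non-negative integer, got {v!r}")
    return event_count * unique_reads


def condition_totals(
    calls: Sequence[TranscriptCall], counts: Iterable[QueryRecord]
) -> list[EventTotals]:
    """Sum read-weighted event counts per kind over all transcripts.

    Every call must have a count record with both conditions present; kinds
    with no events are still reported with totals (0, 0).
    """
    by_tid = {r.transcript_id: r for r in counts}
    acc = {k: [0, 0] for k in EVENT_KINDS}
    for call in calls:
        rec = by_tid.get(call.transcript_id)
        if rec is None or rec.reads_control is None or rec.reads_treatment is None:
            raise InputError(
                f"transcript {call.transcript_id} lacks read counts for both "
                "conditions"
            )
        per_kind: dict[str, int] = {}
        for e in call.events:
            per_kind[e.kind] = per_kind.get(e.kind, 0) + 1
        for kind, n_events in per_kind.items():
            acc[kind][0] += transcript_event_total(n_events, rec.reads_control)
            acc[kind][1] += transcript_event_total(n_events, rec.reads_treatment)
    return [EventTotals(k, acc[k][0], acc[k][1]) for k in EVENT_KINDS]


def chisq_gof(
    total_control: int, total_treatment: int, alpha: float = 0.05
) -> GofResult:
    """Goodness-of-fit of two event totals against an equal split.

    Expected counts are (grand total)/2 in each condition; the statistic is
    the usual sum of (observed - expected)^2 / expected without continuity
    correction, referred to a chi-square distribution with df = 1.  With
    both totals zero there are no events to test: the statistic is 0 and
    the probability undefined.
    """
    if total_control < 0 or total_treatment < 0:
        raise InputError("event totals must be non-negative")
    grand = total_control + total_treatment
    if grand == 0:
        return GofResult("", 0, 0, 0.0, None, None, alpha)
    expected = grand / 2.0
    stat = (
        (total_control - expected) ** 2 + (total_treatment - expected) ** 2
    ) / expected
    p = float(chi2.sf(stat, df=1))
    return GofResult(
        "", total_control, total_treatment, stat, p, p < alpha, alpha
    )


def differential_table(
    totals: Iterable[EventTotals],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[GofResult]:
    """One goodness-of-fit row per event kind, in the report's fixed order.

    ``bonferroni`` divides alpha by the number of tested kinds; the default
    applies no multiple-testing correction, matching the tool's report of
    plain Significant / Not-significant labels per kind.
    """
    by_kind = {t.event_kind: t for t in totals}
    order = list(TABLE_ORDER)
    extra = by_kind.get(A5A3SS)
    if extra is not None and (extra.total_control or extra.total_treatment):
        order.append(A5A3SS)
    eff_alpha = alpha / len(order) if bonferroni else alpha
    rows: list[GofResult] = []
    for kind in order:
        t = by_kind.get(kind, EventTotals(kind, 0, 0))
        r = chisq_gof(t.total_control, t.total_treatment, eff_alpha)
        rows.append(
            GofResult(
                kind,
                t.total_control,
                t.total_treatment,
                r.chi_square,
                r.p_value,
                r.significant,
                eff_alpha,
            )
        )
    return rows


def _fmt_p(p: Optional[float]) -> str:
    if p is None:
        return "NA"
    return f"{p:.4g}"


def table_to_tsv(rows: Sequence[GofResult]) -> str:
    """TSV export with totals, statistic, exact p and significance label."""
    lines = [
        "event_kind\ttotal_control\ttotal_treatment\tchi_square\tp_value\tsignificance"
    ]
    for r in rows:
        chi = "NA" if r.p_value is None and r.total_control + r.total_treatment == 0 else f"{r.chi_square:.4g}"
        lines.append(
            f"{r.event_kind}\t{r.total_control}\t{r.total_treatment}"
            f"\t{chi}\t{_fmt_p(r.p_value)}\t{r.label}"
        )
    return "\n".join(lines) + "\n"
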