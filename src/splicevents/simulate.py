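"""Synthetic multi-transcript gene loci with planted AS events.

The generator emits a gene whose *backbone* transcript contains every
putative exon, plus alternative transcripts derived from the backbone by
applying sampled events.  Construction guarantees make the planted truth
unambiguous and exactly recoverable:

* events planted on one transcript are mutually non-interacting — no two
  events claim the same putative exon or intron;
* alternative boundary coordinates are globally distinct across the gene,
  and truncations stay below half the exon length, so the pooled-frequency
  selection rules always reproduce the backbone exons as the graph;
* a partial intron retention is only kept where at least two transcripts
  retain the unmodified donor boundary, so the extended coordinate can
  never win the frequency vote.

Coordinates live on a synthetic chromosome ``chrSim`` starting at 1,001.
Default event rates are per-transcript attempt probabilities, with intron
retention kept rare (a few percent of events in vertebrates).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    A3SS,
    A5A3SS,
    A5SS,
    AP,
    AT,
    ASEvent,
    ES,
    Gene,
    InputError,
    Interval,
    QueryRecord,
    RI,
    SUB_RI,
    Transcript,
    mirror_back,
    orient_forward,
)

CHROM = "chrSim"
ORIGIN = 1001

DEFAULT_EVENT_RATES = {
    ES: 0.30,
    A5SS: 0.15,
    A3SS: 0.15,
    A5A3SS: 0.05,
    RI: 0.05,
    SUB_RI: 0.05,
    AP: 0.15,
    AT: 0.15,
}


class GenerationError(InputError):
    """Requested simulation parameters cannot be realized."""


@dataclass
class SimulationParams:
    n_putative_exons: int = 5
    exon_length_range: tuple[int, int] = (80, 300)
    intron_length_range: tuple[int, int] = (100, 1000)
    event_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_RATES)
    )
    n_alt_transcripts: int = 4
    strand: str = "+"
    gene_id: str = "SIMGENE"
    seed: int = 0

    def __post_init__(self):
        if self.n_putative_exons < 2:
            raise GenerationError("need at least 2 putative exons")
        for name, (lo, hi) in (
            ("exon_length_range", self.exon_length_range),
            ("intron_length_range", self.intron_length_range),
        ):
            if lo < 1 or lo > hi:
                raise GenerationError(f"invalid {name}: ({lo}, {hi})")
        if self.intron_length_range[0] < 3:
            raise GenerationError("introns must be >= 3 nt for partial retention")
        if self.exon_length_range[0] < 4:
            raise GenerationError("exons must be >= 4 nt for truncation events")
        for kind, rate in self.event_rates.items():
            if kind not in DEFAULT_EVENT_RATES:
                raise GenerationError(f"unknown event kind {kind!r}")
            if not 0.0 <= rate <= 1.0:
                raise GenerationError(f"rate for {kind} must be in [0, 1]")
        if self.strand not in {"+", "-"}:
            raise GenerationError("strand must be + or -")


@dataclass
class TruthSet:
    """Planted events per transcript, in forward-orientation indices."""

    events: dict[str, tuple[ASEvent, ...]]

    def __getitem__(self, tid: str) -> tuple[ASEvent, ...]:
        return self.events[tid]

    def transcript_ids(self) -> list[str]:
        return list(self.events)


@dataclass
class _Plan:
    """One transcript's sampled events as backbone edits."""

    drop_exons: set[int] = field(default_factory=set)
    merge_introns: set[int] = field(default_factory=set)
    start_delta: dict[int, int] = field(default_factory=dict)
    end_delta: dict[int, int] = field(default_factory=dict)  # <0 truncate, >0 extend
    truth: list[ASEvent] = field(default_factory=list)
    claims: set[tuple[str, int]] = field(default_factory=set)

    def free(self, *resources: tuple[str, int]) -> bool:
        return not self.claims.intersection(resources)


def _feasible_placements(
    kind: str, n: int, backbone: list[Interval], plan: _Plan
) -> list[int]:
    """Placements (exon or intron index) not conflicting with prior claims."""
    out = []
    if kind == ES:
        for k in range(2, n):
            if plan.free(("E", k), ("I", k - 1), ("I", k)):
                out.append(k)
    elif kind == RI:
        for k in range(1, n):
            if plan.free(("E", k), ("E", k + 1), ("I", k)):
                out.append(k)
    elif kind == A5SS:
        for k in range(1, n):
            if backbone[k - 1].length >= 4 and plan.free(("E", k), ("I", k)):
                out.append(k)
    elif kind == A3SS:
        for k in range(2, n + 1):
            if backbone[k - 1].length >= 4 and plan.free(("E", k), ("I", k - 1)):
                out.append(k)
    elif kind == A5A3SS:
        for k in range(2, n):
            if backbone[k - 1].length >= 6 and plan.free(
                ("E", k), ("I", k - 1), ("I", k)
            ):
                out.append(k)
    elif kind == SUB_RI:
        for k in range(1, n):
            intron = backbone[k].start - backbone[k - 1].end - 1
            if intron >= 3 and plan.free(("E", k), ("I", k)):
                out.append(k)
    elif kind == AP:
        if n >= 2 and plan.free(("E", 1), ("I", 1)):
            out.append(1)
    elif kind == AT:
        if n >= 2 and plan.free(("E", n), ("I", n - 1)):
            out.append(n)
    return out


def _pick_delta(rng: random.Random, lo: int, hi: int, used: set[int]) -> Optional[int]:
    """A delta in [lo, hi] whose resulting coordinate is globally unused."""
    candidates = [d for d in range(lo, hi + 1) if d not in used]
    if not candidates:
        return None
    return rng.choice(candidates)


def make_gene(params: SimulationParams) -> tuple[Gene, tuple[Interval, ...], TruthSet]:
    """Generate a gene, the true putative-exon set, and the planted events.

    Returns the gene in original genomic coordinates (minus-strand genes are
    mirrored back), the truth graph as the backbone exon intervals in
    forward orientation, and the per-transcript truth labels.
    """
    rng = random.Random(params.seed)
    n = params.n_putative_exons
    backbone: list[Interval] = []
    pos = ORIGIN
    for i in range(n):
        length = rng.randint(*params.exon_length_range)
        backbone.append(Interval(pos, pos + length - 1))
        pos += length + rng.randint(*params.intron_length_range)

    # globally distinct alternative coordinates per boundary side
    used_start_coords: dict[int, set[int]] = {k: set() for k in range(1, n + 1)}
    used_end_coords: dict[int, set[int]] = {k: set() for k in range(1, n + 1)}

    plans: list[_Plan] = []
    kinds_in_order = [ES, RI, A5SS, A3SS, A5A3SS, SUB_RI, AP, AT]
    for _ in range(params.n_alt_transcripts):
        plan = _Plan()
        for kind in kinds_in_order:
            rate = params.event_rates.get(kind, 0.0)
            if rate <= 0.0 or rng.random() >= rate:
                continue
            placements = _feasible_placements(kind, n, backbone, plan)
            if not placements:
                if rate >= 1.0:
                    raise GenerationError(
                        f"event {kind} forced (rate 1) but unrealizable with "
                        f"n_putative_exons={n} and prior placements"
                    )
                continue
            k = rng.choice(placements)
            exon = backbone[k - 1]
            if kind == ES:
                plan.drop_exons.add(k)
                plan.claims |= {("E", k), ("I", k - 1), ("I", k)}
                plan.truth.append(ASEvent(ES, k))
            elif kind == RI:
                plan.merge_introns.add(k)
                plan.claims |= {("E", k), ("E", k + 1), ("I", k)}
                plan.truth.append(ASEvent(RI, k))
            elif kind == A5SS:
                d = _pick_delta(rng, 1, exon.length // 2 - 1, used_end_coords[k])
                if d is None:
                    continue
                used_end_coords[k].add(d)
                plan.end_delta[k] = -d
                plan.claims |= {("E", k), ("I", k)}
                plan.truth.append(ASEvent(A5SS, k))
            elif kind == A3SS:
                d = _pick_delta(rng, 1, exon.length // 2 - 1, used_start_coords[k])
                if d is None:
                    continue
                used_start_coords[k].add(d)
                plan.start_delta[k] = d
                plan.claims |= {("E", k), ("I", k - 1)}
                plan.truth.append(ASEvent(A3SS, k))
            elif kind == A5A3SS:
                d1 = _pick_delta(rng, 1, exon.length // 2 - 1, used_start_coords[k])
                d2 = _pick_delta(rng, 1, exon.length // 2 - 1, used_end_coords[k])
                if d1 is None or d2 is None:
                    continue
                used_start_coords[k].add(d1)
                used_end_coords[k].add(d2)
                plan.start_delta[k] = d1
                plan.end_delta[k] = -d2
                plan.claims |= {("E", k), ("I", k - 1), ("I", k)}
                plan.truth.append(ASEvent(A5A3SS, k))
            elif kind == SUB_RI:
                intron = backbone[k].start - backbone[k - 1].end - 1
                d = _pick_delta(
                    rng,
                    1,
                    intron - 2,
                    {-d for d in used_end_coords[k] if d < 0} | set(),
                )
                if d is None:
                    continue
                used_end_coords[k].add(-d)
                plan.end_delta[k] = d
                plan.claims |= {("E", k), ("I", k)}
                plan.truth.append(ASEvent(SUB_RI, k))
            elif kind == AP:
                plan.drop_exons.add(1)
                plan.claims |= {("E", 1), ("I", 1)}
                plan.truth.append(ASEvent(AP))
            elif kind == AT:
                plan.drop_exons.add(n)
                plan.claims |= {("E", n), ("I", n - 1)}
                plan.truth.append(ASEvent(AT))
        plans.append(plan)

    # a partial intron retention must never out-vote the backbone donor:
    # require >= 2 transcripts (backbone included) retaining that exon end
    changed = True
    while changed:
        changed = False
        for plan in plans:
            for k, delta in list(plan.end_delta.items()):
                if delta <= 0:
                    continue
                support = 1  # backbone
                for other in plans:
                    if other is plan:
                        continue
                    intact = (
                        k not in other.drop_exons
                        and k not in other.merge_introns  # merged keeps end of k+1
                        and other.end_delta.get(k) is None
                    )
                    if k - 1 in other.merge_introns:
                        intact = True  # merged exon ends at end of k
                    if intact:
                        support += 1
                if support < 2:
                    del plan.end_delta[k]
                    plan.claims.discard(("I", k))
                    plan.truth = [
                        e
                        for e in plan.truth
                        if not (e.kind == SUB_RI and e.exon_index == k)
                    ]
                    changed = True

    transcripts: list[Transcript] = []
    truth: dict[str, tuple[ASEvent, ...]] = {}
    tid0 = f"{params.gene_id}.T0"
    transcripts.append(
        Transcript(tid0, params.gene_id, "protein_coding", params.strand,
                   tuple(backbone))
    )
    truth[tid0] = ()
    for j, plan in enumerate(plans, start=1):
        exons: list[Interval] = []
        k = 1
        while k <= n:
            if k in plan.drop_exons:
                k += 1
                continue
            start = backbone[k - 1].start + plan.start_delta.get(k, 0)
            end_exon = k
            while end_exon in plan.merge_introns:
                end_exon += 1
            delta = plan.end_delta.get(end_exon, 0)
            end = backbone[end_exon - 1].end + delta
            exons.append(Interval(start, end))
            k = end_exon + 1
        tid = f"{params.gene_id}.T{j}"
        transcripts.append(
            Transcript(tid, params.gene_id, "protein_coding", params.strand,
                       tuple(exons))
        )
        truth[tid] = tuple(sorted(plan.truth))

    gene = Gene(
        gene_id=params.gene_id,
        chromosome=CHROM,
        strand=params.strand,
        transcripts=transcripts,
        oriented=True,
    )
    if params.strand == "-":
        span = gene.span
        gene.mirror_pivot = span.start + span.end
        gene = mirror_back(gene)
    else:
        gene.oriented = False
    return gene, tuple(backbone), TruthSet(truth)


def write_gtf(genes, path) -> None:
    """Serialize gene models as GTF2.2 exon features (protein_coding
    biotype), in original genomic orientation."""
    with open(path, "w") as fh:
        for gene in genes:
            out = mirror_back(gene) if gene.oriented and gene.mirror_pivot else gene
            for t in out.transcripts:
                biotype = t.biotype or "protein_coding"
                for i, e in enumerate(t.exons, start=1):
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{t.transcript_id}"; '
                        f'transcript_biotype "{biotype}"; '
                        f'exon_number "{i}";'
                    )
                    fh.write(
                        f"{gene.chromosome}\tsplicevents\texon\t{e.start}\t{e.end}"
                        f"\t.\t{gene.strand}\t.\t{attrs}\n"
                    )


def make_count_table(
    truth: TruthSet,
    effect: dict[str, float],
    base_reads: int = 40,
    seed: Optional[int] = None,
    noise: bool = False,
) -> list[QueryRecord]:
    """Per-condition unique-read counts for the truth transcripts.

    Control reads equal ``base_reads``; treatment reads are ``base_reads``
    scaled by the transcript's fold-change (default 1).  With ``noise``
    both columns are Poisson-distributed around those means, reproducibly
    for a fixed seed.
    """
    if base_reads <= 0:
        raise InputError("base_reads must be positive")
    rng = random.Random(seed)
    records = []
    for tid in truth.transcript_ids():
        fold = effect.get(tid, 1.0)
        if fold < 0:
            raise InputError(f"{tid}: fold-change must be non-negative")
        mean_c, mean_t = float(base_reads), base_reads * fold
        if noise:
            reads_c = _poisson(rng, mean_c)
            reads_t = _poisson(rng, mean_t)
        else:
            reads_c, reads_t = base_reads, round(mean_t)
        records.append(QueryRecord(tid, reads_c, reads_t))
    return records


def _poisson(rng: random.Random, mean: float) -> int:
    """Knuth sampler; means here are small (read counts per transcript)."""
    if mean <= 0:
        return 0
    import math

    limit = math.exp(-mean)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def truth_to_tsv(truth: TruthSet) -> str:
    """TSV truth labels: transcript_id, event_kind, exon_index."""
    lines = ["transcript_id\tevent_kind\texon_index"]
    for tid in truth.transcript_ids():
        for e in truth[tid]:
            idx = "" if e.exon_index is None else str(e.exon_index)
            lines.append(f"{tid}\t{e.kind}\t{idx}")
    return "\n".join(lines) + "\n"
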