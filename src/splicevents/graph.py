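"""Per-gene splice-graph construction from pooled splice-site frequencies.

The graph summarizes all graph-eligible (by default protein-coding)
transcripts of a gene as an ordered set of non-overlapping *putative exons*,
selected by three rules applied to the pooled exon boundaries:

1. within a cluster of overlapping observed exons, the boundary coordinates
   with the highest pooled frequency win;
2. frequency ties are broken by exon length — the smaller start for a
   repeated end, the larger end for a repeated start;
3. an exon that spans several smaller, mutually non-overlapping exons is
   discarded in favour of the smaller exons ("multiple exons preferred").

Every exon occurrence of every eligible transcript contributes one count per
boundary; repeated identical exons each count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .model import BuildError, Gene, Interval, UsageError


@dataclass
class SpliceSitePool:
    """Pooled boundary frequencies: starts (acceptor side) and ends (donor
    side) are tallied separately — donors and acceptors are distinct site
    classes even when they share a coordinate."""

    start_freq: dict[int, int]
    end_freq: dict[int, int]


@dataclass
class SpliceGraph:
    """Ordered putative exons of one gene, numbered 1..n in forward
    orientation, with the boundary pool they were selected from."""

    gene_id: str
    putative_exons: tuple[Interval, ...]
    pool: SpliceSitePool
    source_transcript_count: int
    #: exons discarded by rule 3, visible to the classifier as transcript
    #: exons (they surface as retained introns)
    discarded_spanning: tuple[Interval, ...] = ()

    def __post_init__(self):
        for a, b in zip(self.putative_exons, self.putative_exons[1:]):
            if b.start <= a.end:
                raise BuildError(
                    f"gene {self.gene_id}: putative exons {a} and {b} overlap"
                )

    @property
    def n(self) -> int:
        return len(self.putative_exons)

    def exon(self, index: int) -> Interval:
        """1-based putative exon access."""
        return self.putative_exons[index - 1]


def pool_splice_sites(gene: Gene) -> SpliceSitePool:
    """Tally every exon occurrence of every graph-eligible transcript."""
    if not gene.oriented:
        raise UsageError(f"gene {gene.gene_id} must be oriented first")
    eligible = gene.eligible_transcripts
    if not eligible:
        raise BuildError(f"gene {gene.gene_id}: no graph-eligible transcripts")
    starts: Counter[int] = Counter()
    ends: Counter[int] = Counter()
    for t in eligible:
        for e in t.exons:
            starts[e.start] += 1
            ends[e.end] += 1
    return SpliceSitePool(dict(starts), dict(ends))


def cluster_overlapping_exons(exons: list[Interval]) -> list[list[Interval]]:
    """Connected components under interval overlap (>= 1 shared base),
    ordered by leftmost start; multiplicity preserved within a cluster."""
    if not exons:
        return []
    ordered = sorted(exons)
    clusters: list[list[Interval]] = [[ordered[0]]]
    reach = ordered[0].end
    for e in ordered[1:]:
        if e.start <= reach:
            clusters[-1].append(e)
        else:
            clusters.append([e])
        reach = max(reach, e.end)
    return clusters


def _spanning_exons(cluster: list[Interval]) -> set[Interval]:
    """Rule 3 detection: exons containing >= 2 mutually non-overlapping
    distinct smaller exons of the same cluster."""
    distinct = sorted(set(cluster))
    spanning: set[Interval] = set()
    for big in distinct:
        inside = [e for e in distinct if e != big and big.contains(e)]
        for a, b in ((a, b) for i, a in enumerate(inside) for b in inside[i + 1:]):
            if not a.overlaps(b):
                spanning.add(big)
                break
    return spanning


def partition_cluster(cluster: list[Interval]) -> list[list[Interval]]:
    """Apply rule 3: drop exons that span several mutually non-overlapping
    smaller exons, re-cluster the remainder, and recurse until stable.
    Returns the cluster unchanged (as a single sub-cluster) when the rule
    does not trigger."""
    spanning = _spanning_exons(cluster)
    if not spanning:
        return [cluster]
    remaining = [e for e in cluster if e not in spanning]
    out: list[list[Interval]] = []
    for sub in cluster_overlapping_exons(remaining):
        out.extend(partition_cluster(sub))
    return out


def select_putative_exon(subcluster: list[Interval], pool: SpliceSitePool) -> Interval:
    """Rules 1-2: independent argmax over boundary frequencies within the
    sub-cluster; ties go to the longer exon (smaller start, larger end)."""
    if not subcluster:
        raise BuildError("empty sub-cluster")
    starts = sorted({e.start for e in subcluster})
    ends = sorted({e.end for e in subcluster})
    best_start = min(starts, key=lambda s: (-pool.start_freq.get(s, 0), s))
    best_end = max(ends, key=lambda s: (pool.end_freq.get(s, 0), s))
    if best_start > best_end:
        raise BuildError(
            f"pathological cluster {subcluster}: selected start {best_start} "
            f"> end {best_end}"
        )
    return Interval(best_start, best_end)


def build_splicegraph(gene: Gene) -> SpliceGraph:
    """Full pipeline: pool boundaries, cluster overlapping exons, apply the
    multi-exon preference, select one putative exon per sub-cluster."""
    pool = pool_splice_sites(gene)
    all_exons = [e for t in gene.eligible_transcripts for e in t.exons]
    putative: list[Interval] = []
    discarded: list[Interval] = []
    for cluster in cluster_overlapping_exons(all_exons):
        subclusters = partition_cluster(cluster)
        if len(subclusters) > 1 or subclusters[0] != cluster:
            kept = {e for sub in subclusters for e in sub}
            discarded.extend(sorted(set(cluster) - kept))
        for sub in subclusters:
            putative.append(select_putative_exon(sub, pool))
    putative.sort()
    return SpliceGraph(
        gene_id=gene.gene_id,
        putative_exons=tuple(putative),
        pool=pool,
        source_transcript_count=len(gene.eligible_transcripts),
        discarded_spanning=tuple(discarded),
    )


def graph_to_tsv(graph: SpliceGraph) -> str:
    """TSV export: one row per putative exon with its boundary frequencies."""
    lines = ["gene_id\texon_index\tstart\tend\tstart_freq\tend_freq"]
    for i, e in enumerate(graph.putative_exons, start=1):
        lines.append(
            f"{graph.gene_id}\t{i}\t{e.start}\t{e.end}"
            f"\t{graph.pool.start_freq.get(e.start, 0)}"
            f"\t{graph.pool.end_freq.get(e.end, 0)}"
        )
    return "\n".join(lines) + "\n"


def graph_to_bed(graph: SpliceGraph, gene: Gene) -> str:
    """BED export (0-based half-open), restored to original orientation."""
    rows = []
    for i, e in enumerate(graph.putative_exons, start=1):
        a, b = gene.to_genomic(e.start), gene.to_genomic(e.end)
        lo, hi = min(a, b), max(a, b)
        rows.append(
            (lo - 1, f"{gene.chromosome}\t{lo - 1}\t{hi}\t"
                     f"{graph.gene_id}_exon{i}\t0\t{gene.strand}")
        )
    rows.sort()
    return "\n".join(r for _, r in rows) + "\n"
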