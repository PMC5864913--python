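"""Brute-force literal application of the three putative-exon selection
rules, written against plain (start, end) tuples with no imports from the
package's graph code.  Serves as the independent oracle for small loci.
"""

from collections import Counter
from itertools import combinations


def brute_pool(exons):
    """exons: list of (start, end) occurrences."""
    return Counter(e[0] for e in exons), Counter(e[1] for e in exons)


def _overlap(a, b):
    return a[0] <= b[1] and b[0] <= a[1]


def brute_clusters(exons):
    """Connected components under overlap, by transitive closure over
    occurrence pairs (quadratic on purpose — different route than the
    production sweep)."""
    items = list(exons)
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in combinations(range(len(items)), 2):
        if _overlap(items[i], items[j]):
            parent[find(i)] = find(j)
    groups = {}
    for i, e in enumerate(items):
        groups.setdefault(find(i), []).append(e)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def _contained(inner, outer):
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def brute_partition(cluster):
    """Rule 3 by literal subset search: an exon equivalent to several
    mutually non-overlapping smaller exons is dropped; recurse."""
    distinct = sorted(set(cluster))
    spanning = set()
    for big in distinct:
        inside = [e for e in distinct if e != big and _contained(e, big)]
        for r in range(2, len(inside) + 1):
            if any(
                all(not _overlap(a, b) for a, b in combinations(sub, 2))
                for sub in combinations(inside, r)
            ):
                spanning.add(big)
                break
    if not spanning:
        return [cluster]
    remaining = [e for e in cluster if e not in spanning]
    out = []
    for sub in brute_clusters(remaining):
        out.extend(brute_partition(sub))
    return out


def brute_select(subcluster, start_freq, end_freq):
    """Rules 1-2: highest pooled frequency wins; frequency ties go to the
    longer exon (smaller start, larger end)."""
    starts = sorted({e[0] for e in subcluster})
    top = max(start_freq[s] for s in starts)
    start = min(s for s in starts if start_freq[s] == top)
    ends = sorted({e[1] for e in subcluster})
    top = max(end_freq[s] for s in ends)
    end = max(s for s in ends if end_freq[s] == top)
    assert start <= end, subcluster
    return (start, end)


def brute_graph(exons):
    """Full literal pipeline on an exon-occurrence multiset."""
    start_freq, end_freq = brute_pool(exons)
    putative = []
    for cluster in brute_clusters(exons):
        for sub in brute_partition(cluster):
            putative.append(brute_select(sub, start_freq, end_freq))
    return tuple(sorted(putative))


def pack_transcripts(exons):
    """Greedy packing of exon occurrences into non-overlapping gapped
    chains; each chain is a valid transcript exon list."""
    chains = []
    for e in sorted(exons):
        for chain in chains:
            if e[0] >= chain[-1][1] + 2:
                chain.append(e)
                break
        else:
            chains.append([e])
    return chains
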