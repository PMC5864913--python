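"""Reading gene models from GTF/GFF3, query lists, and optional Ensembl REST.

Only ``exon`` features are consumed; coordinates are 1-based inclusive as in
the source formats.  Transcripts whose biotype fails the filter (default
``protein_coding``) are kept on the gene but flagged ineligible for
splice-graph building, so they can still be classified as queries.
"""

from __future__ import annotations

import json
import logging
import urllib.request
import urllib.error
from collections import OrderedDict
from typing import Optional

from .model import (
    Gene,
    InputError,
    Interval,
    ParseError,
    QueryRecord,
    RetrievalError,
    Transcript,
)

logger = logging.getLogger(__name__)

DEFAULT_BIOTYPE = "protein_coding"
ENSEMBL_REST = "https://rest.ensembl.org"


def _parse_gtf_attributes(field: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise ParseError(f"line {lineno}: malformed GTF attribute {chunk!r}")
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _biotype_ok(biotype: Optional[str], biotype_filter: Optional[str]) -> bool:
    # An absent biotype attribute is treated as eligible: toy annotations
    # often omit it and excluding silently would be surprising.
    if biotype_filter is None or biotype is None:
        return True
    return biotype == biotype_filter


def _assemble_genes(
    exon_rows: "OrderedDict[tuple[str, str], list[Interval]]",
    meta: dict[tuple[str, str], tuple[str, str, Optional[str]]],
    biotype_filter: Optional[str],
) -> list[Gene]:
    """Group per-transcript exon lists into Gene objects, in input order."""
    genes: "OrderedDict[str, list[Transcript]]" = OrderedDict()
    gene_loc: dict[str, tuple[str, str]] = {}
    for (gene_id, tid), exons in exon_rows.items():
        chrom, strand, biotype = meta[(gene_id, tid)]
        try:
            tx = Transcript(
                transcript_id=tid,
                gene_id=gene_id,
                biotype=biotype or "",
                strand=strand,
                exons=tuple(exons),
                graph_eligible=_biotype_ok(biotype, biotype_filter),
            )
        except ValueError as exc:
            raise ParseError(str(exc)) from exc
        genes.setdefault(gene_id, []).append(tx)
        prev = gene_loc.setdefault(gene_id, (chrom, strand))
        if prev != (chrom, strand):
            raise ParseError(
                f"gene {gene_id}: transcripts disagree on location "
                f"({prev} vs {(chrom, strand)})"
            )
    return [
        Gene(gene_id=g, chromosome=gene_loc[g][0], strand=gene_loc[g][1],
             transcripts=txs)
        for g, txs in genes.items()
    ]


def read_gtf(path, biotype_filter: Optional[str] = DEFAULT_BIOTYPE) -> list[Gene]:
    """Read gene models from a GTF2.2 file.

    Parameters
    ----------
    path
        GTF file with tab-separated, 1-based inclusive exon features whose
        attribute column carries ``gene_id`` and ``transcript_id``.
    biotype_filter
        Transcripts whose ``transcript_biotype`` (fallback ``gene_biotype``)
        differs are flagged ineligible for graph building but retained.
        ``None`` disables filtering.
    """
    exon_rows: "OrderedDict[tuple[str, str], list[Interval]]" = OrderedDict()
    meta: dict[tuple[str, str], tuple[str, str, Optional[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            if start > end:
                raise ParseError(f"line {lineno}: exon start {start} > end {end}")
            attrs = _parse_gtf_attributes(attr_s, lineno)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise ParseError(
                    f"line {lineno}: exon lacks gene_id or transcript_id attribute"
                )
            gene_id, tid = attrs["gene_id"], attrs["transcript_id"]
            biotype = attrs.get("transcript_biotype", attrs.get("gene_biotype"))
            key = (gene_id, tid)
            exon_rows.setdefault(key, []).append(Interval(start, end))
            meta.setdefault(key, (chrom, strand, biotype))
    return _assemble_genes(exon_rows, meta, biotype_filter)


def read_gff3(path, biotype_filter: Optional[str] = DEFAULT_BIOTYPE) -> list[Gene]:
    """Read gene models from GFF3; exon Parent chains resolve over 1-2 hops.

    Contract is identical to :func:`read_gtf`.  Genes whose features include
    no exons (e.g. CDS-only records) are omitted with a warning.
    """
    # first pass: record every feature with an ID so Parents can resolve
    records: dict[str, dict] = {}
    exon_lines: list[tuple[int, str, int, int, str, dict[str, str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            attrs = _parse_gff3_attributes(attr_s)
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            if start > end:
                raise ParseError(f"line {lineno}: feature start {start} > end {end}")
            if ftype == "exon":
                exon_lines.append((lineno, chrom, start, end, strand, attrs))
            elif "ID" in attrs:
                records[attrs["ID"]] = {"type": ftype, "attrs": attrs}

    exon_rows: "OrderedDict[tuple[str, str], list[Interval]]" = OrderedDict()
    meta: dict[tuple[str, str], tuple[str, str, Optional[str]]] = {}
    for lineno, chrom, start, end, strand, attrs in exon_lines:
        parents = attrs.get("Parent", "")
        if not parents:
            raise ParseError(f"line {lineno}: exon feature has no Parent")
        for parent in parents.split(","):
            if parent not in records:
                raise ParseError(
                    f"line {lineno}: exon Parent {parent!r} does not resolve"
                )
            rec = records[parent]
            tid = rec["attrs"].get("ID", parent)
            gene_parent = rec["attrs"].get("Parent")
            if gene_parent is not None:
                if gene_parent not in records:
                    raise ParseError(
                        f"line {lineno}: transcript Parent {gene_parent!r} "
                        "does not resolve"
                    )
                gene_rec = records[gene_parent]
                gene_id = gene_rec["attrs"].get("ID", gene_parent)
            else:
                gene_rec = rec
                gene_id = tid
            biotype = rec["attrs"].get("biotype") or gene_rec["attrs"].get("biotype")
            key = (gene_id, tid)
            exon_rows.setdefault(key, []).append(Interval(start, end))
            meta.setdefault(key, (chrom, strand, biotype))

    covered_genes = {g for g, _ in exon_rows}
    for rec in records.values():
        if rec["type"] == "gene" and rec["attrs"].get("ID") not in covered_genes:
            logger.warning(
                "gene %s has no exon features and was omitted",
                rec["attrs"].get("ID"),
            )
    return _assemble_genes(exon_rows, meta, biotype_filter)


def read_query_list(path) -> list[QueryRecord]:
    """Read query transcript IDs, optionally with per-condition read counts.

    Accepts either one bare ID per line or a TSV with a header naming
    ``transcript_id``, ``reads_control`` and ``reads_treatment`` columns.
    Order is preserved; duplicate IDs are kept with a warning.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    records: list[QueryRecord] = []
    if lines and lines[0].split("\t")[0] == "transcript_id":
        header = lines[0].split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("reads_control", "reads_treatment"):
            if name not in idx:
                raise InputError(f"query table lacks column {name!r}")
        for ln in lines[1:]:
            fields = ln.split("\t")
            tid = fields[idx["transcript_id"]]
            counts = []
            for name in ("reads_control", "reads_treatment"):
                raw = fields[idx[name]]
                try:
                    value = int(raw)
                except ValueError:
                    raise InputError(
                        f"{tid}: count {raw!r} is not an integer"
                    ) from None
                counts.append(value)
            records.append(QueryRecord(tid, counts[0], counts[1]))
    else:
        for ln in lines:
            records.append(QueryRecord(ln.split("\t")[0].strip()))
    seen = set()
    for r in records:
        if r.transcript_id in seen:
            logger.warning("duplicate query ID %s kept", r.transcript_id)
        seen.add(r.transcript_id)
    return records


def _rest_json(url: str, identifier: str) -> dict:
    req = urllib.request.Request(url, headers={"Accept": "application/json"})
    try:
        with urllib.request.urlopen(req, timeout=30) as resp:
            return json.load(resp)
    except (urllib.error.URLError, OSError, ValueError) as exc:
        raise RetrievalError(
            f"lookup of {identifier!r} at {url} failed: {exc}", identifier
        ) from exc


def fetch_gene_for_transcript(
    transcript_id: str, endpoint: str = ENSEMBL_REST
) -> Gene:
    """Fetch the full gene model for a transcript ID from an Ensembl-style
    REST endpoint (``/lookup/id`` with ``expand``).  Network mode only; the
    offline test suite exercises this through a mocked opener.
    """
    tx = _rest_json(
        f"{endpoint}/lookup/id/{transcript_id}?expand=1", transcript_id
    )
    gene_id = tx.get("Parent")
    if not gene_id:
        raise RetrievalError(
            f"transcript {transcript_id!r} has no parent gene", transcript_id
        )
    gene = _rest_json(f"{endpoint}/lookup/id/{gene_id}?expand=2", gene_id)
    strand = "+" if gene.get("strand", 1) >= 0 else "-"
    transcripts = []
    for t in gene.get("Transcript", []):
        exons = tuple(
            Interval(int(e["start"]), int(e["end"])) for e in t.get("Exon", [])
        )
        if not exons:
            continue
        biotype = t.get("biotype", "")
        transcripts.append(
            Transcript(
                transcript_id=t["id"],
                gene_id=gene["id"],
                biotype=biotype,
                strand=strand,
                exons=exons,
                graph_eligible=(biotype == DEFAULT_BIOTYPE),
            )
        )
    if not transcripts:
        raise RetrievalError(
            f"gene {gene_id!r} has no transcripts with exons", gene_id
        )
    return Gene(
        gene_id=gene["id"],
        chromosome=str(gene.get("seq_region_name", "?")),
        strand=strand,
        transcripts=transcripts,
    )
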