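import logging

import pytest
from hypothesis import given, settings, strategies as st

from splicevents import (
    Gene,
    InputError,
    Interval,
    ParseError,
    QueryRecord,
    RetrievalError,
    Transcript,
    fetch_gene_for_transcript,
    mirror_back,
    orient_forward,
    read_gff3,
    read_gtf,
    read_query_list,
)
import splicevents.annotation_io as aio


class TestReadGtf:
    def test_toy_gene_parses(self, toy_gtf):
        genes = read_gtf(toy_gtf)
        assert len(genes) == 1
        g = genes[0]
        assert g.gene_id == "TOYGENE1" and g.strand == "+"
        assert len(g.transcripts) == 2
        assert sum(len(t.exons) for t in g.transcripts) == 7
        assert g.transcript("T2").exons[0] == Interval(101, 200)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        assert read_gtf(p) == []

    def test_inverted_coordinates_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            'chr1\tx\texon\t200\t100\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        )
        with pytest.raises(ParseError, match="line 1"):
            read_gtf(p)

    def test_missing_transcript_id_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\tx\texon\t100\t200\t.\t+\t.\tgene_id "G";\n')
        with pytest.raises(ParseError, match="line 1"):
            read_gtf(p)

    def test_biotype_filter_keeps_side_index(self, tmp_path):
        p = tmp_path / "mix.gtf"
        p.write_text(
            'chr1\tx\texon\t100\t200\t.\t+\t.\tgene_id "G"; transcript_id "TC"; transcript_biotype "protein_coding";\n'
            'chr1\tx\texon\t100\t200\t.\t+\t.\tgene_id "G"; transcript_id "TN"; transcript_biotype "lncRNA";\n'
        )
        (g,) = read_gtf(p, biotype_filter="protein_coding")
        assert {t.transcript_id for t in g.transcripts} == {"TC", "TN"}
        assert {t.transcript_id for t in g.eligible_transcripts} == {"TC"}
        (g_all,) = read_gtf(p, biotype_filter=None)
        assert len(g_all.eligible_transcripts) == 2


class TestReadGff3:
    def test_matches_gtf_parse(self, toy_gtf, toy_gff3):
        (from_gtf,) = read_gtf(toy_gtf)
        (from_gff3,) = read_gff3(toy_gff3)
        assert from_gff3.gene_id == from_gtf.gene_id
        assert from_gff3.strand == from_gtf.strand
        assert {
            (t.transcript_id, t.exons) for t in from_gff3.transcripts
        } == {(t.transcript_id, t.exons) for t in from_gtf.transcripts}

    def test_orphan_exon_rejected(self, tmp_path):
        p = tmp_path / "orphan.gff3"
        p.write_text("chr1\tx\texon\t100\t200\t.\t+\t.\tParent=NOSUCH\n")
        with pytest.raises(ParseError, match="NOSUCH"):
            read_gff3(p)

    def test_cds_only_gene_omitted_with_warning(self, tmp_path, caplog):
        p = tmp_path / "cds.gff3"
        p.write_text(
            "chr1\tx\tgene\t100\t500\t.\t+\t.\tID=GCDS\n"
            "chr1\tx\tmRNA\t100\t500\t.\t+\t.\tID=TCDS;Parent=GCDS\n"
            "chr1\tx\tCDS\t100\t200\t.\t+\t0\tID=c1;Parent=TCDS\n"
        )
        with caplog.at_level(logging.WARNING):
            assert read_gff3(p) == []
        assert "GCDS" in caplog.text


class TestReadQueryList:
    def test_bare_ids(self, tmp_path):
        p = tmp_path / "q.txt"
        p.write_text("T1\nT2\nT3\n")
        recs = read_query_list(p)
        assert [r.transcript_id for r in recs] == ["T1", "T2", "T3"]
        assert all(r.reads_control is None for r in recs)

    def test_tsv_with_counts(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text(
            "transcript_id\treads_control\treads_treatment\nT2\t40\t20\n"
        )
        assert read_query_list(p) == [QueryRecord("T2", 40, 20)]

    @pytest.mark.parametrize("bad", ["-1", "3.5", "x"])
    def test_bad_counts_rejected(self, tmp_path, bad):
        p = tmp_path / "q.tsv"
        p.write_text(
            f"transcript_id\treads_control\treads_treatment\nT2\t{bad}\t20\n"
        )
        with pytest.raises(InputError):
            read_query_list(p)

    def test_duplicates_kept_with_warning(self, tmp_path, caplog):
        p = tmp_path / "q.txt"
        p.write_text("T1\nT1\n")
        with caplog.at_level(logging.WARNING):
            recs = read_query_list(p)
        assert len(recs) == 2 and "T1" in caplog.text


class TestOrientForward:
    def test_plus_strand_is_identity(self, toygene):
        fwd = orient_forward(toygene)
        assert fwd.oriented and fwd.mirror_pivot is None
        assert [t.exons for t in fwd.transcripts] == [
            t.exons for t in toygene.transcripts
        ]

    def test_minus_strand_mirrors_within_span(self):
        t = Transcript("T", "G", "protein_coding", "-",
                       (Interval(100, 200), Interval(900, 1000)))
        fwd = orient_forward(Gene("G", "chr1", "-", [t]))
        # span [100,1000] -> m(x) = 1100 - x
        assert fwd.transcript("T").exons == (
            Interval(100, 200), Interval(900, 1000),
        )
        t2 = Transcript("T", "G", "protein_coding", "-",
                        (Interval(100, 200), Interval(500, 1000)))
        fwd2 = orient_forward(Gene("G", "chr1", "-", [t2]))
        assert fwd2.transcript("T").exons == (
            Interval(100, 600), Interval(900, 1000),
        )

    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(1, 300)),
            min_size=1, max_size=6,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_mirror_roundtrip_preserves_lengths_and_gaps(self, raw):
        # build a gapped exon chain from (offset, length) pairs
        exons, pos = [], 1
        for off, ln in raw:
            pos += off + 2
            exons.append(Interval(pos, pos + ln - 1))
            pos += ln
        t = Transcript("T", "G", "protein_coding", "-", tuple(exons))
        gene = Gene("G", "chr1", "-", [t])
        fwd = orient_forward(gene)
        fx = fwd.transcript("T").exons
        assert [e.length for e in fx] == [e.length for e in reversed(exons)]
        gaps = lambda xs: [b.start - a.end for a, b in zip(xs, xs[1:])]
        assert gaps(fx) == list(reversed(gaps(exons)))
        back = mirror_back(fwd)
        assert back.transcript("T").exons == tuple(exons)


class TestFetch:
    payload_tx = {"id": "T1", "Parent": "TOYGENE1"}
    payload_gene = {
        "id": "TOYGENE1", "seq_region_name": "chrT", "strand": 1,
        "Transcript": [
            {"id": "T1", "biotype": "protein_coding",
             "Exon": [{"start": 101, "end": 200}, {"start": 301, "end": 400},
                      {"start": 501, "end": 600}, {"start": 701, "end": 800}]},
            {"id": "T2", "biotype": "protein_coding",
             "Exon": [{"start": 101, "end": 200}, {"start": 501, "end": 600},
                      {"start": 701, "end": 800}]},
        ],
    }

    def test_mocked_endpoint_round_trip(self, monkeypatch, toygene):
        def fake(url, identifier):
            return self.payload_tx if "/T1?" in url else self.payload_gene

        monkeypatch.setattr(aio, "_rest_json", fake)
        g = fetch_gene_for_transcript("T1", endpoint="mock://ensembl")
        assert {(t.transcript_id, t.exons) for t in g.transcripts} == {
            (t.transcript_id, t.exons) for t in toygene.transcripts
        }

    def test_unreachable_endpoint_raises_with_id(self):
        with pytest.raises(RetrievalError) as exc:
            fetch_gene_for_transcript(
                "ENST00000000000X", endpoint="http://127.0.0.1:1"
            )
        assert exc.value.identifier == "ENST00000000000X"
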