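import pytest

from splicevents import Gene, Interval, Transcript, build_splicegraph, orient_forward

TOY_GTF = """\
chrT\ttest\texon\t101\t200\t.\t+\t.\tgene_id "TOYGENE1"; transcript_id "T1"; transcript_biotype "protein_coding";
chrT\ttest\texon\t301\t400\t.\t+\t.\tgene_id "TOYGENE1"; transcript_id "T1"; transcript_biotype "protein_coding";
chrT\ttest\texon\t501\t600\t.\t+\t.\tgene_id "TOYGENE1"; transcript_id "T1"; transcript_biotype "protein_coding";
chrT\ttest\texon\t701\t800\t.\t+\t.\tgene_id "TOYGENE1"; transcript_id "T1"; transcript_biotype "protein_coding";
chrT\ttest\texon\t101\t200\t.\t+\t.\tgene_id "TOYGENE1"; transcript_id "T2"; transcript_biotype "protein_coding";
chrT\ttest\texon\t501\t600\t.\t+\t.\tgene_id "TOYGENE1"; transcript_id "T2"; transcript_biotype "protein_coding";
chrT\ttest\texon\t701\t800\t.\t+\t.\tgene_id "TOYGENE1"; transcript_id "T2"; transcript_biotype "protein_coding";
"""

TOY_GFF3 = """\
##gff-version 3
chrT\ttest\tgene\t101\t800\t.\t+\t.\tID=TOYGENE1;biotype=protein_coding
chrT\ttest\tmRNA\t101\t800\t.\t+\t.\tID=T1;Parent=TOYGENE1;biotype=protein_coding
chrT\ttest\texon\t101\t200\t.\t+\t.\tParent=T1
chrT\ttest\texon\t301\t400\t.\t+\t.\tParent=T1
chrT\ttest\texon\t501\t600\t.\t+\t.\tParent=T1
chrT\ttest\texon\t701\t800\t.\t+\t.\tParent=T1
chrT\ttest\tmRNA\t101\t800\t.\t+\t.\tID=T2;Parent=TOYGENE1;biotype=protein_coding
chrT\ttest\texon\t101\t200\t.\t+\t.\tParent=T2
chrT\ttest\texon\t501\t600\t.\t+\t.\tParent=T2
chrT\ttest\texon\t701\t800\t.\t+\t.\tParent=T2
"""


def _iv(pairs):
    return tuple(Interval(a, b) for a, b in pairs)


@pytest.fixture
def toygene():
    """Two-transcript toy gene whose graph is four clean putative exons."""
    t1 = Transcript("T1", "TOYGENE1", "protein_coding", "+",
                    _iv([(101, 200), (301, 400), (501, 600), (701, 800)]))
    t2 = Transcript("T2", "TOYGENE1", "protein_coding", "+",
                    _iv([(101, 200), (501, 600), (701, 800)]))
    return Gene("TOYGENE1", "chrT", "+", [t1, t2])


@pytest.fixture
def toygraph(toygene):
    return build_splicegraph(orient_forward(toygene))


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


@pytest.fixture
def toy_gff3(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF3)
    return path


def query_tx(name, pairs, gene_id="TOYGENE1"):
    return Transcript(name, gene_id, "protein_coding", "+", _iv(pairs))
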