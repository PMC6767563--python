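import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecfmap.genome_io import (Contig, FormatError, GeneModel, PromoterEntry,
                              extract_upstream, read_fasta, read_gff,
                              read_promoter_table, reverse_complement,
                              write_fasta, write_gff, write_promoter_table)


# ---------------------------------------------------------------------------
# FASTA

def test_read_fasta_basic(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">c1\nACGT\n>c2\nacgtN\n")
    contigs = read_fasta(p)
    assert [(c.id, c.sequence) for c in contigs] == [("c1", "ACGT"), ("c2", "ACGTN")]


def test_read_fasta_errors(tmp_path):
    empty = tmp_path / "e.fa"
    empty.write_text("")
    with pytest.raises(FormatError):
        read_fasta(empty)
    dup = tmp_path / "d.fa"
    dup.write_text(">x\nAC\n>x\nGT\n")
    with pytest.raises(FormatError, match="x"):
        read_fasta(dup)
    amb = tmp_path / "a.fa"
    amb.write_text(">y\nACRT\n")
    with pytest.raises(FormatError):
        read_fasta(amb)
    assert read_fasta(amb, ambiguous="n")[0].sequence == "ACNT"


def test_fasta_round_trip(tmp_path):
    contigs = [Contig("a", "ACGTN" * 40), Contig("b", "GGCC")]
    write_fasta(contigs, tmp_path / "rt.fa")
    assert read_fasta(tmp_path / "rt.fa") == contigs


# ---------------------------------------------------------------------------
# GFF3

def test_read_gff_coordinates(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text("##gff-version 3\n"
                 "c1\tsrc\tgene\t101\t190\t.\t+\t.\tID=gplus\n"
                 "c1\tsrc\tgene\t101\t190\t.\t-\t.\tID=gminus\n"
                 "c1\tsrc\tCDS\t5\t10\t.\t+\t.\tID=sco0736\n")
    genes = read_gff(p)
    assert genes[0].span == (100, 190) and genes[0].start_codon_pos == 100
    assert genes[1].start_codon_pos == 189
    assert genes[2].gene_id == "sco0736"


def test_read_gff_errors(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text("c1\tsrc\tgene\t1\t50\t.\t+\t.\tName=noid\n")
    with pytest.raises(FormatError, match="ID"):
        read_gff(p)
    p.write_text("c1\tsrc\tgene\t1\t500\t.\t+\t.\tID=g1\n")
    with pytest.raises(FormatError, match="bounds"):
        read_gff(p, contigs=[Contig("c1", "A" * 100)])


def test_gff_round_trip(tmp_path):
    genes = [GeneModel("g1", "c1", "+", (10, 40)),
             GeneModel("g2", "c1", "-", (60, 90))]
    write_gff(genes, tmp_path / "rt.gff3")
    assert read_gff(tmp_path / "rt.gff3") == genes


# ---------------------------------------------------------------------------
# upstream windows

def _one_contig(n=2000, seed=1):
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return Contig("c", rng.choice(bases, size=n).tobytes().decode())


def test_extract_upstream_plus_strand():
    contig = _one_contig()
    gene = GeneModel("g", "c", "+", (1000, 1300))
    region = extract_upstream([contig], gene, 10, 200)
    assert region.genomic_interval == (800, 990)
    assert len(region) == 190
    assert region.sequence == contig.sequence[800:990]
    assert region.genomic(0) == 800
    assert region.distance_to_start(len(region) - 1) == 10


def test_extract_upstream_minus_strand():
    contig = _one_contig()
    gene = GeneModel("g", "c", "-", (700, 1001))  # start codon at 1000
    region = extract_upstream([contig], gene, 10, 200)
    assert region.genomic_interval == (1010, 1200)
    assert region.sequence == reverse_complement(contig.sequence[1010:1200])
    # region runs 5'->3' toward the start codon
    assert region.genomic(0) == 1199
    assert region.distance_to_start(0) == 199


def test_extract_upstream_clipping():
    contig = _one_contig()
    gene = GeneModel("g", "c", "+", (50, 350))  # start codon 50 bp from the edge
    region = extract_upstream([contig], gene, 10, 200)
    assert len(region) == 40
    assert region.genomic_interval == (0, 40)
    # entirely off-contig: empty region, not an exception
    gene2 = GeneModel("g2", "c", "+", (5, 305))
    assert extract_upstream([contig], gene2, 10, 200).is_empty


@settings(deadline=None, max_examples=30, derandomize=True)
@given(start=st.integers(400, 1500), strand=st.sampled_from("+-"),
       near=st.integers(0, 50), width=st.integers(1, 300))
def test_extract_upstream_length_property(start, strand, near, width):
    """Unclipped windows have length far - near on either strand."""
    contig = _one_contig(3000)
    span = (start, start + 100) if strand == "+" else (start - 100, start + 1)
    gene = GeneModel("g", "c", strand, span)
    region = extract_upstream([contig], gene, near, near + width)
    assert len(region) == width


# ---------------------------------------------------------------------------
# promoter tables

def test_packaged_fixture_invariants(table1_entries, validated_entries):
    assert len(table1_entries) == 91
    assert all(e.spacer_len in (16, 17) for e in table1_entries)
    long_spacers = sorted(e.target_id for e in validated_entries
                          if e.spacer_len == 17)
    assert long_spacers == ["sco3194", "sco4934"]
    classes = [e.promoter_class for e in validated_entries]
    assert (classes.count("I"), classes.count("II"), classes.count("III")) == (5, 10, 4)


@pytest.mark.parametrize("target_id, minus35, spacer_len, minus10, distance", [
    ("sco0736", "AACC", 16, "GGTCT", 70),
    ("sco1875", "AACG", 17, "CGTCC", 18),
    ("hrdD", "AACC", 16, "CGTCT", 375),
])
def test_fixture_rows_match_publication(table1_entries, target_id, minus35,
                                        spacer_len, minus10, distance):
    entry = next(e for e in table1_entries if e.target_id == target_id)
    assert entry.minus35 == minus35
    assert entry.spacer_len == spacer_len
    assert entry.minus10 == minus10
    assert entry.distance_bp == distance


def test_sco0736_spacer_sequence(table1_entries):
    entry = next(e for e in table1_entries if e.target_id == "sco0736")
    assert entry.spacer == "AAAGCCGCCGGACGGC"


def test_promoter_table_round_trip(tmp_path, validated_entries):
    path = tmp_path / "prom.tsv"
    write_promoter_table(validated_entries, path)
    assert read_promoter_table(path) == validated_entries


def test_promoter_table_rejects_bad_spacer(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("target_id\tminus35\tspacer\tminus10\tdistance_bp\t"
                    "validated\tpromoter_class\n"
                    "x\tAACC\tAAAA\tCGTCT\t50\tfalse\tunassigned\n")
    with pytest.raises(FormatError, match="row 0"):
        read_promoter_table(path)


def test_promoter_entry_invariants():
    with pytest.raises(FormatError):
        PromoterEntry("x", "AAC", "A" * 16, "CGTCT", 10)
    with pytest.raises(FormatError):
        PromoterEntry("x", "AACC", "A" * 16, "CGTCT", -1)
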