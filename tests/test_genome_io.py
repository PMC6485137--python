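import pytest

from genefam.errors import FormatError, ValidationError
from genefam.genome_io import (
    GeneModel,
    GenomeAnnotation,
    intron_count,
    read_fasta,
    read_gff3,
    write_fasta,
    write_gff3,
)


def test_read_fasta_single_record(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">a desc\nACGT\n")
    assert read_fasta(p) == {"a": "ACGT"}


def test_read_fasta_lowercase_uppercased_and_order_preserved(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">b\nacgt\n>a\nTTTT\n")
    out = read_fasta(p)
    assert list(out) == ["b", "a"]
    assert out["b"] == "ACGT"


def test_read_fasta_duplicate_id_errors(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">x\nAC\n>x\nGT\n")
    with pytest.raises(FormatError, match="x"):
        read_fasta(p)


def test_read_fasta_empty_errors(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text("")
    with pytest.raises(FormatError):
        read_fasta(p)


def test_fasta_round_trip_byte_identical(tmp_path, sim_genome):
    p1, p2 = tmp_path / "one.fa", tmp_path / "two.fa"
    write_fasta(p1, sim_genome.proteins)
    write_fasta(p2, read_fasta(p1))
    assert p1.read_bytes() == p2.read_bytes()


def _gff(tmp_path, body):
    p = tmp_path / "g.gff3"
    p.write_text("##gff-version 3\n" + body)
    return p


def _feature(chrom, ftype, start, end, attrs):
    return f"{chrom}\tsrc\t{ftype}\t{start}\t{end}\t.\t+\t.\t{attrs}\n"


def test_gff3_rank_by_start(tmp_path):
    body = ""
    for i, s in enumerate([100, 500, 900]):
        gid = f"g{i}"
        body += _feature("chr1", "gene", s, s + 50, f"ID={gid}")
        body += _feature("chr1", "mRNA", s, s + 50, f"ID={gid}.t;Parent={gid}")
        body += _feature("chr1", "exon", s, s + 50, f"Parent={gid}.t")
    ann = read_gff3(_gff(tmp_path, body))
    assert [ann.rank[f"g{i}"] for i in range(3)] == [("chr1", 0), ("chr1", 1), ("chr1", 2)]


def test_gff3_tie_breaks_shorter_gene_first(tmp_path):
    body = ""
    for gid, end in (("a", 300), ("b", 200)):
        body += _feature("chr1", "gene", 100, end, f"ID={gid}")
        body += _feature("chr1", "mRNA", 100, end, f"ID={gid}.t;Parent={gid}")
        body += _feature("chr1", "exon", 100, end, f"Parent={gid}.t")
    ann = read_gff3(_gff(tmp_path, body))
    assert ann.rank["b"] == ("chr1", 0)
    assert ann.rank["a"] == ("chr1", 1)


def test_gff3_exon_outside_gene_span_errors(tmp_path):
    body = _feature("chr1", "gene", 100, 200, "ID=g")
    body += _feature("chr1", "mRNA", 100, 200, "ID=g.t;Parent=g")
    body += _feature("chr1", "exon", 100, 300, "Parent=g.t")
    with pytest.raises(FormatError, match="outside"):
        read_gff3(_gff(tmp_path, body))


def test_gff3_missing_parent_errors(tmp_path):
    body = _feature("chr1", "gene", 100, 200, "ID=g")
    body += _feature("chr1", "exon", 100, 200, "Parent=ghost")
    with pytest.raises(FormatError, match="ghost"):
        read_gff3(_gff(tmp_path, body))


def test_gff3_longest_cds_isoform_kept(tmp_path):
    body = _feature("chr1", "gene", 100, 400, "ID=g")
    body += _feature("chr1", "mRNA", 100, 400, "ID=g.t1;Parent=g")
    body += _feature("chr1", "exon", 100, 150, "Parent=g.t1")
    body += _feature("chr1", "CDS", 100, 150, "Parent=g.t1")
    body += _feature("chr1", "mRNA", 100, 400, "ID=g.t2;Parent=g")
    body += _feature("chr1", "exon", 100, 200, "Parent=g.t2")
    body += _feature("chr1", "exon", 300, 400, "Parent=g.t2")
    body += _feature("chr1", "CDS", 100, 200, "Parent=g.t2")
    body += _feature("chr1", "CDS", 300, 400, "Parent=g.t2")
    ann = read_gff3(_gff(tmp_path, body))
    assert ann.get("g").exons == [(100, 200), (300, 400)]


@pytest.mark.parametrize(
    "n_exons,expected", [(1, 0), (13, 12)], ids=["intronless", "max-introns"]
)
def test_intron_count(n_exons, expected):
    exons = [(1 + 100 * i, 50 + 100 * i) for i in range(n_exons)]
    g = GeneModel("g", "chr1", "+", 1, exons[-1][1], exons=exons)
    assert intron_count(g) == expected


def test_intron_count_without_exons_errors():
    g = GeneModel("g", "chr1", "+", 1, 10)
    with pytest.raises(ValidationError):
        intron_count(g)


def test_intron_count_matches_exon_count_on_simulated_genes(sim_genome):
    for g in sim_genome.annotation.genes[:50]:
        assert intron_count(g) == len(g.exons) - 1


def test_rank_index_is_bijection_per_chromosome(sim_genome):
    ann = sim_genome.annotation
    for chrom in ann.chromosomes():
        genes = ann.chromosome_genes(chrom)
        ranks = [ann.rank[g][1] for g in genes]
        assert ranks == list(range(len(genes)))


def test_gff3_round_trip_preserves_gene_models(tmp_path, sim_genome):
    p = tmp_path / "sim.gff3"
    write_gff3(p, sim_genome.annotation)
    back = read_gff3(p)
    assert len(back) == len(sim_genome.annotation)
    for g in sim_genome.annotation.genes:
        h = back.get(g.gene_id)
        assert (h.chromosome, h.start, h.end, h.exons) == (
            g.chromosome,
            g.start,
            g.end,
            g.exons,
        )
    assert back.rank == sim_genome.annotation.rank


def test_duplicate_gene_ids_rejected():
    g = GeneModel("g", "chr1", "+", 1, 10, exons=[(1, 10)])
    with pytest.raises(ValidationError):
        GenomeAnnotation([g, GeneModel("g", "chr2", "-", 5, 20, exons=[(5, 20)])])
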