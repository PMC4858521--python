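"""Gene-table parsing, GFF round trips and neighborhood semantics."""

import numpy as np
import pytest
from helpers import make_genome

from t4pcensus import synthetic as syn
from t4pcensus.genome_io import (
    TSV_COLUMNS,
    GeneTableFormatError,
    GeneTableValidationError,
    UnknownGeneError,
    neighborhood,
    read_gene_table,
    read_gff_fasta,
    write_gene_table,
    write_gff_fasta,
)


def _tsv(rows):
    lines = ["\t".join(TSV_COLUMNS)]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    return "\n".join(lines) + "\n"


def _row(genome="gA", contig="c1", idx=0, gid="g0", strand="+", start="", end="",
         fam="", product="", seq=""):
    return [genome, "Euryarchaeota", contig, idx, gid, strand, start, end, fam, product, seq]


class TestGeneTableTSV:
    def test_minimal_two_row_file(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(_tsv([_row(gid="g0", idx=0), _row(gid="g1", idx=1)]))
        tables = read_gene_table(path)
        assert len(tables) == 1
        recs = tables[0].contigs["c1"]
        assert [r.order_index for r in recs] == [0, 1]
        assert tables[0].lineage == ["Euryarchaeota"]

    def test_bad_strand_cites_line(self, tmp_path):
        rows = [_row(gid=f"g{i}", idx=i) for i in range(6)]
        rows[5] = _row(gid="g5", idx=5, strand="x")  # file line 7 (after header)
        path = tmp_path / "genes.tsv"
        path.write_text(_tsv(rows))
        with pytest.raises(GeneTableValidationError, match="line 7"):
            read_gene_table(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("genome_id\tgene_id\nx\ty\n")
        with pytest.raises(GeneTableFormatError, match="missing columns"):
            read_gene_table(path)

    def test_duplicate_gene_id_names_the_id(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(_tsv([_row(gid="dup", idx=0), _row(gid="dup", idx=1)]))
        with pytest.raises(GeneTableValidationError, match="dup"):
            read_gene_table(path)

    def test_coordinates_must_come_in_pairs(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(_tsv([_row(start="10")]))
        with pytest.raises(GeneTableValidationError):
            read_gene_table(path)

    def test_generated_collection_round_trips(self, tmp_path):
        params = syn.GeneratorParams(
            n_genomes=20,
            architecture_plan={"archaellum": 6, "sub4D": 5, "clade2_B": 5},
            rng_seed=5,
        )
        tables, _, _ = syn.generate_collection(params)
        path = tmp_path / "genes.tsv"
        write_gene_table(tables, path)
        back = {t.genome_id: t for t in read_gene_table(path)}
        assert len(back) == 20
        for table in tables:
            other = back[table.genome_id]
            assert other.lineage == table.lineage
            for contig, recs in table.contigs.items():
                assert [vars(r) for r in recs] == [vars(r) for r in other.contigs[contig]]


class TestGFF:
    def test_order_index_follows_start_coordinate(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\tsrc\tCDS\t100\t400\t.\t+\t0\tID=a;family=F1\n"
            "c1\tsrc\tCDS\t900\t1200\t.\t-\t0\tID=b\n"
            "c1\tsrc\tCDS\t50\t80\t.\t+\t0\tID=c;family=F2\n"
        )
        fasta = tmp_path / "p.faa"
        fasta.write_text(">a\nMKEL\n")
        table = read_gff_fasta(gff, fasta)
        by_id = {r.gene_id: r for r in table.genes()}
        assert (by_id["a"].order_index, by_id["b"].order_index, by_id["c"].order_index) == (1, 2, 0)
        assert by_id["a"].family_id == "F1"
        assert by_id["a"].protein_seq == "MKEL"
        assert by_id["b"].protein_seq is None

    def test_empty_fasta_leaves_proteins_absent(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\nc1\tsrc\tCDS\t1\t30\t.\t+\t0\tID=a\n"
            "c1\tsrc\tCDS\t100\t130\t.\t+\t0\tID=b\n"
        )
        fasta = tmp_path / "p.faa"
        fasta.write_text("")
        table = read_gff_fasta(gff, fasta)
        assert all(r.protein_seq is None for r in table.genes())

    def test_orphan_fasta_id_warns_and_drops(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\nc1\tsrc\tCDS\t1\t30\t.\t+\t0\tID=a\n")
        fasta = tmp_path / "p.faa"
        fasta.write_text(">a\nMK\n>ghost\nMM\n")
        with pytest.warns(UserWarning, match="absent from GFF"):
            table = read_gff_fasta(gff, fasta)
        assert table.get("a").protein_seq == "MK"

    def test_generator_emitted_pair_round_trips(self, tmp_path):
        params = syn.GeneratorParams(
            n_genomes=5, architecture_plan={"archaellum": 5}, rng_seed=2
        )
        tables, _, _ = syn.generate_collection(params)
        table = tables[0]
        write_gff_fasta(table, tmp_path / "g.gff3", tmp_path / "p.faa")
        back = read_gff_fasta(
            tmp_path / "g.gff3", tmp_path / "p.faa",
            genome_id=table.genome_id, lineage=table.lineage,
        )
        assert [vars(r) for r in back.contigs["c1"]] == [vars(r) for r in table.contigs["c1"]]


class TestNeighborhood:
    def test_window3_interior_returns_seven(self):
        g = make_genome("gA", [f"F{i}" for i in range(20)])
        recs = neighborhood(g, "gA_g5", window=3)
        assert [r.order_index for r in recs] == [2, 3, 4, 5, 6, 7, 8]

    def test_truncated_at_contig_start(self):
        g = make_genome("gA", [f"F{i}" for i in range(20)])
        recs = neighborhood(g, "gA_g0", window=3)
        assert [r.order_index for r in recs] == [0, 1, 2, 3]

    def test_window_zero_is_identity(self):
        g = make_genome("gA", ["F0", "F1"])
        assert [r.gene_id for r in neighborhood(g, "gA_g1", 0)] == ["gA_g1"]

    def test_unknown_gene_raises(self):
        g = make_genome("gA", ["F0"])
        with pytest.raises(UnknownGeneError):
            neighborhood(g, "nope", 1)

    def test_never_crosses_contigs(self):
        g = make_genome("gA", ["F0", "F1"], contig_id="c1")
        other = make_genome("gA", ["F2"], contig_id="c2").contigs["c2"]
        other[0].gene_id = "gA_x0"
        g.contigs["c2"] = other
        g.reindex()
        recs = neighborhood(g, "gA_g1", window=5)
        assert {r.contig_id for r in recs} == {"c1"}

    @pytest.mark.parametrize("focal", [0, 3, 7, 11])
    @pytest.mark.parametrize("window", [0, 1, 3, 6])
    def test_reversal_symmetry_and_size_bound(self, focal, window):
        n = 12
        fams = [f"F{i}" for i in range(n)]
        g = make_genome("gA", fams)
        fwd = {r.gene_id for r in neighborhood(g, f"gA_g{focal}", window)}
        assert len(fwd) <= 2 * window + 1
        expect_full = window <= focal <= n - 1 - window
        assert (len(fwd) == 2 * window + 1) == expect_full
        # reverse the gene order; the same gene ids must be returned
        rev = make_genome("gA", list(reversed(fams)))
        for rec, name in zip(rev.contigs["c1"], reversed([f"gA_g{i}" for i in range(n)])):
            rec.gene_id = name
        rev.reindex()
        bwd = {r.gene_id for r in neighborhood(rev, f"gA_g{focal}", window)}
        assert fwd == bwd
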