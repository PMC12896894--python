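"""Round-trips and gene-model bookkeeping for the I/O layer."""

import numpy as np
import pytest

from xylpscan.core_io import (
    GeneLocus, Msa, ProteinRecord, gene_structure_summary, read_fasta,
    read_gene_loci, read_newick, read_table, write_fasta, write_newick,
    write_table,
)
from xylpscan.evolution import DistanceMatrix, nj_tree, tree_bipartitions
from xylpscan.datasets import load_reference_properties
from xylpscan.synthetic_data import gen_genome_layout


class TestFasta:
    def test_single_record_normalization(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">p1 some desc\nmkv*\n")
        (rec,) = read_fasta(p)
        assert rec.id == "p1"
        assert rec.sequence == "MKV"
        assert rec.description == "some desc"

    def test_duplicate_id_error_names_id(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">p1\nMK\n>p1\nMV\n")
        with pytest.raises(ValueError, match="p1"):
            read_fasta(p)

    def test_empty_file_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_round_trip(self, tmp_path):
        recs = [ProteinRecord("a", "MKVLA", "x"), ProteinRecord("b", "PPAST"),
                ProteinRecord("c", "WYC")]
        p = tmp_path / "rt.fa"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert back == recs

    def test_gap_characters_rejected(self):
        with pytest.raises(ValueError):
            ProteinRecord("g", "MK-V")


_GFF = """##gff-version 3
chr1\tsrc\tgene\t100\t400\t.\t+\t.\tID=gA
chr1\tsrc\texon\t100\t400\t.\t+\t.\tID=gA.e1;Parent=gA
chr1\tsrc\tgene\t500\t900\t.\t-\t.\tID=gB
chr1\tsrc\texon\t500\t600\t.\t-\t.\tID=gB.e1;Parent=gB
chr1\tsrc\texon\t700\t900\t.\t-\t.\tID=gB.e2;Parent=gB
"""


class TestGeneLoci:
    def test_rank_by_start_and_strand_preserved(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(_GFF)
        loci = {l.gene_id: l for l in read_gene_loci(p)}
        assert loci["gA"].rank == 1 and loci["gB"].rank == 2
        assert loci["gB"].strand == "-"
        assert loci["gB"].exon_intervals == ((500, 600), (700, 900))

    def test_exon_outside_gene_span_error(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\ts\tgene\t100\t200\t.\t+\t.\tID=g\n"
            "chr1\ts\texon\t100\t300\t.\t+\t.\tID=g.e;Parent=g\n"
        )
        with pytest.raises(ValueError, match="outside"):
            read_gene_loci(p)

    def test_unknown_strand_error(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\nchr1\ts\tgene\t100\t200\t.\t?\t.\tID=g\n"
        )
        with pytest.raises(ValueError, match="strand"):
            read_gene_loci(p)

    def test_generator_ranks_match_planted(self, tmp_path):
        layout = gen_genome_layout(11)
        p = tmp_path / "layout.gff3"
        p.write_text(layout.gff_text())
        got = {l.gene_id: l.rank for l in read_gene_loci(p)}
        for locus in layout.loci:
            assert got[locus.gene_id] == locus.rank

    def test_ranks_are_permutation_per_chromosome(self, tmp_path):
        layout = gen_genome_layout(3, n_chrom=3, genes_per_chrom=12,
                                   n_collinear_blocks=1, n_dispersed=1,
                                   n_tandem=2)
        p = tmp_path / "layout.gff3"
        p.write_text(layout.gff_text())
        by_chrom = {}
        for l in read_gene_loci(p):
            by_chrom.setdefault(l.chromosome, []).append(l.rank)
        for ranks in by_chrom.values():
            assert sorted(ranks) == list(range(1, len(ranks) + 1))


@pytest.mark.parametrize("n_exons,expected", [(1, (1, 0)), (3, (3, 2)), (4, (4, 3))])
def test_gene_structure_summary(n_exons, expected):
    exons = tuple((100 * i + 1, 100 * i + 50) for i in range(n_exons))
    locus = GeneLocus("g", "chr1", 1, 100 * n_exons, "+", 1, exons)
    assert gene_structure_summary(locus) == expected


def test_gene_structure_zero_exons_error():
    locus = GeneLocus("g", "chr1", 1, 100, "+", 1, ())
    with pytest.raises(ValueError):
        gene_structure_summary(locus)


class TestNewick:
    def _random_tree(self, seed, n=5):
        rng = np.random.default_rng(seed)
        taxa = tuple(f"t{i}" for i in range(n))
        # random distances; NJ yields a well-formed tree to round-trip
        m = rng.uniform(1.0, 5.0, size=(n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        return nj_tree(DistanceMatrix(taxa, d))

    def test_cherry_serialization(self, tmp_path):
        tree = nj_tree(DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 2.0, 3.0], [2.0, 0, 3.0], [3.0, 3.0, 0]]),
        ))
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        text = p.read_text()
        assert "A:" in text and text.strip().endswith(";")

    def test_round_trip_topology_and_lengths(self, tmp_path):
        tree = self._random_tree(7)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert tree_bipartitions(back) == tree_bipartitions(tree)
        lengths = sorted(e.length for e in tree.edges() if e.length is not None)
        lengths_back = sorted(e.length for e in back.edges()
                              if e.length is not None)
        assert np.allclose(lengths, lengths_back, atol=1e-9)

    def test_support_labels_survive_round_trip(self, tmp_path):
        tree = self._random_tree(9)
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node.parent_node is not None:
                node.label = "87"
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        labels = [n.label for n in back.preorder_node_iter()
                  if not n.is_leaf() and n.parent_node is not None]
        assert labels and all(l == "87" for l in labels)


class TestTables:
    def test_ct_table_types(self, tmp_path):
        p = tmp_path / "ct.tsv"
        p.write_text("gene\tsample\treplicate\tct\ng1\ts1\t1\t24.5\n")
        df = read_table(p, {"gene": str, "ct": float})
        assert df["ct"].iloc[0] == pytest.approx(24.5)

    def test_missing_column_error_names_column(self, tmp_path):
        p = tmp_path / "ct.tsv"
        p.write_text("gene\tsample\n g1\ts1\n")
        with pytest.raises(ValueError, match="ct"):
            read_table(p, {"ct": float})

    def test_reference_property_table_shape(self):
        df = load_reference_properties()
        assert df.shape == (28, 11)

    def test_motif_dictionary_round_trip(self, tmp_path):
        from xylpscan.promoter_scan import default_motif_dictionary
        import pandas as pd
        motifs = default_motif_dictionary()
        df = pd.DataFrame([m.__dict__ for m in motifs])
        p = tmp_path / "m.tsv"
        write_table(df, p)
        back = read_table(p, {"name": str, "pattern": str})
        assert list(back["name"]) == [m.name for m in motifs]
        assert list(back["pattern"]) == [m.pattern for m in motifs]


def test_msa_invariants():
    with pytest.raises(ValueError):
        Msa(("a", "b"), ("ACGT", "ACG"))
    with pytest.raises(ValueError):
        Msa(("a", "a"), ("ACGT", "ACGT"))
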