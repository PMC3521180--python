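"""Strict parsing and write/read round-trip identity for every format."""

import numpy as np
import pytest

from conftest import random_matrix
from seednet import formats_io as fio
from seednet.chip_validation import ChipRegion, ChipRegionSet
from seednet.conservation import SPECIES
from seednet.network_build import DIRECT, EXPANDED, RegulatoryNetwork
from seednet.tissue_networks import ExpressionTable


class TestMatrixLibrary:
    def write(self, tmp_path, text):
        p = tmp_path / "lib.txt"
        p.write_text(text)
        return p

    def test_counts_normalised_to_frequencies(self, tmp_path):
        p = self.write(
            tmp_path,
            "ID M$T\nP0 A C G T\n01 8 0 0 0\n02 0 8 0 0\n//\n",
        )
        lib = fio.read_matrix_library(p)
        m = lib["M$T"]
        assert len(m) == 2
        assert m.freq[0].tolist() == [1.0, 0.0, 0.0, 0.0]
        assert m.freq[1].tolist() == [0.0, 1.0, 0.0, 0.0]

    def test_gene_symbols_and_threshold(self, tmp_path):
        p = self.write(
            tmp_path,
            "ID M$T\nBF GA; GB\nP0 A C G T\n01 1 1 1 1\nTH 0.85\n//\n",
        )
        m = fio.read_matrix_library(p)["M$T"]
        assert m.tf_genes == ("GA", "GB")
        assert m.min_fn == 0.85

    def test_duplicate_id_rejected(self, tmp_path):
        body = "ID M$T\nP0 A C G T\n01 1 1 1 1\n//\n"
        with pytest.raises(fio.ParseError, match="duplicate"):
            fio.read_matrix_library(self.write(tmp_path, body * 2))

    def test_all_zero_row_rejected(self, tmp_path):
        p = self.write(
            tmp_path, "ID M$T\nP0 A C G T\n01 0 0 0 0\n//\n"
        )
        with pytest.raises(fio.ParseError, match="all-zero"):
            fio.read_matrix_library(p)

    def test_malformed_count_names_line(self, tmp_path):
        p = self.write(
            tmp_path, "ID M$T\nP0 A C G T\n01 1 x 1 1\n//\n"
        )
        with pytest.raises(fio.ParseError, match="line 3"):
            fio.read_matrix_library(p)

    def test_round_trip_preserves_frequencies(self, tmp_path, rng):
        matrices = {}
        for i in range(4):
            m = random_matrix(rng, mid=f"M$RT_{i}", genes=(f"TF{i}",))
            m.min_fn = float(rng.uniform(0.5, 0.99))
            matrices[m.id] = m
        lib = fio.MatrixLibrary(matrices)
        path = tmp_path / "lib.txt"
        fio.write_matrix_library(lib, path)
        back = fio.read_matrix_library(path)
        assert back.ids == lib.ids
        for m in lib:
            b = back[m.id]
            np.testing.assert_allclose(b.freq, m.freq, atol=1e-12)
            assert b.min_fn == pytest.approx(m.min_fn, abs=1e-15)
            assert b.tf_genes == m.tf_genes

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            fio.MatrixLibrary({})


class TestAlignments:
    def test_four_row_gapless_block(self, tmp_path):
        fasta = "".join(
            f">P1|{sp}\nACGTACGTAC\n" for sp in SPECIES
        )
        p = tmp_path / "aln.fasta"
        p.write_text(fasta)
        alns = fio.read_alignments(p)
        assert len(alns["P1"].stripped("human")) == 10

    def test_missing_species_rejected(self, tmp_path):
        fasta = "".join(f">P1|{sp}\nACGT\n" for sp in SPECIES[:3])
        p = tmp_path / "aln.fasta"
        p.write_text(fasta)
        with pytest.raises(fio.ParseError, match="missing species"):
            fio.read_alignments(p)

    def test_all_gap_human_row_rejected(self, tmp_path):
        rows = {"human": "----", "mouse": "ACGT", "dog": "ACGT",
                "cow": "ACGT"}
        fasta = "".join(f">P1|{sp}\n{rows[sp]}\n" for sp in SPECIES)
        p = tmp_path / "aln.fasta"
        p.write_text(fasta)
        with pytest.raises(ValueError, match="gaps"):
            fio.read_alignments(p)

    def test_round_trip(self, tmp_path, default_dataset):
        path = tmp_path / "aln.fasta"
        fio.write_alignments(default_dataset.alignments, path)
        back = fio.read_alignments(path)
        assert set(back) == set(default_dataset.alignments)
        for pid, aln in default_dataset.alignments.items():
            assert back[pid].rows == aln.rows


class TestBed:
    def test_single_region(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tTFX\n")
        regs = fio.read_bed(p)
        assert len(regs) == 1
        assert len(regs.regions[0]) == 100

    def test_empty_file_is_empty_set(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert len(fio.read_bed(p)) == 0

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(fio.ParseError, match="end"):
            fio.read_bed(p)

    def test_round_trip(self, tmp_path):
        regs = ChipRegionSet(
            [ChipRegion("chr1", 0, 50, "a"), ChipRegion("chr2", 5, 9, "b")],
            name="x",
        )
        path = tmp_path / "x.bed"
        fio.write_bed(regs, path)
        back = fio.read_bed(path, name="x")
        assert back.regions == regs.regions


class TestNetworkTsv:
    def test_three_edge_round_trip(self, tmp_path):
        net = RegulatoryNetwork()
        net.add_edge("A", "g1", provenance=DIRECT, matrices=["M$1"],
                     n_sites=2)
        net.add_edge("A", "g2", provenance=EXPANDED, matrices=["M$1"],
                     n_sites=0)
        net.add_edge("B", "g1", provenance=DIRECT,
                     matrices=["M$2", "M$3"], n_sites=1)
        net.add_node("iso", "nonTF")
        path = tmp_path / "net.tsv"
        fio.write_edges_tsv(net, path)
        back = fio.read_network(path)
        assert back == net

    def test_bad_provenance_rejected(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("tf\ttarget\tprovenance\tmatrices\tn_sites\n"
                     "A\tB\tguessed\t\t1\n")
        with pytest.raises(fio.ParseError, match="provenance"):
            fio.read_network(p)


class TestAnnotation:
    def test_round_trip(self, tmp_path, toy_annotation):
        path = tmp_path / "ann.tsv"
        fio.write_annotation(toy_annotation, path)
        back = fio.read_annotation(path)
        assert back.promoters == toy_annotation.promoters
        assert back.gene_class == toy_annotation.gene_class

    def test_duplicate_promoter_rejected(self, tmp_path, toy_annotation):
        path = tmp_path / "ann.tsv"
        fio.write_annotation(toy_annotation, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines + [lines[1]]) + "\n")
        with pytest.raises(fio.ParseError, match="duplicate"):
            fio.read_annotation(path)


class TestExpression:
    def test_round_trip(self, tmp_path):
        table = ExpressionTable(
            ("brain", "heart"),
            {"brain": {"g1", "g2"}, "heart": {"g2"}},
        )
        path = tmp_path / "expr.tsv"
        fio.write_expression(table, path)
        back = fio.read_expression(path)
        assert back.tissues == table.tissues
        assert back.expressed == table.expressed

    def test_non_binary_values_rejected(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tbrain\ng1\t2\n")
        with pytest.raises(fio.ParseError, match="0/1"):
            fio.read_expression(p)


class TestSiteTables:
    def test_sites_round_trip(self, tmp_path, default_dataset, rng):
        from seednet.pipeline import scan_alignments

        scanned = scan_alignments(
            default_dataset.library, default_dataset.alignments
        )
        sites = [s for per in list(scanned.values())[:5]
                 for s in per["human"]]
        path = tmp_path / "sites.tsv"
        fio.write_sites_tsv(sites, path)
        assert fio.read_sites_tsv(path) == sites

    def test_conserved_round_trip(self, tmp_path, default_dataset):
        from seednet.pipeline import conserve_alignments, scan_alignments

        ds = default_dataset
        scanned = scan_alignments(ds.library, ds.alignments)
        cons = conserve_alignments(ds.alignments, scanned)[:20]
        path = tmp_path / "cons.tsv"
        fio.write_conserved_tsv(cons, path)
        back = fio.read_conserved_tsv(path)
        for a, b in zip(cons, back):
            assert a.human_site == b.human_site
            assert (a.start_col, a.end_col) == (b.start_col, b.end_col)
            assert set(a.support) == set(b.support)
            for sp in a.support:
                assert a.support[sp].start == b.support[sp].start

    def test_sites_bed_promoter_space(self, tmp_path, default_dataset):
        from seednet.pipeline import scan_alignments

        scanned = scan_alignments(
            default_dataset.library, default_dataset.alignments
        )
        pid = next(iter(scanned))
        sites = scanned[pid]["human"][:3]
        path = tmp_path / "sites.bed"
        fio.write_sites_bed(sites, path)
        lines = path.read_text().splitlines()
        assert len(lines) == len(sites)
        chrom, start, end, name = lines[0].split("\t")
        assert chrom == pid
        assert int(end) - int(start) == sites[0].length


class TestClassificationJson:
    def test_round_trip(self, tmp_path, default_dataset):
        path = tmp_path / "cls.json"
        fio.write_classification(default_dataset.classification, path)
        back = fio.read_classification(path)
        assert back.clades == default_dataset.classification.clades
        assert back.matrix_assoc == default_dataset.classification.matrix_assoc
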