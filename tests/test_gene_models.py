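"""Intron inference/classification, UTR summaries, censuses, tandem arrays."""
import logging

import numpy as np
import pytest

from zfp import gene_models as gm


def _gene(gene_id="g", strand="+", exons=(), cds=(), region="chr1", rank=1):
    return gm.GeneModel(gene_id, region, strand, tuple(exons), tuple(cds), rank)


class TestGeneModel:
    def test_rejects_overlapping_exons(self):
        with pytest.raises(ValueError, match="exons"):
            _gene(exons=[(1, 100), (50, 200)], cds=[(10, 90)])

    def test_rejects_cds_outside_exons(self):
        with pytest.raises(ValueError, match="outside exons"):
            _gene(exons=[(1, 100)], cds=[(50, 150)])


class TestInferIntrons:
    def test_five_prime_utr_intron_plus_strand(self):
        gene = _gene(exons=[(1, 100), (201, 300)], cds=[(250, 300)])
        (rec,) = gm.infer_introns(gene)
        assert (rec.start, rec.end, rec.length) == (101, 200, 100)
        assert rec.intron_class == gm.FIVE_UTR

    def test_five_prime_utr_intron_minus_strand_mirror(self):
        gene = _gene(strand="-", exons=[(1, 100), (201, 300)], cds=[(1, 51)])
        (rec,) = gm.infer_introns(gene)
        assert rec.intron_class == gm.FIVE_UTR

    def test_three_prime_and_cds_classes(self):
        gene = _gene(
            exons=[(1, 100), (151, 250), (301, 400)],
            cds=[(50, 100), (151, 200)],
        )
        recs = gm.infer_introns(gene)
        assert [r.intron_class for r in recs] == [gm.CDS_CLASS, gm.THREE_UTR]

    def test_single_exon_gene_is_intronless(self):
        assert gm.infer_introns(_gene(exons=[(1, 500)], cds=[(100, 400)])) == []

    def test_every_intron_gets_exactly_one_class(self):
        rng = np.random.default_rng(0)
        classes = {gm.FIVE_UTR, gm.CDS_CLASS, gm.THREE_UTR, gm.JUNCTION}
        for _ in range(50):
            n_exons = int(rng.integers(2, 6))
            exons, cursor = [], 1
            for _ in range(n_exons):
                length = int(rng.integers(50, 200))
                exons.append((cursor, cursor + length - 1))
                cursor += length + int(rng.integers(50, 300))
            k = int(rng.integers(0, n_exons))
            cs, ce = exons[k]
            cds = [(cs + 5, ce - 5)]
            gene = _gene(
                strand="+" if rng.random() < 0.5 else "-", exons=exons, cds=cds
            )
            recs = gm.infer_introns(gene)
            assert len(recs) == n_exons - 1
            assert all(r.intron_class in classes for r in recs)

    def test_strand_reflection_preserves_class_multiset(self):
        """Mirroring all coordinates and flipping strand must not change
        the intron class multiset."""
        rng = np.random.default_rng(1)
        for _ in range(30):
            exons, cursor = [], 1
            for _ in range(int(rng.integers(2, 5))):
                length = int(rng.integers(30, 150))
                exons.append((cursor, cursor + length - 1))
                cursor += length + int(rng.integers(40, 200))
            k = int(rng.integers(0, len(exons)))
            cs, ce = exons[k]
            gene = _gene(exons=exons, cds=[(cs, ce)])
            total = exons[-1][1] + 10

            def mirror(iv):
                return (total + 1 - iv[1], total + 1 - iv[0])

            flipped = _gene(
                strand="-",
                exons=sorted(mirror(e) for e in gene.exons),
                cds=sorted(mirror(c) for c in gene.cds),
            )
            fwd = sorted(r.intron_class for r in gm.infer_introns(gene))
            rev = sorted(r.intron_class for r in gm.infer_introns(flipped))
            assert fwd == rev

    def test_exons_plus_introns_tile_gene_span(self):
        gene = _gene(exons=[(10, 100), (151, 250), (301, 400)], cds=[(160, 240)])
        pieces = [(s, e) for s, e in gene.exons]
        pieces += [(r.start, r.end) for r in gm.infer_introns(gene)]
        pieces.sort()
        assert pieces[0][0] == 10 and pieces[-1][1] == 400
        for (_, e1), (s2, _) in zip(pieces, pieces[1:]):
            assert s2 == e1 + 1


class TestUtrCounts:
    def test_counting_rules(self):
        rows = [
            ("g1", "sp", (gm.FIVE_UTR,)),
            ("g2", "sp", (gm.FIVE_UTR, gm.THREE_UTR)),
            ("g3", "sp", ()),
            ("g4", "sp", (gm.CDS_CLASS,)),
        ]
        frame = gm.count_utr_intron_genes(rows)
        row = frame.loc["sp"]
        assert row["any_utr"] == 2
        assert row["five_utr"] == 2
        assert row["three_utr"] == 1
        assert row["both_utr"] == 1
        assert row["intronless"] == 1

    def test_duplicate_gene_errors(self):
        rows = [("g1", "sp", ()), ("g1", "sp", ())]
        with pytest.raises(ValueError, match="duplicate"):
            gm.count_utr_intron_genes(rows)

    def test_empty_table_all_zero(self):
        frame = gm.count_utr_intron_genes([])
        assert frame.empty


class TestTable2Fixture:
    def test_roundtrip_is_byte_identical(self, tmp_path):
        frame = gm.load_table2()
        out = tmp_path / "table2.tsv"
        gm.write_table2(frame, out)
        with gm.resources.as_file(gm._table2_path()) as orig:
            assert out.read_bytes() == orig.read_bytes()

    def test_reference_utr_summary_counts(self):
        frame = gm.load_table2()
        counts = gm.count_utr_intron_genes(gm.table2_gene_rows(frame))
        ath = counts.loc["A. thaliana"]
        osa = counts.loc["O. sativa"]
        assert ath["any_utr"] == 9 and ath["five_utr"] == 8
        assert ath["three_utr"] == 1
        assert osa["any_utr"] == 12 and osa["five_utr"] == 9
        assert osa["three_utr"] == 5 and osa["both_utr"] == 2

    def test_length_multiplicity_expands_to_multiple_introns(self):
        frame = gm.load_table2()
        rows = {gid: classes for gid, _, classes in gm.table2_gene_rows(frame)}
        assert rows["osa|LOC_Os05g40980"] == (gm.FIVE_UTR, gm.FIVE_UTR)
        assert rows["osa|LOC_Os11g02670"] == (
            gm.FIVE_UTR, gm.THREE_UTR, gm.THREE_UTR,
        )


class TestTandemArrays:
    def _genes(self, ranks_and_ids, region="chr1"):
        out = []
        for rank, gid in ranks_and_ids:
            start = rank * 1000
            out.append(
                _gene(gid, exons=[(start, start + 99)], cds=[(start, start + 99)],
                      region=region, rank=rank)
            )
        return out

    def test_gap_of_one_allows_array(self):
        genes = self._genes([(10, "f1"), (11, "x"), (12, "f2")])
        arrays = gm.detect_tandem_arrays(genes, {"f1", "f2"}, max_gap=1)
        assert [a.members for a in arrays] == [("f1", "f2")]

    def test_gap_zero_blocks_array(self):
        genes = self._genes([(10, "f1"), (11, "x"), (12, "f2")])
        assert gm.detect_tandem_arrays(genes, {"f1", "f2"}, max_gap=0) == []

    def test_three_adjacent_form_one_array(self):
        genes = self._genes([(5, "f1"), (6, "f2"), (7, "f3")])
        arrays = gm.detect_tandem_arrays(genes, {"f1", "f2", "f3"}, max_gap=0)
        assert [a.members for a in arrays] == [("f1", "f2", "f3")]
        assert arrays[0].size == 3

    def test_missing_family_id_warns(self, caplog):
        genes = self._genes([(1, "f1"), (2, "f2")])
        with caplog.at_level(logging.WARNING):
            arrays = gm.detect_tandem_arrays(genes, {"f1", "f2", "ghost"})
        assert "ghost" in caplog.text
        assert len(arrays) == 1


class TestCensus:
    def test_min_max_formatting(self):
        intronless = _gene("a", exons=[(1, 300)], cds=[(1, 300)])
        two_introns = _gene(
            "b",
            exons=[(1, 100), (201, 300), (401, 500)],
            cds=[(10, 100), (201, 300), (401, 450)],
        )
        exons, cursor = [], 1
        for _ in range(9):
            exons.append((cursor, cursor + 49))
            cursor += 150
        gene8 = _gene("c", exons=exons, cds=[(e[0], e[1]) for e in exons])
        census = gm.cds_intron_census(
            {"mix": [intronless, two_introns], "flat": [intronless],
             "single": [gene8]}
        )
        assert census["mix"] == "0-2"
        assert census["flat"] == "0"
        assert census["single"] == "8"


class TestGff3(object):
    def test_simulated_gff_parses_and_ranks(self, sim_dir):
        genes = gm.read_gff3(sim_dir.paths["gff"])
        # family genes plus non-family filler genes are all parsed
        assert set(sim_dir.truth["genes"]) <= {g.gene_id for g in genes}
        by_region = {}
        for g in genes:
            by_region.setdefault(g.seq_region, []).append(g)
        for region, gs in by_region.items():
            ranks = sorted(g.rank for g in gs)
            assert ranks == list(range(1, len(gs) + 1))

    def test_junction_class_never_appears_on_wellformed_models(self, sim_dir):
        genes = gm.read_gff3(sim_dir.paths["gff"])
        for g in genes:
            for rec in gm.infer_introns(g):
                assert rec.intron_class != gm.JUNCTION
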