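"""FDR filtering, codon-level genome mapping, classification, corroboration."""

import numpy as np
import pytest

from ambercode.evidence import (
    PSM,
    DeNovoTag,
    MappingError,
    SchemaError,
    classify_peptide,
    collect_recoding_events,
    corroborate,
    fdr_filter,
    map_peptide,
    read_psm_table,
    read_tag_table,
    strip_modifications,
    summarize_genes,
)
from ambercode.proteodb import ProteinRecord
from ambercode.seqcore import Contig, GeneModel, reverse_complement


class TestReaders:
    def test_well_formed_psm_table(self, tmp_path):
        p = tmp_path / "psms.tsv"
        p.write_text(
            "peptide\tscore\tparents\n"
            "MKQE\t31.5\tphage-code15|g1\n"
            "AAAK\t12.0\tDECOY_phage-code15|g1\n"
            "M(+15.99)KQE\t20.0\tphage-code15|g1;phage-code11|g2\n"
        )
        psms = read_psm_table(p)
        assert len(psms) == 3
        assert psms[1].is_decoy is True
        assert psms[2].peptide == "MKQE"
        assert psms[2].mods == [(0, "+15.99")]
        assert psms[2].parent_ids == ["phage-code15|g1", "phage-code11|g2"]

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("peptide\tscore\nMK\t3\n")
        with pytest.raises(SchemaError, match="parents"):
            read_psm_table(p)

    def test_malformed_tag_row_rejected_not_fatal(self, tmp_path, caplog):
        p = tmp_path / "tags.tsv"
        p.write_text(
            "tag\talc\tresidue_conf\n"
            "MKQE\t95.0\t95,95,95,95\n"
            "MKQE\t95.0\t95,95\n"  # length mismatch
        )
        tags = read_tag_table(p)
        assert len(tags) == 1

    def test_strip_modifications(self):
        seq, mods = strip_modifications("AM(+15.99)KC(+57.02)R")
        assert seq == "AMKCR"
        assert mods == [(1, "+15.99"), (3, "+57.02")]


class TestFdrFilter:
    def test_boundary_fdr_with_single_decoy(self):
        psms = [PSM(f"T{i}", 100 - i, ["t"]) for i in range(99)]
        decoy = PSM("D0", 0.5, ["DECOY_t"], is_decoy=True)
        psms.append(decoy)
        accepted = fdr_filter(psms, threshold=0.01)
        assert len(accepted) == 99
        assert decoy.q_value == pytest.approx(1 / 99, abs=1e-6)

    def test_all_decoys_on_top_accepts_nothing(self):
        psms = [PSM(f"D{i}", 100 + i, ["DECOY_t"], is_decoy=True) for i in range(10)]
        psms += [PSM(f"T{i}", 10 - i * 0.1, ["t"]) for i in range(10)]
        assert fdr_filter(psms, 0.01) == []

    def test_qvalues_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(3)
        psms = [
            PSM(f"P{i}", float(rng.normal(20, 5)), ["DECOY_t"] if i % 3 == 0 else ["t"], is_decoy=i % 3 == 0)
            for i in range(200)
        ]
        fdr_filter(psms, 0.05)
        ranked = sorted([p for p in psms if p.q_value is not None], key=lambda p: -p.score)
        qs = [p.q_value for p in ranked]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_peptide_level_collapse_keeps_best_score(self):
        psms = [PSM("AAA", 10.0, ["t"]), PSM("AAA", 30.0, ["t"]), PSM("BBB", 5.0, ["t"])]
        accepted = fdr_filter(psms, 1.0)
        scores = {p.peptide: p.score for p in accepted}
        assert scores == {"AAA": 30.0, "BBB": 5.0}

    def test_zero_decoys_accepts_all_targets(self):
        psms = [PSM(f"T{i}", float(i), ["t"]) for i in range(5)]
        accepted = fdr_filter(psms, 0.01)
        assert len(accepted) == 5
        assert all(p.q_value == 0.0 for p in accepted)


def _plus_fixture():
    # contig with gene [0,15): ATG AAA TAG GAA TAA -> MKQE under code 15
    contig = Contig("c", "ATGAAATAGGAATAA" + "GGGGGG")
    gene = GeneModel("g15", "c", 0, 15, "+", 15, "MKQE")
    rec = ProteinRecord("phage-code15|g15", "MKQE", "phage-code15", "g15")
    return contig, gene, rec


def _minus_fixture():
    fwd = "ATGAAATAGGAATAA" + "GGGGGG"
    rc = reverse_complement(fwd)
    n = len(fwd)
    contig = Contig("c", rc)
    gene = GeneModel("g15", "c", n - 15, n, "-", 15, "MKQE")
    rec = ProteinRecord("phage-code15|g15", "MKQE", "phage-code15", "g15")
    return contig, gene, rec


class TestMapPeptide:
    def test_plus_strand_codon_spans_and_tag(self):
        contig, gene, rec = _plus_fixture()
        (aln,) = map_peptide("KQE", rec, gene, contig)
        assert aln.codon_spans == [(3, 6), (6, 9), (9, 12)]
        assert aln.residues_at_TAG == [1]

    def test_minus_strand_mirror(self):
        contig, gene, rec = _minus_fixture()
        (aln,) = map_peptide("KQE", rec, gene, contig)
        n = len(contig)
        assert aln.codon_spans == [(n - 6, n - 3), (n - 9, n - 6), (n - 12, n - 9)]
        assert aln.residues_at_TAG == [1]

    def test_extended_record_maps_upstream_of_start(self):
        # TAC GCA upstream of ATG: extension "YA"; peptide spans the start
        contig = Contig("c", "TAA" + "TACGCA" + "ATGAAATAGGAATAA")
        gene = GeneModel("g15", "c", 9, 24, "+", 15, "MKQE")
        rec = ProteinRecord(
            "phage-code15-extended|g15|ext2", "YAMKQE", "phage-code15-extended", "g15", extension_len=2
        )
        (aln,) = map_peptide("YAMK", rec, gene, contig)
        assert aln.codon_spans[0] == (3, 6)  # upstream of gene.start
        assert aln.codon_spans[2] == (9, 12)

    def test_peptide_absent_from_parent_raises(self):
        contig, gene, rec = _plus_fixture()
        with pytest.raises(MappingError):
            map_peptide("WWW", rec, gene, contig)

    def test_multiple_occurrences_give_multiple_alignments(self):
        contig = Contig("c", "ATG" + "GCAGCA" * 2 + "TAA")
        gene = GeneModel("g", "c", 0, 18, "+", 15, "MAAAA")
        rec = ProteinRecord("phage-code15|g", "MAAAA", "phage-code15", "g")
        alns = map_peptide("AA", rec, gene, contig)
        assert len(alns) == 3  # offsets 1, 2, 3


def _classify_setup():
    contig, gene, rec = _plus_fixture()
    rec11 = ProteinRecord("phage-code11|g11", "MK", "phage-code11", "g11")
    db = [rec, rec11]
    g11 = [GeneModel("g11", "c", 0, 9, "+", 11, "MK")]
    return contig, gene, rec, db, g11


class TestClassify:
    def test_stop_readthrough_needs_flanks(self):
        contig, gene, rec, db, g11 = _classify_setup()
        (aln,) = map_peptide("KQE", rec, gene, contig)
        classes = classify_peptide(aln, db, g11)
        assert "stop-readthrough" in classes
        assert "code15-exclusive" in classes

    def test_tag_at_peptide_edge_is_not_readthrough(self):
        contig, gene, rec, db, g11 = _classify_setup()
        (aln,) = map_peptide("QE", rec, gene, contig)
        assert "stop-readthrough" not in classify_peptide(aln, db, g11)

    def test_shared_peptide_never_exclusive(self):
        contig, gene, rec, db, g11 = _classify_setup()
        (aln,) = map_peptide("MK", rec, gene, contig)
        classes = classify_peptide(aln, db, g11)
        assert "shared" in classes and "code15-exclusive" not in classes

    def test_start_readthrough_plus_strand(self):
        # code-15 gene [0,21); a code-11 gene starts in-frame at 9
        contig = Contig("c", "ATGAAATAG" + "ATGCCCGAATAA" + "TAA")
        gene = GeneModel("g15", "c", 0, 21, "+", 15, "MKQMPE")
        rec = ProteinRecord("phage-code15|g15", "MKQMPE", "phage-code15", "g15")
        g11 = [GeneModel("g11", "c", 9, 21, "+", 11, "MPE")]
        db = [rec, ProteinRecord("phage-code11|g11", "MPE", "phage-code11", "g11")]
        (aln,) = map_peptide("KQMPE", rec, gene, contig)
        classes = classify_peptide(aln, db, g11)
        assert "start-readthrough" in classes

    def test_start_readthrough_minus_strand(self):
        fwd = "ATGAAATAG" + "ATGCCCGAATAA" + "TAA"
        rc = reverse_complement(fwd)
        n = len(fwd)
        contig = Contig("c", rc)
        gene = GeneModel("g15", "c", n - 21, n, "-", 15, "MKQMPE")
        rec = ProteinRecord("phage-code15|g15", "MKQMPE", "phage-code15", "g15")
        g11 = [GeneModel("g11", "c", n - 21, n - 9, "-", 11, "MPE")]
        db = [rec, ProteinRecord("phage-code11|g11", "MPE", "phage-code11", "g11")]
        (aln,) = map_peptide("KQMPE", rec, gene, contig)
        assert "start-readthrough" in classify_peptide(aln, db, g11)

    def test_order_independent_in_db(self):
        contig, gene, rec, db, g11 = _classify_setup()
        (aln,) = map_peptide("KQE", rec, gene, contig)
        assert classify_peptide(aln, db, g11) == classify_peptide(aln, db[::-1], g11)


class TestCorroborate:
    def _aln(self):
        contig, gene, rec = _plus_fixture()
        (aln,) = map_peptide("MKQE", rec, gene, contig)
        return aln

    def test_six_shared_high_confidence_corroborates(self):
        contig = Contig("c", "ATGAAATAGGAAGCAGCATAA")
        gene = GeneModel("g", "c", 0, 21, "+", 15, "MKQEAA")
        rec = ProteinRecord("phage-code15|g", "MKQEAA", "phage-code15", "g")
        (aln,) = map_peptide("MKQEAA", rec, gene, contig)
        tag = DeNovoTag("MKQEAA", 95.0, [95.0] * 6)
        v = corroborate("MKQEAA", [tag], aln)
        assert v.corroborated
        assert v.recoded_ok == {2: True}

    def test_low_confidence_on_recoded_q_fails_recoding_check(self):
        contig = Contig("c", "ATGAAATAGGAAGCAGCATAA")
        gene = GeneModel("g", "c", 0, 21, "+", 15, "MKQEAA")
        rec = ProteinRecord("phage-code15|g", "MKQEAA", "phage-code15", "g")
        (aln,) = map_peptide("MKQEAA", rec, gene, contig)
        conf = [95.0, 95.0, 85.0, 95.0, 95.0, 95.0]  # Q at 85 < 90
        tag = DeNovoTag("MKQEAA", float(np.mean(conf)), conf)
        v = corroborate("MKQEAA", [tag], aln)
        assert v.corroborated  # sequence-level support still holds
        assert v.recoded_ok == {2: False}

    def test_five_shared_residues_fail_length_floor(self):
        aln = self._aln()
        tag = DeNovoTag("MKQEW", 99.0, [99.0] * 5)  # only MKQE (4) shared anyway
        v = corroborate("MKQE", [tag], aln)
        assert not v.corroborated

    def test_low_alc_tags_ignored(self):
        contig = Contig("c", "ATGAAATAGGAAGCAGCATAA")
        gene = GeneModel("g", "c", 0, 21, "+", 15, "MKQEAA")
        rec = ProteinRecord("phage-code15|g", "MKQEAA", "phage-code15", "g")
        (aln,) = map_peptide("MKQEAA", rec, gene, contig)
        tag = DeNovoTag("MKQEAA", 45.0, [45.0] * 6)
        assert not corroborate("MKQEAA", [tag], aln).corroborated

    def test_isoleucine_leucine_equivalence_in_tag_matching(self):
        contig = Contig("c", "ATGATTCTGATTCTGAAATAA")
        gene = GeneModel("g", "c", 0, 21, "+", 15, "MILILK")
        rec = ProteinRecord("phage-code15|g", "MILILK", "phage-code15", "g")
        (aln,) = map_peptide("MILILK", rec, gene, contig)
        tag = DeNovoTag("MLILIK", 95.0, [95.0] * 6)  # I/L swapped
        assert corroborate("MILILK", [tag], aln).corroborated


class TestEventsAndSummary:
    def _run(self):
        contig, gene, rec, db, g11 = _classify_setup()
        psm = PSM("KQE", 30.0, [rec.record_id], q_value=0.0)
        alns = {"KQE": map_peptide("KQE", rec, gene, contig)}
        events = collect_recoding_events([psm], alns, {"c": contig}, db, g11)
        return contig, gene, psm, alns, events, db, g11

    def test_event_emitted_at_tag_codon(self):
        _, _, _, _, events, _, _ = self._run()
        assert len(events) == 1
        assert events[0].span == (6, 9)
        assert events[0].observed_residue == "Q"
        assert events[0].supporting_peptides == ["KQE"]

    def test_summary_counts_and_coverage(self):
        contig, gene, psm, alns, events, db, g11 = self._run()
        summary, coverage = summarize_genes(events, alns, [psm], [gene])
        row = summary.iloc[0]
        assert row.n_peptides == 1
        assert row.n_unique_peptides == 1
        assert row.detected
        assert row.n_recoding_events == 1
        cov = coverage[coverage.gene_id == "g15"]
        assert list(cov.covered_by_peptide) == [False, True, True, True]

    def test_gene_without_peptides_not_detected(self):
        contig, gene, psm, alns, events, db, g11 = self._run()
        other = GeneModel("g2", "c", 0, 9, "+", 15, "MK")
        summary, _ = summarize_genes(events, alns, [psm], [gene, other])
        assert not summary[summary.gene_id == "g2"].detected.iloc[0]
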