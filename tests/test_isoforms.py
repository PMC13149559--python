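"""Transcript models, isoform fractions, structural classes, consequences."""

import numpy as np
import pytest

from vusplice.isoforms import (
    GTFParseError,
    IsoformAbundance,
    TranscriptModel,
    classify_isoform,
    isoform_fractions,
    parse_gtf_transcripts,
    predict_protein_consequence,
    read_abundance_tsv,
    write_abundance_tsv,
    write_gtf,
)

from _oracles import build_toy_gene, consequence_oracle, revcomp, translate_to_stop


def model(tx, exons, strand="+", cds=(), gene="G", contig="toy"):
    return TranscriptModel(tx, gene, contig, strand, tuple(exons), tuple(cds))


class TestGTFParsing:
    GTF = (
        'toy\tsrc\texon\t11\t40\t.\t+\t.\tgene_id "G"; transcript_id "T1";\n'
        'toy\tsrc\texon\t101\t140\t.\t+\t.\tgene_id "G"; transcript_id "T1";\n'
        'toy\tsrc\texon\t201\t240\t.\t+\t.\tgene_id "G"; transcript_id "T1";\n'
    )

    def test_three_exon_transcript(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(self.GTF)
        (m,) = parse_gtf_transcripts(path)
        assert m.exons == ((10, 40), (100, 140), (200, 240))
        assert m.introns == ((40, 100), (140, 200))

    def test_out_of_order_exons_sorted(self, tmp_path):
        lines = self.GTF.splitlines()
        path = tmp_path / "b.gtf"
        path.write_text("\n".join(lines[::-1]) + "\n")
        (m,) = parse_gtf_transcripts(path)
        assert m.exons == ((10, 40), (100, 140), (200, 240))

    def test_missing_attribute_names_line(self, tmp_path):
        path = tmp_path / "c.gtf"
        path.write_text('toy\tsrc\texon\t11\t40\t.\t+\t.\tgene_id "G";\n')
        with pytest.raises(GTFParseError, match=":1:"):
            parse_gtf_transcripts(path)

    def test_write_parse_round_trip(self, tmp_path):
        rng = np.random.default_rng(31)
        models = []
        for t in range(5):
            bounds = np.cumsum(rng.integers(10, 50, size=6))
            exons = [(int(bounds[i]), int(bounds[i + 1]))
                     for i in range(0, 6, 2)]
            models.append(model(f"T{t}", exons, strand=rng.choice(["+", "-"])))
        path = tmp_path / "rt.gtf"
        write_gtf(models, path)
        recovered = {m.transcript_id: m for m in parse_gtf_transcripts(path)}
        for m in models:
            assert recovered[m.transcript_id].exons == m.exons
            assert recovered[m.transcript_id].strand == m.strand


class TestFractions:
    def test_participant_profile(self):
        abundances = [
            IsoformAbundance("canonical", "DEGS1", 6),
            IsoformAbundance("skip", "DEGS1", 69),
            IsoformAbundance("cryptic", "DEGS1", 12),
            IsoformAbundance("other", "DEGS1", 13),
        ]
        fractions = isoform_fractions(abundances)["DEGS1"]
        assert fractions == {
            "canonical": 0.06, "skip": 0.69, "cryptic": 0.12, "other": 0.13,
        }

    def test_control_profile_canonical_dominates(self):
        fractions = isoform_fractions(
            [IsoformAbundance("canonical", "G", 90), IsoformAbundance("rest", "G", 10)]
        )["G"]
        assert fractions["canonical"] == pytest.approx(0.90)

    def test_single_isoform_and_zero_total(self):
        assert isoform_fractions([IsoformAbundance("only", "G", 5)])["G"] == {"only": 1.0}
        assert isoform_fractions([IsoformAbundance("only", "G", 0)])["G"] == {}

    def test_fractions_sum_to_one_per_gene(self):
        rng = np.random.default_rng(37)
        abundances = [
            IsoformAbundance(f"t{i}", f"g{i % 3}", float(rng.gamma(2, 10)))
            for i in range(30)
        ]
        for gene, fractions in isoform_fractions(abundances).items():
            assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            IsoformAbundance("t", "g", -1)

    def test_abundance_tsv_round_trip(self, tmp_path):
        abundances = [IsoformAbundance("t1", "g", 4.5), IsoformAbundance("t2", "g", 0.0)]
        path = tmp_path / "abund.tsv"
        write_abundance_tsv(abundances, path)
        assert read_abundance_tsv(path) == abundances


class TestClassification:
    CANONICAL = ((10, 40), (100, 140), (200, 240))

    def test_identical_chain_is_canonical_match(self):
        c = model("ref", self.CANONICAL)
        got = classify_isoform(model("cand", self.CANONICAL), c)
        assert got.category == "canonical_match"

    def test_exon_two_skip(self):
        cand = model("cand", [(10, 40), (200, 240)])
        got = classify_isoform(cand, model("ref", self.CANONICAL))
        assert got.category == "exon_skipping"
        assert got.skipped_exons == (2,)

    def test_minus_strand_skip_uses_transcript_ordinals(self):
        cand = model("cand", [(10, 40), (200, 240)], strand="-")
        got = classify_isoform(cand, model("ref", self.CANONICAL, strand="-"))
        # genomic middle exon is still transcript exon 2 of 3 on the minus strand
        assert got.skipped_exons == (2,)

    def test_terminal_exon_length_change_is_still_canonical(self):
        cand = model("cand", [(0, 40), (100, 140), (200, 260)])
        got = classify_isoform(cand, model("ref", self.CANONICAL))
        assert got.category == "canonical_match"

    def test_shifted_acceptor_is_altered_splice_site(self):
        cand = model("cand", [(10, 40), (100, 140), (230, 240)])
        got = classify_isoform(cand, model("ref", self.CANONICAL))
        assert got.category == "altered_splice_site"
        assert "230" in got.detail

    def test_unrelated_chain_is_other(self):
        cand = model("cand", [(10, 40), (150, 170), (300, 340)])
        got = classify_isoform(cand, model("ref", self.CANONICAL))
        assert got.category == "other"

    def test_contig_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_isoform(
                model("cand", self.CANONICAL, contig="chr2"),
                model("ref", self.CANONICAL),
            )

    def test_random_skip_constructions_recovered(self):
        rng = np.random.default_rng(41)
        for _ in range(200):
            n_exons = int(rng.integers(3, 7))
            strand = str(rng.choice(["+", "-"]))
            bounds = np.cumsum(rng.integers(10, 60, size=2 * n_exons))
            exons = [(int(bounds[i]), int(bounds[i + 1]))
                     for i in range(0, 2 * n_exons, 2)]
            canonical = model("ref", exons, strand=strand)
            n_skip = int(rng.integers(1, n_exons - 1))
            skip_genomic = sorted(
                rng.choice(np.arange(1, n_exons - 1), size=n_skip, replace=False)
            )
            cand = model(
                "cand",
                [e for i, e in enumerate(exons) if i not in skip_genomic],
                strand=strand,
            )
            got = classify_isoform(cand, canonical)
            assert got.category == "exon_skipping"
            expected = [i + 1 for i in skip_genomic]
            if strand == "-":
                expected = sorted(n_exons - i for i in skip_genomic)
            assert got.skipped_exons == tuple(expected)


class TestProteinConsequence:
    def build(self, rng, n_exons, strand, skip_tx_ordinal):
        genome, intervals, cds, exon_seqs, cds_len = build_toy_gene(
            rng, n_exons, strand
        )
        canonical = model("ref", intervals, strand=strand, cds=cds)
        tx_order = intervals if strand == "+" else intervals[::-1]
        kept = [e for i, e in enumerate(tx_order) if i != skip_tx_ordinal]
        candidate = model("cand", sorted(kept), strand=strand)
        return genome, canonical, candidate, exon_seqs, cds_len

    def test_identity_is_synonymous(self):
        rng = np.random.default_rng(43)
        genome, canonical, _, _, _ = self.build(rng, 3, "+", 1)
        got = predict_protein_consequence(canonical, canonical, genome)
        assert got.kind == "synonymous_structure" and got.hgvs_p == "p.(=)"

    def test_in_frame_skip_is_clean_deletion(self):
        # middle exon of 9 nt, codon-aligned: removes exactly residues 4-6
        e1, e2, e3 = "ATGAAAGAAGGA", "CCTCCCCCA", "GTTTAAGGTAAGTAA"
        genome = {"toy": e1 + "GTAAG" + e2 + "GTAAG" + e3}
        o1 = len(e1)
        i1 = o1 + 5
        o2 = i1 + len(e2)
        i2 = o2 + 5
        exons = [(0, o1), (i1, o2), (i2, i2 + len(e3))]
        cds_end = i2 + 6  # ...GTTTAA
        canonical = model("ref", exons, cds=[(0, o1), (i1, o2), (i2, cds_end)])
        candidate = model("cand", [exons[0], exons[2]])
        got = predict_protein_consequence(canonical, candidate, genome)
        assert got.kind == "in_frame_deletion"
        assert got.hgvs_p == "p.Pro5_Pro7del"

    def test_frame_disrupting_skip_is_frameshift(self):
        rng = np.random.default_rng(47)
        for _ in range(20):
            genome, canonical, candidate, exon_seqs, cds_len = self.build(
                rng, 3, "+", 1
            )
            if len(exon_seqs[1]) % 3 == 0:
                continue
            got = predict_protein_consequence(canonical, candidate, genome)
            assert got.kind in {"frameshift", "other"}
            if got.kind == "frameshift":
                assert "fs*" in got.hgvs_p

    def test_start_codon_removed_is_start_lost(self):
        rng = np.random.default_rng(53)
        genome, canonical, _, _, _ = self.build(rng, 3, "+", 1)
        # candidate missing the first exon entirely
        candidate = model("cand", list(canonical.exons[1:]))
        got = predict_protein_consequence(canonical, candidate, genome)
        assert got.kind == "start_lost"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_brute_force_translator(self, strand):
        rng = np.random.default_rng(59 if strand == "+" else 61)
        for _ in range(100):
            n_exons = int(rng.integers(3, 6))
            skip = int(rng.integers(1, n_exons - 1))
            genome, canonical, candidate, exon_seqs, cds_len = self.build(
                rng, n_exons, strand, skip
            )
            got = predict_protein_consequence(canonical, candidate, genome)
            ref_cds = "".join(exon_seqs)[:cds_len]
            alt_coding = "".join(s for i, s in enumerate(exon_seqs) if i != skip)
            want_hgvs, want_kind = consequence_oracle(ref_cds, alt_coding)
            assert (got.hgvs_p, got.kind) == (want_hgvs, want_kind)
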