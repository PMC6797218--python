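"""Transcript splicing, variant application and ORF consequence prediction."""

import math

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from ploidyscope import seq
from ploidyscope.seq import (ConsequenceReport, Deletion, DonorShift, ExonSkip,
                             GeneModel, Insertion, IntronRetention,
                             Substitution, TranscriptVariant, analyze_orf,
                             apply_variant, consequence, inverse_variant,
                             predict_nmd, protein_mw, spliced_cds)


def single_exon(cds: str) -> GeneModel:
    return GeneModel(name="toy", contig="c", strand="+",
                     exons=((1, len(cds)),), genome={"c": cds})


def multi_exon(exon_seqs, intron_seqs, cds_start=1) -> GeneModel:
    """Plus-strand gene assembled from alternating exon/intron sequences."""
    assert len(intron_seqs) == len(exon_seqs) - 1
    contig, exons, pos = "", [], 0
    for i, ex in enumerate(exon_seqs):
        exons.append((pos + 1, pos + len(ex)))
        contig += ex
        pos += len(ex)
        if i < len(intron_seqs):
            contig += intron_seqs[i]
            pos += len(intron_seqs[i])
    return GeneModel(name="toy", contig="c", strand="+", exons=tuple(exons),
                     genome={"c": contig}, cds_start=cds_start)


# ---------------------------------------------------------------------------
# Independent oracle: rebuild and translate the mutant character by character
# ---------------------------------------------------------------------------

_ORACLE_CODONS = None


def oracle_translate(cds: str):
    """Translate codon by codon; returns (protein, stop_index or None)."""
    global _ORACLE_CODONS
    if _ORACLE_CODONS is None:
        bases = "TCAG"
        aas = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
               "VVVVAAAADDEEGGGG")
        _ORACLE_CODONS = {a + b + c: aa for (a, b, c), aa in
                          zip(((x, y, z) for x in bases for y in bases
                               for z in bases), aas)}
    protein = []
    for i in range(0, len(cds) - 2, 3):
        aa = _ORACLE_CODONS[cds[i:i + 3]]
        if aa == "*":
            return "".join(protein), i
        protein.append(aa)
    return "".join(protein), None


def oracle_consequence(ref_cds: str, mut_cds: str):
    """Expected report fields computed by direct string comparison."""
    ref_protein, _ = oracle_translate(ref_cds)
    protein, stop = oracle_translate(mut_cds)
    intact = 0
    for a, b in zip(protein, ref_protein):
        if a != b:
            break
        intact += 1
    frameshift = (len(mut_cds) - len(ref_cds)) % 3 != 0
    return {
        "protein": protein,
        "nonstop": stop is None,
        "stop_position": None if stop is None else stop + 1,
        "last_intact_residue": intact,
        "frameshift": frameshift,
        "ectopic_codon_count": len(protein) - intact if frameshift else 0,
    }


class TestSplicedCds:
    def test_single_exon(self):
        tx = spliced_cds(single_exon("ATGAAATAA"))
        assert tx.cds == "ATGAAATAA"
        assert tx.junctions == []

    def test_two_exons_one_junction(self):
        m = multi_exon(["ATGAAA", "CCCGGGTAA"], ["GTAAAG"])
        tx = spliced_cds(m)
        assert tx.seq == "ATGAAACCCGGGTAA"
        assert tx.junctions == [6]

    def test_minus_strand_equals_hand_built_reverse_complement(self):
        # 30-nt transcript over three 10-nt exons on the minus strand
        transcript = "ATGGATAAACCCGGGTTTACAGATTAATGA"
        rc = str(Seq(transcript).reverse_complement())
        genome = {"c": "NN" + rc[:10] + "gtag" + rc[10:20] + "gtag" + rc[20:] + "NN"}
        # transcript exon k maps to descending genomic windows
        exons = ((31, 40), (17, 26), (3, 12))
        m = GeneModel(name="toy", contig="c", strand="-", exons=exons,
                      genome=genome)
        assert spliced_cds(m).seq == transcript

    def test_exon_outside_contig_raises(self):
        with pytest.raises(ValueError, match="outside contig"):
            GeneModel(name="t", contig="c", strand="+", exons=((1, 99),),
                      genome={"c": "ATGAAATAA"})

    def test_sub_codon_cds_raises(self):
        with pytest.raises(ValueError, match="codon"):
            spliced_cds(GeneModel(name="t", contig="c", strand="+",
                                  exons=((1, 2),), genome={"c": "AT"}))


class TestApplyVariant:
    def test_in_frame_deletion_removes_one_residue(self):
        m = single_exon("ATGGATAAACCCTAA")  # M D K P *
        tx = spliced_cds(m)
        mut = apply_variant(tx, TranscriptVariant((Deletion(7, 3),)))
        report = analyze_orf(mut, "MDKP", reference_cds_length=15)
        assert not report.frameshift
        assert report.protein == "MDP"
        assert report.ectopic_codon_count == 0

    def test_hand_edited_deletion(self):
        # ATG GAT GAT GAT TAA, deletion(pos 5, len 4) -> ATGGTGATTAA
        tx = spliced_cds(single_exon("ATGGATGATGATTAA"))
        mut = apply_variant(tx, TranscriptVariant((Deletion(5, 4),)))
        assert mut.seq == "ATGGTGATTAA"
        report = analyze_orf(mut, "MDDD", reference_cds_length=15)
        assert report.frameshift and report.nonstop

    def test_exon_skip_of_310nt_span_shifts_frame(self):
        # skipping exons totalling 310 nt (310 mod 3 = 1) must frameshift
        e1 = "ATGGAT"
        skip = ["A" * 100, "C" * 104, "G" * 106]  # 310 nt in three exons
        e5 = "GATAAACCCTAA"
        m = multi_exon([e1, *skip, e5], ["GTAG"] * 4)
        tx = spliced_cds(m)
        mut = apply_variant(tx, TranscriptVariant((ExonSkip((2, 3, 4)),)))
        assert len(tx.seq) - len(mut.seq) == 310
        report = analyze_orf(mut, "M" * 10, reference_cds_length=len(tx.seq))
        assert report.frameshift

    def test_exon_skip_merges_junctions(self):
        m = multi_exon(["ATGAAA", "CCC", "GGGTAA"], ["GTAG", "GCAG"])
        tx = spliced_cds(m)
        mut = apply_variant(tx, TranscriptVariant((ExonSkip((2,)),)))
        assert mut.seq == "ATGAAAGGGTAA"
        assert mut.junctions == [6]

    def test_donor_shift_reads_into_intron(self):
        m = multi_exon(["ATGGAT", "GATTAA"], ["GTAAGTAG"])
        tx = spliced_cds(m)
        mut = apply_variant(tx, TranscriptVariant((DonorShift(1, 4),)))
        assert mut.seq == "ATGGATGTAAGATTAA"
        assert mut.junctions == [10]

    def test_donor_shift_beyond_intron_raises(self):
        m = multi_exon(["ATGGAT", "GATTAA"], ["GTAG"])
        tx = spliced_cds(m)
        with pytest.raises(ValueError, match="intron length"):
            apply_variant(tx, TranscriptVariant((DonorShift(1, 10),)))

    def test_intron_retention_erases_junction(self):
        m = multi_exon(["ATGGAT", "GATTAA"], ["GTAAGTAG"])
        tx = spliced_cds(m)
        mut = apply_variant(tx, TranscriptVariant((IntronRetention(1),)))
        assert mut.seq == "ATGGATGTAAGTAGGATTAA"
        assert mut.junctions == []

    def test_overlapping_edits_raise(self):
        tx = spliced_cds(single_exon("ATGGATGATGATTAA"))
        var = TranscriptVariant((Deletion(5, 4), Substitution(6, "A")))
        with pytest.raises(ValueError, match="overlapping"):
            apply_variant(tx, var)

    def test_out_of_bounds_edit_raises(self):
        tx = spliced_cds(single_exon("ATGGATTAA"))
        with pytest.raises(ValueError, match="out of bounds"):
            apply_variant(tx, TranscriptVariant((Deletion(8, 5),)))

    @pytest.mark.parametrize("edit", [
        Deletion(5, 4), Insertion(7, "ACGT"), Substitution(6, "T")])
    def test_point_edit_round_trip(self, edit):
        tx = spliced_cds(multi_exon(["ATGGATGAT", "GATGGGTAA"], ["GTAAAG"]))
        var = TranscriptVariant((edit,))
        mut = apply_variant(tx, var)
        back = apply_variant(mut, inverse_variant(tx, var))
        assert back.seq == tx.seq
        assert back.junctions == tx.junctions

    def test_donor_shift_round_trip(self):
        tx = spliced_cds(multi_exon(["ATGGAT", "GATTAA"], ["GTAAGTAG"]))
        var = TranscriptVariant((DonorShift(1, 4),))
        mut = apply_variant(tx, var)
        back = apply_variant(mut, inverse_variant(tx, var))
        assert back.seq == tx.seq and back.junctions == tx.junctions


class TestAnalyzeOrf:
    def test_unedited_transcript_is_full_length(self):
        tx = spliced_cds(single_exon("ATGGATGATGATTAA"))
        report = analyze_orf(tx, "MDDD", reference_cds_length=15)
        assert report.full_length
        assert not report.frameshift
        assert report.ectopic_codon_count == 0
        assert report.truncated_protein_length == 4

    def test_one_nt_deletion_goes_nonstop(self):
        # ATGGATGATGATTAA minus base 4 reads ATG ATG ATG ATT AA: no stop
        tx = spliced_cds(single_exon("ATGGATGATGATTAA"))
        mut = apply_variant(tx, TranscriptVariant((Deletion(4, 1),)))
        report = analyze_orf(mut, "MDDD", reference_cds_length=15)
        assert report.protein == "MMMI"
        assert report.nonstop and report.frameshift
        assert report.stop_position is None
        assert report.last_intact_residue == 1
        assert report.last_intact_label == "Met1"

    def test_terminal_exon_ptc_escapes_nmd(self):
        # premature stop in a single-exon CDS: truncated, NMD negative
        tx = spliced_cds(single_exon("ATGGATAAACCCTAA"))
        mut = apply_variant(tx, TranscriptVariant((Substitution(7, "T"),)))
        report = analyze_orf(mut, "MDKP", reference_cds_length=15)
        # TAA created at codon 3: truncated length k-1 = 2
        assert report.truncated_protein_length == 2
        assert not report.nmd_predicted
        assert not report.frameshift

    def test_early_ptc_in_multi_exon_gene_triggers_nmd(self):
        m = multi_exon(["ATGGATAAA", "CCCGATGAT", "GGGTAA"],
                       ["GTAG", "GCAG"])
        tx = spliced_cds(m)
        # codon 3 AAA -> TAA: premature stop in exon 1 of 3
        mut = apply_variant(tx, TranscriptVariant((Substitution(7, "T"),)))
        report = analyze_orf(mut, "MDKPDDG", reference_cds_length=len(tx.seq))
        assert report.nmd_predicted
        assert report.ptc_exon_index == 1
        assert report.stop_position == 7
        assert report.last_intact_residue == 2

    def test_frameshift_counts_ectopic_codons(self):
        # M D K P Q R *; 1-nt deletion in codon 3 shifts the frame
        cds = "ATGGATAAACCCCAACGCTAA"
        tx = spliced_cds(single_exon(cds))
        mut = apply_variant(tx, TranscriptVariant((Deletion(8, 1),)))
        ref_protein, _ = oracle_translate(cds)
        expected = oracle_consequence(cds, mut.seq)
        report = analyze_orf(mut, ref_protein, reference_cds_length=len(cds))
        assert report.frameshift
        assert report.last_intact_residue == expected["last_intact_residue"]
        assert report.ectopic_codon_count == expected["ectopic_codon_count"]
        assert report.truncated_protein_length == (
            report.last_intact_residue + report.ectopic_codon_count)

    def test_termination_one_codon_later_counts_one_ectopic(self):
        # +4nt donor readthrough: MDK then GTC (1 ectopic) then TAA
        m = multi_exon(["ATGGATAAG", "AAGATTTAA"], ["GTCTAAGGT"])
        tx = spliced_cds(m)
        mut = apply_variant(tx, TranscriptVariant((DonorShift(1, 4),)))
        assert mut.seq == "ATGGATAAGGTCTAAGATTTAA"
        ref_protein, _ = oracle_translate(tx.cds)
        report = analyze_orf(mut, ref_protein,
                             reference_cds_length=len(tx.cds))
        assert report.frameshift
        assert report.last_intact_residue == 3
        assert report.ectopic_codon_count == 1
        assert report.truncated_protein_length == 4


class TestPredictNmd:
    def test_stop_in_terminal_exon_is_negative(self):
        assert not predict_nmd(150, [50, 100])

    def test_stop_two_exons_upstream_is_positive(self):
        assert predict_nmd(40, [50, 100])

    def test_50nt_mode_contrast(self):
        # stop 30 nt upstream of the final junction
        assert predict_nmd(70, [50, 100], mode="any-exon")
        assert not predict_nmd(70, [50, 100], mode="50nt")
        assert predict_nmd(50, [50, 100], mode="50nt")

    def test_intronless_gene_never_nmd(self):
        assert not predict_nmd(10, [])


class TestProteinMw:
    def test_glycine(self):
        assert protein_mw("G") == pytest.approx(0.07507, abs=5e-5)

    def test_diglycine(self):
        assert protein_mw("GG") == pytest.approx(0.13212, abs=5e-5)

    def test_additivity_identity(self):
        s1, s2 = "MDKPQ", "WYVR"
        lhs = protein_mw(s1 + s2)
        rhs = protein_mw(s1) + protein_mw(s2) - 0.0180153
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_empty_and_unknown_raise(self):
        with pytest.raises(ValueError, match="empty"):
            protein_mw("")
        with pytest.raises(ValueError, match="X"):
            protein_mw("MDX")


class TestFrameArithmetic:
    @pytest.mark.parametrize("length,shifts", [(3, False), (6, False),
                                               (1, True), (2, True),
                                               (4, True), (5, True)])
    def test_net_length_change_controls_frameshift_flag(self, length, shifts):
        cds = "ATGGATAAACCCGATCAGTGGTAA"
        tx = spliced_cds(single_exon(cds))
        mut = apply_variant(tx, TranscriptVariant((Deletion(7, length),)))
        report = analyze_orf(mut, oracle_translate(cds)[0],
                             reference_cds_length=len(cds))
        assert report.frameshift is shifts


@st.composite
def cds_and_edit(draw):
    n_codons = draw(st.integers(min_value=20, max_value=40))
    body = draw(st.text(alphabet="ACGT", min_size=3 * n_codons,
                        max_size=3 * n_codons))
    cds = "ATG" + body + "TAA"
    kind = draw(st.sampled_from(["del", "ins", "sub"]))
    pos = draw(st.integers(min_value=2, max_value=len(cds)))
    if kind == "del":
        length = draw(st.integers(min_value=1,
                                  max_value=min(6, len(cds) - pos + 1)))
        return cds, Deletion(pos, length)
    if kind == "ins":
        ins = draw(st.text(alphabet="ACGT", min_size=1, max_size=6))
        return cds, Insertion(pos, ins)
    base = draw(st.sampled_from("ACGT"))
    return cds, Substitution(pos, base)


class TestOracleEquivalence:
    @settings(max_examples=250, derandomize=True, deadline=None)
    @given(cds_and_edit())
    def test_random_single_edits_match_brute_force(self, case):
        cds, edit = case
        tx = spliced_cds(single_exon(cds))
        mut = apply_variant(tx, TranscriptVariant((edit,)))
        # brute-force rebuild by string surgery, independent of the package
        if isinstance(edit, Deletion):
            expected_seq = cds[:edit.position - 1] + \
                cds[edit.position - 1 + edit.length:]
        elif isinstance(edit, Insertion):
            expected_seq = cds[:edit.position - 1] + edit.sequence + \
                cds[edit.position - 1:]
        else:
            expected_seq = cds[:edit.position - 1] + edit.base + \
                cds[edit.position:]
        assert mut.seq == expected_seq
        expected = oracle_consequence(cds, expected_seq)
        ref_protein, _ = oracle_translate(cds)
        report = analyze_orf(mut, ref_protein, reference_cds_length=len(cds))
        assert report.protein == expected["protein"]
        assert report.nonstop == expected["nonstop"]
        assert report.stop_position == expected["stop_position"]
        assert report.last_intact_residue == expected["last_intact_residue"]
        assert report.frameshift == expected["frameshift"]
        assert report.ectopic_codon_count == expected["ectopic_codon_count"]


class TestEndToEndConsequence:
    def test_consequence_wrapper_derives_reference(self):
        m = multi_exon(["ATGGATAAA", "CCCGATGAT", "GGGTGGTAA"],
                       ["GTAG", "GCAG"])
        report = consequence(m, TranscriptVariant((Deletion(10, 4),)))
        assert isinstance(report, ConsequenceReport)
        assert report.frameshift
        assert report.last_intact_residue == 3  # MDK intact

    def test_file_round_trip(self, tmp_path):
        genome_fa = tmp_path / "g.fa"
        genome_fa.write_text(">c\nATGGATAAAGTAGCCCGATTAA\n")
        gene_yaml = tmp_path / "gene.yaml"
        gene_yaml.write_text(
            "name: toy\ncontig: c\nstrand: '+'\ncds_start: 1\n"
            "exons:\n- [1, 9]\n- [14, 22]\n")
        var_yaml = tmp_path / "var.yaml"
        var_yaml.write_text("- op: substitution\n  position: 7\n  base: T\n")
        genome = seq.read_fasta(genome_fa)
        model = seq.read_gene_model(gene_yaml, genome)
        variant = seq.read_variant(var_yaml)
        report = consequence(model, variant)
        assert report.nmd_predicted  # PTC in exon 1 of 2
        out = tmp_path / "report.json"
        report.to_json(out)
        assert "nmd_predicted" in out.read_text()

    def test_gff3_model_reader(self, tmp_path):
        gff = tmp_path / "m.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c\ttoy\texon\t1\t9\t.\t+\t.\tParent=toygene\n"
            "c\ttoy\texon\t14\t22\t.\t+\t.\tParent=toygene\n")
        genome = {"c": "ATGGATAAAGTAGCCCGATTAA"}
        model = seq.read_gene_model(gff, genome)
        assert model.exons == ((1, 9), (14, 22))
        assert spliced_cds(model).seq == "ATGGATAAACCCGATTAA"
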