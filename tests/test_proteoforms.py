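"""Proteoform enumeration: codon edits, substitution, stop-skip, frameshift,
and the FASTA database round-trip."""

import pytest

import ptcquant as pq
from ptcquant.fixtures import FUSION_PROTEIN


@pytest.fixture()
def toy_construct():
    # ATG AAA TGA GGG TAA -> "MK" with a declared stop at codon 3
    return pq.CodingConstruct(
        name="TOY",
        cds="ATGAAATGAGGGTAA",
        sites=(pq.StopCodonSite(3, "TGA", "TGA3"),),
    )


class TestCodingConstruct:
    def test_site_triplet_must_match_cds(self):
        with pytest.raises(pq.ValidationError):
            pq.CodingConstruct(
                name="X", cds="ATGAAATGA", sites=(pq.StopCodonSite(2, "TGA", "TGA2"),)
            )

    def test_must_start_with_atg(self):
        with pytest.raises(pq.ValidationError):
            pq.CodingConstruct(name="X", cds="TTGAAATGA")

    def test_declared_site_must_be_stop(self):
        with pytest.raises(pq.ValidationError):
            pq.CodingConstruct(
                name="X", cds="ATGAAATGA", sites=(pq.StopCodonSite(2, "AAA", "A2"),)
            )


class TestApplyCodonEdits:
    def test_empty_edit_list_is_identity(self, toy_construct):
        assert pq.apply_codon_edits(toy_construct, []) == toy_construct

    def test_kppk_edits_change_exactly_two_residues(self):
        """Replacing 221-EPPE-224 by 221-KPPK-224 edits codons 221 and 224."""
        construct = pq.p53_sbp_construct()
        edited = pq.apply_codon_edits(construct, pq.kppk_edits())
        a = pq.translate(construct.cds).protein
        b = pq.translate(edited.cds).protein
        assert a[220:224] == "EPPE"
        assert b[220:224] == "KPPK"
        assert sum(x != y for x, y in zip(a, b)) == 2

    def test_editing_codon_213_to_opal_validates_as_site(self):
        construct = pq.p53_sbp_construct("TGA213")
        assert construct.codon(213) == "TGA"
        assert construct.site("TGA213").triplet == "TGA"

    def test_editing_declared_stop_to_sense_codon_rejected(self, toy_construct):
        with pytest.raises(pq.ValidationError):
            pq.apply_codon_edits(toy_construct, [(3, "CGA")])

    def test_original_untouched_and_edit_logged(self, toy_construct):
        edited = pq.apply_codon_edits(toy_construct, [(2, "AAG")])
        assert toy_construct.cds == "ATGAAATGAGGGTAA"
        assert edited.codon(2) == "AAG"
        assert edited.metadata["edits"] == ["2:AAA>AAG"]


class TestSubstitutionProteoforms:
    def test_all20_counts_and_single_residue_difference(self, toy_construct):
        site = toy_construct.site("TGA3")
        pfs = pq.enumerate_substitution_proteoforms(toy_construct, site)
        assert len(pfs) == 20
        assert len({len(p.sequence) for p in pfs}) == 1
        for a in pfs:
            for b in pfs:
                diff = [i for i, (x, y) in enumerate(zip(a.sequence, b.sequence)) if x != y]
                assert diff in ([], [site.codon_index - 1])

    def test_r_at_213_restores_wild_type_p53_region(self):
        """Arginine incorporation at the opal 213 codon restores the
        wild-type sequence."""
        construct = pq.p53_sbp_construct("TGA213")
        site = construct.site("TGA213")
        (pf,) = pq.enumerate_substitution_proteoforms(construct, site, candidates={"R"})
        assert pf.sequence == FUSION_PROTEIN
        assert pf.sequence[212] == "R"

    def test_tga129_cassette_variants(self, tga129_construct, tga129_site):
        pfs = pq.enumerate_substitution_proteoforms(
            tga129_construct, tga129_site, candidates={"R", "W", "C"}
        )
        assert len(pfs) == 3
        for pf in pfs:
            cassette = pf.sequence[120:132]
            assert cassette == "SVTCTYSP" + pf.incorporated + "LNK"

    def test_retranslating_generating_cds_reproduces_sequence(self, tga129_database):
        for pf in tga129_database:
            assert pq.translate(pf.cds).protein == pf.sequence

    def test_empty_candidate_set_rejected(self, toy_construct):
        with pytest.raises(pq.InputError):
            pq.enumerate_substitution_proteoforms(
                toy_construct, toy_construct.site("TGA3"), candidates=set()
            )


class TestSkipProteoform:
    def test_toy_skip_product(self, toy_construct):
        pf = pq.enumerate_skip_proteoform(toy_construct, toy_construct.site("TGA3"))
        assert pf.sequence == "MKG"
        assert pf.event == "skip"

    def test_cterminal_skip_extends_six_residues_ending_cysteine(self):
        """18 nt separate the terminal stop from the next in-frame stop:
        the skip product gains exactly six residues and ends with C."""
        construct = pq.p53_sbp_construct()
        pf = pq.enumerate_skip_proteoform(construct, construct.site("STOP436"))
        assert len(pf.sequence) == len(FUSION_PROTEIN) + 6
        assert pf.sequence.startswith(FUSION_PROTEIN)
        assert pf.sequence.endswith("C")

    def test_skip_length_law_vs_substitutions(self, tga129_construct, tga129_site):
        subs = pq.enumerate_substitution_proteoforms(tga129_construct, tga129_site)
        skip = pq.enumerate_skip_proteoform(tga129_construct, tga129_site)
        (sub_len,) = {len(p.sequence) for p in subs}
        assert len(skip.sequence) == sub_len - 1
        # identical downstream tail after the site column
        assert skip.sequence[tga129_site.codon_index - 1 :] == subs[0].sequence[
            tga129_site.codon_index :
        ]

    def test_no_downstream_stop_flagged(self):
        construct = pq.CodingConstruct(
            name="X", cds="ATGAAATGAGGG", sites=(pq.StopCodonSite(3, "TGA", "S"),)
        )
        pf = pq.enumerate_skip_proteoform(construct, construct.site("S"))
        assert pf.ran_off_end


class TestFrameshiftProteoforms:
    def test_inframe_shift_to_next_stop_gives_zero_length_extension(self, toy_construct):
        (pf,) = pq.enumerate_frameshift_proteoforms(
            toy_construct, toy_construct.site("TGA3"), shifts={3}
        )
        assert pf.sequence == "MK"
        assert pf.zero_length_extension

    def test_shift_changes_frame_relative_to_skip(self):
        construct = pq.CodingConstruct(
            name="TOY2",
            cds="ATGAAATGACGGTAAGGG",
            sites=(pq.StopCodonSite(3, "TGA", "TGA3"),),
        )
        site = construct.site("TGA3")
        skip = pq.enumerate_skip_proteoform(construct, site)
        (fs1,) = pq.enumerate_frameshift_proteoforms(construct, site, shifts={1})
        assert skip.sequence == "MKR"
        assert fs1.sequence != skip.sequence

    def test_default_shift_set_produces_at_most_seven_variants(
        self, tga129_construct, tga129_site
    ):
        pfs = pq.enumerate_frameshift_proteoforms(tga129_construct, tga129_site)
        assert 0 < len(pfs) <= 7
        assert sorted(p.shift_k for p in pfs) == sorted({p.shift_k for p in pfs})

    def test_resume_beyond_sequence_skipped_with_warning(self, toy_construct):
        with pytest.warns(UserWarning, match="beyond"):
            pfs = pq.enumerate_frameshift_proteoforms(
                toy_construct, toy_construct.site("TGA3"), shifts={50}
            )
        assert pfs == []

    def test_nonpositive_shift_rejected(self, toy_construct):
        with pytest.raises(pq.InputError):
            pq.enumerate_frameshift_proteoforms(
                toy_construct, toy_construct.site("TGA3"), shifts={0}
            )


class TestDatabaseRoundTrip:
    def test_counts_headers_and_round_trip(self, tga129_database, tmp_path):
        path = tmp_path / "db.fasta"
        pq.write_database(tga129_database, path)
        text = path.read_text()
        assert text.count(">") == 21
        assert ">P53SBP|TGA129:sub:R\n" in text
        assert max(len(line) for line in text.splitlines()) <= 61
        back = pq.read_database(path)
        assert back == tga129_database

    def test_duplicate_ids_rejected(self, tga129_database, tmp_path):
        with pytest.raises(pq.ValidationError):
            pq.write_database(tga129_database + tga129_database[:1], tmp_path / "x.fasta")

    def test_empty_database_rejected(self, tmp_path):
        with pytest.raises(pq.InputError):
            pq.write_database([], tmp_path / "x.fasta")

    def test_enumeration_is_order_stable(self, tga129_construct, tga129_site):
        a = pq.enumerate_substitution_proteoforms(tga129_construct, tga129_site)
        b = pq.enumerate_substitution_proteoforms(tga129_construct, tga129_site)
        assert [p.id for p in a] == [p.id for p in b]
        assert [p.incorporated for p in a] == sorted(p.incorporated for p in a)
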