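"""MAF filtering, variant injection, digestion, matching, library algebra."""

import numpy as np
import pytest

from pavprot.gene_model import PavRecord
from pavprot.library_builder import (
    LibraryError,
    ORIGIN_ALT,
    ORIGIN_INVARIANT,
    ORIGIN_REF,
    build_libraries,
    digest,
    filter_pavs_by_maf,
    inject_variant,
    match_peptides,
)

from conftest import digest_oracle, random_protein


def pav(protein_id, pos, ref, alt, maf=0.3, rsid=None, chrom="chr1", gpos=None):
    gpos = gpos if gpos is not None else pos
    return PavRecord(f"{chrom}:{gpos}:A:G", protein_id, pos, ref, alt, maf, rsid)


def digest_set(peptides):
    return {(p.sequence, p.start_pos, p.missed_cleavages, p.met_excised) for p in peptides}


class TestMafFilter:
    @pytest.mark.parametrize(
        "maf,kept", [(0.12, True), (0.10, False), (0.08, False), (0.5, True), (0.0, False)]
    )
    def test_strict_threshold(self, maf, kept):
        record = PavRecord("chr1:1:A:G", "P", 5, "S", "G", maf)
        assert (filter_pavs_by_maf([record]) == [record]) is kept

    def test_out_of_range_maf_rejected(self):
        class Stub:
            variant_id = "x"
            maf = 0.7

        with pytest.raises(LibraryError, match="outside"):
            filter_pavs_by_maf([Stub()])


class TestInjectVariant:
    def test_direct_substitution(self):
        assert inject_variant("MKR", pav("P", 2, "K", "R")) == "MRR"

    def test_incretin_propeptide_example(self):
        # ten-residue peptide ALELA[S/G]QANR occupying positions 98-107
        seq = "M" + "A" * 96 + "ALELASQANR" + "CCC"
        out = inject_variant(seq, pav("P", 103, "S", "G"))
        assert out[97:107] == "ALELAGQANR"
        assert len(out) == len(seq)
        assert out[:97] == seq[:97] and out[107:] == seq[107:]

    def test_reference_mismatch_raises(self):
        with pytest.raises(LibraryError, match="mismatch"):
            inject_variant("MKR", pav("P", 2, "E", "D"))


class TestDigest:
    def test_single_fragment_at_min_length(self):
        entries = digest("ACDEFGH")
        assert digest_set(entries) == {("ACDEFGH", 1, 0, False)}

    def test_below_min_length_empty(self):
        assert digest("ACDEF") == []

    def test_missed_cleavage_enumeration(self):
        got = digest_set(digest("MKAAAAAARCCCCCCK"))
        assert ("AAAAAAR", 3, 0, False) in got
        assert ("AAAAAARCCCCCCK", 3, 1, False) in got
        assert got == digest_oracle("MKAAAAAARCCCCCCK")

    def test_met_excision_forms(self):
        got = digest_set(digest("MAAAAAAKDDDDDDR"))
        assert {("MAAAAAAK", 1, 0, False), ("AAAAAAK", 2, 0, True), ("DDDDDDR", 9, 0, False)} <= got
        assert got == digest_oracle("MAAAAAAKDDDDDDR")

    def test_non_standard_residue_rejected(self):
        with pytest.raises(LibraryError, match="BX"):
            digest("AAAAXXB")

    def test_oracle_equivalence_random_sequences(self, rng):
        for _ in range(300):
            seq = random_protein(rng)
            entries = digest(seq)
            got = digest_set(entries)
            assert len(got) == len(entries)  # no duplicate forms
            assert got == digest_oracle(seq)

    def test_no_proline_exception(self):
        # cleavage happens after K even when followed by P
        got = digest_set(digest("AAAAAAKPCCCCCR", met_excision=False))
        assert ("AAAAAAK", 1, 0, False) in got
        assert ("PCCCCCR", 8, 0, False) in got


class TestMatchPeptides:
    def test_simple_substitution_pairs(self):
        seq = "K" + "ALELASQANR" + "CCCCCCC"
        variant = pav("P", 7, "S", "G")
        ref_d = digest(seq, "P")
        alt_d = digest(inject_variant(seq, variant), "P")
        pairs = match_peptides(ref_d, alt_d, variant)
        simple = [p for p in pairs if p.match_class == "simple"]
        assert {(p.ref.sequence, p.alt.sequence) for p in simple} >= {
            ("ALELASQANR", "ALELAGQANR")
        }
        for p in simple:
            assert p.ref.start_pos == p.alt.start_pos
            assert len(p.ref.sequence) == len(p.alt.sequence)
            assert p.ref.sequence != p.alt.sequence

    def test_apob_style_single_residue_pair(self):
        seq = "MTSQCTLKDDDDDDR"
        variant = pav("P", 6, "T", "I")
        pairs = match_peptides(
            digest(seq, "P"), digest(inject_variant(seq, variant), "P"), variant
        )
        simple = {(p.ref.sequence, p.alt.sequence) for p in pairs if p.match_class == "simple"}
        assert ("TSQCTLK", "TSQCILK") in simple

    def test_k_to_r_at_cleavage_site_is_simple(self):
        # cleavage pattern preserved, only the C-terminal residue differs
        seq = "MAAAAAAKDDDDDDR"
        variant = pav("P", 8, "K", "R")
        pairs = match_peptides(
            digest(seq, "P"), digest(inject_variant(seq, variant), "P"), variant
        )
        simple = {(p.ref.sequence, p.alt.sequence) for p in pairs if p.match_class == "simple"}
        assert ("MAAAAAAK", "MAAAAAAR") in simple

    def test_new_cleavage_site_discards(self):
        # N -> K splits the peptide into fragments below 7 aa
        seq = "AAANAAAKCCCCCCK"
        variant = pav("P", 4, "N", "K")
        pairs = match_peptides(
            digest(seq, "P"), digest(inject_variant(seq, variant), "P"), variant
        )
        assert pairs  # the variant region is covered
        assert all(p.match_class == "discarded" for p in pairs)
        assert not any(p.match_class == "simple" for p in pairs)

    def test_variant_in_undetectable_region_warns(self, caplog):
        seq = "AAKCCKDDDDDDDR"  # first two fragments below min length
        variant = pav("P", 2, "A", "G")
        with caplog.at_level("WARNING"):
            pairs = match_peptides(
                digest(seq, "P"), digest(inject_variant(seq, variant), "P"), variant
            )
        assert pairs == []
        assert "undetectable" in caplog.text


class TestBuildLibraries:
    PROTEINS = {"P1": "MAAAAAAKDDDSDDRWWWWWWK", "P2": "MEEEEEEKFFFFFFR"}

    def test_zero_pavs_libraries_identical(self):
        libs = build_libraries(self.PROTEINS, [])
        assert digest_set(libs.reference) == digest_set(libs.pav_inclusive)
        assert digest_set(libs.reference) == digest_set(libs.pav_exclusive)
        assert libs.isoforms == {}

    def test_single_pav_set_algebra_matches_oracle(self):
        variant = pav("P1", 12, "S", "G", rsid="rs42")
        libs = build_libraries(self.PROTEINS, [variant])
        # oracle: digest both proteins independently
        oracle_ref = {
            (s, p, m, e, pid)
            for pid, seq in self.PROTEINS.items()
            for (s, p, m, e) in digest_oracle(seq)
        }
        got_ref = {
            (p.sequence, p.start_pos, p.missed_cleavages, p.met_excised, p.protein_id)
            for p in libs.reference
        }
        assert got_ref == oracle_ref

        overlapping = {
            t for t in digest_oracle(self.PROTEINS["P1"]) if t[1] <= 12 <= t[1] + len(t[0]) - 1
        }
        alt_simple = {p for p in libs.pav_inclusive if p.origin == ORIGIN_ALT}
        # counts fixed by the digestion oracle
        assert len(libs.pav_inclusive) == len(libs.reference) + len(alt_simple)
        assert len(libs.pav_exclusive) == len(libs.reference) - len(overlapping)
        assert len(alt_simple) == len(overlapping)  # pure substitution: all simple
        assert list(libs.isoforms) == ["P1_rs42"]
        assert libs.isoforms["P1_rs42"][11] == "G"

    def test_two_pavs_one_protein_independent_isoforms(self):
        v1 = PavRecord("chr1:10:A:G", "P1", 4, "A", "G", 0.3, "rs1")
        v2 = PavRecord("chr1:40:A:G", "P1", 12, "S", "T", 0.3, "rs2")
        libs = build_libraries(self.PROTEINS, [v1, v2])
        assert set(libs.isoforms) == {"P1_rs1", "P1_rs2"}
        for name, seq in libs.isoforms.items():
            diffs = [i for i, (a, b) in enumerate(zip(seq, self.PROTEINS["P1"])) if a != b]
            assert len(diffs) == 1  # one substitution per isoform

    def test_missing_rsid_falls_back_to_variant_id(self):
        variant = PavRecord("chr1:40:A:G", "P1", 12, "S", "T", 0.3, None)
        libs = build_libraries(self.PROTEINS, [variant])
        assert list(libs.isoforms) == ["P1_chr1:40:A:G"]

    def test_duplicate_variant_id_rejected(self):
        v = PavRecord("chr1:40:A:G", "P1", 12, "S", "T", 0.3)
        with pytest.raises(LibraryError, match="duplicate"):
            build_libraries(self.PROTEINS, [v, v])

    def test_exclusive_library_has_no_allele_peptides(self):
        variant = pav("P1", 12, "S", "G")
        libs = build_libraries(self.PROTEINS, [variant])
        assert all(p.origin == ORIGIN_INVARIANT for p in libs.pav_exclusive)
        assert not any(p.overlaps(12) and p.protein_id == "P1" for p in libs.pav_exclusive)


class TestLibraryInvariants:
    def test_subset_relations_on_random_models(self):
        from pavprot.synthetic_data import SimConfig, simulate_gene_model

        for seed in range(15):
            model = simulate_gene_model(SimConfig(seed=seed, n_proteins=4, n_pavs=3))
            libs = build_libraries(model.protein_seqs, model.pavs)
            ref = {(p.sequence, p.protein_id) for p in libs.reference}
            incl = {(p.sequence, p.protein_id) for p in libs.pav_inclusive}
            excl = {(p.sequence, p.protein_id) for p in libs.pav_exclusive}
            assert excl <= ref <= incl
            positions = {(p.protein_id, p.protein_pos) for p in model.pavs}
            for p in libs.pav_exclusive:
                assert not any(
                    p.protein_id == pid and p.overlaps(pos) for pid, pos in positions
                )

    def test_simple_pairs_differ_at_one_position(self):
        from pavprot.synthetic_data import SimConfig, simulate_gene_model

        model = simulate_gene_model(SimConfig(seed=3, n_proteins=4, n_pavs=4))
        libs = build_libraries(model.protein_seqs, model.pavs)
        checked = 0
        for pair in libs.matches:
            if pair.match_class != "simple":
                continue
            assert pair.ref.start_pos == pair.alt.start_pos
            assert len(pair.ref.sequence) == len(pair.alt.sequence)
            ndiff = sum(a != b for a, b in zip(pair.ref.sequence, pair.alt.sequence))
            assert ndiff == 1  # simulated substitutions never touch K/R boundaries
            checked += 1
        assert checked > 0
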