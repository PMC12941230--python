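"""HGVS parsing, sequence editing, translation and consequence arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcskit import (
    CodingSequence,
    apply_variant,
    classify_splice,
    consequence,
    fs_stop_position,
    parse_c,
    translate,
)
from tcskit.errors import (
    NotApplicableError,
    ParseError,
    ReferenceMismatchError,
    ValidationError,
)
from tcskit.genome_model import build_transcript
from tcskit.hgvs import parse_p
from tcskit.simulate import random_cds

from conftest import oracle_translate


class TestParseC:
    def test_insertion_between_flanks(self):
        v = parse_c("c.226_227insC")
        assert (v.kind, v.pos1, v.pos2, v.alt) == ("insertion", 226, 227, "C")

    def test_two_base_deletion_with_ref(self):
        v = parse_c("c.290_291delAG")
        assert (v.kind, v.pos1, v.pos2, v.ref) == ("deletion", 290, 291, "AG")

    def test_intronic_donor_substitution(self):
        v = parse_c("c.4345+1G>A")
        assert (v.kind, v.pos1, v.offset, v.ref, v.alt) == (
            "intronic_substitution",
            4345,
            1,
            "G",
            "A",
        )

    def test_whitespace_tolerated(self):
        assert parse_c("c.4345 + 1 G > A") == parse_c("c.4345+1G>A")

    def test_transcript_prefix_recorded(self):
        v = parse_c("NM_015972.4:c.290_291delAG")
        assert v.transcript_id == "NM_015972.4"

    @pytest.mark.parametrize(
        "bad", ["g.100A>T", "c.12insC_13", "c.10_12insC", "c.5A>", "c.1_3delAGXT"]
    )
    def test_unparseable_strings_rejected(self, bad):
        with pytest.raises(ParseError):
            parse_c(bad)


class TestApplyVariant:
    def test_insertion_edit(self, toy_cds):
        assert apply_variant(toy_cds, parse_c("c.6_7insC")) == "ATGAAACGTTGACTAA"

    def test_out_of_range_rejected(self, toy_cds):
        with pytest.raises(ValidationError):
            apply_variant(toy_cds, parse_c("c.290_291delAG"))

    def test_reference_disagreement_names_position(self, toy_cds):
        with pytest.raises(ReferenceMismatchError, match="c.4"):
            apply_variant(toy_cds, parse_c("c.4_5delAG"))

    def test_intronic_variant_not_applicable(self, toy_cds):
        with pytest.raises(NotApplicableError):
            apply_variant(toy_cds, parse_c("c.4+1G>A"))

    def test_substitution_and_deletion_edits(self, toy_cds):
        assert apply_variant(toy_cds, parse_c("c.5A>G")) == "ATGAGAGTTGACTAA"
        assert apply_variant(toy_cds, parse_c("c.4_6delAAA")) == "ATGGTTGACTAA"


class TestTranslate:
    def test_translates_to_first_stop(self):
        assert translate("ATGAAAGTTGACTAA") == ("MKVD", True)

    def test_immediate_stop(self):
        assert translate("ATGTAA") == ("M", True)

    def test_missing_stop_flagged(self):
        assert translate("ATGAAA") == ("MK", False)


class TestConsequence:
    def test_single_base_insertion_frameshift(self, toy_cds):
        c = consequence(toy_cds, parse_c("c.6_7insC"))
        assert c.kind == "frameshift"
        assert c.hgvs_p == "p.Val3Argfs*2"
        assert (c.first_affected_residue, c.ter_offset, c.stop_position) == (3, 2, 4)

    def test_missense_substitution(self, toy_cds):
        c = consequence(toy_cds, parse_c("c.5A>G"))
        assert (c.kind, c.hgvs_p) == ("missense", "p.Lys2Arg")

    def test_identity_substitution_is_synonymous(self, toy_cds):
        c = consequence(toy_cds, parse_c("c.5A>A"))
        assert c.kind == "synonymous"

    def test_nonsense_substitution(self):
        cds = CodingSequence("x", "ATGAAATGGGACTAA")  # M K W D *
        c = consequence(cds, parse_c("c.8G>A"))  # TGG -> TAG
        assert (c.kind, c.stop_position, c.hgvs_p) == ("nonsense", 3, "p.Trp3Ter")

    def test_stop_loss_reports_no_stop_found(self, toy_cds):
        c = consequence(toy_cds, parse_c("c.13T>C"))  # TAA -> CAA
        assert c.kind == "no_stop_found"

    def test_frameshift_without_downstream_stop(self):
        cds = CodingSequence("x", "ATGAAAAAAAAATAA")
        c = consequence(cds, parse_c("c.4_5delAA"))
        assert c.kind == "no_stop_found"
        assert c.hgvs_p.endswith("fs*?")

    def test_two_base_deletion_acts_as_plus_one_frameshift(self):
        # length change -2 == +1 (mod 3): same frame offset the fs*N engine uses
        v = parse_c("c.4_5delAA")
        assert v.length_change % 3 == 1

    def test_roundtrip_through_p_notation(self, toy_cds):
        c = consequence(toy_cds, parse_c("c.6_7insC"))
        again = parse_p(c.hgvs_p)
        assert again.kind == c.kind
        assert again.first_affected_residue == c.first_affected_residue
        assert again.ter_offset == c.ter_offset
        assert again.stop_position == c.stop_position
        assert fs_stop_position(c.hgvs_p).stop_position == c.stop_position


class TestFsStopPosition:
    @pytest.mark.parametrize(
        "p, stop",
        [
            ("p.Arg77Ilefs*97", 173),
            ("p.Gly99Ilefs*2", 100),
            ("p.Xaa10Yaafs*2", 11),
        ],
    )
    def test_stop_arithmetic(self, p, stop):
        res = fs_stop_position(p)
        assert res.stop_position == stop
        assert res.residues_before_stop == stop - 1

    def test_undefined_stop(self):
        assert fs_stop_position("p.Arg77Ilefs*?").stop_position is None

    def test_non_frameshift_rejected(self):
        with pytest.raises(ParseError):
            fs_stop_position("p.Lys2Arg")


class TestClassifySplice:
    def test_donor_at_internal_exon_end(self):
        t = build_transcript(
            [
                {"index": 1, "chrom": "c5", "start": 1000, "end": 5345},
                {"index": 2, "chrom": "c5", "start": 6000, "end": 6255},
            ]
        )
        assert t.exons[0].cdna_end == 4345
        sc = classify_splice(parse_c("c.4345+1G>A"), t)
        assert (sc.site, sc.offset, sc.canonical) == ("donor", 1, True)

    def test_acceptor_at_exon3_start(self, polr1c):
        sc = classify_splice(parse_c("c.163-2A>G"), polr1c)
        assert (sc.site, sc.canonical) == ("acceptor", True)

    def test_non_canonical_donor_offset(self, polr1c):
        sc = classify_splice(parse_c("c.90+6T>C"), polr1c)
        assert (sc.site, sc.offset, sc.canonical) == ("donor", 6, False)

    def test_non_boundary_position_rejected(self, polr1c):
        with pytest.raises(ValidationError):
            classify_splice(parse_c("c.50+1G>A"), polr1c)


class TestRandomisedProperties:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.data())
    def test_substitutions_preserve_length_unless_stop_changes(self, seed, data):
        cds = random_cds(12, seed)
        pos = data.draw(st.integers(min_value=1, max_value=len(cds.seq)))
        alt = data.draw(st.sampled_from("ACGT"))
        v = parse_c(f"c.{pos}{cds.seq[pos - 1]}>{alt}")
        c = consequence(cds, v)
        if c.kind in ("synonymous", "missense"):
            mut_prot, stop = translate(apply_variant(cds, v))
            assert stop and len(mut_prot) == len(cds.protein())
        else:
            assert c.kind in ("nonsense", "no_stop_found")

    def test_small_indels_match_translation_oracle(self):
        rng = np.random.default_rng(42)
        for case in range(150):
            cds = random_cds(int(rng.integers(4, 40)), int(rng.integers(1e6)))
            n = len(cds.seq)
            if rng.random() < 0.5:
                size = int(rng.integers(1, 3))
                pos = int(rng.integers(1, n))
                ins = "".join(rng.choice(list("ACGT"), size))
                hgvs = f"c.{pos}_{pos + 1}ins{ins}"
                dlen = size
            else:
                size = int(rng.integers(1, 3))
                pos = int(rng.integers(1, n - size + 1))
                hgvs = f"c.{pos}_{pos + size - 1}del" if size > 1 else f"c.{pos}del"
                dlen = -size
            v = parse_c(hgvs)
            c = consequence(cds, v)
            mut = apply_variant(cds, v)
            oracle_prot, oracle_stop = oracle_translate(mut)
            wt_prot, _ = oracle_translate(cds.seq)
            if oracle_stop and oracle_prot == wt_prot:
                # indel in/near the stop codon reformed an identical product
                assert c.kind == "synonymous"
                continue
            assert (dlen % 3 != 0) == (
                c.kind in ("frameshift", "nonsense", "no_stop_found")
            )
            if c.kind in ("frameshift", "nonsense"):
                assert c.stop_position == len(oracle_prot) + 1
                assert oracle_stop
            if c.kind == "no_stop_found":
                assert not oracle_stop
            if c.kind == "frameshift":
                assert fs_stop_position(c.hgvs_p).stop_position == c.stop_position
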