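import pytest

from cutfuse import (
    CutModel,
    GuideSpec,
    IndelToken,
    NucSeq,
    RepairMode,
    cut_site,
    enumerate_repair_products,
    explain_indel,
    fill_in_insertion,
    find_guide_sites,
    predict_junctions,
)
from cutfuse.repair import NHEJ_ERROR, diff_single_indel

TOY_PROTO = "ACGTACGTACGTACGGGGCA"

ALL_MODES = (RepairMode.BLUNT_LIGATION, RepairMode.FILL_IN, RepairMode.RESECTION)


@pytest.fixture(scope="module")
def toy_site():
    ref = NucSeq(TOY_PROTO + "TGG")
    (site,) = find_guide_sites(ref, GuideSpec("toy", TOY_PROTO), {"NGG"})
    return site, ref


class TestFillInInsertion:
    def test_blunt_cut_inserts_nothing(self, toy_site):
        site, ref = toy_site
        assert fill_in_insertion(cut_site(site, CutModel(3, 3), ref)) is None

    def test_fourth_nt_duplication(self, toy_site):
        site, ref = toy_site
        tok = fill_in_insertion(cut_site(site, CutModel(3, 4), ref))
        assert tok.token == "+G"

    def test_fourth_and_fifth_nt_duplication(self, toy_site):
        site, ref = toy_site
        tok = fill_in_insertion(cut_site(site, CutModel(3, 5), ref))
        assert tok.token == "+GG"

    def test_insertion_is_tandem_duplication_of_overhang(self, locus, locus_sites):
        for site in locus_sites:
            for off in range(4, 9):
                cs = cut_site(site, CutModel(3, off), locus.sequence)
                tok = fill_in_insertion(cs)
                assert tok.bases == cs.overhang
                assert len(tok) == off - 3 <= 5


class TestDiffSingleIndel:
    def test_identity(self):
        assert diff_single_indel("ACGT", "ACGT") is None

    def test_insertion_left_normalised_in_homopolymer(self):
        tok = diff_single_indel("CCAAAT", "CCAAAAT")
        assert tok.token == "+A"
        assert tok.position == 2  # leftmost placement, anchored on the C

    def test_deletion(self):
        tok = diff_single_indel("ACGTTTA", "ACGTTA")
        assert tok.token == "-T"
        assert tok.position == 3

    def test_non_indel_difference_rejected(self):
        with pytest.raises(ValueError):
            diff_single_indel("ACGT", "AGGT")
        with pytest.raises(ValueError):
            diff_single_indel("ACGTAC", "TTACGT")


class TestEnumerateRepairProducts:
    def test_blunt_only_gives_single_precise_product(self, locus, locus_sites):
        site_a, site_b = locus_sites
        prods = enumerate_repair_products(
            locus.sequence, site_a, site_b, "deletion", offset_range=[3],
            modes=[RepairMode.BLUNT_LIGATION],
        )
        assert len(prods) == 1
        assert prods[0].indel is None

    def test_one_staggered_offset_adds_fill_in_insertion(self, locus, locus_sites):
        # site A of the locus lies on the minus strand, so its filled-in
        # overhang is retained by the upstream flank and appears as a +1
        # insertion at the deletion junction
        site_a, site_b = locus_sites
        prods = enumerate_repair_products(
            locus.sequence, site_a, site_b, "deletion",
            offset_range=[3, 4],
            modes=[RepairMode.BLUNT_LIGATION, RepairMode.FILL_IN],
        )
        tokens = {p.indel.token if p.indel else None for p in prods}
        assert None in tokens
        expected = fill_in_insertion(
            cut_site(site_a, CutModel(3, 4), locus.sequence)
        )
        inserted = [t for t in tokens if t and t.startswith("+") and len(t) == 2]
        assert len(inserted) == 1
        # the inserted base is the overhang base (possibly read on the
        # opposite strand depending on site orientation); here site A is on
        # the minus strand so the junction top strand shows its complement
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        assert inserted[0][1] == comp[expected.bases]

    def test_resection_deletes_the_fourth_nt_upstream_of_pam(self, locus, locus_sites):
        site_a, site_b = locus_sites
        prods = enumerate_repair_products(
            locus.sequence, site_a, site_b, "deletion",
            offset_range=[3, 4],
            modes=[RepairMode.BLUNT_LIGATION, RepairMode.RESECTION],
        )
        # resecting sgB's 1-nt overhang removes the 4th nt upstream of its
        # PAM; the junction top strand (sgB sits on the minus strand) shows
        # the complement of the overhang base
        cs = cut_site(site_b, CutModel(3, 4), locus.sequence)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        dels = [
            p for p in prods if p.indel and p.indel.token == "-" + comp[cs.overhang]
        ]
        assert dels, [p.indel for p in prods]
        assert any(
            m.mode is RepairMode.RESECTION
            and m.model_b.protospacer_strand_offset == 4
            for p in dels
            for m in p.mechanisms
        )

    def test_precise_product_always_present(self, locus, locus_sites):
        site_a, site_b = locus_sites
        for kind in ("deletion", "inversion"):
            prods = enumerate_repair_products(
                locus.sequence, site_a, site_b, kind
            )
            precise = [p for p in prods if p.indel is None]
            assert len(precise) == len(set(p.label for p in prods))
            for p in precise:
                assert any(
                    m.mode is RepairMode.BLUNT_LIGATION for m in p.mechanisms
                )

    def test_product_count_bounded_by_mechanism_space(self, locus, locus_sites):
        site_a, site_b = locus_sites
        offsets = [3, 4, 5]
        prods = enumerate_repair_products(
            locus.sequence, site_a, site_b, "deletion", offset_range=offsets,
            modes=ALL_MODES,
        )
        n_mech = sum(len(p.mechanisms) for p in prods)
        assert len(prods) <= n_mech
        # every valid (offset_a, offset_b, mode) combination appears exactly once
        expected = 0
        for oa in offsets:
            for ob in offsets:
                for mode in ALL_MODES:
                    if mode is RepairMode.BLUNT_LIGATION and (oa != 3 or ob != 3):
                        continue
                    expected += 1
        assert n_mech == expected

    def test_variant_matches_its_indel_against_canonical(self, locus, locus_sites):
        site_a, site_b = locus_sites
        for kind in ("deletion", "inversion"):
            prods = enumerate_repair_products(
                locus.sequence, site_a, site_b, kind, flank=30
            )
            canon = {
                p.label: p.junction_variant.symbols
                for p in prods
                if p.indel is None
            }
            for p in prods:
                tok = diff_single_indel(canon[p.label], p.junction_variant.symbols)
                if p.indel is None:
                    assert tok is None
                else:
                    assert tok.token == p.indel.token
                    assert tok.position == p.indel.position

    def test_fill_in_insertion_length_bounds(self, locus, locus_sites):
        # each filled-in overhang contributes at most 5 nt (offset cap 8
        # minus the fixed 3-nt target-strand offset); a junction joining two
        # filled-in ends can show at most 10
        site_a, site_b = locus_sites
        prods = enumerate_repair_products(
            locus.sequence, site_a, site_b, "deletion",
            modes=[RepairMode.FILL_IN],
        )
        for p in prods:
            if p.indel is None or not p.indel.is_insertion:
                continue
            assert len(p.indel) <= 10
            for m in p.mechanisms:
                if m.model_a.is_blunt or m.model_b.is_blunt:
                    assert len(p.indel) <= 5


class TestExplainIndel:
    def _round_trip(self, locus, site_a, site_b, kind):
        prods = enumerate_repair_products(locus.sequence, site_a, site_b, kind)
        jmap = {
            j.label: j
            for j in predict_junctions(locus.sequence, site_a, site_b, kind)
        }
        for p in prods:
            j = jmap[p.label]
            tok = p.indel
            if tok is not None and tok.position is not None:
                tok = IndelToken(tok.token, tok.position + j.fusion_point - 30, tok.ref_base)
            mechs = explain_indel(tok, j, locus.sequence, site_a, site_b)
            for m in p.mechanisms:
                assert m in mechs, (p.label, p.indel, m)

    def test_round_trip_every_product_recovers_its_mechanisms(self, locus, locus_sites):
        site_a, site_b = locus_sites
        self._round_trip(locus, *locus_sites, "deletion")
        self._round_trip(locus, *locus_sites, "inversion")

    def test_precise_observation_explained_by_blunt_ligation(self, locus, locus_sites):
        site_a, site_b = locus_sites
        (j,) = predict_junctions(locus.sequence, site_a, site_b, "deletion")
        mechs = explain_indel(None, j, locus.sequence, site_a, site_b)
        assert any(
            m != NHEJ_ERROR
            and m.mode is RepairMode.BLUNT_LIGATION
            and m.model_a.is_blunt
            and m.model_b.is_blunt
            for m in mechs
        )
        assert NHEJ_ERROR not in mechs

    def test_unreachable_insertion_gets_only_nhej(self, locus, locus_sites):
        site_a, site_b = locus_sites
        (j,) = predict_junctions(locus.sequence, site_a, site_b, "deletion")
        # find a 1-nt insertion no overhang can produce at this junction
        reachable = {
            p.indel.token
            for p in enumerate_repair_products(
                locus.sequence, site_a, site_b, "deletion"
            )
            if p.indel
        }
        candidates = [f"+{b}" for b in "ACGT" if f"+{b}" not in reachable]
        assert candidates, "toy junction exhausts all four 1-nt insertions"
        mechs = explain_indel(
            IndelToken(candidates[0]), j, locus.sequence, site_a, site_b
        )
        assert mechs == [NHEJ_ERROR]

    def test_mechanistic_explanations_precede_nhej(self, locus, locus_sites):
        site_a, site_b = locus_sites
        prods = enumerate_repair_products(
            locus.sequence, site_a, site_b, "deletion"
        )
        jmap = {
            j.label: j
            for j in predict_junctions(locus.sequence, site_a, site_b, "deletion")
        }
        for p in prods:
            if p.indel is None or len(p.indel) > 2:
                continue
            j = jmap[p.label]
            tok = IndelToken(
                p.indel.token, p.indel.position + j.fusion_point - 30, p.indel.ref_base
            )
            mechs = explain_indel(tok, j, locus.sequence, site_a, site_b)
            assert mechs[-1] == NHEJ_ERROR
            assert all(m != NHEJ_ERROR for m in mechs[:-1])

    def test_observation_outside_fusion_window_rejected(self, locus, locus_sites):
        site_a, site_b = locus_sites
        (j,) = predict_junctions(locus.sequence, site_a, site_b, "deletion")
        far = IndelToken("+G", position=5)
        with pytest.raises(ValueError, match="outside the fusion"):
            explain_indel(far, j, locus.sequence, site_a, site_b)
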