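import math
import random

import pytest

from cutfuse import (
    IndelObservation,
    IndelToken,
    NucSeq,
    Scoring,
    align_reads,
    align_to_junction,
    build_report,
    classify_perfect_fusion,
    filter_observations,
    indel_significance,
    pileup_indels,
)
from cutfuse.quant import SpectrumReport, recovered_spectrum

from conftest import glocal_affine_oracle, make_junction, random_dna


class TestAlignToJunction:
    def test_exact_window_is_all_match(self):
        rng = random.Random(0)
        ref = random_dna(rng, 120)
        j = make_junction(ref)
        read = ref[20:80]
        a = align_to_junction(read, j)
        assert a.mapped and a.identity == 1.0
        assert (a.ref_start, a.ref_end) == (20, 80)
        assert a.events == () and a.mismatches == ()
        assert a.cigar() == "60M"

    def test_single_deletion_at_fusion(self):
        rng = random.Random(1)
        ref = random_dna(rng, 120)
        j = make_junction(ref)
        f = j.fusion_point
        read = ref[f - 30 : f] + ref[f + 1 : f + 30]  # one base deleted
        a = align_to_junction(read, j)
        assert a.mapped
        assert len(a.events) == 1
        pos, kind, bases = a.events[0]
        assert kind == "-" and len(bases) == 1

    def test_low_identity_read_unmapped(self):
        rng = random.Random(2)
        ref = random_dna(rng, 120)
        j = make_junction(ref)
        garbage = "".join(
            {"A": "C", "C": "A", "G": "T", "T": "G"}[b] for b in ref[30:90]
        )
        a = align_to_junction(garbage, j)
        assert not a.mapped

    def test_short_read_rejected(self):
        j = make_junction("ACGT" * 20)
        with pytest.raises(ValueError):
            align_to_junction("ACGTACGT", j)

    @pytest.mark.parametrize("case_seed", range(40))
    def test_score_matches_brute_force_oracle(self, case_seed):
        """Glocal score equals an independent affine DP on small instances."""
        rng = random.Random(case_seed)
        ref = random_dna(rng, rng.randrange(40, 61))
        mode = rng.choice(["window", "mutated", "indel", "random"])
        if mode == "window":
            i = rng.randrange(0, len(ref) - 30)
            read = ref[i : i + 30]
        elif mode == "mutated":
            i = rng.randrange(0, len(ref) - 30)
            r = list(ref[i : i + 30])
            for _ in range(rng.randrange(1, 4)):
                p = rng.randrange(30)
                r[p] = rng.choice("ACGT")
            read = "".join(r)
        elif mode == "indel":
            i = rng.randrange(0, len(ref) - 32)
            r = ref[i : i + 32]
            p = rng.randrange(5, 25)
            read = (r[:p] + r[p + 2 :])[:30]
        else:
            read = random_dna(rng, 30)
        j = make_junction(ref)
        a = align_to_junction(read, j, identity_floor=0.0)
        expect = glocal_affine_oracle(ref, read)
        assert a.score == pytest.approx(expect)


class TestPileupIndels:
    def _simple_alignments(self, j, n_perfect, n_ins, token="+G"):
        ref = j.sequence.symbols
        f = j.fusion_point
        reads = [(f"p{i}", ref[f - 30 : f + 30]) for i in range(n_perfect)]
        var = ref[f - 30 : f] + token[1:] + ref[f : f + 30]
        reads += [(f"v{i}", var) for i in range(n_ins)]
        return align_reads(reads, j)

    def test_constructed_counts(self):
        rng = random.Random(3)
        # avoid homopolymer shift at the fusion for exact position asserts
        ref = random_dna(rng, 200)
        j = make_junction(ref)
        alns = self._simple_alignments(j, 80, 20, "+G")
        obs = pileup_indels(alns, j)
        assert len(obs) == 1
        assert obs[0].var_reads == 20
        assert obs[0].ref_reads == 80
        assert obs[0].var_freq == pytest.approx(0.20)
        assert obs[0].indel.token == "+G"

    def test_homopolymer_insertion_aggregates_leftmost(self):
        ref = "ACGTACGTAC" + "CCTAAAAGGC" + "ACGTACGTAC" * 4
        j = make_junction(ref, fusion=16)  # inside the A-run
        f = j.fusion_point
        reads = []
        # same molecule: an extra A placed at different offsets in the run
        for shift in range(3):
            pos = 13 + shift
            var = ref[:pos] + "A" + ref[pos:]
            reads.append((f"r{shift}", var[f - 14 : f + 30]))
        alns = align_reads(reads, j)
        obs = pileup_indels(alns, j)
        assert len(obs) == 1  # single aggregated row at the leftmost anchor
        assert obs[0].var_reads == 3
        assert obs[0].indel.token == "+A"
        assert ref[obs[0].indel.position] == "A"  # anchored before the run

    def test_non_spanning_reads_excluded(self):
        rng = random.Random(4)
        ref = random_dna(rng, 200)
        j = make_junction(ref)
        f = j.fusion_point
        # read ends 5 nt past the fusion: below the 10-nt spanning minimum
        reads = [("short", ref[f - 45 : f + 5]), ("ok", ref[f - 30 : f + 30])]
        alns = align_reads(reads, j)
        obs = pileup_indels(alns, j)
        assert obs == []  # no indels at all
        rep = build_report(alns, j)
        assert rep.n_spanning == 1

    def test_no_mapped_reads_gives_empty_report(self):
        rng = random.Random(5)
        ref = random_dna(rng, 200)
        j = make_junction(ref)
        garbage = [("g", random_dna(rng, 60))]
        rep = build_report(align_reads(garbage, j), j)
        assert rep.mapped_fraction == 0.0
        assert rep.observations == ()

    def test_report_invariant_to_read_order(self):
        rng = random.Random(6)
        ref = random_dna(rng, 200)
        j = make_junction(ref)
        alns = self._simple_alignments(j, 30, 10, "+T")
        rev = list(reversed(alns))
        a = build_report(alns, j)
        b = build_report(rev, j)
        assert a.observations == b.observations
        assert a.perfect_fraction == b.perfect_fraction


class TestIndelSignificance:
    def _obs(self, var, total):
        return IndelObservation(
            indel=IndelToken("+G", 10, "A"), ref_reads=total - var, var_reads=var
        )

    def test_zero_support_not_significant(self):
        assert indel_significance(self._obs(0, 100), 0.01) == pytest.approx(1.0)

    def test_full_support_extreme(self):
        p = indel_significance(self._obs(10, 10), 0.01)
        assert p == pytest.approx(0.01**10, rel=1e-9)

    def test_exact_binomial_tail(self):
        # independent oracle: explicit tail sum with math.comb
        e = 0.01
        expect = sum(
            math.comb(50, k) * e**k * (1 - e) ** (50 - k) for k in range(5, 51)
        )
        assert indel_significance(self._obs(5, 50), e) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(1.4569e-4, rel=1e-3)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            indel_significance(self._obs(0, 0))


class TestPerfectFusion:
    def test_error_free_reads_are_perfect(self):
        rng = random.Random(7)
        ref = random_dna(rng, 200)
        j = make_junction(ref)
        f = j.fusion_point
        reads = [(f"r{i}", ref[f - 40 + i : f + 20 + i]) for i in range(10)]
        assert classify_perfect_fusion(align_reads(reads, j), j) == 1.0

    def test_fractional_perfect(self):
        rng = random.Random(8)
        ref = random_dna(rng, 200)
        j = make_junction(ref)
        f = j.fusion_point
        perfect = [(f"p{i}", ref[f - 30 : f + 30]) for i in range(22)]
        var = ref[f - 30 : f] + "G" + ref[f : f + 30]
        others = [(f"v{i}", var) for i in range(78)]
        frac = classify_perfect_fusion(align_reads(perfect + others, j), j)
        assert frac == pytest.approx(0.22)

    def test_variant_only_reads_give_zero(self):
        rng = random.Random(9)
        ref = random_dna(rng, 200)
        j = make_junction(ref)
        f = j.fusion_point
        var = ref[f - 30 : f] + "GG" + ref[f : f + 30]
        frac = classify_perfect_fusion(align_reads([("v", var)], j), j)
        assert frac == 0.0


class TestFilterObservations:
    def _report(self, counts):
        obs = tuple(
            IndelObservation(
                indel=IndelToken(tok, 100 + i, "A"),
                ref_reads=1000 - v,
                var_reads=v,
                p_value=0.0,
            )
            for i, (tok, v) in enumerate(counts)
        )
        return SpectrumReport(
            sample="s",
            replicate="1",
            junction_label="x",
            observations=obs,
            perfect_fraction=0.5,
            mapped_fraction=1.0,
            n_reads=1000,
            n_mapped=1000,
            n_spanning=1000,
        )

    def test_low_frequency_dropped(self):
        rep = self._report([("+G", 5)])  # var_freq 0.005
        out = filter_observations(rep, min_freq=0.01, min_var_reads=2)
        assert out.observations == ()

    def test_zero_thresholds_identity(self):
        rep = self._report([("+G", 5), ("-A", 1)])
        out = filter_observations(rep, 0, 0)
        assert out.observations == rep.observations

    def test_representation_renormalised(self):
        rep = self._report([("+G", 60), ("+GG", 30), ("-A", 10)])
        out = filter_observations(rep, min_freq=0.02, min_var_reads=2)
        rep_map = out.indel_representation
        assert rep_map["+G"] == pytest.approx(2 / 3)
        assert rep_map["+GG"] == pytest.approx(1 / 3)
        assert "-A" not in rep_map


def test_recovered_spectrum_sums_to_one():
    rng = random.Random(10)
    ref = random_dna(rng, 200)
    j = make_junction(ref)
    f = j.fusion_point
    reads = [(f"p{i}", ref[f - 30 : f + 30]) for i in range(6)]
    var = ref[f - 30 : f] + "G" + ref[f : f + 30]
    reads += [(f"v{i}", var) for i in range(4)]
    spec = recovered_spectrum(align_reads(reads, j), j)
    assert sum(spec.values()) == pytest.approx(1.0)
    assert spec[None] == pytest.approx(0.6)
    assert spec["+G"] == pytest.approx(0.4)
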