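"""Staggered Cas9 cuts and the junction indels they explain.

Cas9 cuts the sgRNA-complementary strand 3 nt upstream of the PAM but can
cut the other strand 3-8 nt upstream, leaving a 5' overhang.  Filling in
the overhang before ligation duplicates it (a templated insertion);
resecting it trims junction bases.  This example enumerates every junction
variant reachable from that mechanism space and then inverts the map for
one observed indel.
"""

from cutfuse import (
    CutModel,
    NHEJ_ERROR,
    cut_site,
    enumerate_repair_products,
    explain_indel,
    fill_in_insertion,
    make_fixture,
    predict_junctions,
)

fx = make_fixture("two_cut_locus", scale=3000, seed=7)
site_a = fx.guide_sites("sgA")[0]
site_b = fx.guide_sites("sgB")[0]

print("fill-in insertions predicted at site A (overhang duplication):")
for off in range(3, 7):
    cs = cut_site(site_a, CutModel(3, off), fx.sequence)
    tok = fill_in_insertion(cs)
    print(f"  non-complementary strand cut {off} nt upstream of PAM -> "
          f"{tok.token if tok else 'blunt, no insertion'}")

prods = enumerate_repair_products(fx.sequence, site_a, site_b, "deletion")
print(f"\n{len(prods)} distinct deletion-junction variants from offsets 3-8:")
for p in prods[:8]:
    tok = p.indel.token if p.indel else "precise"
    print(f"  {tok:>8s}  ({len(p.mechanisms)} generating mechanism(s))")

(jr,) = predict_junctions(fx.sequence, site_a, site_b, "deletion")
obs = next(p.indel for p in prods if p.indel and len(p.indel) == 1 and p.indel.is_insertion)
from cutfuse import IndelToken

anchored = IndelToken(obs.token, obs.position + jr.fusion_point - 30, obs.ref_base)
print(f"\nmechanisms consistent with an observed {obs.token} at the junction:")
for m in explain_indel(anchored, jr, fx.sequence, site_a, site_b):
    if m == NHEJ_ERROR:
        print("  generic NHEJ error (indistinguishable from alternative cutting)")
    else:
        print(f"  cut offsets A={m.model_a.protospacer_strand_offset} "
              f"B={m.model_b.protospacer_strand_offset}, {m.mode.value}")
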