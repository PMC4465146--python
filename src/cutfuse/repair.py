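"""Mechanistic enumeration of fusion-junction repair products.

The staggered-cleavage model: Cas9 always cuts the sgRNA-complementary
strand 3 nt upstream of the PAM, but may cut the non-complementary
(PAM-bearing) strand 3-8 nt upstream, leaving a 0-5 nt 5' overhang.  Before
two break ends are ligated, each 5' overhang is either filled in by a
polymerase (the recessed 3' end is extended, so the overhang sequence ends
up duplicated across the junction -- a templated insertion) or resected (the
overhang is trimmed, producing a small deletion).  Blunt ligation of two
canonical (3,3) cuts reproduces the predicted junction exactly -- precise
ligation.

This module enumerates every junction sequence variant reachable from a
chosen offset range and set of repair modes, and inverts the map: given an
observed indel at a fusion junction, list every (cut offsets, repair mode)
mechanism that would produce it.  Small indels can equally arise from
ordinary NHEJ errors; the two explanations are not distinguishable from
sequence alone, so both are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

from .guides import CutModel, CutSite, GuideSite, cut_site
from .junctions import (
    DELETION,
    INVERSION,
    JunctionRef,
    LABEL_DELETION,
    LABEL_INV_3P,
    LABEL_INV_5P,
)
from .seqs import NucSeq, revcomp_str

MAX_FILL_IN = 5  # offset cap 8 minus fixed target-strand offset 3


class RepairMode(str, Enum):
    BLUNT_LIGATION = "blunt_ligation"
    FILL_IN = "fill_in"
    RESECTION = "resection"


class Mechanism(NamedTuple):
    """A (cut model at site A, cut model at site B, repair mode) triple."""

    model_a: CutModel
    model_b: CutModel
    mode: RepairMode


#: Sentinel explanation for indels attributable to ordinary NHEJ errors.
NHEJ_ERROR = "nhej_error"


@dataclass(frozen=True)
class IndelToken:
    """A single indel in Table-style notation: ``+X`` insertion, ``-X`` deletion.

    ``position`` is the 1-based anchor base on the junction reference (the
    base immediately 5' of the event after left-normalisation); it is None
    for tokens describing a mechanism in isolation, before anchoring to a
    junction.  ``ref_base`` is the base at the anchor.
    """

    token: str
    position: int | None = None
    ref_base: str | None = None

    def __post_init__(self) -> None:
        if not self.token or self.token[0] not in "+-" or len(self.token) < 2:
            raise ValueError(f"malformed indel token {self.token!r}")
        if any(c not in "ACGTN" for c in self.token[1:]):
            raise ValueError(f"malformed indel token {self.token!r}")

    @property
    def is_insertion(self) -> bool:
        return self.token[0] == "+"

    @property
    def bases(self) -> str:
        return self.token[1:]

    def __len__(self) -> int:
        return len(self.token) - 1


@dataclass(frozen=True)
class RepairProduct:
    """A junction variant with every mechanism that generates it.

    ``junction_variant`` is the variant junction window (same flanks as the
    canonical junction); ``indel`` is the left-normalised difference from the
    canonical window, or None for the precise product.
    """

    label: str
    junction_variant: NucSeq
    mechanisms: tuple[Mechanism, ...]
    indel: IndelToken | None


def fill_in_insertion(cut: CutSite) -> IndelToken | None:
    """Templated insertion produced by filling in a 5' overhang.

    Blunt cuts yield None.  For a staggered cut the polymerase copies the
    overhang, so the inserted bases equal the overhang sequence -- the bases
    ``target_offset+1 .. protospacer_offset`` upstream of the PAM read on the
    PAM-bearing strand.  The insertion is a tandem duplication of sequence
    already flanking the cut.
    """
    if cut.is_blunt:
        return None
    return IndelToken(token="+" + cut.overhang)


def diff_single_indel(canonical: str, variant: str) -> IndelToken | None:
    """Express ``variant`` as the canonical sequence plus one indel.

    Returns None when the sequences are identical, otherwise a
    left-normalised :class:`IndelToken` (shifted to the smallest 1-based
    anchor preserving the alternate sequence, the convention used by variant
    callers).  Raises ValueError if the difference is not a single contiguous
    insertion or deletion.
    """
    if canonical == variant:
        return None
    if len(canonical) == len(variant):
        raise ValueError("sequences differ but have equal length (not an indel)")
    longer, shorter = (variant, canonical) if len(variant) > len(canonical) else (canonical, variant)
    d = len(longer) - len(shorter)
    # maximal common prefix
    p = 0
    while p < len(shorter) and shorter[p] == longer[p]:
        p += 1
    if longer[p + d :] != shorter[p:]:
        raise ValueError("difference is not a single contiguous indel")
    bases = longer[p : p + d]
    # left-normalise: shift while the base before the event equals the last
    # base of the event
    while p > 0 and shorter[p - 1] == bases[-1]:
        bases = bases[-1] + bases[:-1]
        p -= 1
    sign = "+" if len(variant) > len(canonical) else "-"
    ref_base = canonical[p - 1] if p > 0 else None
    return IndelToken(token=sign + bases, position=p, ref_base=ref_base)


def _end_extent(cut: CutSite, side: str, mode: RepairMode) -> int:
    """Blunt extent of a processed break end, as a plus-strand gap.

    ``side`` is which fragment the end belongs to: ``"left"`` for the
    fragment upstream of the cut (retained sequence is ``ref[:extent]``) and
    ``"right"`` for the downstream fragment (``ref[extent:]``).  Fill-in
    extends the recessed 3' strand across the overhang (the fragment keeps
    the overhang); resection trims the overhang away.
    """
    lo, hi = sorted((cut.top_cut, cut.bottom_cut))
    if mode is RepairMode.BLUNT_LIGATION:
        if not cut.is_blunt:
            raise ValueError("blunt ligation requires a blunt cut")
        return lo
    if mode is RepairMode.FILL_IN:
        return hi if side == "left" else lo
    if mode is RepairMode.RESECTION:
        return lo if side == "left" else hi
    raise ValueError(f"unknown repair mode {mode}")


def _canonical_gaps(ref: NucSeq, site_a: GuideSite, site_b: GuideSite) -> tuple[int, int]:
    blunt = CutModel(3, 3)
    ga = cut_site(site_a, blunt, ref).blunt_gap
    gb = cut_site(site_b, blunt, ref).blunt_gap
    if ga > gb:
        raise ValueError("site_a must cut upstream of site_b")
    return ga, gb


def enumerate_repair_products(
    ref: NucSeq,
    site_a: GuideSite,
    site_b: GuideSite,
    kind: str,
    offset_range: Sequence[int] = range(3, 9),
    modes: Iterable[RepairMode] = (
        RepairMode.BLUNT_LIGATION,
        RepairMode.FILL_IN,
        RepairMode.RESECTION,
    ),
    flank: int = 30,
) -> list[RepairProduct]:
    """All junction variants reachable from the cut-offset/repair-mode space.

    One candidate is generated per (protospacer-strand offset at A, offset at
    B, mode) combination and per junction (deletions have one junction,
    inversions two); candidates with identical variant sequences are merged,
    retaining every generating mechanism.  The precise product (both cuts
    blunt, blunt ligation) is always present when offset 3 and blunt
    ligation are in the search space.

    ``flank`` sets the window half-width used to represent variants; it only
    needs to exceed the largest offset deviation (5 nt), and defaults to 30.
    """
    modes = list(modes)
    offsets = list(offset_range)
    if not offsets or not modes:
        raise ValueError("offset_range and modes must be non-empty")
    ga, gb = _canonical_gaps(ref, site_a, site_b)
    if gb - ga < 2 * flank:
        raise ValueError("cut sites too close together for the requested flank")

    # canonical windows per junction label
    if kind == DELETION:
        canon = {
            LABEL_DELETION: ref.fetch(ga - flank, ga) + ref.fetch(gb, gb + flank)
        }
    elif kind == INVERSION:
        canon = {
            LABEL_INV_5P: ref.fetch(ga - flank, ga)
            + revcomp_str(ref.fetch(gb - flank, gb)),
            LABEL_INV_3P: revcomp_str(ref.fetch(ga, ga + flank))
            + ref.fetch(gb, gb + flank),
        }
    else:
        raise ValueError(f"unknown event kind {kind!r}")

    merged: dict[tuple[str, str], dict] = {}

    def emit(label: str, variant: str, mech: Mechanism) -> None:
        key = (label, variant)
        entry = merged.get(key)
        if entry is None:
            indel = diff_single_indel(canon[label], variant)
            merged[key] = {"indel": indel, "mechs": [mech]}
        else:
            entry["mechs"].append(mech)

    for off_a in offsets:
        model_a = CutModel(3, off_a)
        ca = cut_site(site_a, model_a, ref)
        for off_b in offsets:
            model_b = CutModel(3, off_b)
            cb = cut_site(site_b, model_b, ref)
            for mode in modes:
                if mode is RepairMode.BLUNT_LIGATION and not (
                    ca.is_blunt and cb.is_blunt
                ):
                    continue
                mech = Mechanism(model_a, model_b, mode)
                ea_left = _end_extent(ca, "left", mode)
                eb_right = _end_extent(cb, "right", mode)
                if kind == DELETION:
                    variant = ref.fetch(ga - flank, ea_left) + ref.fetch(
                        eb_right, gb + flank
                    )
                    emit(LABEL_DELETION, variant, mech)
                else:
                    seg_a = _end_extent(ca, "right", mode)  # segment 5' end
                    seg_b = _end_extent(cb, "left", mode)  # segment 3' end
                    # windows anchored at the canonical outer boundaries so
                    # variants differ from the canonical window only by the
                    # junction indel
                    v5 = ref.fetch(ga - flank, ea_left) + revcomp_str(
                        ref.fetch(gb - flank, seg_b)
                    )
                    v3 = revcomp_str(ref.fetch(seg_a, ga + flank)) + ref.fetch(
                        eb_right, gb + flank
                    )
                    emit(LABEL_INV_5P, v5, mech)
                    emit(LABEL_INV_3P, v3, mech)

    products = []
    for (label, variant), entry in merged.items():
        mechs = sorted(
            entry["mechs"],
            key=lambda m: (
                m.model_a.protospacer_strand_offset,
                m.model_b.protospacer_strand_offset,
                m.mode.value,
            ),
        )
        products.append(
            RepairProduct(
                label=label,
                junction_variant=NucSeq(variant, name=f"{label}_variant"),
                mechanisms=tuple(mechs),
                indel=entry["indel"],
            )
        )
    products.sort(
        key=lambda p: (
            p.label,
            0 if p.indel is None else 1,
            "" if p.indel is None else p.indel.token,
        )
    )
    return products


def _token_matches(a: IndelToken | None, b: IndelToken | None) -> bool:
    if a is None or b is None:
        return a is None and b is None
    if a.token != b.token:
        return False
    # positions compare only when both are anchored
    if a.position is not None and b.position is not None:
        return a.position == b.position
    return True


def explain_indel(
    obs: IndelToken | None,
    canonical: JunctionRef,
    ref: NucSeq,
    site_a: GuideSite,
    site_b: GuideSite,
    offset_range: Sequence[int] = range(3, 9),
    modes: Iterable[RepairMode] = (
        RepairMode.BLUNT_LIGATION,
        RepairMode.FILL_IN,
        RepairMode.RESECTION,
    ),
    fusion_window: int = 20,
) -> list[Mechanism | str]:
    """Every mechanism consistent with an observed indel at a junction.

    The observed token must be left-normalised against the canonical
    junction.  Mechanistic explanations (alternative cut offsets with
    fill-in or resection) come first, smaller offsets first; a generic
    ``NHEJ_ERROR`` explanation is appended for any 1-2 nt event at the
    fusion, since NHEJ-induced errors and alternative cutting cannot be
    distinguished from the junction sequence alone.  A precise observation
    (``obs=None``) is explained by canonical blunt ligation.
    """
    if obs is not None and obs.position is not None:
        if abs(obs.position - canonical.fusion_point) > fusion_window:
            raise ValueError(
                f"indel at position {obs.position} lies outside the fusion "
                f"window (fusion at {canonical.fusion_point} +/- {fusion_window})"
            )
    kind = DELETION if canonical.label == LABEL_DELETION else INVERSION
    flank = min(30, canonical.fusion_point)
    products = enumerate_repair_products(
        ref, site_a, site_b, kind, offset_range, modes, flank=flank
    )
    # anchored positions from enumerate are relative to its flank; compare to
    # the observation's junction coordinates by re-anchoring
    shift = canonical.fusion_point - flank
    out: list[Mechanism | str] = []
    for prod in products:
        if prod.label != canonical.label:
            continue
        tok = prod.indel
        if tok is not None and tok.position is not None:
            tok = IndelToken(tok.token, tok.position + shift, tok.ref_base)
        if _token_matches(obs, tok):
            out.extend(m for m in prod.mechanisms if m not in out)
    if obs is not None and 1 <= len(obs) <= 2:
        out.append(NHEJ_ERROR)
    return out


def build_variant_molecule(
    ref: NucSeq,
    site_a: GuideSite,
    site_b: GuideSite,
    kind: str,
    mechanism: Mechanism,
) -> tuple[NucSeq, tuple[int, ...]]:
    """Full edited molecule under a repair mechanism, with fusion gap(s).

    Used by the pool simulator: returns the molecule and the gap
    coordinate(s) of its fusion junction(s) (one for deletions, two for
    inversions), in the edited molecule's coordinates.
    """
    ca = cut_site(site_a, mechanism.model_a, ref)
    cb = cut_site(site_b, mechanism.model_b, ref)
    mode = mechanism.mode
    if mode is RepairMode.BLUNT_LIGATION and not (ca.is_blunt and cb.is_blunt):
        raise ValueError("blunt ligation requires blunt cuts at both sites")
    ea_left = _end_extent(ca, "left", mode)
    eb_right = _end_extent(cb, "right", mode)
    n = len(ref)
    if kind == DELETION:
        if ref.is_circular:
            kept = ref.fetch(eb_right, ea_left + n if ea_left < eb_right else ea_left)
            return (
                NucSeq(kept, topology="circular", name=ref.name + "_del"),
                (len(kept),),
            )
        seq = ref.symbols[:ea_left] + ref.symbols[eb_right:]
        return NucSeq(seq, name=ref.name + "_del"), (ea_left,)
    if kind == INVERSION:
        seg_a = _end_extent(ca, "right", mode)
        seg_b = _end_extent(cb, "left", mode)
        seg = revcomp_str(ref.fetch(seg_a, seg_b if seg_b > seg_a else seg_b + n))
        if ref.is_circular:
            rest = ref.fetch(eb_right, ea_left + n if ea_left < eb_right else ea_left)
            seq = NucSeq(
                ref.fetch(0, ea_left) + seg + ref.fetch(eb_right, n),
                topology="circular",
                name=ref.name + "_inv",
            ) if max(ea_left, eb_right) <= n else None
            if seq is None:
                raise ValueError("inversion across the origin is not supported")
            return seq, (ea_left, ea_left + len(seg))
        seq = ref.symbols[:ea_left] + seg + ref.symbols[eb_right:]
        return NucSeq(seq, name=ref.name + "_inv"), (ea_left, ea_left + len(seg))
    raise ValueError(f"unknown event kind {kind!r}")
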