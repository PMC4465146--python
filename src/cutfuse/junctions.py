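"""Rearranged molecules, fusion-junction references, and in-silico PCR.

Two double-strand breaks on one molecule can resolve as a deletion (the
intervening segment is lost and the flanks ligate) or an inversion (the
segment re-inserts in the opposite orientation).  A deletion creates one
novel fusion junction; an inversion creates two (a 5' and a 3' fusion).  The
canonical junction assumes blunt cleavage 3 nt upstream of each PAM and
precise ligation; it is the alignment reference against which repair-derived
indels are called.
"""

from __future__ import annotations

from dataclasses import dataclass

from .guides import CutModel, CutSite, GuideSite, cut_site
from .seqs import NucSeq, revcomp_str

DELETION = "deletion"
INVERSION = "inversion"

LABEL_DELETION = "deletion_junction"
LABEL_INV_5P = "inversion_5prime"
LABEL_INV_3P = "inversion_3prime"


@dataclass(frozen=True)
class RearrangementEvent:
    """A deletion or inversion between two cut sites on one molecule.

    ``cut_a`` must lie strictly upstream of ``cut_b`` on the plus strand; on
    circular molecules the rearranged segment is the arc running forward
    (5'->3' on the plus strand) from ``cut_a`` to ``cut_b``, so the
    complementary arc is selected by swapping the cuts.
    """

    kind: str
    cut_a: CutSite
    cut_b: CutSite

    def __post_init__(self) -> None:
        if self.kind not in (DELETION, INVERSION):
            raise ValueError(f"kind must be deletion or inversion, got {self.kind!r}")

    @property
    def gap_a(self) -> int:
        return self.cut_a.blunt_gap

    @property
    def gap_b(self) -> int:
        return self.cut_b.blunt_gap


@dataclass(frozen=True)
class JunctionRef:
    """A predicted fusion-junction reference sequence.

    ``fusion_point`` is the gap coordinate of the fusion within ``sequence``;
    with symmetric flanks it equals ``flank``.
    """

    sequence: NucSeq
    fusion_point: int
    label: str
    flank: int
    event: RearrangementEvent | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not 0 < self.fusion_point < n:
            raise ValueError("fusion_point must be interior to the sequence")
        if self.flank > self.fusion_point or self.flank > n - self.fusion_point:
            raise ValueError("flank exceeds available sequence on one side")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse PCR primer pair (each given 5'->3')."""

    forward: str
    reverse: str
    name: str = ""

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if len(p) < 15:
                raise ValueError("primers must be at least 15 nt")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on a template."""

    sequence: str
    start: int
    end: int
    orientation: str  # "+": forward primer on plus strand; "-": on minus

    @property
    def size(self) -> int:
        return len(self.sequence)


def _segment_bounds(event: RearrangementEvent, n: int, circular: bool) -> tuple[int, int]:
    a, b = event.gap_a, event.gap_b
    if circular:
        if a == b:
            raise ValueError("cut gaps coincide; no segment to rearrange")
        return a, b
    if not a < b:
        raise ValueError("cut_a must lie strictly upstream of cut_b")
    return a, b


def apply_deletion(ref: NucSeq, event: RearrangementEvent) -> NucSeq:
    """Remove the segment between the two (blunt) cut gaps and re-ligate.

    Linear molecules lose ``gap_b - gap_a`` nt.  Circular molecules lose the
    forward arc from ``gap_a`` to ``gap_b`` and retain the complementary arc
    as a (smaller) circle opening at the fusion.
    """
    if event.kind != DELETION:
        raise ValueError("event kind must be deletion")
    n = len(ref)
    a, b = _segment_bounds(event, n, ref.is_circular)
    if ref.is_circular:
        kept = ref.fetch(b, a + n if a < b else a)
        return NucSeq(kept, topology="circular", name=ref.name + "_del")
    return NucSeq(
        ref.symbols[:a] + ref.symbols[b:], topology="linear", name=ref.name + "_del"
    )


def apply_inversion(ref: NucSeq, event: RearrangementEvent) -> NucSeq:
    """Replace the segment between the cut gaps by its reverse complement."""
    if event.kind != INVERSION:
        raise ValueError("event kind must be inversion")
    n = len(ref)
    a, b = _segment_bounds(event, n, ref.is_circular)
    if ref.is_circular:
        seg = ref.fetch(a, b if b > a else b + n)
        rest_start, rest_end = b % n, (a if a > b % n else a + n)
        rest = ref.fetch(rest_start, rest_end)
        # rebuild with the inverted segment in place, keeping gap_a at the
        # same rotational position
        rebuilt = revcomp_str(seg) + rest
        # rotate so that plus-coordinate 0 of the original maps to index 0
        shift = (n - a) % n
        rebuilt = rebuilt[shift:] + rebuilt[:shift]
        return NucSeq(rebuilt, topology="circular", name=ref.name + "_inv")
    return NucSeq(
        ref.symbols[:a] + revcomp_str(ref.symbols[a:b]) + ref.symbols[b:],
        topology="linear",
        name=ref.name + "_inv",
    )


def junction_reference(
    edited: NucSeq, fusion_gap: int, flank: int, label: str
) -> JunctionRef:
    """Cut a symmetric window of ``flank`` nt around a fusion gap.

    The fusion point of the returned reference is at coordinate ``flank``.
    Windows exceeding the ends of a linear molecule are rejected; circular
    molecules wrap.
    """
    n = len(edited)
    if not edited.is_circular:
        if fusion_gap - flank < 0 or fusion_gap + flank > n:
            need = max(flank - fusion_gap, fusion_gap + flank - n)
            raise ValueError(
                f"flank {flank} does not fit around gap {fusion_gap} "
                f"(reduce by {need} nt)"
            )
    window = edited.fetch(fusion_gap - flank, fusion_gap + flank)
    return JunctionRef(
        sequence=NucSeq(window, name=f"{edited.name}|{label}"),
        fusion_point=flank,
        label=label,
        flank=flank,
    )


def predict_junctions(
    ref: NucSeq,
    site_a: GuideSite,
    site_b: GuideSite,
    kind: str,
    flank: int = 100,
) -> list[JunctionRef]:
    """Canonical (blunt 3-nt-upstream cut, precise ligation) junctions.

    Deletions yield one junction; inversions yield two, labelled
    ``inversion_5prime`` (upstream fusion) and ``inversion_3prime``.
    """
    model = CutModel(3, 3)
    cut_a = cut_site(site_a, model, ref)
    cut_b = cut_site(site_b, model, ref)
    if cut_a.blunt_gap > cut_b.blunt_gap and not ref.is_circular:
        cut_a, cut_b = cut_b, cut_a
    event = RearrangementEvent(kind=kind, cut_a=cut_a, cut_b=cut_b)
    a, b = event.gap_a, event.gap_b
    if kind == DELETION:
        edited = apply_deletion(ref, event)
        # circular deletion result starts at gap_b, so the fusion sits at the
        # wrap point (== kept-arc length)
        fusion = len(edited) if ref.is_circular else a
        jr = junction_reference(edited, fusion, flank, LABEL_DELETION)
        return [_with_event(jr, event)]
    edited = apply_inversion(ref, event)
    j5 = junction_reference(edited, a, flank, LABEL_INV_5P)
    j3 = junction_reference(edited, b if not ref.is_circular else b % len(ref), flank, LABEL_INV_3P)
    return [_with_event(j5, event), _with_event(j3, event)]


def _with_event(jr: JunctionRef, event: RearrangementEvent) -> JunctionRef:
    return JunctionRef(
        sequence=jr.sequence,
        fusion_point=jr.fusion_point,
        label=jr.label,
        flank=jr.flank,
        event=event,
    )


def _occurrences(template: NucSeq, probe: str) -> list[int]:
    """Start positions of exact probe matches on the plus strand (wrapping)."""
    hay = template.symbols * 2 if template.is_circular else template.symbols
    n = len(template)
    limit = n if template.is_circular else n - len(probe) + 1
    out = []
    start = 0
    while True:
        i = hay.find(probe, start)
        if i < 0 or i >= limit:
            break
        out.append(i)
        start = i + 1
    return out


def insilico_pcr(
    template: NucSeq, primers: PrimerPair, max_size: int = 10000
) -> list[Amplicon]:
    """Predict PCR products from exact primer matches.

    An amplicon requires the forward primer annealing to one strand and the
    reverse primer to the other, 3' ends facing each other, total size at
    most ``max_size``.  Both template orientations are considered, and
    circular templates may amplify across the origin.  Exact matching only:
    this reproduces detection logic (which bands can exist), not PCR
    thermodynamics.
    """
    if max_size <= len(primers.forward) + len(primers.reverse):
        raise ValueError("max_size must exceed the summed primer lengths")
    n = len(template)
    found: list[Amplicon] = []

    def pair_up(fwd: str, rev: str, orientation: str) -> None:
        f_hits = _occurrences(template, fwd)
        r_hits = [
            (i, i + len(rev)) for i in _occurrences(template, revcomp_str(rev))
        ]
        for f in f_hits:
            for r_start, r_end in r_hits:
                end = r_end
                if template.is_circular and end <= f:
                    end += n
                elif end <= f:
                    continue
                if r_start < f and not template.is_circular:
                    continue
                size = end - f
                if size < len(fwd) + len(rev) or size > max_size:
                    continue
                if template.is_circular and size > n:
                    continue
                found.append(
                    Amplicon(
                        sequence=template.fetch(f, end),
                        start=f % max(n, 1),
                        end=end,
                        orientation=orientation,
                    )
                )

    pair_up(primers.forward, primers.reverse, "+")
    pair_up(primers.reverse, primers.forward, "-")
    # dedupe identical products (e.g. palindromic degeneracies)
    uniq: dict[tuple, Amplicon] = {}
    for amp in found:
        uniq.setdefault((amp.start, amp.end, amp.orientation), amp)
    return sorted(uniq.values(), key=lambda a: (a.start, a.end, a.orientation))
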