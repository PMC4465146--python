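"""sgRNA target-site discovery and Cas9 cut-site geometry.

S. pyogenes Cas9 requires a protospacer-adjacent motif (PAM) immediately 3'
of the 20-nt protospacer on the PAM-bearing (non-complementary) strand.  The
canonical model places a blunt cut 3 nt upstream of the PAM; biochemical
evidence also supports staggered cleavage in which the sgRNA-complementary
(target) strand is cut 3 nt upstream while the non-complementary strand is
cut 3-8 nt upstream, leaving a short 5' overhang.  Both models are
represented here by :class:`CutModel`; only 5' overhangs are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqs import NucSeq, revcomp_str

PAM_PATTERNS = {
    "NGG": ("G", "G"),
    "NAG": ("A", "G"),
}

PROTOSPACER_LEN = 20
PAM_LEN = 3


@dataclass(frozen=True)
class GuideSpec:
    """A named sgRNA spacer: exactly 20 nt, no ambiguity codes."""

    name: str
    protospacer: str

    def __post_init__(self) -> None:
        p = self.protospacer.upper()
        if len(p) != PROTOSPACER_LEN:
            raise ValueError(
                f"protospacer must be {PROTOSPACER_LEN} nt, got {len(p)}"
            )
        if any(ch not in "ACGT" for ch in p):
            raise ValueError("protospacer may not contain N or non-ACGT symbols")
        object.__setattr__(self, "protospacer", p)


@dataclass(frozen=True)
class GuideSite:
    """A located protospacer+PAM occurrence.

    Intervals are 0-based half-open on the plus strand.  For circular
    references a site crossing the origin is stored unwrapped
    (``end = start + len``, possibly > sequence length); slice with
    ``NucSeq.fetch``.  The PAM is immediately 3' of the protospacer *on the
    site's strand*, so for minus-strand sites ``pam_interval`` lies to the
    left of ``protospacer_interval`` in plus-strand coordinates.
    """

    guide: GuideSpec
    strand: str
    protospacer_interval: tuple[int, int]
    pam_interval: tuple[int, int]
    pam_class: str
    pam_seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        if self.pam_class not in PAM_PATTERNS:
            raise ValueError(f"unknown PAM class {self.pam_class}")
        s, e = self.protospacer_interval
        ps, pe = self.pam_interval
        if e - s != PROTOSPACER_LEN or pe - ps != PAM_LEN:
            raise ValueError("malformed site intervals")
        adjacent = (ps == e) if self.strand == "+" else (pe == s)
        if not adjacent:
            raise ValueError("PAM must be immediately 3' of the protospacer")


@dataclass(frozen=True)
class CutModel:
    """Per-strand cut offsets, in nt upstream of the PAM.

    ``target_strand_offset`` applies to the sgRNA-complementary strand and is
    3 in both the blunt and staggered models; ``protospacer_strand_offset``
    applies to the PAM-bearing strand and ranges over 3-8.  The overhang
    length is their difference, and because the protospacer-strand cut is
    farther from the PAM the overhang is always 5'-recessed-free, i.e. a 5'
    overhang.  3' overhang geometries are rejected.
    """

    target_strand_offset: int = 3
    protospacer_strand_offset: int = 3

    def __post_init__(self) -> None:
        if self.target_strand_offset != 3:
            raise ValueError("target (complementary) strand offset is fixed at 3 nt")
        if not 3 <= self.protospacer_strand_offset <= 8:
            raise ValueError("protospacer strand offset must be in [3, 8]")
        if self.protospacer_strand_offset < self.target_strand_offset:
            raise ValueError("3' overhangs are not modeled")

    @property
    def overhang_length(self) -> int:
        return self.protospacer_strand_offset - self.target_strand_offset

    @property
    def is_blunt(self) -> bool:
        return self.overhang_length == 0


@dataclass(frozen=True)
class CutSite:
    """A (possibly staggered) double-strand break located on a reference.

    ``top_cut`` is the gap coordinate where the plus strand backbone is cut;
    ``bottom_cut`` is the gap coordinate (still in plus-strand coordinates)
    where the minus strand is cut.  Blunt breaks have ``top_cut ==
    bottom_cut``.  ``overhang`` is the single-stranded 5' overhang sequence
    read 5'->3' on the PAM-bearing strand (empty for blunt cuts).
    """

    top_cut: int
    bottom_cut: int
    overhang: str
    site: GuideSite
    model: CutModel

    def __post_init__(self) -> None:
        if len(self.overhang) != abs(self.top_cut - self.bottom_cut):
            raise ValueError("overhang length must equal the cut stagger")

    @property
    def is_blunt(self) -> bool:
        return self.top_cut == self.bottom_cut

    @property
    def blunt_gap(self) -> int:
        """The single gap coordinate of a blunt cut."""
        if not self.is_blunt:
            raise ValueError("cut is staggered; no single gap coordinate")
        return self.top_cut

    @property
    def canonical_gap(self) -> int:
        """Gap of the canonical blunt (3,3) cut at this site (model-independent)."""
        s, e = self.site.protospacer_interval
        return e - 3 if self.site.strand == "+" else s + 3


def _pam_matches(pam: str, pam_class: str) -> bool:
    b2, b3 = PAM_PATTERNS[pam_class]
    return len(pam) == 3 and pam[1] == b2 and pam[2] == b3


def _classify_pam(pam: str, pam_classes: Iterable[str]) -> str | None:
    # NGG wins over NAG when both are requested (they are disjoint anyway).
    for cls in ("NGG", "NAG"):
        if cls in pam_classes and _pam_matches(pam, cls):
            return cls
    return None


def find_guide_sites(
    ref: NucSeq,
    guide: GuideSpec,
    pam_classes: Iterable[str] = ("NGG",),
) -> list[GuideSite]:
    """Locate every exact protospacer match followed by a qualifying PAM.

    Both strands are scanned; minus-strand hits are reported with intervals
    on the plus strand.  Circular references are scanned across the origin by
    doubling the sequence and deduplicating hits modulo length.

    Returns sites sorted by (protospacer start, strand).
    """
    pam_classes = set(pam_classes)
    if not pam_classes:
        raise ValueError("pam_classes must not be empty")
    bad = pam_classes - set(PAM_PATTERNS)
    if bad:
        raise ValueError(f"unknown PAM classes: {sorted(bad)}")
    n = len(ref)
    win = PROTOSPACER_LEN + PAM_LEN
    if not ref.is_circular and n < win:
        raise ValueError(f"linear reference shorter than {win} nt")

    sites: list[GuideSite] = []
    scan = ref.symbols * 2 if ref.is_circular else ref.symbols
    limit = n if ref.is_circular else n - win + 1

    def add_plus(i: int) -> None:
        pam = scan[i + PROTOSPACER_LEN : i + win]
        cls = _classify_pam(pam, pam_classes)
        if cls is not None:
            sites.append(
                GuideSite(
                    guide=guide,
                    strand="+",
                    protospacer_interval=(i, i + PROTOSPACER_LEN),
                    pam_interval=(i + PROTOSPACER_LEN, i + win),
                    pam_class=cls,
                    pam_seq=pam,
                )
            )

    def add_minus(i: int) -> None:
        # window scan[i:i+23] equals revcomp(PAM + protospacer) on the plus
        # strand: plus-strand layout is [PAM'][protospacer'] where X' denotes
        # reverse complement.
        window = scan[i : i + win]
        if revcomp_str(window[PAM_LEN:]) != guide.protospacer:
            return
        pam = revcomp_str(window[:PAM_LEN])
        cls = _classify_pam(pam, pam_classes)
        if cls is not None:
            sites.append(
                GuideSite(
                    guide=guide,
                    strand="-",
                    protospacer_interval=(i + PAM_LEN, i + win),
                    pam_interval=(i, i + PAM_LEN),
                    pam_class=cls,
                    pam_seq=pam,
                )
            )

    proto = guide.protospacer
    for i in range(limit):
        if scan[i : i + PROTOSPACER_LEN] == proto:
            add_plus(i)
        add_minus(i)

    if ref.is_circular:
        seen = set()
        uniq = []
        for s in sites:
            key = (s.strand, s.protospacer_interval[0] % n)
            if key not in seen:
                seen.add(key)
                uniq.append(s)
        sites = uniq
    sites.sort(key=lambda s: (s.protospacer_interval[0], s.strand))
    return sites


def cut_site(site: GuideSite, model: CutModel, ref: NucSeq) -> CutSite:
    """Locate the double-strand break produced at ``site`` under ``model``.

    For a plus-strand site with protospacer [s, s+20): the target strand
    (minus strand) is cut ``target_strand_offset`` nt upstream of the PAM,
    i.e. at gap ``s + 20 - target_strand_offset``; the PAM-bearing plus
    strand at gap ``s + 20 - protospacer_strand_offset``.  Minus-strand sites
    are the mirror image.  The overhang is read on the PAM-bearing strand.
    """
    s, e = site.protospacer_interval
    n = len(ref)
    if site.strand == "+":
        top = e - model.protospacer_strand_offset  # PAM-bearing strand = plus
        bottom = e - model.target_strand_offset
        lo, hi = top, bottom
        overhang = ref.fetch(lo, hi)
    else:
        top = s + model.target_strand_offset  # plus strand is the target strand
        bottom = s + model.protospacer_strand_offset
        lo, hi = top, bottom
        overhang = revcomp_str(ref.fetch(lo, hi))
    if not ref.is_circular:
        for g in (top, bottom):
            if g < 0 or g > n:
                raise ValueError(f"cut gap {g} outside linear reference [0, {n}]")
    else:
        # shift both gaps together so the stagger never wraps numerically
        if min(top, bottom) >= n:
            top, bottom = top - n, bottom - n
        elif max(top, bottom) < 0:
            top, bottom = top + n, bottom + n
    return CutSite(top_cut=top, bottom_cut=bottom, overhang=overhang, site=site, model=model)


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(s: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in s), dtype=np.int8, count=len(s))


def enumerate_offtarget_sites(
    guide: GuideSpec,
    ref: NucSeq,
    max_mismatches: int,
    pam_classes: Iterable[str] = ("NGG",),
) -> list[tuple[GuideSite, int]]:
    """Exhaustive Hamming-distance scan for near-matches with a qualifying PAM.

    Every 20-nt window on either strand with at most ``max_mismatches``
    mismatches to the protospacer and a PAM of a requested class immediately
    3' is reported, sorted by (mismatch count, plus-strand coordinate,
    strand).  ``N`` in the reference never matches.  With ``max_mismatches=0``
    this reduces exactly to :func:`find_guide_sites`.
    """
    if not 0 <= max_mismatches <= PROTOSPACER_LEN:
        raise ValueError("max_mismatches must be in [0, 20]")
    pam_classes = set(pam_classes)
    if not pam_classes:
        raise ValueError("pam_classes must not be empty")
    n = len(ref)
    win = PROTOSPACER_LEN + PAM_LEN
    hits: list[tuple[GuideSite, int]] = []

    scan = ref.symbols * 2 if ref.is_circular else ref.symbols
    limit = n if ref.is_circular else n - win + 1
    if limit <= 0:
        return []
    arr = _encode(scan)
    proto = _encode(guide.protospacer)

    # mismatches of every window against proto, vectorized over positions
    m = len(scan)
    nwin = m - PROTOSPACER_LEN + 1
    mm_plus = np.zeros(nwin, dtype=np.int16)
    for j in range(PROTOSPACER_LEN):
        col = arr[j : j + nwin]
        mm_plus += (col != proto[j]) | (col == 4)

    rc_proto = _encode(revcomp_str(guide.protospacer))
    mm_minus = np.zeros(nwin, dtype=np.int16)
    for j in range(PROTOSPACER_LEN):
        col = arr[j : j + nwin]
        mm_minus += (col != rc_proto[j]) | (col == 4)

    for i in range(limit):
        # plus strand: protospacer at [i, i+20), PAM at [i+20, i+23)
        if mm_plus[i] <= max_mismatches and i + win <= m:
            pam = scan[i + PROTOSPACER_LEN : i + win]
            cls = _classify_pam(pam, pam_classes)
            if cls is not None:
                hits.append(
                    (
                        GuideSite(
                            guide=guide,
                            strand="+",
                            protospacer_interval=(i, i + PROTOSPACER_LEN),
                            pam_interval=(i + PROTOSPACER_LEN, i + win),
                            pam_class=cls,
                            pam_seq=pam,
                        ),
                        int(mm_plus[i]),
                    )
                )
        # minus strand: plus-strand layout [PAM'][protospacer'] at [i, i+23)
        if i + win <= m and mm_minus[i + PAM_LEN] <= max_mismatches:
            pam = revcomp_str(scan[i : i + PAM_LEN])
            cls = _classify_pam(pam, pam_classes)
            if cls is not None:
                hits.append(
                    (
                        GuideSite(
                            guide=guide,
                            strand="-",
                            protospacer_interval=(i + PAM_LEN, i + win),
                            pam_interval=(i, i + PAM_LEN),
                            pam_class=cls,
                            pam_seq=pam,
                        ),
                        int(mm_minus[i + PAM_LEN]),
                    )
                )

    if ref.is_circular:
        seen = set()
        uniq = []
        for site, mm in hits:
            key = (site.strand, site.protospacer_interval[0] % n)
            if key not in seen:
                seen.add(key)
                uniq.append((site, mm))
        hits = uniq
    hits.sort(key=lambda t: (t[1], t[0].protospacer_interval[0], t[0].strand))
    return hits
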