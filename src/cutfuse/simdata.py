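"""Synthetic reporter constructs, edited-molecule pools, and read simulation.

Three desk-scale construct archetypes are generated, emulating the designs
used to visualise CRISPR/Cas9-mediated rearrangements:

``igfp_like``
    A circular plasmid carrying a promoter and a reporter cassette cloned in
    the *inverted* orientation, flanked by two NGG-PAM guide sites and by two
    LoxP-like 34-nt sites (13-bp inverted-repeat arms around an asymmetric
    8-bp spacer) in head-to-head orientation, each containing an internal
    NAG PAM targeted by a single guide.  Inversion of the cassette restores
    the reporter's orientation.

``lsl_like``
    A circular promoter--STOP--reporter plasmid whose STOP cassette is
    flanked by two *identical*, same-orientation LoxP-like sites, so one
    NAG-PAM guide cuts twice and deletion removes the STOP cassette.

``two_cut_locus``
    A linear locus with two NGG guide sites separated by about half the
    construct length -- a desk-scale stand-in for a multi-kilobase genomic
    region deleted or inverted between two cuts (distance between cuts is a
    parameter; no property modeled here depends on the literal size).

The read simulator draws single-end reads centered on a fusion point with
random offset, applies a configured repair-outcome spectrum (indel tokens at
the fusion) and per-base substitution errors, and keeps per-read truth
labels.  All randomness flows through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .guides import GuideSpec, GuideSite, find_guide_sites
from .junctions import DELETION, INVERSION, JunctionRef, PrimerPair
from .repair import IndelToken, Mechanism, RepairMode, build_variant_molecule
from .seqs import Feature, NucSeq, revcomp_str

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = {65: 0, 67: 1, 71: 2, 84: 3}


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@dataclass
class ConstructFixture:
    """A synthetic construct with declared guides, primers, and features.

    This is a structural emulation of the reporter designs (element layout,
    PAM classes, site multiplicities), not a reproduction of any real
    plasmid or sgRNA sequence.
    """

    name: str
    sequence: NucSeq
    features: list[Feature]
    guides: dict[str, GuideSpec]
    primers: dict[str, PrimerPair]
    expected_site_counts: dict[str, int]
    pam_classes: dict[str, tuple[str, ...]]

    def guide_sites(self, guide_name: str) -> list[GuideSite]:
        g = self.guides[guide_name]
        return find_guide_sites(
            self.sequence, g, self.pam_classes.get(guide_name, ("NGG",))
        )


@dataclass(frozen=True)
class PoolMolecule:
    sequence: NucSeq
    label: str  # unedited | deletion | inversion
    mechanism: Mechanism | None
    fusion_gaps: tuple[int, ...]


@dataclass
class EditedPool:
    """A multiset of simulated molecules with truth labels."""

    molecules: list[PoolMolecule]
    rates: dict[str, float]
    seed: int

    def label_fractions(self) -> dict[str, float]:
        n = len(self.molecules)
        out: dict[str, float] = {}
        for m in self.molecules:
            out[m.label] = out.get(m.label, 0) + 1
        return {k: v / n for k, v in out.items()}


@dataclass(frozen=True)
class ReadSimSpec:
    """Parameters for junction-read simulation.

    ``spectrum`` maps indel tokens (``"+G"`` style; None for the precise
    outcome) to probabilities summing to 1.  Substitution-only error model
    by default; ``indel_error_rate`` adds random 1-nt sequencing indels for
    stress tests.
    """

    junction: JunctionRef
    spectrum: Mapping[str | None, float]
    n_reads: int = 10000
    read_length: int = 150
    error_rate: float = 0.001
    indel_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum probabilities sum to {total}, not 1")
        if self.read_length > len(self.junction.sequence):
            raise ValueError("read_length exceeds junction template length")


def _embed(parts: list[tuple[str, str, str]]) -> tuple[str, list[Feature]]:
    """Concatenate (name, seq, strand) parts into a sequence + feature list."""
    seq = []
    feats = []
    pos = 0
    for name, s, strand in parts:
        if name:
            feats.append(Feature(name, pos, pos + len(s), strand))
        seq.append(s)
        pos += len(s)
    return "".join(seq), feats


def _loxp_like(rng: np.random.Generator) -> tuple[str, GuideSpec]:
    """A 34-nt LoxP-like site (13-bp arms, asymmetric 8-bp spacer) with an
    internal NAG PAM, plus the guide targeting it on the site's plus strand.

    Site layout: arm(13) + spacer(8) + revcomp(arm)(13).  The protospacer is
    site[6:26] (arm tail + spacer + arm head) and the PAM site[26:29] is
    constrained to NAG by fixing two arm bases.
    """
    for _ in range(100):
        arm = list(_random_dna(rng, 13))
        # rc(arm)[6] == 'A' and rc(arm)[7] == 'G' make site[27:29] == "AG"
        arm[6] = "T"
        arm[5] = "C"
        arm = "".join(arm)
        spacer = _random_dna(rng, 8)
        if spacer == revcomp_str(spacer):
            continue  # spacer must be asymmetric
        site = arm + spacer + revcomp_str(arm)
        proto = site[6:26]
        if "N" in proto or site[26:29][1:] != "AG":
            continue
        try:
            return site, GuideSpec("sgLoxPlike", proto)
        except ValueError:
            continue
    raise RuntimeError("failed to build a LoxP-like site")


def _unique_protospacer(rng: np.random.Generator, name: str, avoid: str) -> GuideSpec:
    for _ in range(100):
        p = _random_dna(rng, 20)
        if p not in avoid and revcomp_str(p) not in avoid:
            return GuideSpec(name, p)
    raise RuntimeError("failed to draw a unique protospacer")


def _validate_fixture(fx: ConstructFixture) -> None:
    for gname, expected in fx.expected_site_counts.items():
        sites = fx.guide_sites(gname)
        if len(sites) != expected:
            raise RuntimeError(
                f"fixture {fx.name}: guide {gname} has {len(sites)} sites, "
                f"expected {expected}"
            )


def make_fixture(kind: str, scale: int = 3000, seed: int = 0) -> ConstructFixture:
    """Build one of the three construct archetypes; deterministic per seed."""
    if scale < 500:
        raise ValueError("scale must be at least 500 nt")
    rng = np.random.default_rng(seed)
    if kind == "igfp_like":
        fx = _make_igfp_like(rng, scale)
    elif kind == "lsl_like":
        fx = _make_lsl_like(rng, scale)
    elif kind == "two_cut_locus":
        fx = _make_two_cut_locus(rng, scale)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    _validate_fixture(fx)
    return fx


def _cassette_len(scale: int, overhead: int) -> int:
    ln = scale - overhead
    if ln < 60:
        raise ValueError(f"scale {scale} too small to fit the construct features")
    return ln


def _make_igfp_like(rng: np.random.Generator, scale: int) -> ConstructFixture:
    promoter = _random_dna(rng, 200)
    loxp_site, sg_loxp = _loxp_like(rng)
    sg1 = _unique_protospacer(rng, "sg1", promoter)
    sg2 = _unique_protospacer(rng, "sg2", promoter)
    # fixed element lengths: backbone pads computed to hit `scale`
    cassette_core = _random_dna(rng, _cassette_len(scale, 200 + 2 * 23 + 2 * 34 + 400))
    pad5 = _random_dna(rng, 200)
    pad3_len = scale - (
        len(pad5) + 200 + 23 + 34 + len(cassette_core) + 34 + 23
    )
    pad3 = _random_dna(rng, pad3_len)
    parts = [
        ("backbone5", pad5, "+"),
        ("promoter", promoter, "+"),
        ("sg1_site", sg1.protospacer + "TGG", "+"),
        ("loxp_left", loxp_site, "+"),
        ("reporter_cassette", revcomp_str(cassette_core), "-"),
        ("loxp_right", revcomp_str(loxp_site), "-"),
        ("sg2_site", "CCA" + revcomp_str(sg2.protospacer), "-"),
        ("backbone3", pad3, "+"),
    ]
    seq, feats = _embed(parts)
    fmap = {f.name: f for f in feats}
    p1 = fmap["promoter"]
    fwd = seq[p1.start + 100 : p1.start + 120]
    cas = fmap["reporter_cassette"]
    # inversion-only reverse primer: plus-strand sense inside the cassette,
    # so its reverse complement appears downstream of `fwd` only after the
    # cassette flips
    inv_rev = seq[cas.start + 50 : cas.start + 70]
    b3 = fmap["backbone3"]
    del_rev = revcomp_str(seq[b3.start + 50 : b3.start + 70])
    primers = {
        "inversion": PrimerPair(fwd, inv_rev, "p1+p2"),
        "deletion": PrimerPair(fwd, del_rev, "p1+p3"),
    }
    return ConstructFixture(
        name="igfp_like",
        sequence=NucSeq(seq, topology="circular", name="igfp_like"),
        features=feats,
        guides={"sg1": sg1, "sg2": sg2, "sgLoxPlike": sg_loxp},
        primers=primers,
        expected_site_counts={"sg1": 1, "sg2": 1, "sgLoxPlike": 2},
        pam_classes={
            "sg1": ("NGG",),
            "sg2": ("NGG",),
            "sgLoxPlike": ("NGG", "NAG"),
        },
    )


def _make_lsl_like(rng: np.random.Generator, scale: int) -> ConstructFixture:
    promoter = _random_dna(rng, 200)
    loxp_site, sg_loxp = _loxp_like(rng)
    reporter = _random_dna(rng, 400)
    stop_len = _cassette_len(scale, 200 + 2 * 34 + 400 + 400)
    stop = _random_dna(rng, stop_len)
    pad5 = _random_dna(rng, 200)
    pad3 = _random_dna(rng, 200)
    parts = [
        ("backbone5", pad5, "+"),
        ("promoter", promoter, "+"),
        ("loxp_left", loxp_site, "+"),
        ("stop_cassette", stop, "+"),
        ("loxp_right", loxp_site, "+"),  # identical, same orientation
        ("reporter", reporter, "+"),
        ("backbone3", pad3, "+"),
    ]
    seq, feats = _embed(parts)
    fmap = {f.name: f for f in feats}
    p = fmap["promoter"]
    fwd = seq[p.start + 100 : p.start + 120]
    r = fmap["reporter"]
    rev = revcomp_str(seq[r.start + 100 : r.start + 120])
    return ConstructFixture(
        name="lsl_like",
        sequence=NucSeq(seq, topology="circular", name="lsl_like"),
        features=feats,
        guides={"sgLoxPlike": sg_loxp},
        primers={"deletion": PrimerPair(fwd, rev, "pF+pR")},
        expected_site_counts={"sgLoxPlike": 2},
        pam_classes={"sgLoxPlike": ("NGG", "NAG")},
    )


def _make_two_cut_locus(rng: np.random.Generator, scale: int) -> ConstructFixture:
    sg_a = GuideSpec("sgA", _random_dna(rng, 20))
    # fix sgB protospacer bases 15-18 to "GTAC" so the canonical junctions
    # always read ...|AC... 3' of the fusion (with sgB on the minus strand
    # the deletion junction continues with the complements of bases 16-17
    # and the inversion 5' junction with bases 17-18), letting standard demo
    # spectra with -A/-AC deletion tokens apply to any seed
    pb = list(_random_dna(rng, 20))
    pb[15:19] = "GTAC"
    sg_b = GuideSpec("sgB", "".join(pb))
    # flanks of ~scale/4 each put the two cuts ~scale/2 apart
    flank_len = max(300, scale // 4)
    seg_len = _cassette_len(scale, 2 * flank_len + 2 * 23)
    left = _random_dna(rng, flank_len)
    mid = _random_dna(rng, seg_len)
    right = _random_dna(rng, flank_len)
    # both guide sites on the minus strand: upstream of the deletion fusion
    # the filled-in sgA overhang is retained (templated insertions), while
    # downstream resection of the sgB overhang trims junction bases (small
    # deletions) -- together the junction can display both indel classes
    parts = [
        ("left_flank", left, "+"),
        ("sgA_site", "CCT" + revcomp_str(sg_a.protospacer), "-"),
        ("segment", mid, "+"),
        ("sgB_site", "CCT" + revcomp_str(sg_b.protospacer), "-"),
        ("right_flank", right, "+"),
    ]
    seq, feats = _embed(parts)
    fmap = {f.name: f for f in feats}
    lf, rf = fmap["left_flank"], fmap["right_flank"]
    fwd = seq[lf.start + 50 : lf.start + 70]
    del_rev = revcomp_str(seq[rf.start + 200 : rf.start + 220])
    seg = fmap["segment"]
    inv_rev = seq[seg.start + 60 : seg.start + 80]
    return ConstructFixture(
        name="two_cut_locus",
        sequence=NucSeq(seq, topology="linear", name="two_cut_locus"),
        features=feats,
        guides={"sgA": sg_a, "sgB": sg_b},
        primers={
            "deletion": PrimerPair(fwd, del_rev, "pF+pR"),
            "inversion": PrimerPair(fwd, inv_rev, "pF+pInv"),
        },
        expected_site_counts={"sgA": 1, "sgB": 1},
        pam_classes={"sgA": ("NGG",), "sgB": ("NGG",)},
    )


def simulate_editing_pool(
    fixture: ConstructFixture,
    rates: Mapping[str, float],
    mechanism_mixture: Mapping[Mechanism, float],
    n: int,
    seed: int = 0,
    guide_a: str | None = None,
    guide_b: str | None = None,
) -> EditedPool:
    """Sample ``n`` molecules under event rates and a mechanism mixture.

    ``rates`` maps {unedited, deletion, inversion} to probabilities summing
    to 1.  Each edited molecule is built by applying its sampled mechanism's
    junction variant between the fixture's two cut sites.  Reproducible
    bit-for-bit given (seed, arguments).
    """
    keys = ("unedited", DELETION, INVERSION)
    probs = [float(rates.get(k, 0.0)) for k in keys]
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ValueError("rates must sum to 1")
    mechs = list(mechanism_mixture)
    mprobs = np.array([mechanism_mixture[m] for m in mechs], dtype=float)
    if len(mechs) == 0 or abs(mprobs.sum() - 1.0) > 1e-9:
        raise ValueError("mechanism mixture must be non-empty and sum to 1")
    for m in mechs:
        if m.mode is RepairMode.BLUNT_LIGATION and (
            not m.model_a.is_blunt or not m.model_b.is_blunt
        ):
            raise ValueError("blunt_ligation mechanism with staggered cut models")

    gnames = list(fixture.guides)
    ga = guide_a or gnames[0]
    gb = guide_b or (gnames[1] if len(gnames) > 1 else gnames[0])
    if ga == gb:
        sites = fixture.guide_sites(ga)
        if len(sites) < 2:
            raise ValueError("single-guide pools need a guide with two sites")
        site_a, site_b = sites[0], sites[1]
    else:
        site_a = fixture.guide_sites(ga)[0]
        site_b = fixture.guide_sites(gb)[0]

    rng = np.random.default_rng(seed)
    labels = rng.choice(len(keys), size=n, p=probs)
    mech_idx = rng.choice(len(mechs), size=n, p=mprobs)

    cache: dict[tuple[str, int], tuple[NucSeq, tuple[int, ...]]] = {}
    molecules = []
    for lab_i, m_i in zip(labels, mech_idx):
        label = keys[lab_i]
        if label == "unedited":
            molecules.append(
                PoolMolecule(fixture.sequence, "unedited", None, ())
            )
            continue
        key = (label, int(m_i))
        if key not in cache:
            cache[key] = build_variant_molecule(
                fixture.sequence, site_a, site_b, label, mechs[m_i]
            )
        seq, gaps = cache[key]
        molecules.append(PoolMolecule(seq, label, mechs[m_i], gaps))
    return EditedPool(molecules=molecules, rates=dict(rates), seed=seed)


def _apply_token(junction: JunctionRef, token: str | None) -> tuple[str, int]:
    """Variant template and its (possibly shifted) fusion-centre coordinate."""
    seq = junction.sequence.symbols
    f = junction.fusion_point
    if token is None:
        return seq, f
    tok = IndelToken(token)
    if tok.is_insertion:
        return seq[:f] + tok.bases + seq[f:], f + len(tok) // 2
    k = len(tok)
    if seq[f : f + k] == tok.bases:
        return seq[:f] + seq[f + k :], f
    if seq[f - k : f] == tok.bases:
        return seq[: f - k] + seq[f:], f - k
    raise ValueError(
        f"deletion token {token} does not match the junction at the fusion"
    )


def simulate_reads(spec: ReadSimSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw error-bearing single-end reads from a junction under a spectrum.

    Reads are centered on the fusion point with a uniform random offset
    (keeping at least ``MIN_FLANK_SPAN + 5`` nt on each side of the fusion),
    receive their sampled outcome token, then per-base substitution errors.
    Returns (reads, truth table); reads are (id, sequence) pairs.
    """
    rng = np.random.default_rng(spec.seed)
    tokens = list(spec.spectrum)
    probs = np.array([spec.spectrum[t] for t in tokens], dtype=float)
    templates = {}
    for t in tokens:
        templates[t] = _apply_token(spec.junction, t)

    choice = rng.choice(len(tokens), size=spec.n_reads, p=probs)
    half = spec.read_length // 2
    margin = 15  # keep the fusion well inside the read
    max_shift = max(half - margin, 0)
    shifts = rng.integers(-max_shift, max_shift + 1, size=spec.n_reads)

    reads: list[tuple[str, str]] = [("", "")] * spec.n_reads
    rows = []
    for ti, token in enumerate(tokens):
        idx = np.nonzero(choice == ti)[0]
        if idx.size == 0:
            continue
        template, centre = templates[token]
        tarr = np.frombuffer(template.encode(), dtype=np.uint8)
        codes = np.zeros(tarr.size, dtype=np.int8)
        for b, c in _B2I.items():
            codes[tarr == b] = c
        starts = centre + shifts[idx] - half
        starts = np.clip(starts, 0, len(template) - spec.read_length)
        mat = codes[starts[:, None] + np.arange(spec.read_length)[None, :]]
        err_mask = rng.random(mat.shape) < spec.error_rate
        n_err = int(err_mask.sum())
        if n_err:
            mat[err_mask] = (mat[err_mask] + rng.integers(1, 4, n_err)) % 4
        if spec.indel_error_rate > 0:
            mat, starts = _inject_indel_errors(
                rng, mat, starts, codes, spec
            )
        byte_mat = _BASES[mat]
        for row_i, read_i in enumerate(idx):
            rid = f"read{read_i:06d}|{token or 'none'}"
            reads[read_i] = (rid, byte_mat[row_i].tobytes().decode())
            rows.append(
                {
                    "read_id": rid,
                    "token": token if token is not None else "none",
                    "start": int(starts[row_i]),
                    "n_subst_errors": int(err_mask[row_i].sum()),
                }
            )
    truth = pd.DataFrame(rows).sort_values("read_id").reset_index(drop=True)
    return reads, truth


def _inject_indel_errors(rng, mat, starts, codes, spec):
    """Random 1-nt sequencing indels (stress-test mode, off by default)."""
    n_reads, L = mat.shape
    hit = rng.random(n_reads) < spec.indel_error_rate * L
    for i in np.nonzero(hit)[0]:
        pos = int(rng.integers(5, L - 5))
        if rng.random() < 0.5:  # 1-nt insertion, truncate back to L
            base = int(rng.integers(0, 4))
            row = np.concatenate([mat[i, :pos], [base], mat[i, pos:-1]])
        else:  # 1-nt deletion, pull in the next template base
            nxt_idx = starts[i] + L
            nxt = codes[nxt_idx] if nxt_idx < codes.size else 0
            row = np.concatenate([mat[i, :pos], mat[i, pos + 1 :], [nxt]])
        mat[i] = row
    return mat, starts
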