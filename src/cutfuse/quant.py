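"""Amplicon read alignment to junction references and indel spectrum reports.

Reads from a junction-spanning PCR product are aligned glocally (read
global, reference local) to the predicted junction reference; indels inside
a window around the fusion point are left-normalised, aggregated into a
Table-style spectrum (position, token, supporting read counts, variant
frequency, binomial significance against sequencing error), and summarised
by the precise-ligation fraction and per-token indel representation.

Variant frequency uses the two-allele definition
``var_reads / (ref_reads + var_reads)``; raw counts are always carried so
other denominators can be recomputed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import Align
from scipy import stats

from .junctions import JunctionRef
from .repair import IndelToken, diff_single_indel


@dataclass(frozen=True)
class Scoring:
    """Affine-gap alignment scoring; penalties must be negative."""

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -6.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")


@dataclass(frozen=True)
class AlignedRead:
    """A read's glocal alignment against a junction reference.

    ``events`` holds indels as (ref position, '+'/'-', bases): insertions use
    the gap coordinate where the bases are inserted, deletions the start of
    the deleted reference run (coordinates not yet left-normalised).
    ``mismatches`` holds reference positions of substituted bases.
    """

    read_id: str
    junction_label: str
    mapped: bool
    ref_start: int = 0
    ref_end: int = 0
    score: float = 0.0
    identity: float = 0.0
    events: tuple[tuple[int, str, str], ...] = ()
    mismatches: tuple[int, ...] = ()
    read_seq: str = ""

    def cigar(self) -> str:
        """CIGAR over the aligned span (M includes mismatches)."""
        if not self.mapped:
            return "*"
        ops: list[tuple[str, int]] = []

        def push(op: str, ln: int) -> None:
            if ln <= 0:
                return
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + ln)
            else:
                ops.append((op, ln))

        ref_pos = self.ref_start
        for pos, kind, bases in sorted(self.events, key=lambda e: e[0]):
            push("M", pos - ref_pos)
            if kind == "+":
                push("I", len(bases))
                ref_pos = pos
            else:
                push("D", len(bases))
                ref_pos = pos + len(bases)
        push("M", self.ref_end - ref_pos)
        return "".join(f"{ln}{op}" for op, ln in ops)


@dataclass(frozen=True)
class IndelObservation:
    """Aggregated support for one left-normalised indel at one anchor."""

    indel: IndelToken
    ref_reads: int
    var_reads: int
    p_value: float | None = None

    @property
    def var_freq(self) -> float:
        total = self.ref_reads + self.var_reads
        return self.var_reads / total if total else 0.0


@dataclass(frozen=True)
class SpectrumReport:
    """Table-style indel spectrum at one fusion junction."""

    sample: str
    replicate: str
    junction_label: str
    observations: tuple[IndelObservation, ...]
    perfect_fraction: float
    mapped_fraction: float
    n_reads: int
    n_mapped: int
    n_spanning: int

    @property
    def indel_representation(self) -> dict[str, float]:
        """Each token's share of all indel-supporting reads."""
        total = sum(o.var_reads for o in self.observations)
        if total == 0:
            return {}
        return {o.indel.token: o.var_reads / total for o in self.observations}


MIN_READ_LEN = 30
MIN_FLANK_SPAN = 10  # nt required on each side of the fusion to count a read


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    # free end gaps on the reference side -> glocal (read global, ref local)
    a.end_deletion_score = 0
    return a


def align_to_junction(
    read: str,
    junction: JunctionRef,
    scoring: Scoring = Scoring(),
    identity_floor: float = 0.8,
    read_id: str = "read",
    _aligner: Align.PairwiseAligner | None = None,
) -> AlignedRead:
    """Glocal alignment of one read against a junction reference.

    The read aligns end-to-end; the reference contributes a local window.
    ``identity`` is matched bases over read length, and reads below
    ``identity_floor`` are reported unmapped.  An exact-substring fast path
    handles error-free reads.
    """
    read = read.upper()
    if len(read) < MIN_READ_LEN:
        raise ValueError(f"read shorter than {MIN_READ_LEN} nt")
    ref = junction.sequence.symbols
    label = junction.label

    hit = ref.find(read)
    if hit >= 0:
        return AlignedRead(
            read_id=read_id,
            junction_label=label,
            mapped=True,
            ref_start=hit,
            ref_end=hit + len(read),
            score=scoring.match * len(read),
            identity=1.0,
            read_seq=read,
        )

    aligner = _aligner if _aligner is not None else _make_aligner(scoring)
    aln = aligner.align(ref, read)[0]
    blocks_t, blocks_q = aln.aligned
    if len(blocks_t) == 0:
        return AlignedRead(read_id=read_id, junction_label=label, mapped=False, read_seq=read)

    events: list[tuple[int, str, str]] = []
    mismatches: list[int] = []
    matches = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            if ts > prev_t and qs == prev_q:
                events.append((int(prev_t), "-", ref[prev_t:ts]))
            elif qs > prev_q and ts == prev_t:
                events.append((int(ts), "+", read[prev_q:qs]))
            elif ts > prev_t and qs > prev_q:
                # adjacent gap on both sides (rare); record as del + ins
                events.append((int(prev_t), "-", ref[prev_t:ts]))
                events.append((int(ts), "+", read[prev_q:qs]))
        for i in range(te - ts):
            if ref[ts + i] == read[qs + i]:
                matches += 1
            else:
                mismatches.append(int(ts + i))
        prev_t, prev_q = te, qe

    identity = matches / len(read)
    mapped = identity >= identity_floor
    return AlignedRead(
        read_id=read_id,
        junction_label=label,
        mapped=mapped,
        ref_start=int(blocks_t[0][0]),
        ref_end=int(blocks_t[-1][1]),
        score=float(aln.score),
        identity=identity,
        events=tuple(events) if mapped else (),
        mismatches=tuple(mismatches) if mapped else (),
        read_seq=read,
    )


def align_reads(
    reads: Iterable[tuple[str, str]],
    junction: JunctionRef,
    scoring: Scoring = Scoring(),
    identity_floor: float = 0.8,
) -> list[AlignedRead]:
    """Align (read_id, sequence) pairs, sharing one aligner instance."""
    aligner = _make_aligner(scoring)
    return [
        align_to_junction(
            seq,
            junction,
            scoring,
            identity_floor,
            read_id=rid,
            _aligner=aligner,
        )
        for rid, seq in reads
    ]


def _normalise_event(
    ref: str, pos: int, kind: str, bases: str
) -> tuple[int, str]:
    """Left-normalise an indel event; returns (1-based anchor, token)."""
    if kind == "+":
        variant = ref[:pos] + bases + ref[pos:]
    else:
        variant = ref[:pos] + ref[pos + len(bases) :]
    tok = diff_single_indel(ref, variant)
    assert tok is not None
    return tok.position, tok.token


def _spans_fusion(a: AlignedRead, fusion: int) -> bool:
    return (
        a.mapped
        and a.ref_start <= fusion - MIN_FLANK_SPAN
        and a.ref_end >= fusion + MIN_FLANK_SPAN
    )


def pileup_indels(
    alignments: Sequence[AlignedRead],
    junction: JunctionRef,
    window: int = 20,
) -> list[IndelObservation]:
    """Aggregate left-normalised indels within the fusion window.

    Only reads spanning the fusion by at least 10 nt on each side
    contribute.  ``ref_reads`` for an observation counts spanning reads
    covering its anchor without that indel (mismatch-only reads count as
    reference, matching indel-centric calling).  Positions are 1-based.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ref = junction.sequence.symbols
    fusion = junction.fusion_point
    lo, hi = fusion - window, fusion + window

    per_read_events: list[tuple[AlignedRead, set[tuple[int, str]]]] = []
    counts: dict[tuple[int, str], int] = {}
    for a in alignments:
        if not _spans_fusion(a, fusion):
            continue
        keys: set[tuple[int, str]] = set()
        for pos, kind, bases in a.events:
            anchor, token = _normalise_event(ref, pos, kind, bases)
            if lo <= anchor <= hi:
                keys.add((anchor, token))
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
        per_read_events.append((a, keys))

    observations = []
    for (anchor, token), var_reads in sorted(counts.items()):
        ref_reads = 0
        for a, keys in per_read_events:
            if (anchor, token) in keys:
                continue
            # read must cover the anchor base
            if a.ref_start < anchor <= a.ref_end:
                ref_reads += 1
        observations.append(
            IndelObservation(
                indel=IndelToken(
                    token=token,
                    position=anchor,
                    ref_base=ref[anchor - 1] if anchor > 0 else None,
                ),
                ref_reads=ref_reads,
                var_reads=var_reads,
            )
        )
    return observations


def indel_significance(obs: IndelObservation, error_rate: float = 0.01) -> float:
    """One-sided binomial tail: P(X >= var_reads) at the sequencing error rate.

    Tests whether the indel's support exceeds what per-read error at
    ``error_rate`` would produce among ``ref_reads + var_reads`` trials.
    """
    if not 0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    n = obs.ref_reads + obs.var_reads
    if n == 0:
        raise ValueError("no reads at this anchor; significance undefined")
    return float(stats.binom.sf(obs.var_reads - 1, n, error_rate))


def classify_perfect_fusion(
    alignments: Sequence[AlignedRead],
    junction: JunctionRef,
    window: int = 20,
) -> float:
    """Fraction of spanning reads matching the junction exactly in the window.

    A read is perfect when it carries no mismatch and no indel whose
    reference position falls inside ``fusion +/- window`` (intersected with
    the read's aligned extent).  Returns 0.0 when no read spans the fusion.
    """
    ref = junction.sequence.symbols
    fusion = junction.fusion_point
    n_span = 0
    n_perfect = 0
    for a in alignments:
        if not _spans_fusion(a, fusion):
            continue
        n_span += 1
        lo = max(fusion - window, a.ref_start)
        hi = min(fusion + window, a.ref_end)
        clean = all(not (lo <= m < hi) for m in a.mismatches)
        if clean:
            for pos, kind, bases in a.events:
                anchor, _ = _normalise_event(ref, pos, kind, bases)
                if lo <= anchor <= hi:
                    clean = False
                    break
        if clean:
            n_perfect += 1
    return n_perfect / n_span if n_span else 0.0


def recovered_spectrum(
    alignments: Sequence[AlignedRead],
    junction: JunctionRef,
    window: int = 20,
) -> dict[str | None, float]:
    """Read-level outcome spectrum at the fusion (sums to 1 over spanning reads).

    Each fusion-spanning read is classified by the left-normalised indel
    token(s) it carries inside the window: ``None`` for indel-free reads,
    the token for single-indel reads, and ``"multiple"`` otherwise.
    Substitution errors do not change a read's class, so this estimates the
    repair-outcome mixture directly.
    """
    ref = junction.sequence.symbols
    fusion = junction.fusion_point
    lo, hi = fusion - window, fusion + window
    counts: dict[str | None, int] = {}
    n_span = 0
    for a in alignments:
        if not _spans_fusion(a, fusion):
            continue
        n_span += 1
        tokens = []
        for pos, kind, bases in a.events:
            anchor, token = _normalise_event(ref, pos, kind, bases)
            if lo <= anchor <= hi:
                tokens.append(token)
        key: str | None
        if not tokens:
            key = None
        elif len(tokens) == 1:
            key = tokens[0]
        else:
            key = "multiple"
        counts[key] = counts.get(key, 0) + 1
    return {k: v / n_span for k, v in counts.items()} if n_span else {}


def build_report(
    alignments: Sequence[AlignedRead],
    junction: JunctionRef,
    sample: str = "sample",
    replicate: str = "1",
    window: int = 20,
    error_rate: float = 0.01,
) -> SpectrumReport:
    """Full spectrum report: pileup + significance + perfect fraction."""
    n_reads = len(alignments)
    mapped = [a for a in alignments if a.mapped]
    spanning = [a for a in alignments if _spans_fusion(a, junction.fusion_point)]
    obs = [
        replace(o, p_value=indel_significance(o, error_rate))
        for o in pileup_indels(alignments, junction, window)
    ]
    return SpectrumReport(
        sample=sample,
        replicate=replicate,
        junction_label=junction.label,
        observations=tuple(obs),
        perfect_fraction=classify_perfect_fusion(alignments, junction, window),
        mapped_fraction=len(mapped) / n_reads if n_reads else 0.0,
        n_reads=n_reads,
        n_mapped=len(mapped),
        n_spanning=len(spanning),
    )


def filter_observations(
    report: SpectrumReport, min_freq: float = 0.01, min_var_reads: int = 2
) -> SpectrumReport:
    """Drop observations below frequency/support thresholds.

    ``indel_representation`` is recomputed over the survivors (it is a
    property of the observation list).
    """
    if min_freq < 0 or min_var_reads < 0:
        raise ValueError("thresholds must be >= 0")
    kept = tuple(
        o
        for o in report.observations
        if o.var_freq >= min_freq and o.var_reads >= min_var_reads
    )
    return replace(report, observations=kept)
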