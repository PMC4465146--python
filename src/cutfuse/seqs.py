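"""Nucleotide sequences with explicit topology.

All coordinates in this package are 0-based, half-open intervals on the plus
strand; cut positions are *gap* coordinates (gap ``k`` is the phosphodiester
boundary immediately before base index ``k``).  1-based positions appear only
in user-facing reports.  Circular molecules (plasmids) are first-class:
``fetch`` wraps across the origin, and intervals on circular molecules may
have ``end > len`` to denote wrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")

Topology = str  # "linear" | "circular"


def _validate_symbols(symbols: str) -> None:
    for i, ch in enumerate(symbols):
        if ch not in _VALID:
            raise ValueError(f"invalid nucleotide symbol {ch!r} at position {i}")


@dataclass(frozen=True)
class NucSeq:
    """An uppercase DNA sequence over {A, C, G, T, N} with a topology.

    Parameters
    ----------
    symbols:
        The plus-strand sequence, 5'->3'.  Normalised to uppercase.
    topology:
        ``"linear"`` or ``"circular"``.
    name:
        Free-text label carried through FASTA round trips.
    """

    symbols: str
    topology: Topology = "linear"
    name: str = ""

    def __post_init__(self) -> None:
        up = self.symbols.upper()
        _validate_symbols(up)
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "symbols", up)

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, end: int) -> str:
        """Plus-strand slice [start, end); wraps the origin when circular.

        On circular molecules coordinates are taken modulo length and ``end``
        may exceed ``len`` (or ``start`` may be negative) to denote an arc
        through the origin.  On linear molecules out-of-range coordinates are
        rejected.
        """
        if end < start:
            raise ValueError(f"end {end} < start {start}")
        n = len(self.symbols)
        if not self.is_circular:
            if start < 0 or end > n:
                raise ValueError(
                    f"window [{start}, {end}) outside linear sequence of length {n}"
                )
            return self.symbols[start:end]
        if end - start > n:
            raise ValueError(f"window [{start}, {end}) longer than circle ({n})")
        s = start % n
        e = s + (end - start)
        if e <= n:
            return self.symbols[s:e]
        return self.symbols[s:] + self.symbols[: e - n]

    def replace(self, **kw) -> "NucSeq":
        d = {"symbols": self.symbols, "topology": self.topology, "name": self.name}
        d.update(kw)
        return NucSeq(**d)


def revcomp_str(symbols: str) -> str:
    """Reverse complement of a raw symbol string (validates symbols)."""
    _validate_symbols(symbols.upper())
    return symbols.upper().translate(_COMPLEMENT)[::-1]


def reverse_complement(seq: NucSeq | str) -> NucSeq | str:
    """Watson-Crick reverse complement; topology and name are preserved.

    Accepts either a ``NucSeq`` (returns ``NucSeq``) or a plain string
    (returns a string) so callers can use it on fragments.
    """
    if isinstance(seq, str):
        return revcomp_str(seq)
    return seq.replace(symbols=revcomp_str(seq.symbols))


@dataclass(frozen=True)
class Feature:
    """A labeled interval on a construct (BED-like, 0-based half-open)."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end < self.start:
            raise ValueError("feature end < start")
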