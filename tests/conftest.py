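import random

import pytest

from cutfuse import JunctionRef, NucSeq, make_fixture


@pytest.fixture(scope="session")
def locus():
    """Linear two-cut locus fixture shared across tests."""
    return make_fixture("two_cut_locus", scale=3000, seed=7)


@pytest.fixture(scope="session")
def locus_sites(locus):
    return locus.guide_sites("sgA")[0], locus.guide_sites("sgB")[0]


@pytest.fixture(scope="session")
def igfp():
    return make_fixture("igfp_like", scale=4000, seed=1)


@pytest.fixture(scope="session")
def lsl():
    return make_fixture("lsl_like", scale=4000, seed=2)


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_junction(seq: str, fusion: int | None = None, label: str = "test") -> JunctionRef:
    if fusion is None:
        fusion = len(seq) // 2
    return JunctionRef(
        sequence=NucSeq(seq, name=label),
        fusion_point=fusion,
        label=label,
        flank=min(fusion, len(seq) - fusion),
    )


def glocal_affine_oracle(
    ref: str,
    read: str,
    match: float = 2.0,
    mismatch: float = -4.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
) -> float:
    """Brute-force optimal glocal affine alignment score.

    Read is aligned globally, the reference locally (unaligned reference
    prefix/suffix are free).  Plain dynamic program over three states:
    M (read base vs ref base), X (read base vs gap), Y (ref base vs gap,
    interior only).  A gap of length L costs gap_open + (L-1)*gap_extend.
    Independent of the production aligner.
    """
    n, m = len(read), len(ref)
    NEG = float("-inf")
    # rows indexed by read position i (0..n), cols by ref position j (0..m)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    start = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        start[0][j] = 0.0  # free reference prefix
    for i in range(1, n + 1):
        for j in range(m + 1):
            if j >= 1:
                s = match if read[i - 1] == ref[j - 1] else mismatch
                best_prev = max(
                    M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], start[i - 1][j - 1]
                )
                if best_prev > NEG:
                    M[i][j] = best_prev + s
            # read base against a gap in the reference
            opens = max(M[i - 1][j], Y[i - 1][j], start[i - 1][j])
            X[i][j] = max(
                opens + gap_open if opens > NEG else NEG,
                X[i - 1][j] + gap_extend if X[i - 1][j] > NEG else NEG,
            )
            # reference base against a gap in the read (interior deletion)
            if j >= 1:
                opens = max(M[i][j - 1], X[i][j - 1])
                Y[i][j] = max(
                    opens + gap_open if opens > NEG else NEG,
                    Y[i][j - 1] + gap_extend if Y[i][j - 1] > NEG else NEG,
                )
    # free reference suffix: take the best over all end columns
    return max(max(M[n][j], X[n][j]) for j in range(m + 1))
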