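"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own algorithms: the junction oracle
enumerates every (alignment, crossover, insertion) explanation of a fusion
sequence; the reciprocal oracle counts orphaned/duplicated bases with
explicit indicator vectors over a miniature chromosome.
"""

from __future__ import annotations

import numpy as np

ACGT = set("ACGT")


def oracle_decompose(fusion: str, refA: str, refB: str, min_anchor: int = 12):
    """Enumerate all explanations; minimal insertion, leftmost crossover.

    Returns (mechanism, mh_len, ins_seq, posA, posB) with posA the last
    retained A base and posB the first retained B base of the canonical
    (leftmost) placement, or None when no explanation has both anchors.
    """
    L = len(fusion)

    def max_prefix(a: int) -> int:
        p = 0
        while p < L and a + p < len(refA) and fusion[p] == refA[a + p] and fusion[p] in ACGT:
            p += 1
        return p

    def max_suffix(e: int) -> int:
        s = 0
        while s < L and e - s - 1 >= 0 and fusion[L - s - 1] == refB[e - s - 1] and fusion[L - s - 1] in ACGT:
            s += 1
        return s

    pre = {a: max_prefix(a) for a in range(len(refA))}
    pre = {a: p for a, p in pre.items() if p >= min_anchor}
    suf = {e: max_suffix(e) for e in range(1, len(refB) + 1)}
    suf = {e: s for e, s in suf.items() if s >= min_anchor}
    if not pre or not suf:
        return None

    best = None
    for a, pa in pre.items():
        for e, se in suf.items():
            ell = max(0, L - pa - se)
            # tie-break matches the caller-facing convention: minimal
            # insertion first; for insertions the maximal-prefix split is
            # the unique minimiser; for overlap the leftmost crossover
            if ell > 0:
                key = (ell, -(pa + se), a)
                cand = (key, "insertion", 0, fusion[pa : L - se], a + pa - 1, e - se)
            else:
                h = pa + se - L
                j = L - se  # leftmost: A contributes its minimal share
                mech = "microhomology" if h >= 1 else "blunt"
                key = (0, -(pa + se), a + j - 1)
                cand = (key, mech, h, "", a + j - 1, e - se)
            if best is None or cand[0] < best[0]:
                best = cand
    return best[1], best[2], best[3], best[4], best[5]


def oracle_reciprocal_deltas(pos22_f, pos9_f, pos22_r, pos9_r, len22, len9):
    """Set-arithmetic deltas via explicit retained-base indicator vectors.

    delta > 0: bases on neither derivative (deletion); delta < 0: minus the
    number of bases on both derivatives (duplication).
    """
    der22_fwd = np.zeros(len22, dtype=bool)
    der22_fwd[: pos22_f + 1] = True  # chr22 bases retained on derivative 22
    der22_rec = np.zeros(len22, dtype=bool)
    der22_rec[pos22_r:] = True  # chr22 bases retained on derivative 9
    orphan22 = int((~der22_fwd & ~der22_rec).sum())
    dup22 = int((der22_fwd & der22_rec).sum())

    der9_fwd = np.zeros(len9, dtype=bool)
    der9_fwd[pos9_f:] = True  # chr9 bases retained on derivative 22
    der9_rec = np.zeros(len9, dtype=bool)
    der9_rec[: pos9_r + 1] = True  # chr9 bases retained on derivative 9
    orphan9 = int((~der9_fwd & ~der9_rec).sum())
    dup9 = int((der9_fwd & der9_rec).sum())

    assert orphan22 == 0 or dup22 == 0
    assert orphan9 == 0 or dup9 == 0
    return orphan22 - dup22, orphan9 - dup9


def random_junction_instance(rng, ref_len: int = 400, flank_lo: int = 20, flank_hi: int = 60):
    """A random fusion instance with NO boundary control (the hard case:
    accidental homology and chance insert-flank matches are all possible).

    Returns (fusion, refA, refB, a_start, cutA, cutB, ins).
    """
    refA = "".join(rng.choice(list("ACGT"), ref_len))
    refB = "".join(rng.choice(list("ACGT"), ref_len))
    fl_a = int(rng.integers(flank_lo, flank_hi))
    fl_b = int(rng.integers(flank_lo, flank_hi))
    cutA = int(rng.integers(fl_a + 5, ref_len - 5))
    cutB = int(rng.integers(5, ref_len - fl_b - 5))
    ell = int(rng.integers(0, 7))
    ins = "".join(rng.choice(list("ACGT"), ell))
    fusion = refA[cutA - fl_a : cutA] + ins + refB[cutB : cutB + fl_b]
    return fusion, refA, refB, cutA - fl_a, cutA, cutB, ins
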