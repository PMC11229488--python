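"""Junction primary-structure classification.

A fusion sequence F spanning a translocation junction is decomposed against
its two partner references into

* ``p`` — the length of the maximal prefix of F matching partner A
  contiguously from its aligned start, and
* ``s`` — the length of the maximal suffix of F matching partner B
  contiguously up to its aligned end.

The arithmetic of p and s against ``|F|`` determines the repair signature:

* ``p + s == |F|``  → blunt join (no shared, no untemplated bases),
* ``p + s  > |F|``  → microhomology of ``h = p + s - |F|`` bases shared by
  both partners at the crossover; the crossover is ambiguous over ``h + 1``
  equivalent placements,
* ``p + s  < |F|``  → untemplated insertion ``F[p : |F|-s]`` (minimal over
  all explanations; the minimiser is unique).

These three categories are the classic non-homologous end joining (NHEJ)
junction signatures.  Canonical breakpoints are reported under the leftmost
rule: within a microhomology window the crossover is placed at the 5'-most
equivalent position on both partners.

Coordinates follow the package convention: ``canonical_posA`` is the last
partner-A base retained in the fusion, ``canonical_posB`` the first
partner-B base retained (both 0-based).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "JunctionCall",
    "UnanchoredJunctionError",
    "classify_junction",
    "classify_cohort",
    "canonicalize_breakpoints",
    "CohortJunctionSummary",
]

MECHANISMS = ("microhomology", "blunt", "insertion")
_EXACT = set("ACGT")


class UnanchoredJunctionError(ValueError):
    """Fusion sequence cannot be anchored to both partners (prefix or
    suffix match below the minimum anchor length)."""


@dataclass(frozen=True)
class JunctionCall:
    mechanism: str
    mh_len: int
    ins_seq: str
    canonical_posA: int
    canonical_posB: int
    ambiguity_window: int

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "microhomology" and not (self.mh_len >= 1 and not self.ins_seq):
            raise ValueError("microhomology requires mh_len >= 1 and empty ins_seq")
        if self.mechanism == "blunt" and not (self.mh_len == 0 and not self.ins_seq):
            raise ValueError("blunt requires mh_len == 0 and empty ins_seq")
        if self.mechanism == "insertion" and not (self.ins_seq and self.mh_len == 0):
            raise ValueError("insertion requires non-empty ins_seq and mh_len == 0")
        if self.ambiguity_window != self.mh_len + 1:
            raise ValueError("ambiguity_window must equal mh_len + 1")


def _bases_match(a: str, b: str) -> bool:
    # IUPAC ambiguity codes in references are conservative mismatches,
    # even against an identical code.
    return a == b and a in _EXACT


def _prefix_len(fusion: str, ref: str, start: int) -> int:
    """Maximal contiguous match of fusion's prefix to ref from ``start``."""
    n = 0
    limit = min(len(fusion), len(ref) - start)
    while n < limit and _bases_match(fusion[n], ref[start + n]):
        n += 1
    return n

def _suffix_len(fusion: str, ref: str, end: int) -> int:
    """Maximal contiguous match of fusion's suffix to ref ending at ``end``
    (half-open, i.e. the last matched ref base is ``end - 1``)."""
    n = 0
    limit = min(len(fusion), end)
    L = len(fusion)
    while n < limit and _bases_match(fusion[L - n - 1], ref[end - n - 1]):
        n += 1
    return n


def _seed_occurrences(seed: str, ref: str, lo: int, hi: int) -> list[int]:
    """All occurrence starts of ``seed`` in ``ref[lo:hi]`` (absolute)."""
    lo = max(0, lo)
    hi = min(len(ref), hi)
    out = []
    pos = ref.find(seed, lo)
    while 0 <= pos and pos + len(seed) <= hi:
        out.append(pos)
        pos = ref.find(seed, pos + 1)
    return out


def _best_prefix_alignment(
    fusion: str, refA: str, anchorA: int | None, min_anchor: int, slack: int
):
    """(start, p) of the alignment maximising the prefix extension."""
    seed = fusion[:min_anchor]
    if anchorA is None:
        lo, hi = 0, len(refA)
    else:
        lo, hi = anchorA - len(fusion) - slack, anchorA + slack + min_anchor
    best = None
    for a in _seed_occurrences(seed, refA, lo, hi):
        p = min_anchor + _prefix_len(fusion[min_anchor:], refA, a + min_anchor)
        key = (p, -(abs((a + p) - anchorA) if anchorA is not None else a))
        if best is None or key > best[0]:
            best = (key, a, p)
    if best is None:
        return None
    return best[1], best[2]


def _best_suffix_alignment(
    fusion: str, refB: str, anchorB: int | None, min_anchor: int, slack: int
):
    """(end, s) of the alignment maximising the suffix extension."""
    seed = fusion[-min_anchor:]
    if anchorB is None:
        lo, hi = 0, len(refB)
    else:
        lo, hi = anchorB - slack - min_anchor, anchorB + len(fusion) + slack
    best = None
    L = len(fusion)
    for q in _seed_occurrences(seed, refB, lo, hi):
        end = q + min_anchor
        s = min_anchor + _suffix_len(fusion[: L - min_anchor], refB, end - min_anchor)
        key = (s, -(abs((end - s) - anchorB) if anchorB is not None else -end))
        if best is None or key > best[0]:
            best = (key, end, s)
    if best is None:
        return None
    return best[1], best[2]


def classify_junction(
    fusion_seq: str,
    refA: str,
    refB: str,
    anchorA: int | None = None,
    anchorB: int | None = None,
    min_anchor: int = 12,
    search_slack: int = 200,
) -> JunctionCall:
    """Decompose a junction-spanning sequence into a mechanism call.

    ``anchorA``/``anchorB`` are approximate crossover coordinates (last
    retained base on A / first retained base on B); when given, the
    alignment search is restricted to ``search_slack`` bases around them,
    otherwise the whole references are searched (feasible for region-sized
    references).

    Raises :class:`UnanchoredJunctionError` when the prefix or suffix match
    is shorter than ``min_anchor`` — the escape hatch for complex events
    (e.g. inserted third-chromosome sequence longer than the read-out, or
    chromosome-9 fragments inserted into BCR) that this classifier only
    flags.
    """
    fusion_seq = fusion_seq.upper()
    if len(fusion_seq) < 2 * min_anchor:
        raise UnanchoredJunctionError(
            f"fusion sequence of {len(fusion_seq)} bases is shorter than two "
            f"anchors ({2 * min_anchor})"
        )
    pref = _best_prefix_alignment(fusion_seq, refA, anchorA, min_anchor, search_slack)
    if pref is None:
        raise UnanchoredJunctionError(
            f"no prefix anchor of {min_anchor} bases found on partner A"
        )
    suf = _best_suffix_alignment(fusion_seq, refB, anchorB, min_anchor, search_slack)
    if suf is None:
        raise UnanchoredJunctionError(
            f"no suffix anchor of {min_anchor} bases found on partner B"
        )
    a, p = pref
    b_end, s = suf
    L = len(fusion_seq)

    if p + s >= L:
        h = p + s - L
        # leftmost placement: A contributes its minimal share (L - s bases)
        cutA = a + (L - s)
        cutB = b_end - s
        mech = "microhomology" if h >= 1 else "blunt"
        return JunctionCall(mech, h, "", cutA - 1, cutB, h + 1)
    ins = fusion_seq[p : L - s]
    cutA = a + p
    cutB = b_end - s
    return JunctionCall("insertion", 0, ins, cutA - 1, cutB, 1)


def canonicalize_breakpoints(
    refA: str, refB: str, posA: int, posB: int, ins_seq: str = ""
) -> tuple[int, int, str, int]:
    """Leftmost-canonicalize a breakpoint pair against the references.

    ``posA`` = last retained A base, ``posB`` = first retained B base.
    Returns ``(posA, posB, ins_seq, mh_len)`` after (1) absorbing insertion
    bases into either flank where they match the reference (maximal prefix
    first, then maximal suffix — mirroring the p/s decomposition) and
    (2) for insertion-free junctions, sliding the crossover to the 5'-most
    placement within the microhomology window.  ``mh_len`` is the window
    size found in step 2.
    """
    cutA, cutB = posA + 1, posB
    ins = ins_seq.upper()
    changed = True
    while changed:
        changed = False
        while ins and cutA < len(refA) and _bases_match(refA[cutA], ins[0]):
            cutA += 1
            ins = ins[1:]
            changed = True
        while ins and cutB > 0 and _bases_match(refB[cutB - 1], ins[-1]):
            cutB -= 1
            ins = ins[:-1]
            changed = True
    h = 0
    if not ins:
        # slide left through shared (microhomologous) bases
        while cutA > 0 and cutB > 0 and _bases_match(refA[cutA - 1], refB[cutB - 1]):
            cutA -= 1
            cutB -= 1
            h += 1
        # the window also extends to the right of the drawn crossover
        j = 0
        while (
            cutA + h + j < len(refA)
            and cutB + h + j < len(refB)
            and _bases_match(refA[cutA + h + j], refB[cutB + h + j])
        ):
            j += 1
        h += j
    return cutA - 1, cutB, ins, h


@dataclass
class CohortJunctionSummary:
    """Mechanism mixture and length summaries over a classified cohort."""

    fractions: dict[str, float]
    counts: dict[str, int]
    n_classified: int
    n_unclassifiable: int
    unclassifiable_ids: list[str]
    mh_len_median: float | None
    mh_len_range: tuple[int, int] | None
    ins_len_median: float | None
    ins_len_range: tuple[int, int] | None
    calls: pd.DataFrame = field(repr=False, default=None)


def classify_cohort(
    records: Iterable,
    refA: str,
    refB: str,
    min_anchor: int = 12,
    search_slack: int = 200,
) -> CohortJunctionSummary:
    """Classify every record carrying a junction sequence.

    ``records`` are :class:`~phbreak.io_formats.PatientRecord` objects whose
    ``junction_seq`` spans the forward junction; the recorded forward
    breakpoints serve as alignment anchors.  Mechanism fractions are taken
    over classifiable records (they sum to 1); length medians/ranges are
    computed within the relevant mechanism class only, matching how junction
    structure mixtures are reported for fusion cohorts.
    """
    rows = []
    unclassifiable = []
    for rec in records:
        if rec.junction_seq is None:
            continue
        try:
            call = classify_junction(
                rec.junction_seq,
                refA,
                refB,
                anchorA=rec.forward.pos22,
                anchorB=rec.forward.pos9,
                min_anchor=min_anchor,
                search_slack=search_slack,
            )
        except UnanchoredJunctionError:
            unclassifiable.append(rec.patient_id)
            continue
        rows.append(
            {
                "patient_id": rec.patient_id,
                "mechanism": call.mechanism,
                "mh_len": call.mh_len,
                "ins_len": len(call.ins_seq),
                "ins_seq": call.ins_seq,
                "canonical_posA": call.canonical_posA,
                "canonical_posB": call.canonical_posB,
                "ambiguity_window": call.ambiguity_window,
            }
        )
    if not rows:
        raise ValueError("no classifiable junction sequences in cohort")
    calls = pd.DataFrame(rows)
    n = len(calls)
    counts = {m: int((calls["mechanism"] == m).sum()) for m in MECHANISMS}
    fractions = {m: counts[m] / n for m in MECHANISMS}
    mh = calls.loc[calls["mechanism"] == "microhomology", "mh_len"]
    ins = calls.loc[calls["mechanism"] == "insertion", "ins_len"]
    return CohortJunctionSummary(
        fractions=fractions,
        counts=counts,
        n_classified=n,
        n_unclassifiable=len(unclassifiable),
        unclassifiable_ids=unclassifiable,
        mh_len_median=float(mh.median()) if len(mh) else None,
        mh_len_range=(int(mh.min()), int(mh.max())) if len(mh) else None,
        ins_len_median=float(ins.median()) if len(ins) else None,
        ins_len_range=(int(ins.min()), int(ins.max())) if len(ins) else None,
        calls=calls,
    )
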