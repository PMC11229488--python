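"""Split-read fusion calling against two partner references.

A desk-scale stand-in for target-enrichment NGS breakpoint identification:
references are region-sized (up to a few hundred kbp), so an exact k-mer
seed index with mismatch-tolerant extension is both sufficient and fully
deterministic.  Each junction-spanning read is split into a prefix aligned
to the head partner and a suffix aligned to the tail partner (both
orientations are tried: BCR::ABL1-type reads have their head on partner A,
reciprocal ABL1::BCR-type reads on partner B).  An untemplated-insert gap
between prefix and suffix is allowed and priced below a mismatch, so short
insertion junctions are recovered rather than forced into noisy splits.

Per-read votes are leftmost-canonicalized, clustered within a +/-3 base
window (absorbing canonicalization jitter from sequencing errors), a
consensus junction sequence is built by per-column majority over the
cluster's reads, and the consensus is classified by
:mod:`~phbreak.junction_classifier`, which yields the final canonical
coordinates and mechanism call.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .junction_classifier import (
    JunctionCall,
    UnanchoredJunctionError,
    canonicalize_breakpoints,
    classify_junction,
)

__all__ = ["FusionCall", "call_fusion"]

logger = logging.getLogger(__name__)

# cost of one untemplated inserted base relative to one mismatch (=1);
# below the 0.75 expected per-base cost of forcing a random insert into
# alignment, above typical per-base error rates
INS_BASE_COST = 0.6
CLUSTER_WINDOW = 3


@dataclass
class FusionCall:
    """One called fusion junction.

    ``posA``/``posB`` are canonical coordinates on partner A / partner B
    regardless of orientation.  For ``orientation="AB"`` (head on A) posA is
    the last retained A base and posB the first retained B base; for
    ``orientation="BA"`` (reciprocal) posB is the last retained B base and
    posA the first retained A base.
    """

    posA: int
    posB: int
    orientation: str
    junction_consensus: str
    support: int
    call: JunctionCall


def _to_seq(read) -> str:
    if hasattr(read, "seq"):
        return str(read.seq).upper()
    return str(read).upper()


def _build_index(ref: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(ref) - k + 1):
        index[ref[i : i + k]].append(i)
    return dict(index)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _diagonals(read: str, index: dict, k: int, step: int, max_diags: int = 2) -> list[int]:
    """Candidate alignment diagonals (position of read[0] on the ref)."""
    votes: Counter = Counter()
    offsets = list(range(0, len(read) - k + 1, step))
    if offsets and offsets[-1] != len(read) - k:
        offsets.append(len(read) - k)
    for o in offsets:
        for pos in index.get(read[o : o + k], ()):
            votes[pos - o] += 1
    return [d for d, _ in votes.most_common(max_diags)]


def _mismatch_profiles(read_arr: np.ndarray, ref_arr: np.ndarray, d: int):
    """(cum_prefix, suffix) mismatch arrays for the read on diagonal ``d``.

    cum_prefix[j] = mismatches of read[:j] vs ref[d:d+j];
    suffix[m] = mismatches of read[m:] vs ref[d+m:].  Out-of-range ref
    positions count as mismatches.
    """
    L = len(read_arr)
    mism = np.ones(L, dtype=np.int32)
    lo = max(0, -d)
    hi = min(L, len(ref_arr) - d)
    if hi > lo:
        mism[lo:hi] = (read_arr[lo:hi] != ref_arr[d + lo : d + hi]).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(mism)))
    suffix = cum[-1] - cum
    return cum, suffix


def _best_split(cum_head, suf_tail, L: int, min_anchor: int):
    """Minimal-cost (j, m): head takes read[:j], tail takes read[m:]."""
    j_lo, m_hi = min_anchor, L - min_anchor
    if j_lo > m_hi:
        return None
    gs = cum_head[j_lo : m_hi + 1] - INS_BASE_COST * np.arange(j_lo, m_hi + 1)
    best_g = np.minimum.accumulate(gs)
    # first index achieving each running minimum (stable leftmost tie-break)
    strict_new = gs < np.concatenate(([np.inf], best_g[:-1]))
    arg = np.maximum.accumulate(np.where(strict_new, np.arange(len(gs)), 0))
    ms = np.arange(j_lo, m_hi + 1)
    cost = best_g + suf_tail[j_lo : m_hi + 1] + INS_BASE_COST * ms
    t = int(np.argmin(cost))
    return j_lo + int(arg[t]), j_lo + t, float(cost[t])


def _best_feasible_split(
    cum_head, suf_tail, L: int, min_anchor: int, max_ins: int, max_mismatch_rate: float
):
    """Constrained fallback: minimal-cost split among those passing the
    mismatch-rate and insert-length filters (the unconstrained optimum can
    be an infeasible chance alignment of a long untemplated insert)."""
    j_lo, m_hi = min_anchor, L - min_anchor
    if j_lo > m_hi:
        return None
    js = np.arange(j_lo, m_hi + 1)
    mism = cum_head[js][:, None] + suf_tail[js][None, :]
    ell = js[None, :] - js[:, None]
    cost = mism + INS_BASE_COST * ell
    feasible = (ell >= 0) & (ell <= max_ins) & (mism <= max_mismatch_rate * (L - ell))
    if not feasible.any():
        return None
    cost = np.where(feasible, cost, np.inf)
    flat = int(np.argmin(cost))
    ji, mi = divmod(flat, cost.shape[1])
    return int(js[ji]), int(js[mi]), float(cost[ji, mi])


def call_fusion(
    reads: Iterable,
    refA: str,
    refB: str,
    min_anchor: int = 12,
    min_support: int = 2,
    max_mismatch_rate: float = 0.05,
    max_ins: int = 60,
    seed_step: int = 6,
) -> list[FusionCall]:
    """Call fusion junctions from junction-spanning reads.

    ``reads`` may be sequence strings or Biopython SeqRecords.  Returns one
    :class:`FusionCall` per breakpoint cluster with at least ``min_support``
    voting reads, sorted by (orientation, posA, posB).  Reads whose best
    split is unanchored, too mismatched, or ambiguous between orientations
    are discarded (with a debug-log reason); reads matching only one
    reference never vote, so pure non-chimeric input yields an empty list.
    """
    refA = refA.upper()
    refB = refB.upper()
    arrA, arrB = _encode(refA), _encode(refB)
    k = min_anchor
    idxA = _build_index(refA, k)
    idxB = _build_index(refB, k)

    # votes[orientation] -> list of (posH, posT, ins, dH, dT, j, m, read)
    votes: dict[str, list] = {"AB": [], "BA": []}
    for read in reads:
        seq = _to_seq(read)
        L = len(seq)
        if L < 2 * min_anchor:
            continue
        arr = _encode(seq)
        cand = []
        for orientation, (refH, arrH, idxH, refT, arrT, idxT) in (
            ("AB", (refA, arrA, idxA, refB, arrB, idxB)),
            ("BA", (refB, arrB, idxB, refA, arrA, idxA)),
        ):
            for dH in _diagonals(seq, idxH, k, seed_step):
                cumH, _ = _mismatch_profiles(arr, arrH, dH)
                for dT in _diagonals(seq, idxT, k, seed_step):
                    _, sufT = _mismatch_profiles(arr, arrT, dT)
                    split = _best_split(cumH, sufT, L, min_anchor)
                    if split is None:
                        continue
                    j, m, cost = split
                    mism = int(cumH[j] + sufT[m])
                    ins_len = m - j
                    if ins_len > max_ins or mism > max_mismatch_rate * (L - ins_len):
                        split = _best_feasible_split(
                            cumH, sufT, L, min_anchor, max_ins, max_mismatch_rate
                        )
                        if split is None:
                            continue
                        j, m, cost = split
                    cand.append((cost, orientation, dH, dT, j, m))
        if not cand:
            continue
        cand.sort(key=lambda c: c[0])
        if len(cand) > 1 and cand[1][0] == cand[0][0]:
            a, b = cand[0], cand[1]
            if (a[1], a[2] + a[4], a[3] + a[5]) != (b[1], b[2] + b[4], b[3] + b[5]):
                logger.debug("ambiguous multi-mapping read discarded: %s...", seq[:20])
                continue
        cost, orientation, dH, dT, j, m = cand[0]
        refH, refT = (refA, refB) if orientation == "AB" else (refB, refA)
        posH, posT, ins, _h = canonicalize_breakpoints(
            refH, refT, dH + j - 1, dT + m, seq[j:m]
        )
        votes[orientation].append((posH, posT, ins, dH, dT, j, m, seq))

    # classify every cluster, then merge clusters that canonicalize to the
    # same junction (vote jitter from chance-aligned insert bases can split
    # one junction's reads across nearby clusters) and apply min_support to
    # the merged support
    merged: dict[tuple, FusionCall] = {}
    for orientation, vote_list in votes.items():
        refH, refT = (refA, refB) if orientation == "AB" else (refB, refA)
        for cluster in _cluster(vote_list):
            call = _consensus_call(cluster, refH, refT, min_anchor)
            if call is None:
                continue
            consensus, jcall = call
            if orientation == "AB":
                posA, posB = jcall.canonical_posA, jcall.canonical_posB
            else:
                posB, posA = jcall.canonical_posA, jcall.canonical_posB
            key = (orientation, posA, posB)
            if key in merged:
                old = merged[key]
                keep = old if old.support >= len(cluster) else FusionCall(
                    posA, posB, orientation, consensus, len(cluster), jcall
                )
                keep.support = old.support + len(cluster)
                merged[key] = keep
            else:
                merged[key] = FusionCall(
                    posA, posB, orientation, consensus, len(cluster), jcall
                )
    calls = [c for c in merged.values() if c.support >= min_support]
    calls.sort(key=lambda c: (c.orientation, c.posA, c.posB))
    return calls


def _cluster(vote_list: list) -> list[list]:
    """Greedy clustering of votes within a Chebyshev +/-CLUSTER_WINDOW."""
    clusters: list[list] = []
    for vote in sorted(vote_list, key=lambda v: (v[0], v[1])):
        placed = False
        for cl in clusters:
            ph, pt = cl[0][0], cl[0][1]
            if abs(vote[0] - ph) <= CLUSTER_WINDOW and abs(vote[1] - pt) <= CLUSTER_WINDOW:
                cl.append(vote)
                placed = True
                break
        if not placed:
            clusters.append([vote])
    return clusters


def _consensus_call(cluster: list, refH: str, refT: str, min_anchor: int):
    """Per-column majority consensus over a cluster, then classification."""
    # modal canonical vote anchors the consensus coordinate frame
    (posH0, posT0, ins0), _n = Counter((v[0], v[1], v[2]) for v in cluster).most_common(1)[0]
    cutH0, cutT0 = posH0 + 1, posT0
    ell0 = len(ins0)
    w = max(min_anchor + 8, 30)
    ncols = w + ell0 + w  # head flank | insert | tail flank
    counts: list[Counter] = [Counter() for _ in range(ncols)]
    for posH, posT, ins, dH, dT, j, m, seq in cluster:
        for i, base in enumerate(seq):
            if i < j:  # head-partner part
                col = (dH + i) - (cutH0 - w)
            elif i >= m:  # tail-partner part
                col = w + ell0 + ((dT + i) - cutT0)
            else:  # insert part
                col = w + (i - j)
                if i - j >= ell0:
                    continue
            if 0 <= col < ncols:
                counts[col][base] += 1
    consensus = []
    for col, ctr in enumerate(counts):
        if ctr:
            top = max(sorted(ctr), key=lambda b: ctr[b])
            consensus.append(top)
        else:
            # uncovered column: fill from the modal reconstruction
            if col < w:
                consensus.append(refH[cutH0 - w + col])
            elif col < w + ell0:
                consensus.append(ins0[col - w])
            else:
                consensus.append(refT[cutT0 + col - w - ell0])
    try:
        jcall = classify_junction(
            "".join(consensus),
            refH,
            refT,
            anchorA=posH0,
            anchorB=posT0,
            min_anchor=min_anchor,
        )
    except UnanchoredJunctionError:
        logger.debug("cluster at (%d, %d): consensus unclassifiable", posH0, posT0)
        return None
    return "".join(consensus), jcall
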