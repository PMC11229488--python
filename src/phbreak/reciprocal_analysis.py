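"""Reciprocal-translocation balance arithmetic.

A reciprocal t(9;22)-type exchange produces two derivative chromosomes.
With both partner genes plus-strand, the forward (BCR::ABL1-type)
derivative retains chr22 bases <= ``pos22_f`` and chr9 bases >= ``pos9_f``;
the reciprocal (ABL1::BCR-type) derivative retains chr9 bases <= ``pos9_r``
and chr22 bases >= ``pos22_r``.  The per-chromosome imbalance is

    delta22 = pos22_r - pos22_f - 1
    delta9  = pos9_f  - pos9_r  - 1

so that adjacency (every base on exactly one derivative) gives delta = 0:
positive deltas count bases on neither derivative (deletion), negative
deltas bases present on both (duplication).  "Perfectly balanced" means
delta = 0 on both chromosomes; the +/-1 bp and +/-100 bp windows are
|delta| <= 1 (on both) and |delta| <= 100 (per gene).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import BreakpointPair, PatientRecord

__all__ = ["ReciprocalSummary", "reciprocal_deltas", "cohort_reciprocal_report"]

LARGE_EVENT_THRESHOLD = 10_000  # bases; "large" deletions/duplications


def _classify_delta(delta: int) -> str:
    if delta == 0:
        return "balanced"
    return "deletion" if delta > 0 else "duplication"


@dataclass(frozen=True)
class ReciprocalSummary:
    delta22: int
    delta9: int
    class22: str
    class9: str
    within_1bp: bool
    within_100bp_22: bool
    within_100bp_9: bool


def reciprocal_deltas(fwd: BreakpointPair, rec: BreakpointPair) -> ReciprocalSummary:
    """Per-chromosome deletion/duplication deltas for one patient."""
    if fwd.kind != "forward" or rec.kind != "reciprocal":
        raise ValueError(
            f"expected (forward, reciprocal) pair, got ({fwd.kind}, {rec.kind})"
        )
    delta22 = rec.pos22 - fwd.pos22 - 1
    delta9 = fwd.pos9 - rec.pos9 - 1
    return ReciprocalSummary(
        delta22=delta22,
        delta9=delta9,
        class22=_classify_delta(delta22),
        class9=_classify_delta(delta9),
        within_1bp=abs(delta22) <= 1 and abs(delta9) <= 1,
        within_100bp_22=abs(delta22) <= 100,
        within_100bp_9=abs(delta9) <= 100,
    )


def cohort_reciprocal_report(
    records: Iterable[PatientRecord],
    large_threshold: int = LARGE_EVENT_THRESHOLD,
) -> dict:
    """Cohort-level reciprocal concordance counts.

    Computed over patients with both fusions characterized; percentages come
    with their denominator (``n_paired``).  ``n_del_gt_thr_*`` /
    ``n_dup_gt_thr_*`` count events strictly larger than
    ``large_threshold`` bases.
    """
    summaries = [
        reciprocal_deltas(rec.forward, rec.reciprocal)
        for rec in records
        if rec.reciprocal is not None
    ]
    n = len(summaries)
    if n == 0:
        raise ValueError("no records with both forward and reciprocal fusions")
    dels22 = [s.delta22 for s in summaries if s.delta22 > 0]
    dels9 = [s.delta9 for s in summaries if s.delta9 > 0]
    dups22 = [-s.delta22 for s in summaries if s.delta22 < 0]
    dups9 = [-s.delta9 for s in summaries if s.delta9 < 0]
    report = {
        "n_paired": n,
        "n_within_1bp_both": sum(s.within_1bp for s in summaries),
        "n_perfectly_balanced": sum(
            s.delta22 == 0 and s.delta9 == 0 for s in summaries
        ),
        "n_within_100bp_22": sum(s.within_100bp_22 for s in summaries),
        "n_within_100bp_9": sum(s.within_100bp_9 for s in summaries),
        "n_del_gt_thr_22": sum(d > large_threshold for d in dels22),
        "n_del_gt_thr_9": sum(d > large_threshold for d in dels9),
        "n_dup_gt_thr_22": sum(d > large_threshold for d in dups22),
        "n_dup_gt_thr_9": sum(d > large_threshold for d in dups9),
        "max_del_22": max(dels22, default=0),
        "max_del_9": max(dels9, default=0),
        "max_dup_22": max(dups22, default=0),
        "max_dup_9": max(dups9, default=0),
        "large_threshold": large_threshold,
    }
    report["pct_within_100bp_22"] = 100.0 * report["n_within_100bp_22"] / n
    report["pct_within_100bp_9"] = 100.0 * report["n_within_100bp_9"] / n
    report["pct_within_1bp_both"] = 100.0 * report["n_within_1bp_both"] / n
    return report
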