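import numpy as np
import pytest

from phbreak.io_formats import GenomicRegion
from phbreak.motif_enrichment import (
    MotifPattern,
    adjust_enrichment,
    default_motifs,
    proximity_enrichment,
    reverse_complement,
    scan_iupac,
    scan_rss,
)

REGION = GenomicRegion("scan", "chr9", 0, 10_000, "toy")


def test_palindromic_pattern_hits_both_strands():
    m = MotifPattern("acgt", "iupac", pattern="ACGT")
    assert scan_iupac("AACGTT", m) == [(1, 5, "+"), (1, 5, "-")]


def test_planted_motif_recovered_exactly():
    from phbreak import make_toy_reference

    offsets = [5_000, 12_345, 30_000]
    ref = make_toy_reference(
        seed=5, planted_motifs=[("CACAGTG", "chr9", o) for o in offsets]
    )
    m = MotifPattern("hep", "iupac", pattern="CACAGTG")
    hits = scan_iupac(ref.sequences["chr9"], m)
    plus = {h[0] for h in hits if h[2] == "+"}
    assert set(offsets) <= plus


def test_fully_degenerate_pattern_hit_count(rng):
    """NNNN matches every window: |seq| - 3 hits per strand."""
    seq = "".join(rng.choice(list("ACGT"), 10_000))
    m = MotifPattern("n4", "iupac", pattern="NNNN")
    hits = scan_iupac(seq, m)
    assert sum(1 for h in hits if h[2] == "+") == 10_000 - 3
    assert sum(1 for h in hits if h[2] == "-") == 10_000 - 3


def test_iupac_mismatch_allowance():
    m0 = MotifPattern("x", "iupac", pattern="AAAAAA", max_mismatches=0)
    m1 = MotifPattern("x", "iupac", pattern="AAAAAA", max_mismatches=1)
    seq = "CCAAAATACC"
    assert [h for h in scan_iupac(seq, m0) if h[2] == "+"] == []
    assert any(h[2] == "+" for h in scan_iupac(seq, m1))


def test_invalid_iupac_code_named():
    with pytest.raises(ValueError, match="'X'"):
        MotifPattern("bad", "iupac", pattern="ACXGT")


def test_rss_requires_heptamer_spacer_nonamer():
    rss = MotifPattern("rss12", "rss", spacer=12)
    hep, non = "CACAGTG", "ACAAAAACC"
    hit_seq = "TTTT" + hep + "G" * 12 + non + "TTTT"
    assert scan_rss(hit_seq, rss) == [(4, 4 + 7 + 12 + 9, "+")]
    assert scan_rss("TTTT" + hep + "TTTT", rss) == []  # heptamer alone
    # wrong spacer
    assert scan_rss("TTTT" + hep + "G" * 10 + non + "TTTT", rss) == []


def test_rss_minus_strand_orientation():
    rss = MotifPattern("rss12", "rss", spacer=12)
    hep, non = "CACAGTG", "ACAAAAACC"
    plus = "TT" + hep + "G" * 12 + non + "TT"
    minus = reverse_complement(plus)
    hits = scan_rss(minus, rss)
    assert len(hits) == 1 and hits[0][2] == "-"


def test_rss_nonamer_mismatch_allowance():
    hep, non = "CACAGTG", "ACAAAAACC"
    non_1mm = "ACATAAACC"
    seq = "TTTT" + hep + "G" * 12 + non_1mm + "TTTT"
    strict = MotifPattern("s", "rss", spacer=12, nonamer_mismatches=0)
    loose = MotifPattern("l", "rss", spacer=12, nonamer_mismatches=1)
    assert scan_rss(seq, strict) == []
    assert len(scan_rss(seq, loose)) == 1


def test_rss_spacer_slack():
    hep, non = "CACAGTG", "ACAAAAACC"
    seq = "TTTT" + hep + "G" * 13 + non + "TTTT"
    assert scan_rss(seq, MotifPattern("a", "rss", spacer=12)) == []
    assert len(scan_rss(seq, MotifPattern("b", "rss", spacer=12, spacer_slack=1))) == 1


def test_proximity_planted_signal_detected(rng):
    """Breakpoints placed exactly on motif hits give p at the permutation
    floor."""
    hits = [(int(p), int(p) + 7, "+") for p in rng.integers(100, 9_900, 40)]
    breakpoints = [h[0] + 3 for h in hits] + [h[0] for h in hits[:10]]
    res = proximity_enrichment(breakpoints, hits, REGION, n_perm=2000, seed=3)
    assert res.observed == len(breakpoints)
    assert res.p_value <= 0.001


def test_proximity_no_hits_flagged():
    res = proximity_enrichment([100, 200], [], REGION, n_perm=1000, seed=1)
    assert res.observed == 0
    assert res.p_value == 1.0
    assert "no hits" in res.flags


def test_proximity_deterministic_and_bounded(rng):
    hits = [(int(p), int(p) + 5, "+") for p in rng.integers(0, 9_000, 30)]
    bps = rng.integers(0, 10_000, 50)
    a = proximity_enrichment(bps, hits, REGION, n_perm=1500, seed=9)
    b = proximity_enrichment(bps, hits, REGION, n_perm=1500, seed=9)
    assert a.p_value == b.p_value and a.null_mean == b.null_mean
    assert a.p_value >= 1 / 1501


def test_observed_invariant_to_duplicated_hits(rng):
    hits = [(500, 507, "+"), (2_000, 2_007, "+")]
    bps = rng.integers(0, 10_000, 80)
    a = proximity_enrichment(bps, hits, REGION, n_perm=500, seed=4)
    b = proximity_enrichment(bps, hits * 5, REGION, n_perm=500, seed=4)
    assert a.observed == b.observed
    assert a.p_value == b.p_value


def test_density_matched_null_absorbs_regional_skew(rng):
    """With breakpoints drawn from a skewed profile and hits uniform, the
    density-matched null gives a larger (less significant) p than the
    uniform null whenever hits happen to sit in the dense part."""
    bps = rng.integers(0, 3_000, 60)  # strongly 5'-clustered
    hits = [(int(p), int(p) + 5, "+") for p in rng.integers(0, 3_000, 25)]
    uni = proximity_enrichment(bps, hits, REGION, n_perm=2000, seed=7, null="uniform")
    den = proximity_enrichment(bps, hits, REGION, n_perm=2000, seed=7, null="density")
    assert den.p_value > uni.p_value


def test_bh_adjustment_monotone(rng):
    results = []
    for seed in range(8):
        hits = [(int(p), int(p) + 5, "+") for p in rng.integers(0, 9_000, 20)]
        res = proximity_enrichment(
            rng.integers(0, 10_000, 40), hits, REGION, n_perm=500, seed=seed
        )
        res.motif = f"m{seed}"
        results.append(res)
    adjust_enrichment(results)
    assert all(r.adjusted_p >= r.p_value for r in results)
    by_p = sorted(results, key=lambda r: r.p_value)
    assert all(
        a.adjusted_p <= b.adjusted_p for a, b in zip(by_p, by_p[1:])
    )


def test_default_motif_catalog_loads():
    motifs = default_motifs()
    names = {m.name for m in motifs}
    assert {"rss_12", "rss_23"} <= names
    assert any(m.kind == "iupac" for m in motifs)
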