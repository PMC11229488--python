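import numpy as np
import pytest

from phbreak.junction_classifier import (
    JunctionCall,
    UnanchoredJunctionError,
    canonicalize_breakpoints,
    classify_cohort,
    classify_junction,
)

from _oracles import oracle_decompose, random_junction_instance


def _mk_refs(rng, n=400):
    return (
        "".join(rng.choice(list("ACGT"), n)),
        "".join(rng.choice(list("ACGT"), n)),
    )


def test_blunt_disjoint_flanks():
    """Flanks over disjoint alphabets can share nothing: a blunt join."""
    refA = "C" * 20 + "A" * 20 + "C" * 20
    refB = "G" * 20 + "T" * 20 + "G" * 20
    fusion = "A" * 20 + "T" * 20
    call = classify_junction(fusion, refA, refB, anchorA=39, anchorB=20)
    assert call.mechanism == "blunt"
    assert call.mh_len == 0 and call.ins_seq == ""
    assert call.ambiguity_window == 1
    assert call.canonical_posA == 39  # last A base retained
    assert call.canonical_posB == 20  # first B base retained


def test_microhomology_window_matches_crossover_enumeration(rng):
    """A shared ACGT at the junction gives h=4 and 5 equivalent crossover
    placements, verified by brute-force enumeration of all explanations."""
    refA, refB = _mk_refs(rng)
    cutA, cutB = 200, 150
    # engineer a 4-base shared word immediately 5' of the crossover
    refA = refA[: cutA - 4] + "ACGT" + refA[cutA:]
    refB = refB[: cutB - 4] + "ACGT" + refB[cutB:]
    # regenerate until the window is exactly 4 (no accidental extension)
    while refA[cutA - 5] == refB[cutB - 5] or refA[cutA] == refB[cutB]:
        refB = refB[: cutB - 5] + ("A" if refB[cutB - 5] != "A" else "C") + refB[cutB - 4 :]
        refB = refB[:cutB] + ("A" if refB[cutB] != "A" else "C") + refB[cutB + 1 :]
    fusion = refA[cutA - 40 : cutA] + refB[cutB : cutB + 40]
    call = classify_junction(fusion, refA, refB, anchorA=cutA - 1, anchorB=cutB)
    assert call.mechanism == "microhomology"
    assert call.mh_len == 4
    assert call.ambiguity_window == 5
    mech, h, ins, posA, posB = oracle_decompose(fusion, refA, refB)
    assert (call.mechanism, call.mh_len, call.ins_seq) == (mech, h, ins)
    assert (call.canonical_posA, call.canonical_posB) == (posA, posB)


def test_untemplated_insertion_detected_by_flank_comparison(rng):
    """Bases matching neither flank are reported as the insertion."""
    refA, refB = _mk_refs(rng)
    cutA, cutB = 180, 220
    ins = "GG"
    # make sure the insert cannot be absorbed into either flank
    while refA[cutA] == "G":
        cutA += 1
    while refB[cutB - 1] == "G":
        cutB += 1
    fusion = refA[cutA - 30 : cutA] + ins + refB[cutB : cutB + 30]
    call = classify_junction(fusion, refA, refB, anchorA=cutA - 1, anchorB=cutB)
    assert call.mechanism == "insertion"
    assert call.ins_seq == "GG"
    assert call.mh_len == 0
    assert fusion[30:32] == "GG"
    assert fusion[30:32] != refA[cutA : cutA + 2]
    assert fusion[30:32] != refB[cutB - 2 : cutB]


def test_reconstruction_identity(rng):
    """Rebuilding head[:posA+1] + ins + tail[posB:] reproduces the fusion."""
    for _ in range(200):
        fusion, refA, refB, a_start, _, _, _ = random_junction_instance(rng)
        call = classify_junction(fusion, refA, refB)
        rebuilt_len_tail = len(fusion) - (call.canonical_posA + 1 - a_start) - len(call.ins_seq)
        rebuilt = (
            refA[a_start : call.canonical_posA + 1]
            + call.ins_seq
            + refB[call.canonical_posB : call.canonical_posB + rebuilt_len_tail]
        )
        assert rebuilt == fusion


def test_decomposition_agrees_with_bruteforce_oracle(rng):
    """p/s decomposition == exhaustive minimal-insertion enumeration on
    random uncontrolled instances (accidental homology included)."""
    for _ in range(2000):
        fusion, refA, refB, *_ = random_junction_instance(rng)
        call = classify_junction(fusion, refA, refB)
        oracle = oracle_decompose(fusion, refA, refB)
        assert oracle is not None
        mech, h, ins, posA, posB = oracle
        assert call.mechanism == mech
        assert call.mh_len == h
        assert call.ins_seq == ins
        assert (call.canonical_posA, call.canonical_posB) == (posA, posB)


def test_leftmost_canonicalization_is_anchor_shift_invariant(rng):
    """Anchors anywhere within the ambiguity window give the same call."""
    refA, refB = _mk_refs(rng)
    cutA, cutB = 200, 150
    refA = refA[: cutA - 6] + "TAGCAT" + refA[cutA:]
    refB = refB[: cutB - 6] + "TAGCAT" + refB[cutB:]
    fusion = refA[cutA - 40 : cutA] + refB[cutB : cutB + 40]
    base = classify_junction(fusion, refA, refB, anchorA=cutA - 1, anchorB=cutB)
    assert base.mh_len >= 6
    for shift in range(-base.mh_len, 1):
        shifted = classify_junction(
            fusion, refA, refB, anchorA=cutA - 1 + shift, anchorB=cutB + shift
        )
        assert shifted == base
    # and with no anchors at all
    assert classify_junction(fusion, refA, refB) == base


def test_canonicalize_breakpoints_idempotent(rng):
    for _ in range(100):
        fusion, refA, refB, _, cutA, cutB, ins = random_junction_instance(rng)
        pA, pB, ins2, h = canonicalize_breakpoints(refA, refB, cutA - 1, cutB, ins)
        again = canonicalize_breakpoints(refA, refB, pA, pB, ins2)
        assert again == (pA, pB, ins2, h)


def test_insertion_and_microhomology_cannot_tie():
    """p + s < |F| (insertion) and p + s >= |F| (homology/blunt) are
    mutually exclusive, so every call is exactly one mechanism."""
    with pytest.raises(ValueError):
        JunctionCall("insertion", 1, "GG", 0, 0, 2)
    with pytest.raises(ValueError):
        JunctionCall("microhomology", 1, "GG", 0, 0, 2)
    with pytest.raises(ValueError):
        JunctionCall("blunt", 1, "", 0, 0, 2)


def test_unanchored_junction_raises(rng):
    refA, refB = _mk_refs(rng)
    foreign = "".join(rng.choice(list("ACGT"), 40))
    with pytest.raises(UnanchoredJunctionError):
        classify_junction(foreign + refB[100:130], refA, refB)
    with pytest.raises(UnanchoredJunctionError):
        classify_junction("ACGTACGT", refA, refB)  # shorter than two anchors


def test_iupac_ambiguity_in_reference_is_mismatch(rng):
    """An N in the partner reference never matches, so homology windows are
    called conservatively."""
    refA, refB = _mk_refs(rng)
    cutA, cutB = 200, 150
    refA = refA[: cutA - 3] + "TTT" + refA[cutA:]
    refB = refB[: cutB - 3] + "TNT" + refB[cutB:]  # middle base ambiguous
    fusion = refA[cutA - 30 : cutA] + refB[cutB : cutB + 30]
    call = classify_junction(fusion, refA, refB, anchorA=cutA - 1, anchorB=cutB)
    # the shared TTT on A cannot extend through refB's N
    assert call.mh_len <= 1


def test_classify_cohort_summaries(sim_small):
    summary = classify_cohort(
        sim_small.records, sim_small.refs["chr22"], sim_small.refs["chr9"]
    )
    assert summary.n_unclassifiable == 0
    assert summary.n_classified == len(sim_small.records)
    assert abs(sum(summary.fractions.values()) - 1.0) < 1e-12
    truth = sim_small.truth
    mh = truth.loc[truth.mechanism == "microhomology", "mh_len"]
    assert summary.mh_len_median == float(mh.median())
    assert summary.mh_len_range == (int(mh.min()), int(mh.max()))


def test_classify_cohort_single_blunt():
    refA = "C" * 30 + "A" * 30
    refB = "T" * 30 + "G" * 30
    from phbreak.io_formats import BreakpointPair, PatientRecord

    rec = PatientRecord(
        "p", "CML", BreakpointPair(59, 30), junction_seq="A" * 20 + "G" * 20
    )
    summary = classify_cohort([rec], refA, refB)
    assert summary.fractions == {"microhomology": 0.0, "blunt": 1.0, "insertion": 0.0}


def test_classify_cohort_empty_errors():
    with pytest.raises(ValueError, match="no classifiable"):
        classify_cohort([], "ACGT" * 20, "ACGT" * 20)


def test_length_summaries_are_per_mechanism(rng):
    """Homology lengths {1,1,3} give median 1 and range 1-3, computed over
    microhomology junctions only (a blunt patient does not dilute them)."""
    from phbreak.io_formats import BreakpointPair, PatientRecord

    refA, refB = _mk_refs(rng, 600)
    records = []
    for i, m in enumerate([1, 1, 3, 0]):  # three homologies + one blunt
        cutA, cutB = 100 + 100 * i, 80 + 100 * i
        if m:
            refB = refB[: cutB - m] + refA[cutA - m : cutA] + refB[cutB:]
        # fix boundary bases so the realized window is exactly m
        left = "A" if refA[cutA - m - 1] != "A" else "C"
        right = "A" if refA[cutA] != "A" else "C"
        refB = refB[: cutB - m - 1] + left + refB[cutB - m : cutB] + right + refB[cutB + 1 :]
        fusion = refA[cutA - 30 : cutA] + refB[cutB : cutB + 30]
        records.append(
            PatientRecord(f"p{i}", "CML", BreakpointPair(cutA - 1, cutB), junction_seq=fusion)
        )
    summary = classify_cohort(records, refA, refB)
    assert summary.counts["microhomology"] == 3
    assert summary.counts["blunt"] == 1
    assert summary.mh_len_median == 1.0
    assert summary.mh_len_range == (1, 3)
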