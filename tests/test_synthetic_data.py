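import numpy as np
import pytest

from phbreak import (
    SimParams,
    classify_junction,
    make_toy_reference,
    simulate_cohort,
    simulate_reads,
)


def test_toy_reference_deterministic_and_seed_sensitive():
    a = make_toy_reference(seed=1)
    b = make_toy_reference(seed=1)
    c = make_toy_reference(seed=2)
    assert a.sequences == b.sequences
    assert a.sequences["chr22"] != c.sequences["chr22"]
    for region in a.catalog:
        assert region.end <= len(a.sequences[region.chrom])


def test_toy_reference_planted_motif_matches_bed():
    ref = make_toy_reference(seed=3, planted_motifs=[("CACAGTG", "chr9", 30_000)])
    chrom, start, end, name, *_ = ref.motif_bed[0]
    assert ref.sequences["chr9"][start:end] == "CACAGTG" == name
    assert (chrom, start, end) == ("chr9", 30_000, 30_007)


def test_toy_reference_rejects_bad_motifs():
    with pytest.raises(ValueError, match="out of range"):
        make_toy_reference(seed=1, planted_motifs=[("ACGT", "chr9", 10**9)])
    with pytest.raises(ValueError, match="1 kbp"):
        make_toy_reference(seed=1, region_lengths={"ABL1": 10})


def test_simulated_mechanisms_recovered_exactly(sim_small):
    """Error-free junction sequences decompose to exactly the drawn
    mechanism, homology/insert length and canonical coordinates."""
    refA, refB = sim_small.refs["chr22"], sim_small.refs["chr9"]
    for row in sim_small.truth.itertuples():
        rec = sim_small.records[int(row.Index)]
        call = classify_junction(
            rec.junction_seq, refA, refB, anchorA=row.pos22, anchorB=row.pos9
        )
        assert call.mechanism == row.mechanism
        assert call.mh_len == row.mh_len
        assert call.ins_seq == (row.ins_seq or "")
        assert call.canonical_posA == row.canon_pos22
        assert call.canonical_posB == row.canon_pos9


def test_forced_insertion_matches_neither_flank(toy_ref):
    """An insertion junction's inserted bases match neither reference
    flank, verified by exhaustive flank comparison."""
    params = SimParams(n_patients=30, mech_probs=(0.0, 0.0, 1.0), seed=9)
    res = simulate_cohort(params, toy_ref)
    for row in res.truth.itertuples():
        cut22, cut9 = row.pos22 + 1, row.pos9
        ins = row.ins_seq
        assert len(ins) >= 1
        # the insert as a block equals neither flank continuation
        assert ins != res.refs["chr22"][cut22 : cut22 + len(ins)]
        assert ins != res.refs["chr9"][cut9 - len(ins) : cut9]
        # and cannot be partially absorbed at the junction boundary
        assert ins[0] != res.refs["chr22"][cut22]
        assert ins[-1] != res.refs["chr9"][cut9 - 1]


def test_zero_imbalance_forces_perfect_balance(toy_ref):
    params = SimParams(n_patients=50, p_imbalance=0.0, seed=11)
    res = simulate_cohort(params, toy_ref)
    assert (res.truth.delta22 == 0).all()
    assert (res.truth.delta9 == 0).all()
    assert (res.truth.pos22_recip == res.truth.pos22 + 1).all()
    assert (res.truth.pos9_recip == res.truth.pos9 - 1).all()


def test_imbalance_deltas_conserved_in_emitted_coordinates(toy_ref):
    """Drawn deletion/duplication sizes equal the delta arithmetic
    recomputed from the emitted coordinates, for every patient."""
    params = SimParams(n_patients=200, p_imbalance=0.6, seed=13)
    res = simulate_cohort(params, toy_ref)
    t = res.truth
    assert (t.pos22_recip - t.pos22 - 1 == t.delta22).all()
    assert (t.pos9 - t.pos9_recip - 1 == t.delta9).all()
    assert (t.delta22 != 0).any()  # imbalances actually drawn


def test_mechanism_mixture_within_3se(toy_ref):
    params = SimParams(n_patients=2000, seed=21)
    res = simulate_cohort(params, toy_ref)
    fracs = res.truth.mechanism.value_counts(normalize=True)
    for mech, p in zip(("microhomology", "blunt", "insertion"), params.mech_probs):
        se = np.sqrt(p * (1 - p) / 2000)
        assert abs(fracs.get(mech, 0.0) - p) < 3 * se


def test_length_distributions_respect_caps(toy_ref):
    res = simulate_cohort(SimParams(n_patients=1500, seed=23), toy_ref)
    t = res.truth
    mh = t.loc[t.mechanism == "microhomology", "mh_len"]
    ins = t.loc[t.mechanism == "insertion", "ins_seq"].str.len()
    assert mh.min() >= 1 and mh.max() <= 71
    assert ins.min() >= 1 and ins.max() <= 42
    assert mh.median() == 1.0


def test_error_free_reads_are_exact_substrings(sim_small):
    reads = simulate_reads(sim_small, n_reads_per_junction=3, error_rate=0.0, seed=5)
    fused = {}
    for row in sim_small.truth.itertuples():
        cut22, cut9 = row.pos22 + 1, row.pos9
        fused[row.patient_id] = (
            sim_small.refs["chr22"][cut22 - 200 : cut22]
            + (row.ins_seq or "")
            + sim_small.refs["chr9"][cut9 : cut9 + 200]
        )
    for read in reads:
        pid = read.id.rsplit("_r", 1)[0]
        assert str(read.seq) in fused[pid]


def test_reads_deterministic_and_empty_case(sim_small):
    r1 = simulate_reads(sim_small, n_reads_per_junction=2, error_rate=0.01, seed=8)
    r2 = simulate_reads(sim_small, n_reads_per_junction=2, error_rate=0.01, seed=8)
    assert [str(a.seq) for a in r1] == [str(b.seq) for b in r2]
    assert [a.id for a in r1] == [b.id for b in r2]
    assert simulate_reads(sim_small, n_reads_per_junction=0, seed=8) == []


def test_reads_reject_impossible_geometry(sim_small):
    with pytest.raises(ValueError):
        simulate_reads(sim_small, read_len=10, min_anchor=12, seed=1)


def test_cohort_deterministic_per_seed(toy_ref):
    a = simulate_cohort(SimParams(n_patients=40, seed=3), toy_ref)
    b = simulate_cohort(SimParams(n_patients=40, seed=3), toy_ref)
    assert a.truth.equals(b.truth)
    assert a.refs == b.refs


def test_write_outputs_round_trip(tmp_path, sim_small):
    from phbreak.io_formats import read_cohort_table, read_sequences

    paths = sim_small.write_outputs(tmp_path / "sim")
    seqs = read_sequences(paths["refs"])
    assert seqs == sim_small.refs
    records = read_cohort_table(paths["cohort"])
    assert len(records) == len(sim_small.records)
    assert records[0].forward == sim_small.records[0].forward
    assert records[0].junction_seq == sim_small.records[0].junction_seq
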