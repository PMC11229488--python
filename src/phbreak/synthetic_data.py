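"""Synthetic translocation cohorts with known ground truth.

The generator emulates the situation of a t(9;22)-type fusion study: a
chr22-analog carrying three breakpoint cluster regions (minor/Major/micro)
and a chr9-analog carrying a single large acceptor region, cohorts of CML-
and ALL-analog patients with locus usage and non-uniform breakpoint
densities that differ between the groups, a junction-mechanism mixture of
microhomology / blunt / untemplated-insertion joins (the NHEJ signatures),
mostly-balanced reciprocal fusions with occasional deletions/duplications
including a >10 kbp tail, and junction-spanning reads.

Microhomology realization: the required homologous k-mer is injected into
the chr9-analog at the partner breakpoint *before* sequences are emitted,
and the bases flanking every junction are reserved so that later patients
cannot disturb them.  This guarantees each simulated junction decomposes to
exactly its drawn mechanism and length — exact ground truth rather than
approximate sampling.  All randomness flows from a single seed through
:class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io_formats import (
    BreakpointPair,
    GenomicRegion,
    PatientRecord,
    RegionCatalog,
)

__all__ = [
    "SimParams",
    "ToyReference",
    "SimResult",
    "make_toy_reference",
    "simulate_cohort",
    "simulate_reads",
    "default_density_profiles",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_SITE_RETRIES = 200


def _geometric_p_for_median(median: float) -> float:
    """p of a geometric (support >= 1) with continuous-sense median."""
    return 1.0 - 2.0 ** (-1.0 / median)


def default_density_profiles() -> dict[tuple[str, str], np.ndarray]:
    """Piecewise-constant (10-bin) breakpoint densities per region+group.

    Shapes emulate the observed clinical pattern: minor-BCR breaks pile up
    toward the 3' end of intron 1 in both groups; Major-BCR breaks lean 5'
    (intron 13) in CML and slightly less so in ALL; the ABL1-analog is
    5'-skewed in the CML-analog and 3'-skewed in the ALL-analog, which is
    what drives the between-group distribution difference.
    """
    up = np.linspace(0.3, 1.7, 10)
    profiles = {
        ("minor_BCR", "CML"): up.copy(),
        ("minor_BCR", "ALL"): up.copy(),
        ("Major_BCR", "CML"): np.linspace(1.3, 0.7, 10),
        ("Major_BCR", "ALL"): np.linspace(0.9, 1.1, 10),
        ("micro_BCR", "CML"): np.ones(10),
        ("micro_BCR", "ALL"): np.ones(10),
        ("ABL1", "CML"): np.linspace(1.5, 0.5, 10),
        ("ABL1", "ALL"): np.linspace(0.5, 1.5, 10),
    }
    return {k: v / v.sum() for k, v in profiles.items()}


def _default_locus_probs() -> dict[str, dict[str, float]]:
    # CML is almost exclusively Major-BCR (p210); ALL-analog patients are
    # mostly minor-BCR (p190) with a Major minority; micro is rare.
    return {
        "CML": {"minor_BCR": 0.02, "Major_BCR": 0.97, "micro_BCR": 0.01},
        "ALL": {"minor_BCR": 0.75, "Major_BCR": 0.24, "micro_BCR": 0.01},
    }


@dataclass
class SimParams:
    """Cohort-simulation parameters.

    Mechanism mixture and length distributions default to the values
    reported for large BCR::ABL1 cohorts: 48.6% microhomology (median 1 bp,
    max 71), 36.6% blunt, 12.4% untemplated insertion (median 2.5 bp,
    max 42).
    """

    n_patients: int = 500
    mech_probs: tuple[float, float, float] = (0.486, 0.366, 0.124)
    mh_geom_p: float = 0.5
    mh_max: int = 71
    ins_median: float = 2.5
    ins_max: int = 42
    p_all: float = 0.54  # fraction of ALL-analog patients
    locus_probs: dict = field(default_factory=_default_locus_probs)
    density_profiles: dict = field(default_factory=default_density_profiles)
    age_density_shift: float = 0.3  # adult-vs-child profile blend, minor-BCR ALL
    p_reciprocal: float = 1.0  # fraction of patients with a reciprocal fusion
    p_imbalance: float = 0.9  # pair carries >=1 nonzero delta
    p_deletion: float = 0.7  # given nonzero delta, deletion vs duplication
    imbalance_small_frac: float = 0.85
    imbalance_small_mean: float = 30.0
    imbalance_large_min: int = 100
    imbalance_large_max: int = 20_000
    # flank must exceed mh_max + caller/classifier min_anchor so that the
    # longest homology window still leaves an anchored A-side prefix
    junction_flank: int = 100
    seed: int = 0

    @property
    def mech_names(self) -> tuple[str, str, str]:
        return ("microhomology", "blunt", "insertion")

    def __post_init__(self):
        probs = np.asarray(self.mech_probs, dtype=float)
        # published cohort fractions (48.6/36.6/12.4) leave a 2.4% remainder
        # of complex/unclassifiable events; renormalize over the three
        # simple-junction mechanisms
        if probs.min() < 0 or probs.max() > 1 or not 0.9 < probs.sum() < 1.1:
            raise ValueError("mech_probs must be probabilities summing to ~1")
        self.mech_probs = tuple(probs / probs.sum())
        for group, loci in self.locus_probs.items():
            if abs(sum(loci.values()) - 1.0) > 1e-9:
                raise ValueError(f"locus_probs[{group}] must sum to 1")


@dataclass
class ToyReference:
    sequences: dict[str, str]
    catalog: RegionCatalog
    motif_bed: list[tuple] = field(default_factory=list)


DEFAULT_REGION_LENGTHS = {
    "minor_BCR": 20_000,
    "Major_BCR": 3_000,
    "micro_BCR": 1_300,
    "ABL1": 40_000,
}
# pads leave room for large reciprocal deletions/duplications and read flanks
_PAD = 22_000
_GAP = 1_000


def make_toy_reference(
    seed: int,
    region_lengths: Mapping[str, int] | None = None,
    planted_motifs: Sequence[tuple[str, str, int]] = (),
    pad: int = _PAD,
) -> ToyReference:
    """Deterministic toy two-chromosome reference with a region catalog.

    ``region_lengths`` maps minor_BCR/Major_BCR/micro_BCR/ABL1 to lengths
    (>= 1 kbp).  ``planted_motifs`` is a list of ``(pattern, chrom, start)``
    triples inserted verbatim (0-based start) and returned as BED rows.
    """
    lengths = dict(DEFAULT_REGION_LENGTHS)
    if region_lengths:
        lengths.update(region_lengths)
    for name, length in lengths.items():
        if length < 1_000:
            raise ValueError(f"region {name}: length {length} < 1 kbp")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    start = pad
    regions = []
    for name in ("minor_BCR", "Major_BCR", "micro_BCR"):
        regions.append(GenomicRegion(name, "chr22", start, start + lengths[name], "toy"))
        start += lengths[name] + _GAP
    len22 = start - _GAP + pad
    regions.append(GenomicRegion("ABL1", "chr9", pad, pad + lengths["ABL1"], "toy"))
    len9 = pad + lengths["ABL1"] + pad

    seqs = {
        "chr22": rng.choice(BASES, size=len22).tobytes().decode(),
        "chr9": rng.choice(BASES, size=len9).tobytes().decode(),
    }
    bed = []
    for pattern, chrom, pos in planted_motifs:
        pattern = pattern.upper()
        if chrom not in seqs:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if len(pattern) > len(seqs[chrom]):
            raise ValueError(f"motif {pattern!r} longer than {chrom}")
        if not 0 <= pos <= len(seqs[chrom]) - len(pattern):
            raise ValueError(f"motif position {pos} out of range on {chrom}")
        seq = seqs[chrom]
        seqs[chrom] = seq[:pos] + pattern + seq[pos + len(pattern):]
        bed.append((chrom, pos, pos + len(pattern), pattern, 0, "+"))
    return ToyReference(seqs, RegionCatalog(regions), bed)


@dataclass
class SimResult:
    """Output of :func:`simulate_cohort`.

    ``refs`` are the *final* reference sequences (after microhomology
    injection) — all downstream classification and calling must use these,
    not the pre-simulation toy sequences.
    """

    truth: pd.DataFrame
    records: list[PatientRecord]
    refs: dict[str, str]
    catalog: RegionCatalog
    retry_count: int

    def write_outputs(self, out_dir) -> dict[str, str]:
        from pathlib import Path

        from .io_formats import write_cohort_table, write_sequences

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "truth": str(out / "truth.tsv"),
            "cohort": str(out / "cohort.tsv"),
            "refs": str(out / "refs.fasta"),
            "catalog": str(out / "catalog.tsv"),
        }
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        write_cohort_table(self.records, paths["cohort"])
        write_sequences(self.refs, paths["refs"])
        with open(paths["catalog"], "w") as handle:
            handle.write("name\tchrom\tstart\tend\n")
            for region in self.catalog:
                handle.write(
                    f"{region.name}\t{region.chrom}\t{region.start + 1}\t{region.end}\n"
                )
        return paths


def _sample_from_profile(rng, region: GenomicRegion, weights: np.ndarray) -> int:
    """Draw a 0-based position from a piecewise-constant density."""
    nbins = len(weights)
    b = rng.choice(nbins, p=weights / weights.sum())
    edges = np.linspace(region.start, region.end, nbins + 1)
    lo, hi = int(edges[b]), int(edges[b + 1])
    return int(rng.integers(lo, hi))


def _random_base_not(rng, *exclude: str) -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return choices[rng.integers(len(choices))]


def _draw_imbalance_size(rng, params: SimParams) -> int:
    if rng.random() < params.imbalance_small_frac:
        return int(max(1, rng.geometric(1.0 / params.imbalance_small_mean)))
    lo = np.log10(params.imbalance_large_min)
    hi = np.log10(params.imbalance_large_max)
    return int(round(10 ** rng.uniform(lo, hi)))


def simulate_cohort(params: SimParams, ref: ToyReference) -> SimResult:
    """Simulate a cohort with exact per-patient ground truth.

    Forward junction construction: the fused sequence is
    ``chr22[:cut22] + ins + chr9[cut9:]`` where ``cut22 = pos22 + 1`` and
    ``cut9 = pos9``.  For microhomology junctions the drawn homology length
    is injected into chr9 immediately 5' of ``cut9`` (copied from the chr22
    flank) and the boundary bases are fixed so the realized homology window
    is exactly the drawn length; for blunt and insertion junctions the
    boundary bases are constrained so no accidental homology arises.  The
    drawn crossover is therefore the rightmost placement of its ambiguity
    window; ``canon_pos22``/``canon_pos9`` carry the leftmost-canonical
    coordinates used by the classifier and caller.
    """
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    chr22 = ref.sequences["chr22"]
    chr9 = bytearray(ref.sequences["chr9"], "ascii")
    catalog = ref.catalog
    abl1 = catalog["ABL1"]
    reserved: set[int] = set()
    mech_names = ("microhomology", "blunt", "insertion")
    ins_p = _geometric_p_for_median(params.ins_median)
    flank = params.junction_flank
    total_retries = 0

    rows = []
    for i in range(params.n_patients):
        group = "ALL" if rng.random() < params.p_all else "CML"
        loci = params.locus_probs[group]
        locus = list(loci)[int(rng.choice(len(loci), p=np.array(list(loci.values()))))]
        region22 = catalog[locus]
        sex = "M" if rng.random() < 0.5 else "F"
        if group == "ALL":
            age = float(rng.uniform(1, 16)) if rng.random() < 0.68 else float(rng.uniform(17, 60))
        else:
            age = float(rng.uniform(18, 75)) if rng.random() < 0.9 else float(rng.uniform(5, 17))
        mech = mech_names[int(rng.choice(3, p=np.asarray(params.mech_probs)))]

        w22 = np.asarray(params.density_profiles[(locus, group)], dtype=float)
        if (
            group == "ALL"
            and locus == "minor_BCR"
            and age > 16
            and params.age_density_shift > 0
        ):
            w22 = (1 - params.age_density_shift) * w22 + params.age_density_shift * w22[::-1]
        w9 = np.asarray(params.density_profiles[("ABL1", group)], dtype=float)

        # rejection-sample a site satisfying this mechanism's boundary
        # constraints without touching previously reserved chr9 bases
        for attempt in range(_MAX_SITE_RETRIES):
            pos22 = _sample_from_profile(rng, region22, w22)
            pos9 = _sample_from_profile(rng, abl1, w9)
            cut22, cut9 = pos22 + 1, pos9
            mh_len, ins_seq = 0, ""
            if mech == "blunt":
                need = {cut9 - 1, cut9}
                if (
                    chr22[cut22 - 1] != chr(chr9[cut9 - 1])
                    and chr22[cut22] != chr(chr9[cut9])
                ):
                    reserved |= need
                    break
            elif mech == "microhomology":
                mh_len = int(min(rng.geometric(params.mh_geom_p), params.mh_max))
                write = set(range(cut9 - mh_len, cut9))
                need = write | {cut9 - mh_len - 1, cut9}
                if need & reserved:
                    continue
                chr9[cut9 - mh_len : cut9] = chr22[cut22 - mh_len : cut22].encode()
                if chr(chr9[cut9 - mh_len - 1]) == chr22[cut22 - mh_len - 1]:
                    chr9[cut9 - mh_len - 1] = ord(
                        _random_base_not(rng, chr22[cut22 - mh_len - 1])
                    )
                if chr(chr9[cut9]) == chr22[cut22]:
                    chr9[cut9] = ord(_random_base_not(rng, chr22[cut22]))
                reserved |= need
                break
            else:  # insertion
                ins_len = int(min(rng.geometric(ins_p), params.ins_max))
                ins = [
                    "ACGT"[rng.integers(4)] for _ in range(ins_len)
                ]
                if ins_len == 1:
                    ins[0] = _random_base_not(rng, chr22[cut22], chr(chr9[cut9 - 1]))
                else:
                    ins[0] = _random_base_not(rng, chr22[cut22])
                    ins[-1] = _random_base_not(rng, chr(chr9[cut9 - 1]))
                ins_seq = "".join(ins)
                reserved |= {cut9 - 1, cut9}
                break
        else:
            raise RuntimeError(
                f"patient {i}: no admissible breakpoint site after "
                f"{_MAX_SITE_RETRIES} retries"
            )
        total_retries += attempt

        # leftmost-canonical coordinates of the forward junction
        canon22 = pos22 - mh_len
        canon9 = pos9 - mh_len

        # reciprocal fusion: adjacency (nothing lost, nothing duplicated)
        # unless the pair draws an imbalance
        has_recip = rng.random() < params.p_reciprocal
        pos22_r = pos9_r = None
        delta22 = delta9 = None
        if has_recip:
            delta22, delta9 = 0, 0
            if params.p_imbalance > 0 and rng.random() < params.p_imbalance:
                while delta22 == 0 and delta9 == 0:
                    for which in ("chr22", "chr9"):
                        if rng.random() < 0.75:
                            size = _draw_imbalance_size(rng, params)
                            sign = 1 if rng.random() < params.p_deletion else -1
                            if which == "chr22":
                                delta22 = sign * size
                            else:
                                delta9 = sign * size
                # clamp into sequence bounds (pads make clipping rare)
                lo22, hi22 = -(pos22 - 10), len(chr22) - pos22 - 10
                delta22 = int(np.clip(delta22, lo22, hi22))
                lo9, hi9 = -(len(chr9) - pos9 - 10), pos9 - 10
                delta9 = int(np.clip(delta9, lo9, hi9))
            pos22_r = pos22 + 1 + delta22
            pos9_r = pos9 - 1 - delta9

        rows.append(
            {
                "patient_id": f"P{i:05d}",
                "group": group,
                "locus": locus,
                "age_years": round(age, 1),
                "sex": sex,
                "mechanism": mech,
                "mh_len": mh_len,
                "ins_seq": ins_seq,
                "pos22": pos22,
                "pos9": pos9,
                "canon_pos22": canon22,
                "canon_pos9": canon9,
                "pos22_recip": pos22_r,
                "pos9_recip": pos9_r,
                "delta22": delta22,
                "delta9": delta9,
            }
        )

    refs_final = {"chr22": chr22, "chr9": chr9.decode()}
    chr9_str = refs_final["chr9"]

    # second pass: junction sequences are cut from the *final* references
    records = []
    for row in rows:
        cut22, cut9 = row["pos22"] + 1, row["pos9"]
        junction = (
            chr22[cut22 - flank : cut22]
            + row["ins_seq"]
            + chr9_str[cut9 : cut9 + flank]
        )
        reciprocal = None
        if row["pos22_recip"] is not None:
            reciprocal = BreakpointPair(
                row["pos22_recip"], row["pos9_recip"], kind="reciprocal"
            )
        records.append(
            PatientRecord(
                patient_id=row["patient_id"],
                diagnosis=row["group"],
                forward=BreakpointPair(row["pos22"], row["pos9"], kind="forward"),
                reciprocal=reciprocal,
                age_years=row["age_years"],
                sex=row["sex"],
                locus=row["locus"],
                junction_seq=junction,
            )
        )
    truth = pd.DataFrame(rows)
    return SimResult(truth, records, refs_final, catalog, total_retries)


def simulate_reads(
    result: SimResult,
    read_len: int = 150,
    n_reads_per_junction: int = 20,
    error_rate: float = 0.0,
    seed: int = 0,
    min_anchor: int = 12,
    include_reciprocal: bool = False,
) -> list[SeqRecord]:
    """Junction-spanning reads for every simulated patient.

    Each read covers its patient's junction with at least ``min_anchor``
    aligned bases on both partners; the split point is uniform over the
    admissible range.  Substitution errors are applied independently per
    base at ``error_rate``; reads are emitted plus-strand (both partner
    genes are modeled plus-strand).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chr22 = result.refs["chr22"]
    chr9 = result.refs["chr9"]
    pad = read_len
    reads: list[SeqRecord] = []

    def emit(name: str, head: str, tail: str, ins: str):
        fused = head + ins + tail
        if read_len > len(fused):
            raise ValueError(
                f"read_len {read_len} exceeds fused junction sequence "
                f"({len(fused)} bases)"
            )
        max_j = read_len - min_anchor - len(ins)
        if max_j < min_anchor:
            raise ValueError(
                f"{name}: insertion of {len(ins)} bases leaves no admissible "
                f"split for read_len {read_len} and min_anchor {min_anchor}"
            )
        for r in range(n_reads_per_junction):
            j = int(rng.integers(min_anchor, max_j + 1))
            start = len(head) - j
            seq = np.frombuffer(fused[start : start + read_len].encode(), dtype=np.uint8).copy()
            if error_rate > 0:
                hits = np.nonzero(rng.random(read_len) < error_rate)[0]
                for k in hits:
                    seq[k] = ord(_random_base_not(rng, chr(seq[k])))
            rec = SeqRecord(
                Seq(seq.tobytes().decode()), id=f"{name}_r{r}", description=""
            )
            rec.letter_annotations["phred_quality"] = [40] * read_len
            reads.append(rec)

    for row in result.truth.itertuples():
        cut22, cut9 = row.pos22 + 1, row.pos9
        emit(
            row.patient_id,
            chr22[cut22 - pad : cut22],
            chr9[cut9 : cut9 + pad],
            row.ins_seq or "",
        )
        if include_reciprocal and row.pos22_recip is not None:
            cut9r, cut22r = row.pos9_recip + 1, row.pos22_recip
            emit(
                f"{row.patient_id}_rec",
                chr9[cut9r - pad : cut9r],
                chr22[cut22r : cut22r + pad],
                "",
            )
    return reads
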