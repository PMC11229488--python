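"""Readers/writers for cohort tables, sequences and intervals.

Coordinate conventions
----------------------
Internally every breakpoint is a 0-based index of a single base and every
region is 0-based half-open.  All *files* (cohort TSV, BED output aside,
which is natively 0-based half-open) carry 1-based inclusive coordinates,
matching the GRCh38 notation used in the clinical literature for the
BCR and ABL1 breakpoint cluster regions.

Breakpoint semantics: for a forward (BCR::ABL1-type) fusion ``pos22`` is the
last chr22 base retained on the derivative chromosome 22 and ``pos9`` is the
first chr9 base retained.  For a reciprocal (ABL1::BCR-type) fusion ``pos9``
is the last chr9 base retained on the derivative 9 and ``pos22`` the first
chr22 base retained.  Both partner genes are modeled as plus-strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicRegion",
    "RegionCatalog",
    "BreakpointPair",
    "PatientRecord",
    "CohortFormatError",
    "SequenceFormatError",
    "default_catalog",
    "read_cohort_table",
    "write_cohort_table",
    "read_sequences",
    "write_sequences",
    "write_bed",
    "to_file_coord",
    "to_internal_coord",
]

IUPAC_CODES = set("ACGTRYSWKMBDHVN")


class CohortFormatError(ValueError):
    """Raised when a cohort table violates the documented TSV layout."""


class SequenceFormatError(ValueError):
    """Raised when a FASTA record contains non-IUPAC characters."""


def to_internal_coord(pos_1based: int) -> int:
    """Convert a 1-based file coordinate to the internal 0-based index."""
    return int(pos_1based) - 1


def to_file_coord(pos_0based: int) -> int:
    """Convert an internal 0-based index to the 1-based file coordinate."""
    return int(pos_0based) + 1


@dataclass(frozen=True)
class GenomicRegion:
    """A named region, 0-based half-open internally."""

    name: str
    chrom: str
    start: int
    end: int
    assembly: str = "GRCh38"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(
                f"region {self.name}: start ({self.start}) must be < end ({self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


class RegionCatalog:
    """A set of uniquely named :class:`GenomicRegion` objects.

    The default catalog (``default_catalog()``) carries the GRCh38 probe
    regions for the three BCR breakpoint cluster regions and the ABL1
    breakpoint area; toy catalogs built by the simulator use the same class
    with ``assembly="toy"``.
    """

    def __init__(self, regions: Iterable[GenomicRegion]):
        self._regions: dict[str, GenomicRegion] = {}
        for region in regions:
            if region.name in self._regions:
                raise ValueError(f"duplicate region name: {region.name}")
            self._regions[region.name] = region

    def __getitem__(self, name: str) -> GenomicRegion:
        return self._regions[name]

    def __contains__(self, name: str) -> bool:
        return name in self._regions

    def __iter__(self):
        return iter(self._regions.values())

    def __len__(self) -> int:
        return len(self._regions)

    @property
    def names(self) -> list[str]:
        return list(self._regions)

    def locate(self, chrom: str, pos: int) -> str | None:
        """Name of the region containing ``pos`` on ``chrom``, else None."""
        for region in self._regions.values():
            if region.chrom == chrom and region.contains(pos):
                return region.name
        return None

    def assign_locus(self, pos22: int, chrom22: str = "chr22") -> str:
        """Locus label for a chr22 breakpoint: region name or ``upstream``."""
        name = self.locate(chrom22, pos22)
        return name if name is not None else "upstream"


def default_catalog() -> RegionCatalog:
    """GRCh38 coordinates of the probe-covered breakpoint regions.

    minor BCR chr22:23,180,958-23,254,000; Major BCR chr22:23,289,491-
    23,292,664; micro BCR chr22:23,311,732-23,313,035; ABL1 (EXOSC2/ABL1
    area) chr9:130,699,582-130,855,101 -- stored 0-based half-open.
    """
    return RegionCatalog(
        [
            GenomicRegion("minor_BCR", "chr22", 23_180_957, 23_254_000),
            GenomicRegion("Major_BCR", "chr22", 23_289_490, 23_292_664),
            GenomicRegion("micro_BCR", "chr22", 23_311_731, 23_313_035),
            GenomicRegion("ABL1", "chr9", 130_699_581, 130_855_101),
        ]
    )


@dataclass(frozen=True)
class BreakpointPair:
    """One fusion's chr22/chr9 coordinate pair (internal 0-based).

    ``kind="forward"``: pos22 = last retained chr22 base, pos9 = first
    retained chr9 base (derivative 22).  ``kind="reciprocal"``: pos9 = last
    retained chr9 base, pos22 = first retained chr22 base (derivative 9).
    """

    pos22: int
    pos9: int
    kind: str = "forward"

    def __post_init__(self):
        if self.kind not in ("forward", "reciprocal"):
            raise ValueError(f"kind must be 'forward' or 'reciprocal', got {self.kind!r}")


@dataclass
class PatientRecord:
    """One patient's breakpoints and basic characteristics."""

    patient_id: str
    diagnosis: str  # "CML" or "ALL"
    forward: BreakpointPair
    reciprocal: BreakpointPair | None = None
    age_years: float | None = None
    sex: str | None = None  # "M" / "F" / None
    locus: str | None = None  # minor_BCR / Major_BCR / micro_BCR / upstream
    junction_seq: str | None = None


# Documented cohort TSV layout (1-based inclusive coordinates in the file).
COHORT_COLUMNS = [
    "patient_id",
    "diagnosis",
    "age_years",
    "sex",
    "locus",
    "pos22",
    "pos9",
    "pos22_reciprocal",
    "pos9_reciprocal",
    "junction_seq",
]
MANDATORY_COLUMNS = ["patient_id", "diagnosis", "pos22", "pos9"]


def read_cohort_table(
    path,
    catalog: RegionCatalog | None = None,
    column_map: Mapping[str, str] | None = None,
    on_bad_rows: str = "warn",
) -> list[PatientRecord]:
    """Read a cohort TSV into :class:`PatientRecord` objects.

    The file is tab-separated, UTF-8, ``#`` comments allowed; coordinates
    are 1-based inclusive and are converted to internal 0-based indices.
    ``column_map`` maps the documented column names to the names actually
    present in the file (for externally produced tables whose layout
    differs).  The locus is (re)assigned from ``catalog`` when one is given;
    a chr22 coordinate outside every catalog region is flagged ``upstream``
    with a warning.

    ``on_bad_rows``: "warn" reports rows with unparseable coordinates via
    :class:`UserWarning` and drops them; "raise" raises CohortFormatError.
    """
    if on_bad_rows not in ("warn", "raise"):
        raise ValueError("on_bad_rows must be 'warn' or 'raise'")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(
            f"cohort table {path} is missing mandatory column(s): {', '.join(missing)}"
        )

    records: list[PatientRecord] = []
    bad: list[str] = []
    for idx, row in df.iterrows():
        try:
            pos22 = to_internal_coord(int(float(row["pos22"])))
            pos9 = to_internal_coord(int(float(row["pos9"])))
        except (TypeError, ValueError):
            bad.append(f"row {idx + 2}: unparseable pos22/pos9 ({row['pos22']!r}, {row['pos9']!r})")
            continue
        rec_pair = None
        r22, r9 = row.get("pos22_reciprocal"), row.get("pos9_reciprocal")
        if _present(r22) and _present(r9):
            try:
                rec_pair = BreakpointPair(
                    to_internal_coord(int(float(r22))),
                    to_internal_coord(int(float(r9))),
                    kind="reciprocal",
                )
            except (TypeError, ValueError):
                bad.append(f"row {idx + 2}: unparseable reciprocal coordinates")
                continue
        age = float(row["age_years"]) if _present(row.get("age_years")) else None
        sex = row.get("sex") if _present(row.get("sex")) else None
        junction = row.get("junction_seq") if _present(row.get("junction_seq")) else None
        locus = row.get("locus") if _present(row.get("locus")) else None
        if catalog is not None:
            assigned = catalog.assign_locus(pos22)
            if assigned == "upstream":
                warnings.warn(
                    f"patient {row['patient_id']}: chr22 coordinate "
                    f"{to_file_coord(pos22)} falls outside every catalog region; "
                    "locus flagged 'upstream'",
                    UserWarning,
                    stacklevel=2,
                )
            locus = assigned
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                diagnosis=str(row["diagnosis"]),
                forward=BreakpointPair(pos22, pos9, kind="forward"),
                reciprocal=rec_pair,
                age_years=age,
                sex=sex,
                locus=locus,
                junction_seq=junction.upper() if junction else None,
            )
        )
    if bad:
        msg = "; ".join(bad)
        if on_bad_rows == "raise":
            raise CohortFormatError(msg)
        warnings.warn(f"skipped {len(bad)} unparseable row(s): {msg}", UserWarning, stacklevel=2)
    return records


def _present(value) -> bool:
    return value is not None and not pd.isna(value) and str(value).strip() != ""


def write_cohort_table(records: Iterable[PatientRecord], path) -> None:
    """Write records to the documented TSV layout (1-based coordinates)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "diagnosis": rec.diagnosis,
                "age_years": "" if rec.age_years is None else rec.age_years,
                "sex": rec.sex or "",
                "locus": rec.locus or "",
                "pos22": to_file_coord(rec.forward.pos22),
                "pos9": to_file_coord(rec.forward.pos9),
                "pos22_reciprocal": ""
                if rec.reciprocal is None
                else to_file_coord(rec.reciprocal.pos22),
                "pos9_reciprocal": ""
                if rec.reciprocal is None
                else to_file_coord(rec.reciprocal.pos9),
                "junction_seq": rec.junction_seq or "",
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sequences(path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}; validates IUPAC alphabet."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        for i, base in enumerate(seq):
            if base not in IUPAC_CODES:
                raise SequenceFormatError(
                    f"record {record.id}: non-IUPAC character {base!r} at position {i + 1}"
                )
        sequences[record.id] = seq
    return sequences


def write_sequences(sequences: Mapping[str, str], path, width: int = 80) -> None:
    """Write {name: sequence} as FASTA (uppercased)."""
    records = [
        SeqRecord(Seq(str(seq).upper()), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write (chrom, start, end, name[, score[, strand]]) tuples as BED.

    BED is natively 0-based half-open, so internal coordinates are written
    unchanged.
    """
    with open(path, "w") as handle:
        for row in intervals:
            handle.write("\t".join(str(x) for x in row) + "\n")
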