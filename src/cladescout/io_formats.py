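"""File formats and shared domain types.

Everything external is plain text: FASTA for sequences and tab-delimited
UTF-8 tables with a header row for metadata, occurrence matrices, primer
tables and niche reports. ``NA`` marks a missing value in every table.

Coordinate convention
---------------------
All sequence coordinates anywhere in this package are **0-based,
half-open** ``[start, end)``.  Region boundaries, primer footprints and
predicted amplicons all follow this single convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: IUPAC DNA alphabet accepted on input (unambiguous bases + ambiguity codes).
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

#: Canonical order of rRNA operon regions, 5' to 3'.
REGION_ORDER = ("SSU18S", "ITS1", "r5_8S", "ITS2", "LSU28S")

#: Conserved-gene regions (mutate slowly; flank the variable spacers).
GENE_REGIONS = frozenset({"SSU18S", "r5_8S", "LSU28S"})

MISSING = "NA"


class FormatError(ValueError):
    """A file does not conform to its declared external format."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


class NotDeterminedError(RuntimeError):
    """A statistic cannot be computed (e.g. a group with zero occurrences).

    Mirrors the 'nd' (not determined) entries of per-group niche reports.
    """


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def _check_alphabet(sequence: str, who: str) -> None:
    bad = set(sequence) - IUPAC_DNA
    if bad:
        raise ValidationError(
            f"{who}: sequence contains non-IUPAC characters {sorted(bad)!r}"
        )


@dataclass
class OtuRecord:
    """An ITS OTU representative sequence with per-sample read counts."""

    otu_id: str
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.otu_id:
            raise ValidationError("otu_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.otu_id}: empty sequence")
        self.sequence = self.sequence.upper()
        _check_alphabet(self.sequence, self.otu_id)
        for sample, n in self.counts.items():
            if n < 0:
                raise ValidationError(
                    f"{self.otu_id}: negative count for sample {sample!r}"
                )

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class ReferenceRecord:
    """A named reference sequence (a species with a Latin binomial)."""

    ref_id: str
    binomial: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.binomial:
            raise ValidationError(f"{self.ref_id}: empty binomial")
        self.sequence = self.sequence.upper()
        _check_alphabet(self.sequence, self.ref_id)


@dataclass
class OperonAnnotation:
    """Region coordinates (18S, ITS1, 5.8S, ITS2, 28S) on a template.

    ``regions`` is an ordered list of ``(name, start, end)`` in 0-based
    half-open coordinates; regions are contiguous, non-overlapping, appear
    in operon order and jointly cover ``[0, len(sequence))``.
    """

    template_id: str
    sequence: str
    regions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        _check_alphabet(self.sequence, self.template_id)
        names = [name for name, _, _ in self.regions]
        order = [r for r in REGION_ORDER if r in names]
        if names != order or len(set(names)) != len(names):
            raise ValidationError(
                f"{self.template_id}: regions must appear once each, in "
                f"operon order {REGION_ORDER}; got {names}"
            )
        pos = 0
        for name, start, end in self.regions:
            if start != pos or end <= start:
                raise ValidationError(
                    f"{self.template_id}: region {name} [{start},{end}) is not "
                    f"contiguous with the previous region (expected start {pos})"
                )
            pos = end
        if pos != len(self.sequence):
            raise ValidationError(
                f"{self.template_id}: regions cover [0,{pos}) but the sequence "
                f"has length {len(self.sequence)}"
            )

    def region(self, name: str) -> tuple[int, int]:
        for rname, start, end in self.regions:
            if rname == name:
                return start, end
        raise KeyError(f"{self.template_id}: no region {name!r}")

    def region_sequence(self, name: str) -> str:
        start, end = self.region(name)
        return self.sequence[start:end]

    def region_of(self, position: int) -> str:
        """Name of the region containing ``position``."""
        for rname, start, end in self.regions:
            if start <= position < end:
                return rname
        raise ValidationError(
            f"{self.template_id}: position {position} outside [0,{len(self.sequence)})"
        )


#: Numeric environmental predictors, in report order.
NUMERIC_SITE_COLUMNS = ("MAT", "MAP", "pH", "soil_C", "soil_P", "fire_time")
SITE_COLUMNS = ("sample_id",) + NUMERIC_SITE_COLUMNS + ("biome", "region")


@dataclass
class SiteMetadata:
    """Environmental metadata for one site; NaN marks a missing value."""

    sample_id: str
    MAT: float
    MAP: float
    pH: float
    soil_C: float
    soil_P: float
    fire_time: float
    biome: str | None
    region: str | None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not math.isnan(self.pH) and not 0.0 <= self.pH <= 14.0:
            raise ValidationError(
                f"{self.sample_id}: pH {self.pH} outside [0, 14]"
            )
        if not math.isnan(self.MAP) and self.MAP < 0:
            raise ValidationError(f"{self.sample_id}: negative MAP {self.MAP}")
        if not math.isnan(self.fire_time) and self.fire_time < 0:
            raise ValidationError(
                f"{self.sample_id}: negative fire_time {self.fire_time}"
            )


@dataclass
class OccurrenceMatrix:
    """Site x OTU occurrence table (binary presence or counts, all >= 0).

    Backed by a :class:`pandas.DataFrame` with sample ids as the index and
    OTU ids as columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates or self.table.columns.has_duplicates:
            raise ValidationError("duplicate sample or OTU ids in occurrence matrix")
        if (self.table.to_numpy() < 0).any():
            raise ValidationError("occurrence matrix has negative entries")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def otus(self) -> list[str]:
        return list(self.table.columns)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta_records(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTA into ``[(id, description, sequence), ...]``.

    The id is the first whitespace-delimited token of the header, the
    description the remainder.  Order is preserved, sequences upper-cased
    with whitespace stripped.  Raises :class:`FormatError` for an empty
    file, a file that does not start with a header line (the offending
    line is named) or duplicate ids.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    records: list[tuple[str, str, list[str]]] = []
    seen_any = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        seen_any = True
        if line.startswith(">"):
            tokens = line[1:].split(maxsplit=1)
            if not tokens:
                raise FormatError(f"{path}:{lineno}: empty FASTA header")
            header = tokens[0]
            description = tokens[1] if len(tokens) > 1 else ""
            records.append((header, description, []))
        else:
            if not records:
                raise FormatError(
                    f"{path}:{lineno}: expected a '>' header line, got {line[:30]!r}"
                )
            records[-1][2].append(line.upper())
    if not seen_any:
        raise FormatError(f"{path}: empty FASTA file")
    ids = [rid for rid, _, _ in records]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise FormatError(f"{path}: duplicate FASTA ids {dups}")
    return [(rid, desc, "".join(chunks)) for rid, desc, chunks in records]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` (see read_fasta_records)."""
    return [(rid, seq) for rid, _, seq in read_fasta_records(path)]


def write_fasta(
    records: Iterable[tuple[str, str] | tuple[str, str, str]],
    path: str | Path,
    width: int = 80,
) -> None:
    """Write ``(id, seq)`` or ``(id, description, seq)`` tuples as FASTA."""
    with open(path, "w") as fh:
        for record in records:
            if len(record) == 3:
                rid, description, seq = record
                header = f">{rid} {description}".rstrip()
            else:
                rid, seq = record
                header = f">{rid}"
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Site metadata table
# ---------------------------------------------------------------------------


def read_site_table(path: str | Path) -> list[SiteMetadata]:
    """Read a tab-delimited site metadata table.

    Unparseable numeric cells become NaN (their count is logged); a missing
    mandatory column raises :class:`FormatError` naming it; invariant
    violations (pH outside [0, 14], negative MAP / fire_time) raise
    :class:`ValidationError`.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    for column in SITE_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"{path}: missing mandatory column {column!r}")
    n_unparseable = 0
    records: list[SiteMetadata] = []
    for _, row in frame.iterrows():
        values: dict[str, float] = {}
        for column in NUMERIC_SITE_COLUMNS:
            cell = row[column]
            if pd.isna(cell):
                values[column] = math.nan
                continue
            try:
                values[column] = float(cell)
            except ValueError:
                values[column] = math.nan
                n_unparseable += 1
        records.append(
            SiteMetadata(
                sample_id=str(row["sample_id"]),
                biome=None if pd.isna(row["biome"]) else str(row["biome"]),
                region=None if pd.isna(row["region"]) else str(row["region"]),
                **values,
            )
        )
    if n_unparseable:
        logger.warning("%s: %d unparseable numeric cells treated as missing", path, n_unparseable)
    return records


def site_table_to_frame(records: Sequence[SiteMetadata]) -> pd.DataFrame:
    """Site metadata as a DataFrame indexed by sample_id."""
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            **{c: [getattr(r, c) for r in records] for c in NUMERIC_SITE_COLUMNS},
            "biome": [r.biome for r in records],
            "region": [r.region for r in records],
        }
    )
    return frame.set_index("sample_id")


def write_site_table(records: Sequence[SiteMetadata], path: str | Path) -> None:
    frame = site_table_to_frame(records).reset_index()
    frame.to_csv(path, sep="\t", index=False, na_rep=MISSING)


# ---------------------------------------------------------------------------
# Occurrence matrix
# ---------------------------------------------------------------------------


def read_occurrence_matrix(path: str | Path) -> OccurrenceMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    return OccurrenceMatrix(table)


def write_occurrence_matrix(matrix: OccurrenceMatrix, path: str | Path) -> None:
    matrix.table.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Primer table
# ---------------------------------------------------------------------------

PRIMER_TABLE_COLUMNS = (
    "target_id",
    "direction",
    "primer_seq",
    "length",
    "Tm",
    "GC_pct",
    "three_prime_hits",
    "distance_to_flank",
    "universal_partner",
    "amplified_gene",
)


def write_primer_table(pairs: Sequence, path: str | Path) -> None:
    """Write primer pairs as TSV (one row per specific/universal pairing)."""
    rows = []
    for pair in pairs:
        cand = pair.specific
        rows.append(
            {
                "target_id": cand.target_id,
                "direction": cand.direction,
                "primer_seq": cand.sequence,
                "length": len(cand.sequence),
                "Tm": round(cand.tm, 2),
                "GC_pct": round(cand.gc_pct, 2),
                "three_prime_hits": cand.three_prime_hits,
                "distance_to_flank": cand.flank_distance,
                "universal_partner": pair.universal_name,
                "amplified_gene": pair.amplified_gene,
            }
        )
    frame = pd.DataFrame(rows, columns=PRIMER_TABLE_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_primer_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in PRIMER_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing primer-table columns {missing}")
    return frame


# ---------------------------------------------------------------------------
# Small auxiliary tables (truth labels, region annotations)
# ---------------------------------------------------------------------------


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    """Write otu_id -> clade_id truth labels as a two-column TSV."""
    frame = pd.DataFrame(sorted(labels.items()), columns=["otu_id", "clade_id"])
    frame.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns) != ["otu_id", "clade_id"]:
        raise FormatError(f"{path}: expected columns otu_id, clade_id")
    return dict(zip(frame["otu_id"], frame["clade_id"]))


def write_annotations(annotations: Mapping[str, OperonAnnotation], path: str | Path) -> None:
    rows = [
        {"template_id": ann.template_id, "region": name, "start": start, "end": end}
        for ann in annotations.values()
        for name, start, end in ann.regions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path, sequences: Mapping[str, str]) -> dict[str, OperonAnnotation]:
    """Re-attach region coordinates (TSV) to template sequences."""
    frame = pd.read_csv(path, sep="\t", dtype={"template_id": str, "region": str})
    annotations: dict[str, OperonAnnotation] = {}
    for template_id, group in frame.groupby("template_id", sort=False):
        if template_id not in sequences:
            raise FormatError(f"{path}: no sequence for template {template_id!r}")
        regions = [
            (row["region"], int(row["start"]), int(row["end"]))
            for _, row in group.iterrows()
        ]
        annotations[str(template_id)] = OperonAnnotation(
            str(template_id), sequences[str(template_id)], regions
        )
    return annotations
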