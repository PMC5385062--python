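"""Construct assembly and overlap-based initial chimera control.

Long 18S-ITS-28S constructs are chained from a pyrosequenced ITS fragment
and Sanger reads of the flanking genes.  Because neighbouring reads must
overlap, the identity of each suffix-prefix overlap is itself a chimera
check: a read pair whose best dovetail overlap is long but clearly below
near-identity (default >= 30 bases at < 97% identity) is flagged instead
of merged.  Overlaps are gapless (sliding dovetail), consistent with
substitution-dominated Sanger/pyrosequencing consensus reads after quality
trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import FormatError, ValidationError, read_fasta_records, write_fasta
from .primer_design import reverse_complement

__all__ = [
    "ReadSegment",
    "OverlapResult",
    "ConstructReport",
    "AssemblyParams",
    "overlap_consistency",
    "assemble_construct",
    "read_read_segments",
    "write_read_segments",
]

#: Assembly order of claimed regions, 5' to 3'.
REGION_RANK = {"SSU18S": 0, "ITS": 1, "LSU28S": 2}


@dataclass
class ReadSegment:
    read_id: str
    sequence: str
    claimed_region: str  # SSU18S | ITS | LSU28S
    source: str = "sanger"  # sanger | pyrosequencing

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.read_id}: empty sequence")
        if self.claimed_region not in REGION_RANK:
            raise ValidationError(
                f"{self.read_id}: unknown claimed_region {self.claimed_region!r}"
            )
        self.sequence = self.sequence.upper()


@dataclass(frozen=True)
class OverlapResult:
    overlap: int
    identity: float
    status: str  # ok | chimera_flag | no_overlap
    reverse_complemented: bool = False


@dataclass
class AssemblyParams:
    min_overlap: int = 30
    min_identity: float = 0.97


@dataclass
class ConstructReport:
    status: str  # ok | chimera_flag | no_overlap | conflict
    sequence: str | None = None
    segment_order: list[str] = field(default_factory=list)
    offsets: list[int] = field(default_factory=list)
    overlaps: list[OverlapResult] = field(default_factory=list)


def _best_dovetail(seq_a: str, seq_b: str) -> tuple[int, int]:
    """Best gapless suffix(A)/prefix(B) overlap by match - mismatch score.

    Returns ``(overlap_length, matches)``; ties prefer the longer overlap.
    """
    a = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
    best_len, best_matches, best_score = 0, 0, 0
    for length in range(1, min(a.size, b.size) + 1):
        matches = int((a[a.size - length :] == b[:length]).sum())
        score = 2 * matches - length  # matches - mismatches
        if score > best_score or (score == best_score and length > best_len):
            best_len, best_matches, best_score = length, matches, score
    return best_len, best_matches


def overlap_consistency(
    seg_a: ReadSegment | str,
    seg_b: ReadSegment | str,
    min_overlap: int = 30,
    min_identity: float = 0.97,
) -> OverlapResult:
    """Score the suffix-prefix overlap of A against B (both orientations of B).

    ``ok`` when the best overlap is at least ``min_overlap`` bases at
    ``min_identity`` or better; ``chimera_flag`` when a substantial overlap
    exists but its identity falls below the bar; ``no_overlap`` otherwise.
    """
    a = seg_a.sequence if isinstance(seg_a, ReadSegment) else seg_a.upper()
    b = seg_b.sequence if isinstance(seg_b, ReadSegment) else seg_b.upper()
    if not a or not b:
        raise ValidationError("overlap_consistency: empty segment")
    candidates = []
    for flipped, b_oriented in ((False, b), (True, reverse_complement(b))):
        length, matches = _best_dovetail(a, b_oriented)
        candidates.append((2 * matches - length, length, matches, flipped))
    score, length, matches, flipped = max(candidates, key=lambda t: (t[0], t[1]))
    identity = matches / length if length else 0.0
    if length < min_overlap:
        status = "no_overlap"
    elif identity >= min_identity:
        status = "ok"
    else:
        status = "chimera_flag"
    return OverlapResult(
        overlap=length, identity=identity, status=status, reverse_complemented=flipped
    )


def assemble_construct(
    segments: Sequence[ReadSegment],
    params: AssemblyParams | None = None,
) -> ConstructReport:
    """Chain 18S -> ITS -> 28S segments into one construct.

    Segments are ordered by claimed region (input order is irrelevant);
    consecutive pairs must pass :func:`overlap_consistency`.  Any flagged
    overlap aborts the merge with status ``chimera_flag``; a missing
    overlap yields ``no_overlap``.  Where bases disagree inside an accepted
    overlap, the Sanger segment wins (higher per-base quality than the
    pyrosequenced fragment).  Two segments claiming the same region with
    different sequences yield ``conflict``.
    """
    params = params or AssemblyParams()
    if not 2 <= len(segments) <= 4:
        raise ValidationError("assemble_construct: expected 2-4 segments")
    by_region: dict[str, ReadSegment] = {}
    for segment in segments:
        other = by_region.get(segment.claimed_region)
        if other is not None:
            if other.sequence != segment.sequence:
                return ConstructReport(status="conflict")
            continue  # identical duplicate claim is harmless
        by_region[segment.claimed_region] = segment
    ordered = sorted(by_region.values(), key=lambda s: REGION_RANK[s.claimed_region])
    merged = ordered[0].sequence
    merged_source_is_sanger = ordered[0].source == "sanger"
    offsets = [0]
    overlaps: list[OverlapResult] = []
    for nxt in ordered[1:]:
        result = overlap_consistency(
            merged, nxt.sequence, params.min_overlap, params.min_identity
        )
        overlaps.append(result)
        if result.status != "ok":
            return ConstructReport(
                status=result.status,
                segment_order=[s.read_id for s in ordered],
                overlaps=overlaps,
            )
        incoming = (
            reverse_complement(nxt.sequence)
            if result.reverse_complemented
            else nxt.sequence
        )
        offset = len(merged) - result.overlap
        offsets.append(offset)
        if nxt.source == "sanger" and not merged_source_is_sanger:
            # resolve overlap disagreements in favour of the Sanger read
            merged = merged[:offset] + incoming
        else:
            merged = merged + incoming[result.overlap :]
        merged_source_is_sanger = nxt.source == "sanger"
    return ConstructReport(
        status="ok",
        sequence=merged,
        segment_order=[s.read_id for s in ordered],
        offsets=offsets,
        overlaps=overlaps,
    )


def read_read_segments(path) -> dict[str, list[ReadSegment]]:
    """Read segment FASTA grouped by construct.

    Headers carry key=value metadata, e.g.
    ``>read1 construct=otu_00_01 region=SSU18S source=sanger``.
    """
    constructs: dict[str, list[ReadSegment]] = {}
    for read_id, description, sequence in read_fasta_records(path):
        meta = dict(
            token.split("=", 1) for token in description.split() if "=" in token
        )
        for key in ("construct", "region"):
            if key not in meta:
                raise FormatError(f"{path}: read {read_id!r} lacks {key}= metadata")
        segment = ReadSegment(
            read_id=read_id,
            sequence=sequence,
            claimed_region=meta["region"],
            source=meta.get("source", "sanger"),
        )
        constructs.setdefault(meta["construct"], []).append(segment)
    return constructs


def write_read_segments(constructs: dict[str, list[ReadSegment]], path) -> None:
    records = [
        (
            segment.read_id,
            f"construct={construct_id} region={segment.claimed_region} "
            f"source={segment.source}",
            segment.sequence,
        )
        for construct_id, segments in constructs.items()
        for segment in segments
    ]
    write_fasta(records, path)
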